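"""Sequence-similarity statistics by inheritance mode.

Summarizes DNA percent identity (PID) of ohnolog pairs into the six
mode x similarity-bin categories, compares modes with a Welch two-sample
t-test, and produces histograms scaled to integrate to 1 for cross-mode
comparison.  The per-gene convention — each pair contributes its PID twice,
once per member gene — is the default, so that reported n equals twice the
pair count; a per-pair mode is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import InheritanceMode
from .ohnolog_calling import PID_BINS, OhnologPair, bin_pid

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WelchResult:
    """Welch two-sample t-test with unequal variances."""

    t: float
    df: float
    p: float
    mean_x: float
    mean_y: float
    n_x: int
    n_y: int

    def format_p(self) -> str:
        """Human-readable p, reported as '< 2.2e-16' below that floor."""
        return "< 2.2e-16" if self.p < 2.2e-16 else f"{self.p:.4g}"


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch's t-test: t = (mx - my) / sqrt(sx^2/nx + sy^2/ny), with
    Welch-Satterthwaite degrees of freedom and a two-sided p-value.

    With both sample variances zero and equal means, t is defined as 0 and
    p as 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError(f"need >= 2 observations per sample, got {nx} and {ny}")
    mx, my = float(np.mean(x)), float(np.mean(y))
    vx, vy = float(np.var(x, ddof=1)), float(np.var(y, ddof=1))
    if vx == 0.0 and vy == 0.0:
        if mx == my:
            return WelchResult(0.0, float(nx + ny - 2), 1.0, mx, my, nx, ny)
        raise ValueError("both variances zero with unequal means: t undefined")
    se2x, se2y = vx / nx, vy / ny
    se = math.sqrt(se2x + se2y)
    t = (mx - my) / se
    df = (se2x + se2y) ** 2 / (se2x**2 / (nx - 1) + se2y**2 / (ny - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(t, df, p, mx, my, nx, ny)


def welch_confidence_interval(
    x: Sequence[float], y: Sequence[float], confidence: float = 0.95
) -> tuple[float, float]:
    """Confidence interval for mean(x) - mean(y) under the Welch test."""
    res = welch_t_test(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    se = math.sqrt(np.var(x, ddof=1) / len(x) + np.var(y, ddof=1) / len(y))
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, res.df))
    diff = res.mean_x - res.mean_y
    return diff - tcrit * se, diff + tcrit * se


def per_gene_pid_vectors(
    pairs: Iterable[OhnologPair], per_gene: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """(disomic, tetrasomic) PID vectors.

    With ``per_gene`` (default) each pair contributes its PID twice — once per
    member gene — so vector lengths equal twice the pair counts, matching the
    per-ohnolog reporting convention.  Pairs with missing PID are skipped with
    a warning.
    """
    reps = 2 if per_gene else 1
    dis: list[float] = []
    tet: list[float] = []
    for pair in pairs:
        if math.isnan(pair.pid):
            logger.warning("pair (%s, %s): missing pid; skipped", pair.gene_a, pair.gene_b)
            continue
        target = tet if pair.mode is InheritanceMode.TETRASOMIC else dis
        target.extend([pair.pid] * reps)
    return np.asarray(dis, dtype=float), np.asarray(tet, dtype=float)


def summarize_bins(pairs: Iterable[OhnologPair]) -> pd.DataFrame:
    """Six-category summary: pair count and within-mode percentage per
    (inheritance mode x PID bin).

    Returns a DataFrame with columns mode, bin, count, percent (unrounded) and
    percent_rounded (nearest integer, the report convention).  Percentages for
    an empty mode are NaN.
    """
    counts = {
        (mode.value, b): 0 for mode in InheritanceMode for b in PID_BINS
    }
    for pair in pairs:
        if math.isnan(pair.pid):
            continue
        counts[(pair.mode.value, bin_pid(pair.pid))] += 1
    rows = []
    for mode in InheritanceMode:
        total = sum(counts[(mode.value, b)] for b in PID_BINS)
        for b in PID_BINS:
            c = counts[(mode.value, b)]
            pct = 100.0 * c / total if total else float("nan")
            rows.append(
                {
                    "mode": mode.value,
                    "bin": b,
                    "count": c,
                    "percent": pct,
                    "percent_rounded": int(round(pct)) if total else None,
                    "mode_total": total,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScaledHistogram:
    """Histogram normalized to integrate to 1 (densities in 1/PID units)."""

    bin_edges: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        widths = np.diff(self.bin_edges)
        total = float(np.sum(self.density * widths))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"histogram does not integrate to 1: {total}")


def scaled_histogram(
    values: Sequence[float], bin_width: float, lo: float | None = None, hi: float | None = None
) -> ScaledHistogram:
    """Density histogram with fixed-width bins: density = count / (n x width)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot histogram an empty vector")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = float(np.min(values)) if lo is None else lo
    hi = float(np.max(values)) if hi is None else hi
    n_bins = max(1, int(math.ceil((hi - lo) / bin_width - 1e-12)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, edges = np.histogram(values, bins=edges if n_bins > 1 or hi > lo else 1)
    density = counts / (values.size * np.diff(edges))
    return ScaledHistogram(bin_edges=edges, density=density)


def pid_mode_report(pairs: Sequence[OhnologPair], per_gene: bool = True) -> dict:
    """Headline similarity contrast: per-mode mean PID, n, and Welch test
    (disomic vs tetrasomic), as a plain dict for reporting."""
    dis, tet = per_gene_pid_vectors(pairs, per_gene=per_gene)
    res = welch_t_test(dis, tet)
    return {
        "mean_pid_disomic": res.mean_x,
        "n_disomic": res.n_x,
        "mean_pid_tetrasomic": res.mean_y,
        "n_tetrasomic": res.n_y,
        "welch_t": res.t,
        "welch_df": res.df,
        "welch_p": res.p,
    }


def per_block_bin_shares(pairs: Iterable[OhnologPair]) -> pd.DataFrame:
    """Per homeolog block pair, the share of its ohnolog pairs in each PID bin
    (tetrasomic-region box-plot analogue; useful for spotting blocks such as
    Omy01q-Omy23 whose >95% share is depressed)."""
    rows = []
    by_block: dict[str, list[OhnologPair]] = {}
    for p in pairs:
        if p.block_label and not math.isnan(p.pid):
            by_block.setdefault(p.block_label, []).append(p)
    for label in sorted(by_block):
        members = by_block[label]
        n = len(members)
        for b in PID_BINS:
            c = sum(1 for p in members if bin_pid(p.pid) == b)
            rows.append(
                {"block_label": label, "bin": b, "count": c, "share": c / n, "n": n}
            )
    return pd.DataFrame(rows)
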