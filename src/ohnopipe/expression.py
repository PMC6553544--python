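"""Expression divergence between ohnolog pair members, and cross-type DE.

Works from a gene-level count matrix (genes x samples, integer reads) with a
two-factor sample design: cross type (AxA = two anadromous parents, RxR = two
resident parents) and sex.  Counts are normalized by median-of-ratios size
factors.  Within each of seven cross x sex sample subsets, the expression
divergence of an ohnolog pair is the absolute log2 fold change between the
subset-mean normalized counts of its two member genes; divergence is then
contrasted between disomic and tetrasomic pairs with a Welch t-test.

Cross-type differential expression uses a deliberately simple two-group
negative-binomial Wald test (method-of-moments dispersion pooled across
groups, sex handled by stratified mean-centering), with Benjamini-Hochberg
adjustment and significance at adjusted p < 0.1.  It is a transparent
in-repo engine meant for direction and error-rate fidelity, not a shrinkage
GLM.
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
from .ohnolog_calling import OhnologPair
from .similarity_stats import WelchResult, welch_confidence_interval, welch_t_test

logger = logging.getLogger(__name__)

CROSS_LEVELS = ("AxA", "RxR")
SEX_LEVELS = ("F", "M")

#: the seven cross x sex contrasts reported for pair divergence
SUBSETS: tuple[tuple[str | None, str | None], ...] = (
    ("AxA", "F"),
    ("AxA", "M"),
    ("AxA", None),
    ("RxR", "F"),
    ("RxR", "M"),
    ("RxR", None),
    (None, None),
)


def subset_label(cross: str | None, sex: str | None) -> str:
    return f"{cross or 'Both'}-{sex or 'All'}"


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a genes x samples count matrix: unique ids, non-negative ints."""
    if counts.index.has_duplicates:
        raise ValueError("duplicate gene ids in count matrix")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample ids in count matrix")
    values = counts.to_numpy()
    if (values < 0).any():
        raise ValueError("negative entries in count matrix")
    return counts


def validate_meta(meta: pd.DataFrame, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Check sample metadata (columns: sample_id, cross, sex)."""
    required = {"sample_id", "cross", "sex"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    bad_cross = set(meta["cross"]) - set(CROSS_LEVELS)
    if bad_cross:
        raise ValueError(f"unknown cross levels {sorted(bad_cross)}; expected {CROSS_LEVELS}")
    bad_sex = set(meta["sex"]) - set(SEX_LEVELS)
    if bad_sex:
        raise ValueError(f"unknown sex levels {sorted(bad_sex)}; expected {SEX_LEVELS}")
    if counts is not None:
        missing = set(counts.columns) - set(meta["sample_id"])
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
    return meta


def select_samples(
    meta: pd.DataFrame, cross: str | None = None, sex: str | None = None
) -> list[str]:
    """Sample ids matching a cross x sex selector (None = all levels)."""
    mask = pd.Series(True, index=meta.index)
    if cross is not None:
        mask &= meta["cross"] == cross
    if sex is not None:
        mask &= meta["sex"] == sex
    return list(meta.loc[mask, "sample_id"])


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    For each gene with all-positive counts, form the geometric mean across
    samples; each sample's factor is the median over those reference genes of
    count / geometric mean.  When no gene is positive in every sample, either
    raise (default) or, with ``pseudo_reference``, fall back to computing the
    geometric mean over positive entries only.
    """
    validate_counts(counts)
    values = counts.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if all_positive.any():
        ref = values[all_positive]
        log_gmean = np.log(ref).mean(axis=1)
    else:
        if not pseudo_reference:
            raise ValueError(
                "no gene has positive counts in every sample; rerun with "
                "pseudo_reference=True to use a positive-entry geometric mean"
            )
        with np.errstate(divide="ignore"):
            logv = np.where(values > 0, np.log(values), np.nan)
        log_gmean_all = np.nanmean(logv, axis=1)
        usable = np.isfinite(log_gmean_all)
        if not usable.any():
            raise ValueError("count matrix has no nonzero gene")
        ref = values[usable]
        log_gmean = log_gmean_all[usable]
    gmean = np.exp(log_gmean)
    with np.errstate(invalid="ignore"):
        ratios = np.where(ref > 0, ref / gmean[:, None], np.nan)
    factors = np.nanmedian(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts divided by per-sample size factors."""
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def filter_min_total(counts: pd.DataFrame, min_total: int = 5) -> pd.DataFrame:
    """Keep genes with at least ``min_total`` reads summed across the samples
    present in the matrix (applied per tested subset)."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    return counts.loc[counts.sum(axis=1) >= min_total]


@dataclass(frozen=True)
class PairDivergence:
    """|log2 fold change| between the two members of one ohnolog pair,
    within one cross x sex sample subset."""

    gene_a: str
    gene_b: str
    mode: InheritanceMode
    subset: str
    abs_log2fc: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.abs_log2fc) and self.abs_log2fc >= 0):
            raise ValueError(f"abs_log2fc must be finite and >= 0: {self.abs_log2fc}")


def pair_abs_log2fc(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    pairs: Iterable[OhnologPair],
    cross: str | None = None,
    sex: str | None = None,
    pseudocount: float = 0.5,
    min_total: int = 5,
) -> list[PairDivergence]:
    """Per-pair |log2FC| over one cross x sex subset.

    The subset's columns are re-normalized by their own size factors and
    genes failing the >= ``min_total`` read filter (summed over the subset's
    samples) are excluded; a pair is reported only when both members survive.
    abs_log2fc = |log2((mean_a + pseudocount) / (mean_b + pseudocount))| over
    subset-mean normalized counts.
    """
    validate_meta(meta, counts)
    samples = select_samples(meta, cross, sex)
    if not samples:
        raise ValueError(f"subset {subset_label(cross, sex)!r} selects no samples")
    sub = filter_min_total(counts[samples], min_total)
    norm = normalize(sub)
    means = norm.mean(axis=1)
    label = subset_label(cross, sex)
    out: list[PairDivergence] = []
    for pair in pairs:
        if pair.gene_a not in means.index or pair.gene_b not in means.index:
            logger.warning(
                "pair (%s, %s): member absent from filtered matrix in subset %s; skipped",
                pair.gene_a, pair.gene_b, label,
            )
            continue
        lfc = math.log2(
            (means[pair.gene_a] + pseudocount) / (means[pair.gene_b] + pseudocount)
        )
        out.append(PairDivergence(pair.gene_a, pair.gene_b, pair.mode, label, abs(lfc)))
    return out


def divergence_contrast(divs: Sequence[PairDivergence]) -> dict:
    """Welch contrast of |log2FC| between disomic and tetrasomic pairs.

    Returns the per-mode mean and sample variance, the Welch t/df/p, and the
    95% confidence interval of the disomic - tetrasomic mean difference (the
    per-contrast report row).
    """
    dis = np.array([d.abs_log2fc for d in divs if d.mode is InheritanceMode.DISOMIC])
    tet = np.array([d.abs_log2fc for d in divs if d.mode is InheritanceMode.TETRASOMIC])
    if dis.size < 2 or tet.size < 2:
        raise ValueError("both inheritance modes must be represented (n >= 2 each)")
    res: WelchResult = welch_t_test(dis, tet)
    ci_lo, ci_hi = welch_confidence_interval(dis, tet)
    return {
        "mean_disomic": float(np.mean(dis)),
        "mean_tetrasomic": float(np.mean(tet)),
        "var_disomic": float(np.var(dis, ddof=1)),
        "var_tetrasomic": float(np.var(tet, ddof=1)),
        "n_disomic": int(dis.size),
        "n_tetrasomic": int(tet.size),
        "t": res.t,
        "df": res.df,
        "p": res.p,
        "ci_low": ci_lo,
        "ci_high": ci_hi,
    }


def seven_contrasts(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    pairs: Sequence[OhnologPair],
    pseudocount: float = 0.5,
    min_total: int = 5,
) -> pd.DataFrame:
    """Divergence-contrast rows for the seven cross x sex subsets."""
    rows = []
    for cross, sex in SUBSETS:
        divs = pair_abs_log2fc(counts, meta, pairs, cross, sex, pseudocount, min_total)
        row = {"cross": cross or "Both", "sex": sex or "All"}
        row.update(divergence_contrast(divs))
        rows.append(row)
    return pd.DataFrame(rows)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log2fc: float
    p: float
    p_adjusted: float
    significant: bool


def de_test(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    sex_as_cofactor: bool = True,
    cross: tuple[str, str] = ("AxA", "RxR"),
    fdr: float = 0.1,
    min_total: int = 5,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Two-group cross-type DE test per gene.

    Normalized counts are compared between the two cross types with a Wald
    test on the log mean ratio, using a negative-binomial variance
    (var = mu + phi mu^2) with a single method-of-moments dispersion per gene
    pooled across groups.  With ``sex_as_cofactor``, each sample's normalized
    counts are rescaled per gene so that both sex strata share the gene's
    grand mean before testing (small-n stratified mean-centering).  P-values
    are BH-adjusted; significance at adjusted p < ``fdr``.

    Returns a DataFrame (gene, log2fc with group ``cross[0]`` in the
    numerator, p, p_adjusted, significant).
    """
    validate_meta(meta, counts)
    g1 = select_samples(meta, cross=cross[0])
    g2 = select_samples(meta, cross=cross[1])
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each cross group needs >= 2 samples")
    sub = filter_min_total(counts[g1 + g2], min_total)
    norm = normalize(sub)

    if sex_as_cofactor:
        meta_idx = meta.set_index("sample_id")
        grand = norm.mean(axis=1)
        adjusted = norm.copy()
        for sex in SEX_LEVELS:
            cols = [s for s in norm.columns if meta_idx.loc[s, "sex"] == sex]
            if not cols:
                continue
            stratum_mean = norm[cols].mean(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                scale = np.where(stratum_mean > 0, grand / stratum_mean, 1.0)
            adjusted[cols] = norm[cols].mul(scale, axis=0)
        norm = adjusted

    a = norm[g1].to_numpy(dtype=float)
    b = norm[g2].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    mu1, mu2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)

    # pooled method-of-moments dispersion: var = mu + phi mu^2
    with np.errstate(divide="ignore", invalid="ignore"):
        phi1 = (v1 - mu1) / mu1**2
        phi2 = (v2 - mu2) / mu2**2
    phi = np.nanmean(np.stack([phi1, phi2]), axis=0)
    phi = np.clip(np.nan_to_num(phi, nan=0.0), 0.0, None)

    m1, m2 = mu1 + pseudocount, mu2 + pseudocount
    log2fc = np.log2(m1 / m2)
    # delta-method SE of log(mean): var(mean)/mean^2 with NB variance;
    # Student-t reference (df = n1 + n2 - 2) because the variances are
    # moment estimates from few replicates
    se2 = (m1 + phi * m1**2) / (n1 * m1**2) + (m2 + phi * m2**2) / (n2 * m2**2)
    wald = np.log(m1 / m2) / np.sqrt(se2)
    p = 2.0 * stats.t.sf(np.abs(wald), df=n1 + n2 - 2)
    zero_var = (v1 == 0) & (v2 == 0) & (mu1 == mu2)
    p = np.where(zero_var, 1.0, p)
    p_adj = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene_id": sub.index,
            "log2fc": log2fc,
            "p": p,
            "p_adjusted": p_adj,
            "significant": p_adj < fdr,
        }
    ).set_index("gene_id")


def annotate_de_with_mode(
    de: pd.DataFrame, pairs: Iterable[OhnologPair]
) -> pd.DataFrame:
    """Tag each DE gene with its ohnolog inheritance mode or 'non-ohnolog'."""
    mode_of: dict[str, str] = {}
    for pair in pairs:
        mode_of[pair.gene_a] = pair.mode.value
        mode_of[pair.gene_b] = pair.mode.value
    out = de.copy()
    out["ohnolog_mode"] = [mode_of.get(g, "non-ohnolog") for g in out.index]
    return out
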