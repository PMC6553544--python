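"""GO-term over-representation among tetrasomic vs disomic ohnologs.

For each GO term, a 2x2 table is formed — (term, no-term) x (target set,
background set) — and tested with Fisher's exact test, one-sided for
over-representation in the target.  Following the raw-p convention of the
analysis this reproduces, enrichment is inferred at p < 0.001 without
multiple-testing correction (a BH option exists but is off by default).
The gene universe is the annotated genes of the two sets; unannotated genes
can be included by flag.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .expression import bh_adjust

logger = logging.getLogger(__name__)

GO_ID_RE = re.compile(r"^GO:\d{7}$")


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, alternative: str = "greater"
) -> float:
    """Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    ``alternative='greater'`` gives the one-sided over-representation tail
    P[X >= a] under the hypergeometric null with fixed margins; 'two-sided'
    sums the probabilities of all tables at most as probable as the observed.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("degenerate table: all counts zero")
    if alternative not in {"greater", "two-sided"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


@dataclass(frozen=True)
class EnrichmentRow:
    """One GO term's 2x2 test: a = term in target, b = no-term in target,
    c = term in background, d = no-term in background."""

    term: str
    namespace: str
    a: int
    b: int
    c: int
    d: int
    p: float
    enriched: bool


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a gene -> GO annotation TSV (gene_id, go_id[, name[, namespace]]).

    Returns gene_id -> set of term ids; term names/namespaces are read by
    :func:`read_term_namespaces`.  Invalid term ids raise.
    """
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.lower().startswith("gene_id"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
            gene, term = fields[0], fields[1]
            if not GO_ID_RE.match(term):
                raise ValueError(f"{path}:{lineno}: malformed GO id {term!r}")
            out.setdefault(gene, set()).add(term)
    return out


def read_term_namespaces(path: str | Path) -> dict[str, str]:
    """Term -> namespace (BP/MF/CC) from column 4 of the annotation TSV."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            fields = raw.rstrip("\n").split("\t")
            if len(fields) >= 4 and GO_ID_RE.match(fields[1]):
                out[fields[1]] = fields[3]
    return out


def go_enrichment(
    target: Iterable[str],
    background: Iterable[str],
    annotations: Mapping[str, set[str]],
    p_cut: float = 0.001,
    min_term_count: int = 1,
    alternative: str = "greater",
    include_unannotated: bool = False,
    bh_correct: bool = False,
    namespaces: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-term over-representation of ``target`` genes vs ``background``.

    The two gene sets must be disjoint.  By default only annotated genes
    enter the margins.  Rows are sorted by ascending p; ``enriched`` is
    p < ``p_cut`` (on the BH-adjusted p when ``bh_correct``).
    """
    target = set(target)
    background = set(background)
    if target & background:
        raise ValueError("target and background gene sets overlap")
    if not target or not background:
        raise ValueError("target and background must both be non-empty")
    if not annotations:
        logger.warning("empty annotation table; no terms to test")
        return pd.DataFrame(
            columns=["term", "namespace", "a", "b", "c", "d", "p", "enriched"]
        )
    if not include_unannotated:
        target = {g for g in target if annotations.get(g)}
        background = {g for g in background if annotations.get(g)}
    terms: dict[str, tuple[int, int]] = {}
    for gene_set, idx in ((target, 0), (background, 1)):
        for g in gene_set:
            for term in annotations.get(g, ()):
                cur = terms.setdefault(term, (0, 0))
                terms[term] = (cur[0] + (idx == 0), cur[1] + (idx == 1))
    n_t, n_b = len(target), len(background)
    rows = []
    for term in sorted(terms):
        a, c = terms[term]
        if a + c < min_term_count:
            continue
        p = fisher_exact_2x2(a, n_t - a, c, n_b - c, alternative=alternative)
        rows.append(
            {
                "term": term,
                "namespace": (namespaces or {}).get(term, ""),
                "a": a,
                "b": n_t - a,
                "c": c,
                "d": n_b - c,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=["term", "namespace", "a", "b", "c", "d", "p"])
    if bh_correct and len(df):
        df["p_adjusted"] = bh_adjust(df["p"].to_numpy())
        df["enriched"] = df["p_adjusted"] < p_cut
    else:
        df["enriched"] = df["p"] < p_cut if len(df) else pd.Series(dtype=bool)
    return df.sort_values("p", kind="mergesort").reset_index(drop=True)


def mode_gene_sets(pairs) -> tuple[set[str], set[str]]:
    """(tetrasomic genes, disomic genes) — both members of each pair enter
    their mode's set, the per-gene convention used throughout."""
    from .genome_model import InheritanceMode

    tet: set[str] = set()
    dis: set[str] = set()
    for p in pairs:
        s = tet if p.mode is InheritanceMode.TETRASOMIC else dis
        s.add(p.gene_a)
        s.add(p.gene_b)
    return tet, dis
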