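"""Five-way categorization of protein subunit-structure text.

UniProt-style "subunit structure" free text is mapped to one of five complex
categories — monomer, homomultimer, heterodimer, heteromultimer, other — by a
case-insensitive keyword cascade with precedence
heteromultimer > heterodimer > homomultimer > monomer > other.
Heteromultimer means more than two different subunits (heterotrimer and up,
or text naming >= 3 distinct chains); "other" collects descriptions that
cannot be categorized automatically.  Category proportions are compared
between disomic and tetrasomic ohnologs with a two-sample chi-squared
proportion test (Yates continuity correction on by default, matching base-R
prop.test for 2x2 tables).

The keyword patterns are shipped as a module-level table so users can audit
and extend them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import chi2_contingency

CATEGORIES = ("monomer", "homomultimer", "heterodimer", "heteromultimer", "other")

# hetero-oligomer words above dimer => more than two different subunits
_HETERO_MULTI_WORDS = (
    "heterotrimer", "heterotetramer", "heteropentamer", "heterohexamer",
    "heteroheptamer", "heterooctamer", "hetero-oligomer", "heterooligomer",
    "heteromultimer", "heteropolymer",
)
_HOMO_WORDS = (
    "homodimer", "homotrimer", "homotetramer", "homopentamer", "homohexamer",
    "homoheptamer", "homooctamer", "homo-oligomer", "homooligomer",
    "homomultimer", "homopolymer",
)

#: ordered (category, compiled pattern) cascade; first match wins
PATTERN_TABLE: tuple[tuple[str, re.Pattern], ...] = (
    ("heteromultimer", re.compile("|".join(_HETERO_MULTI_WORDS), re.IGNORECASE)),
    ("heterodimer", re.compile(r"heterodimer", re.IGNORECASE)),
    ("homomultimer", re.compile("|".join(_HOMO_WORDS), re.IGNORECASE)),
    ("monomer", re.compile(r"\bmonomer", re.IGNORECASE)),
)

# "alpha(2)beta(2)"-style chain listings: count distinct named chains
_CHAIN_RE = re.compile(
    r"\b(alpha|beta|gamma|delta|epsilon|zeta|eta|theta|kappa|lambda|sigma)\b",
    re.IGNORECASE,
)


def categorize_subunit_text(text: str) -> str:
    """Map one subunit-structure description to its complex category.

    Deterministic, case-insensitive, total: anything unmatched is 'other'.
    Texts naming three or more distinct Greek-letter chains count as
    heteromultimers even without an explicit hetero-oligomer word.
    """
    if not text or not text.strip():
        return "other"
    distinct_chains = {m.group(0).lower() for m in _CHAIN_RE.finditer(text)}
    if len(distinct_chains) >= 3:
        return "heteromultimer"
    for category, pattern in PATTERN_TABLE:
        if pattern.search(text):
            return category
    return "other"


@dataclass(frozen=True)
class SubunitAnnotation:
    gene_id: str
    organism: str
    text: str


def read_subunit_table(path) -> list[SubunitAnnotation]:
    """Read a subunit-structure TSV: gene_id, organism, subunit_text."""
    out: list[SubunitAnnotation] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.lower().startswith("gene_id"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            out.append(SubunitAnnotation(fields[0], fields[1], fields[2]))
    return out


def category_counts(annotations: Iterable[SubunitAnnotation], genes: set[str]) -> dict[str, int]:
    """Per-category counts over the annotated genes in ``genes``."""
    counts = {c: 0 for c in CATEGORIES}
    for ann in annotations:
        if ann.gene_id in genes:
            counts[categorize_subunit_text(ann.text)] += 1
    return counts


@dataclass(frozen=True)
class ProportionTestResult:
    category: str
    proportion_a: float
    proportion_b: float
    x_squared: float
    df: int
    p: float
    reliable: bool


def category_proportion_test(
    counts_a: Mapping[str, int],
    counts_b: Mapping[str, int],
    category: str,
    continuity_correction: bool = True,
) -> ProportionTestResult:
    """Two-sample test of equal proportions for one category.

    The 2x2 chi-squared statistic (Yates-corrected when enabled, df = 1) on
    (category, not-category) x (set A, set B); equivalent to base-R
    prop.test.  A table with any expected cell below 1 is flagged unreliable
    rather than rejected.
    """
    n_a = sum(counts_a.values())
    n_b = sum(counts_b.values())
    if n_a == 0 or n_b == 0:
        raise ValueError("both gene sets must have annotated genes")
    x_a = counts_a.get(category, 0)
    x_b = counts_b.get(category, 0)
    table = [[x_a, n_a - x_a], [x_b, n_b - x_b]]
    if x_a + x_b == 0 or (n_a - x_a) + (n_b - x_b) == 0:
        # degenerate margin: proportions identical by construction
        return ProportionTestResult(category, x_a / n_a, x_b / n_b, 0.0, 1, 1.0, False)
    chi2, p, df, expected = chi2_contingency(table, correction=continuity_correction)
    return ProportionTestResult(
        category=category,
        proportion_a=x_a / n_a,
        proportion_b=x_b / n_b,
        x_squared=float(chi2),
        df=int(df),
        p=float(p),
        reliable=bool((expected >= 1.0).all()),
    )


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Closed-form uncorrected Pearson chi-squared for [[a,b],[c,d]]:
    N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ValueError("degenerate margin")
    return n * (a * d - b * c) ** 2 / denom


def compare_modes(
    annotations: Sequence[SubunitAnnotation],
    tetrasomic_genes: set[str],
    disomic_genes: set[str],
    organism: str | None = None,
    continuity_correction: bool = True,
) -> pd.DataFrame:
    """Per-category proportion comparison, disomic vs tetrasomic.

    Organisms are kept separate (pass ``organism``); annotations are never
    merged across organisms silently.
    """
    if organism is not None:
        annotations = [a for a in annotations if a.organism == organism]
    c_dis = category_counts(annotations, disomic_genes)
    c_tet = category_counts(annotations, tetrasomic_genes)
    rows = []
    for cat in CATEGORIES:
        res = category_proportion_test(c_dis, c_tet, cat, continuity_correction)
        rows.append(
            {
                "category": cat,
                "count_disomic": c_dis[cat],
                "count_tetrasomic": c_tet[cat],
                "proportion_disomic": res.proportion_a,
                "proportion_tetrasomic": res.proportion_b,
                "x_squared": res.x_squared,
                "p": res.p,
                "reliable": res.reliable,
            }
        )
    return pd.DataFrame(rows)
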