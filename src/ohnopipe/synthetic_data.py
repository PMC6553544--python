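"""Synthetic genomes, sequences, annotations, and RNA-seq counts.

Generates data with the statistical structure the pipeline assumes, so every
stage runs and is testable without downloads:

* Ohnolog pairs descend from a stop-free ancestral CDS; the two copies
  diverge by independent per-site Jukes-Cantor substitutions (per-lineage
  divergence ``d``), giving the closed-form expected pairwise identity
  ``1/4 + 3/4 exp(-8 d / 3)``.
* Tetrasomic pairs additionally receive Poisson-distributed gene-conversion
  events, each copying a geometric-length tract from one copy onto the other
  — the homogenization mechanism that keeps tetrasomic identity high.
* Genes are placed inside paired homeolog blocks on simulated chromosomes
  consistent with their true inheritance mode, so positional classification
  can recover the truth exactly.
* Expression: per-pair baseline means are log-normal; the true pair log2
  fold change is Normal(0, sigma_mode) with a smaller sigma for tetrasomic
  pairs (expression dosage sharing); counts are negative-binomial with a
  common dispersion and log-uniform sample size factors, for the 15-sample
  4 AxA-F / 3 AxA-M / 4 RxR-F / 4 RxR-M design.
* GO terms are planted preferentially on tetrasomic genes at known odds;
  subunit-structure texts are drawn per mode from category templates.

The default parameter set is the "trout-like" preset: a 28%/72%
tetrasomic/disomic split and divergence/conversion rates calibrated so mean
disomic PID is near 91.3 and mean tetrasomic PID near 95.0.  All randomness
flows from one seeded generator in a documented draw order, so identical
parameters give byte-identical fixture bundles.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genome_model import (
    GeneLocus,
    GenomicInterval,
    HomeologBlockPair,
    InheritanceMode,
    TetrasomyRegistry,
)
from .ohnolog_calling import OhnologPair, SequenceRecord

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = np.array(
    [a + b + c
     for a in "ACGT" for b in "ACGT" for c in "ACGT"
     if a + b + c not in _STOPS]
)

#: subunit-structure text templates per complex category
SUBUNIT_TEMPLATES = {
    "monomer": "Monomer.",
    "homomultimer": "Homodimer; disulfide-linked.",
    "heterodimer": "Heterodimer of a catalytic and a regulatory chain.",
    "heteromultimer": "Heterotetramer of two alpha, one beta and one gamma chain.",
    "other": "Interacts with several partners in vivo.",
}


def jc_expected_identity(d: float) -> float:
    """Expected pairwise site identity of two lineages each at Jukes-Cantor
    divergence ``d`` (expected substitutions/site) from their ancestor:
    1/4 + 3/4 exp(-8 d / 3)."""
    return 0.25 + 0.75 * math.exp(-8.0 * d / 3.0)


@dataclass(frozen=True)
class SimParams:
    """Full parameterization of the synthetic genome + expression generator.

    Defaults are the "trout-like" preset.  ``divergence`` is calibrated from
    the Jukes-Cantor closed form so that disomic identity is ~0.913;
    ``conversion_rate`` from a Poisson tract-coverage argument so that
    tetrasomic identity is ~0.950 (see docs/methods.md).
    """

    n_pairs: int = 1000
    frac_tetrasomic: float = 0.28
    cds_length: int = 300              # codons
    divergence: float = 0.0463         # subs/site per lineage since WGD
    conversion_rate: float = 2.45      # homogenization events per tetrasomic pair
    tract_mean: int = 300              # bp, geometric tract length
    n_tetrasomic_blocks: int = 8
    n_disomic_blocks: int = 17
    gene_spacing: int = 5000           # bp between gene starts within a block
    # expression
    mu_log_mean: float = 4.0           # ln-scale mean of baseline expression
    mu_log_sd: float = 1.0
    nb_dispersion: float = 0.1
    lfc_sigma_tetrasomic: float = 2.1
    lfc_sigma_disomic: float = 2.6
    de_frac: float = 0.0               # fraction of genes with a cross-type effect
    de_log2fc: float = 2.0
    sample_design: tuple[tuple[str, str, int], ...] = (
        ("AxA", "F", 4), ("AxA", "M", 3), ("RxR", "F", 4), ("RxR", "M", 4),
    )
    # annotations
    go_n_terms: int = 40
    go_base_prob: float = 0.05
    go_planted_terms: int = 3
    go_planted_prob: float = 0.30
    subunit_prob: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_tetrasomic <= 1.0:
            raise ValueError("frac_tetrasomic must be in [0, 1]")
        for name in ("divergence", "conversion_rate", "nb_dispersion",
                     "lfc_sigma_tetrasomic", "lfc_sigma_disomic", "de_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lfc_sigma_tetrasomic > self.lfc_sigma_disomic:
            raise ValueError(
                "preset invariant: lfc_sigma_tetrasomic <= lfc_sigma_disomic"
            )
        # under the neutral model protein identity ~ (site identity)^3, so the
        # 85% protein-identity call filter bites well before DNA PID does
        if jc_expected_identity(self.divergence) ** 3 < 0.85:
            logger.warning(
                "divergence %.4f implies expected protein identity ~%.1f%%, "
                "below the 85%% call filter; pair recovery will be incomplete",
                self.divergence, 100 * jc_expected_identity(self.divergence) ** 3,
            )

    def replace(self, **kwargs) -> "SimParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SimulatedGenome:
    """Sequences, loci, registry, and the truth table of simulated pairs."""

    sequences: dict[str, SequenceRecord]
    loci: dict[str, GeneLocus]
    registry: TetrasomyRegistry
    chrom_sizes: dict[str, int]
    truth_pairs: list[OhnologPair]   # pid = realized ungapped site identity


def _site_identity(a: str, b: str) -> float:
    arr_a = np.frombuffer(a.encode(), dtype="S1")
    arr_b = np.frombuffer(b.encode(), dtype="S1")
    return float(np.mean(arr_a == arr_b)) * 100.0


def _mutate_jc(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """One Jukes-Cantor lineage: each site substitutes with probability
    3/4 (1 - exp(-4 d / 3)) to a uniformly chosen different base."""
    p_sub = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    out = seq.copy()
    hit = np.nonzero(rng.random(seq.size) < p_sub)[0]
    if hit.size:
        # uniform over the three other bases
        shift = rng.integers(1, 4, size=hit.size)
        idx = np.searchsorted(_BASES, out[hit])
        out[hit] = _BASES[(idx + shift) % 4]
    return out


def _apply_conversions(
    a: np.ndarray, b: np.ndarray, rate: float, tract_mean: int, rng: np.random.Generator
) -> None:
    """Poisson(rate) homogenization events; each copies a geometric-length
    tract (mean ``tract_mean``) from a random donor onto the other copy,
    truncated at the gene end.  In-place."""
    n_events = int(rng.poisson(rate))
    length = a.size
    for _ in range(n_events):
        donor_is_a = bool(rng.integers(0, 2))
        start = int(rng.integers(0, length))
        tract = int(rng.geometric(1.0 / tract_mean))
        end = min(length, start + tract)
        if donor_is_a:
            b[start:end] = a[start:end]
        else:
            a[start:end] = b[start:end]


def _translate(cds: str) -> str:
    protein = str(Seq(cds).translate())
    # substitution noise can create interior stops; represent as unknown
    return protein.replace("*", "X")


def simulate_ohnolog_sequences(params: SimParams) -> SimulatedGenome:
    """Simulate ohnolog pair sequences, loci, and the block registry.

    Draw order per pair: ancestral codons, copy-a substitutions, copy-b
    substitutions, then (tetrasomic only) conversion events.  Exactly
    ``round(frac_tetrasomic * n_pairs)`` pairs are tetrasomic, distributed
    round-robin over the tetrasomic blocks; the rest fill disomic blocks.
    """
    rng = np.random.default_rng(params.seed)
    n_tet = int(round(params.frac_tetrasomic * params.n_pairs))
    n_bp = params.cds_length * 3

    # block layout: each block pair owns two chromosomes
    block_specs: list[tuple[str, bool]] = [
        (f"T{i + 1:02d}", True) for i in range(params.n_tetrasomic_blocks)
    ] + [(f"D{i + 1:02d}", False) for i in range(params.n_disomic_blocks)]

    # assign pairs to blocks round-robin within each mode
    assignment: dict[str, list[int]] = {label: [] for label, _ in block_specs}
    tet_labels = [lab for lab, t in block_specs if t]
    dis_labels = [lab for lab, t in block_specs if not t]
    for i in range(n_tet):
        assignment[tet_labels[i % len(tet_labels)]].append(i)
    for j in range(n_tet, params.n_pairs):
        assignment[dis_labels[(j - n_tet) % len(dis_labels)]].append(j)

    sequences: dict[str, SequenceRecord] = {}
    loci: dict[str, GeneLocus] = {}
    chrom_sizes: dict[str, int] = {}
    blocks: list[HomeologBlockPair] = []
    truth: list[OhnologPair] = []

    margin = 10_000
    gene_len = n_bp

    for label, tetrasomic in block_specs:
        pair_idx = assignment[label]
        chrom_a, chrom_b = f"chr{label}a", f"chr{label}b"
        n_here = max(1, len(pair_idx))
        block_span = params.gene_spacing * n_here + margin
        block_a = GenomicInterval(chrom_a, margin, margin + block_span)
        block_b = GenomicInterval(chrom_b, margin, margin + block_span)
        blocks.append(HomeologBlockPair(block_a, block_b, tetrasomic, label))
        chrom_sizes[chrom_a] = block_a.end + margin
        chrom_sizes[chrom_b] = block_b.end + margin

        for slot, i in enumerate(pair_idx):
            gid_a, gid_b = f"g{i:05d}_a", f"g{i:05d}_b"
            ancestral = _CODONS[rng.integers(0, len(_CODONS), size=params.cds_length)]
            anc = np.frombuffer("".join(ancestral).encode(), dtype="S1").copy()
            copy_a = _mutate_jc(anc, params.divergence, rng)
            copy_b = _mutate_jc(anc, params.divergence, rng)
            if tetrasomic:
                _apply_conversions(
                    copy_a, copy_b, params.conversion_rate, params.tract_mean, rng
                )
            cds_a = copy_a.tobytes().decode()
            cds_b = copy_b.tobytes().decode()
            sequences[gid_a] = SequenceRecord(gid_a, _translate(cds_a), cds_a)
            sequences[gid_b] = SequenceRecord(gid_b, _translate(cds_b), cds_b)
            start = margin + slot * params.gene_spacing
            loci[gid_a] = GeneLocus(
                gid_a, GenomicInterval(chrom_a, start, start + gene_len),
                chrom_sizes[chrom_a],
            )
            loci[gid_b] = GeneLocus(
                gid_b, GenomicInterval(chrom_b, start, start + gene_len),
                chrom_sizes[chrom_b],
            )
            truth.append(
                OhnologPair(
                    gid_a, gid_b,
                    pid=_site_identity(cds_a, cds_b),
                    mode=InheritanceMode.TETRASOMIC if tetrasomic else InheritanceMode.DISOMIC,
                    block_label=label,
                )
            )

    truth.sort(key=lambda p: p.gene_a)
    return SimulatedGenome(
        sequences=sequences,
        loci=loci,
        registry=TetrasomyRegistry(blocks),
        chrom_sizes=chrom_sizes,
        truth_pairs=truth,
    )


@dataclass
class SimulatedExpression:
    counts: pd.DataFrame       # genes x samples, integer reads
    meta: pd.DataFrame         # sample_id, cross, sex
    true_lfc: pd.DataFrame     # gene_a, gene_b, mode, true_log2fc
    size_factors: pd.Series    # the true per-sample factors used


def simulate_counts(
    params: SimParams, truth_pairs: list[OhnologPair], seed_offset: int = 1
) -> SimulatedExpression:
    """Negative-binomial count matrix for the simulated pairs.

    Draw order: per-pair baseline means, per-pair true log2FCs, DE gene
    choice and signs, sample size factors, then the count matrix.  The true
    pair log2FC is split symmetrically between the two members; counts are
    NB(mean = size_factor x gene mean, dispersion phi), Poisson when phi = 0.
    """
    rng = np.random.default_rng(params.seed + seed_offset)
    n = len(truth_pairs)
    mu_pair = rng.lognormal(params.mu_log_mean, params.mu_log_sd, size=n)
    sigmas = np.array(
        [
            params.lfc_sigma_tetrasomic
            if p.mode is InheritanceMode.TETRASOMIC
            else params.lfc_sigma_disomic
            for p in truth_pairs
        ]
    )
    true_lfc = rng.normal(0.0, 1.0, size=n) * sigmas

    genes: list[str] = []
    gene_means: list[float] = []
    for pair, mu, lfc in zip(truth_pairs, mu_pair, true_lfc):
        genes.extend([pair.gene_a, pair.gene_b])
        gene_means.extend([mu * 2.0 ** (lfc / 2.0), mu * 2.0 ** (-lfc / 2.0)])
    gene_means = np.asarray(gene_means)

    n_genes = len(genes)
    n_de = int(round(params.de_frac * n_genes))
    de_effect = np.zeros(n_genes)
    if n_de:
        de_idx = rng.choice(n_genes, size=n_de, replace=False)
        de_sign = rng.choice([-1.0, 1.0], size=n_de)
        de_effect[de_idx] = de_sign * params.de_log2fc

    sample_ids: list[str] = []
    cross_of: list[str] = []
    sex_of: list[str] = []
    for cross, sex, k in params.sample_design:
        for r in range(1, k + 1):
            sample_ids.append(f"{cross}_{sex}{r}")
            cross_of.append(cross)
            sex_of.append(sex)
    n_samples = len(sample_ids)
    size_f = np.exp(rng.uniform(math.log(0.5), math.log(2.0), size=n_samples))

    means = np.empty((n_genes, n_samples))
    for j in range(n_samples):
        fold = 2.0 ** de_effect if (n_de and cross_of[j] == "AxA") else 1.0
        means[:, j] = gene_means * size_f[j] * fold

    phi = params.nb_dispersion
    if not np.isfinite(means).all():
        raise ValueError("non-finite simulated means")
    if phi == 0.0:
        counts = rng.poisson(means)
    else:
        shape = 1.0 / phi
        lam = rng.gamma(shape, means * phi)
        counts = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)
    meta = pd.DataFrame({"sample_id": sample_ids, "cross": cross_of, "sex": sex_of})
    lfc_df = pd.DataFrame(
        {
            "gene_a": [p.gene_a for p in truth_pairs],
            "gene_b": [p.gene_b for p in truth_pairs],
            "mode": [p.mode.value for p in truth_pairs],
            "true_log2fc": true_lfc,
        }
    )
    return SimulatedExpression(
        counts=counts_df, meta=meta, true_lfc=lfc_df,
        size_factors=pd.Series(size_f, index=sample_ids, name="size_factor"),
    )


def simulate_go_annotations(
    params: SimParams, truth_pairs: list[OhnologPair], seed_offset: int = 2
) -> tuple[dict[str, set[str]], list[str]]:
    """Gene -> GO term annotations with terms planted on tetrasomic genes.

    The first ``go_planted_terms`` terms annotate tetrasomic genes with
    probability ``go_planted_prob`` (vs ``go_base_prob`` elsewhere); the rest
    annotate uniformly at the base probability.  Returns (annotations,
    planted term ids).
    """
    rng = np.random.default_rng(params.seed + seed_offset)
    terms = [f"GO:{i + 1:07d}" for i in range(params.go_n_terms)]
    planted = terms[: params.go_planted_terms]
    annotations: dict[str, set[str]] = {}
    for pair in truth_pairs:
        tet = pair.mode is InheritanceMode.TETRASOMIC
        for gid in (pair.gene_a, pair.gene_b):
            terms_here: set[str] = set()
            for t_i, term in enumerate(terms):
                p = (
                    params.go_planted_prob
                    if (tet and t_i < params.go_planted_terms)
                    else params.go_base_prob
                )
                if rng.random() < p:
                    terms_here.add(term)
            annotations[gid] = terms_here
    return annotations, planted


#: per-mode category probabilities for the subunit-text fixture; monomer
#: (and heterodimer) mass shifted toward tetrasomic genes
SUBUNIT_CATEGORY_PROBS = {
    "tetrasomic": {"monomer": 0.26, "homomultimer": 0.17, "heterodimer": 0.21,
                   "heteromultimer": 0.10, "other": 0.26},
    "disomic": {"monomer": 0.15, "homomultimer": 0.20, "heterodimer": 0.15,
                "heteromultimer": 0.15, "other": 0.35},
}


def simulate_subunit_annotations(
    params: SimParams, truth_pairs: list[OhnologPair],
    organism: str = "mouse", seed_offset: int = 3,
):
    """Subunit-structure texts per gene, drawn from category templates with
    per-mode probabilities (monomer share higher among tetrasomic genes)."""
    from .complex_categories import SubunitAnnotation

    rng = np.random.default_rng(params.seed + seed_offset)
    cats = list(SUBUNIT_TEMPLATES)
    out: list[SubunitAnnotation] = []
    for pair in truth_pairs:
        probs_key = (
            "tetrasomic" if pair.mode is InheritanceMode.TETRASOMIC else "disomic"
        )
        probs = [SUBUNIT_CATEGORY_PROBS[probs_key][c] for c in cats]
        for gid in (pair.gene_a, pair.gene_b):
            if rng.random() < params.subunit_prob:
                cat = cats[int(rng.choice(len(cats), p=probs))]
                out.append(SubunitAnnotation(gid, organism, SUBUNIT_TEMPLATES[cat]))
    return out


# ---------------------------------------------------------------------------
# fixture bundle


def write_fixture_bundle(params: SimParams, out_dir: str | Path) -> dict[str, Path]:
    """Write every pipeline input plus truth tables to ``out_dir``.

    Same parameters (including seed) => byte-identical files.  Returns a
    name -> path mapping of everything written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genome = simulate_ohnolog_sequences(params)
    expr = simulate_counts(params, genome.truth_pairs)
    go_ann, planted = simulate_go_annotations(params, genome.truth_pairs)
    subunit = simulate_subunit_annotations(params, genome.truth_pairs)

    paths = {name: out_dir / fname for name, fname in [
        ("cds_fasta", "cds.fasta"),
        ("protein_fasta", "protein.fasta"),
        ("loci_bed", "loci.bed"),
        ("chrom_sizes", "chrom.sizes"),
        ("block_registry", "blocks.tsv"),
        ("counts", "counts.tsv"),
        ("samples", "samples.tsv"),
        ("go_annotations", "go_annotations.tsv"),
        ("subunit", "subunit.tsv"),
        ("truth_pairs", "truth_pairs.tsv"),
        ("truth_lfc", "truth_lfc.tsv"),
        ("planted_terms", "planted_terms.txt"),
    ]}

    with open(paths["cds_fasta"], "w") as cds_fh, open(paths["protein_fasta"], "w") as prot_fh:
        for gid in sorted(genome.sequences):
            rec = genome.sequences[gid]
            cds_fh.write(f">{gid}\n{rec.cds_seq}\n")
            prot_fh.write(f">{gid}\n{rec.protein_seq}\n")

    with open(paths["loci_bed"], "w") as fh:
        for gid in sorted(genome.loci):
            locus = genome.loci[gid]
            iv = locus.interval
            fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{gid}\n")

    with open(paths["chrom_sizes"], "w") as fh:
        for chrom in sorted(genome.chrom_sizes):
            fh.write(f"{chrom}\t{genome.chrom_sizes[chrom]}\n")

    with open(paths["block_registry"], "w") as fh:
        fh.write("chrom_a\tstart_a\tend_a\tchrom_b\tstart_b\tend_b\ttetrasomic\tlabel\n")
        for bp in genome.registry:
            fh.write(
                f"{bp.block_a.chromosome}\t{bp.block_a.start}\t{bp.block_a.end}\t"
                f"{bp.block_b.chromosome}\t{bp.block_b.start}\t{bp.block_b.end}\t"
                f"{int(bp.tetrasomic)}\t{bp.label}\n"
            )

    expr.counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    expr.meta.to_csv(paths["samples"], sep="\t", index=False)

    with open(paths["go_annotations"], "w") as fh:
        fh.write("gene_id\tgo_id\n")
        for gid in sorted(go_ann):
            for term in sorted(go_ann[gid]):
                fh.write(f"{gid}\t{term}\n")
    with open(paths["planted_terms"], "w") as fh:
        fh.write("\n".join(planted) + ("\n" if planted else ""))

    with open(paths["subunit"], "w") as fh:
        fh.write("gene_id\torganism\tsubunit_text\n")
        for ann in subunit:
            fh.write(f"{ann.gene_id}\t{ann.organism}\t{ann.text}\n")

    with open(paths["truth_pairs"], "w") as fh:
        fh.write("gene_a\tgene_b\tmode\tblock_label\ttrue_pid\n")
        for p in genome.truth_pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.mode.value}\t{p.block_label}\t{p.pid:.6f}\n")

    expr.true_lfc.to_csv(paths["truth_lfc"], sep="\t", index=False, float_format="%.6f")

    return paths
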