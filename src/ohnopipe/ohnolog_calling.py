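"""Ohnolog pair calling from protein similarity within homeolog blocks.

Candidate duplicate pairs are found by pairwise local alignment of the protein
translations (longest transcript per locus), filtered at a minimum query
coverage of 50% and minimum percent identity of 85%, restricted to gene pairs
whose loci fall in opposite blocks of a known homeolog block pair, and reduced
to a one-to-one matching by descending alignment score ("top ranked" hit).
Each called pair then gets a DNA percent identity (PID) from a global alignment
of the two coding sequences, binned into <90% / 90-95% / >95%.

The similarity search is exact pairwise alignment (BLOSUM62, affine gap
open/extend 11/1) rather than a heuristic seeded search; a reader for
12-column tabular hit files lets an external search be substituted at scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_model import GeneLocus, InheritanceMode, TetrasomyRegistry, classify_inheritance

logger = logging.getLogger(__name__)

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = frozenset("ACGTN")

PID_BINS = ("<90%", "90-95%", ">95%")


@dataclass(frozen=True)
class SequenceRecord:
    """Protein (and optionally CDS) sequence for one gene locus."""

    gene_id: str
    protein_seq: str
    cds_seq: str | None = None

    def __post_init__(self) -> None:
        if self.cds_seq is not None and len(self.cds_seq) % 3 != 0:
            # annotation edge cases tolerated
            logger.warning(
                "%s: CDS length %d not divisible by 3", self.gene_id, len(self.cds_seq)
            )


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise protein alignment between two genes."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    query_coverage: float
    score: float

    @property
    def is_hit(self) -> bool:
        return self.alignment_length > 0


@dataclass(frozen=True)
class OhnologPair:
    """A called duplicate gene pair with DNA PID and inheritance mode.

    ``gene_a < gene_b`` lexicographically; ``pid`` may be NaN when no CDS was
    available.
    """

    gene_a: str
    gene_b: str
    pid: float
    mode: InheritanceMode
    block_label: str = ""

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("gene_a must sort before gene_b")
        if not math.isnan(self.pid) and not 0.0 <= self.pid <= 100.0:
            raise ValueError(f"pid out of range: {self.pid}")


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _dna_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    # gap costs chosen so an insertion+deletion pair can never outscore a run
    # of mismatch columns; substitution-only divergence aligns column-wise
    aligner.match_score = 5.0
    aligner.mismatch_score = -4.0
    aligner.open_gap_score = -16.0
    aligner.extend_gap_score = -4.0
    return aligner


_PROT_ALIGNER = _protein_aligner()
_DNA_ALIGNER = _dna_aligner()


def _validate_seq(seq: str, alphabet: frozenset[str], gene_id: str, kind: str) -> str:
    if not seq:
        raise ValueError(f"{gene_id}: empty {kind} sequence")
    seq = seq.upper()
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(
            f"{gene_id}: invalid {kind} symbol(s) {sorted(bad)!r}"
        )
    return seq


def _column_counts(alignment) -> tuple[int, int]:
    """(identities, total columns incl. gap columns) of one alignment."""
    counts = alignment.counts()
    return counts.identities, counts.identities + counts.mismatches + counts.gaps


def align_protein(a: SequenceRecord, b: SequenceRecord) -> AlignmentHit:
    """Locally align two protein sequences (BLOSUM62, affine gaps 11/1).

    ``percent_identity`` is identities over alignment columns (gap columns
    included) x 100; ``query_coverage`` is the aligned span of *a* divided by
    its length.  When no positive-scoring alignment exists the hit is returned
    with ``alignment_length`` 0 ("no hit").
    """
    seq_a = _validate_seq(a.protein_seq, PROTEIN_ALPHABET, a.gene_id, "protein")
    seq_b = _validate_seq(b.protein_seq, PROTEIN_ALPHABET, b.gene_id, "protein")
    alignments = _PROT_ALIGNER.align(seq_a, seq_b)
    if len(alignments) == 0 or alignments.score <= 0:
        return AlignmentHit(a.gene_id, b.gene_id, 0.0, 0, 0.0, 0.0)
    aln = alignments[0]
    identities, length = _column_counts(aln)
    blocks = aln.aligned[0]
    span = int(blocks[-1][1] - blocks[0][0]) if len(blocks) else 0
    return AlignmentHit(
        query_id=a.gene_id,
        subject_id=b.gene_id,
        percent_identity=100.0 * identities / length if length else 0.0,
        alignment_length=length,
        query_coverage=span / len(seq_a),
        score=float(alignments.score),
    )


def dna_pid(a: SequenceRecord, b: SequenceRecord) -> float:
    """DNA percent identity from a global CDS alignment.

    PID = identical columns / aligned columns x 100, gap columns counted in
    the denominator.
    """
    if a.cds_seq is None or b.cds_seq is None:
        missing = a.gene_id if a.cds_seq is None else b.gene_id
        raise ValueError(
            f"{missing}: no CDS sequence; call pairs in protein-only mode "
            "(pair retained with pid flagged missing)"
        )
    seq_a = _validate_seq(a.cds_seq, DNA_ALPHABET, a.gene_id, "DNA")
    seq_b = _validate_seq(b.cds_seq, DNA_ALPHABET, b.gene_id, "DNA")
    aln = _DNA_ALIGNER.align(seq_a, seq_b)[0]
    identities, length = _column_counts(aln)
    return 100.0 * identities / length


def filter_hits(
    hits: Iterable[AlignmentHit],
    min_coverage: float = 0.5,
    min_pid: float = 85.0,
) -> list[AlignmentHit]:
    """Keep hits with query coverage >= ``min_coverage`` and percent identity
    >= ``min_pid`` (both thresholds inclusive); drop self-hits and no-hits."""
    if not 0.0 <= min_coverage <= 1.0:
        raise ValueError("min_coverage must be in [0, 1]")
    if not 0.0 <= min_pid <= 100.0:
        raise ValueError("min_pid must be in [0, 100]")
    return [
        h
        for h in hits
        if h.is_hit
        and h.query_id != h.subject_id
        and h.query_coverage >= min_coverage
        and h.percent_identity >= min_pid
    ]


def candidate_block_pairs(
    gene_ids: Sequence[str],
    loci: Mapping[str, GeneLocus],
    registry: TetrasomyRegistry,
) -> list[tuple[str, str]]:
    """Unordered gene pairs whose loci fall in opposite blocks of one
    homeolog block pair — the only pairs eligible for an ohnolog call."""
    by_block: dict[tuple[str, int], list[str]] = {}
    for gid in gene_ids:
        locus = loci.get(gid)
        if locus is None:
            continue
        for bp in registry:
            if bp.block_a.contains_point(locus.interval.chromosome, locus.interval.midpoint):
                by_block.setdefault((bp.label, 0), []).append(gid)
            if bp.block_b.contains_point(locus.interval.chromosome, locus.interval.midpoint):
                by_block.setdefault((bp.label, 1), []).append(gid)
    out: list[tuple[str, str]] = []
    labels = {lab for lab, _ in by_block}
    for lab in sorted(labels):
        for ga in by_block.get((lab, 0), []):
            for gb in by_block.get((lab, 1), []):
                if ga != gb:
                    out.append((ga, gb))
    return out


def all_vs_all_hits(
    sequences: Mapping[str, SequenceRecord],
    loci: Mapping[str, GeneLocus] | None = None,
    registry: TetrasomyRegistry | None = None,
) -> list[AlignmentHit]:
    """Protein alignment hits for every gene pair (both directions).

    When ``loci`` and ``registry`` are given, alignment is restricted to the
    cross-block candidate pairs — the only pairs a homeolog-block-restricted
    call can ever retain — which keeps the exact search tractable.
    """
    hits: list[AlignmentHit] = []
    if loci is not None and registry is not None:
        pairs = candidate_block_pairs(sorted(sequences), loci, registry)
    else:
        ids = sorted(sequences)
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    for ga, gb in pairs:
        hit = align_protein(sequences[ga], sequences[gb])
        if hit.is_hit:
            hits.append(hit)
            hits.append(
                replace(hit, query_id=gb, subject_id=ga,
                        query_coverage=_swap_coverage(hit, sequences[gb]))
            )
    return hits


def _swap_coverage(hit: AlignmentHit, new_query: SequenceRecord) -> float:
    # approximate reverse-direction coverage from alignment length
    return min(1.0, hit.alignment_length / max(1, len(new_query.protein_seq)))


def call_pairs(
    hits: Iterable[AlignmentHit],
    loci: Mapping[str, GeneLocus],
    registry: TetrasomyRegistry,
    sequences: Mapping[str, SequenceRecord] | None = None,
) -> list[OhnologPair]:
    """Reduce filtered hits to one-to-one ohnolog pairs.

    Hits are restricted to gene pairs lying in opposite blocks of some
    homeolog block pair, then greedily matched by descending score (ties:
    higher percent identity, then lexicographic pair label).  Each pair
    carries the inheritance mode of its block pair and, when ``sequences``
    with CDS are supplied, a DNA PID.
    """
    candidates: dict[tuple[str, str], tuple[float, float, str]] = {}
    for hit in hits:
        if not hit.is_hit:
            continue
        la, lb = loci.get(hit.query_id), loci.get(hit.subject_id)
        if la is None or lb is None:
            missing = hit.query_id if la is None else hit.subject_id
            logger.warning("gene %r has no locus; skipping its hits", missing)
            continue
        bp = registry.block_pair_of(la, lb)
        if bp is None:
            continue
        key = (min(hit.query_id, hit.subject_id), max(hit.query_id, hit.subject_id))
        entry = (hit.score, hit.percent_identity, bp.label)
        if key not in candidates or entry[:2] > candidates[key][:2]:
            candidates[key] = entry

    ranked = sorted(
        candidates.items(),
        key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]),
    )
    used: set[str] = set()
    pairs: list[OhnologPair] = []
    for (ga, gb), (_score, _pid, label) in ranked:
        if ga in used or gb in used:
            continue
        used.update((ga, gb))
        mode = classify_inheritance(loci[ga], loci[gb], registry)
        pid = float("nan")
        if sequences is not None:
            ra, rb = sequences.get(ga), sequences.get(gb)
            if ra is not None and rb is not None and ra.cds_seq and rb.cds_seq:
                pid = dna_pid(ra, rb)
            else:
                logger.warning("pair (%s, %s): missing CDS; pid flagged missing", ga, gb)
        pairs.append(OhnologPair(ga, gb, pid, mode, label))
    pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    return pairs


def bin_pid(pid: float) -> str:
    """Bin a DNA PID into <90% / 90-95% / >95% (90 and 95 in the middle bin)."""
    if math.isnan(pid) or not 0.0 <= pid <= 100.0:
        raise ValueError(f"pid out of range: {pid}")
    if pid < 90.0:
        return "<90%"
    if pid <= 95.0:
        return "90-95%"
    return ">95%"


# ---------------------------------------------------------------------------
# Tabular hit IO (12-column BLAST-style dialect)

BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_tabular_hits(
    path: str | Path, query_lengths: Mapping[str, int]
) -> list[AlignmentHit]:
    """Read a 12-column tab-separated hit table (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore; 1-based
    inclusive coordinates).  ``query_lengths`` supplies the query lengths the
    tabular format omits, for coverage computation."""
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns")
            qid, sid = fields[0], fields[1]
            if qid not in query_lengths:
                raise ValueError(f"{path}:{lineno}: unknown query id {qid!r}")
            qstart, qend = int(fields[6]), int(fields[7])
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    subject_id=sid,
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    query_coverage=(qend - qstart + 1) / query_lengths[qid],
                    score=float(fields[11]),
                )
            )
    return hits
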