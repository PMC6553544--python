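"""Gene loci, homeolog blocks, and inheritance-mode classification.

After the salmonid fourth-round whole-genome duplication (Ss4R), most of the
genome has rediploidized, but eight chromosome-arm pairs still pair as
tetravalents during meiosis.  A duplicated gene pair (ohnolog pair) is
classified as *tetrasomically* inherited when its two members sit in the two
opposite blocks of one such residually-tetrasomic homeolog block pair, and
*disomically* otherwise.  Positional evidence alone licenses the call.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)


class InheritanceMode(str, Enum):
    """Mode of meiotic inheritance of a homeolog region."""

    DISOMIC = "disomic"
    TETRASOMIC = "tetrasomic"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on a chromosome."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValueError("chromosome must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval on {self.chromosome}: start {self.start} >= end {self.end}"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def contains_point(self, chromosome: str, position: float) -> bool:
        return (
            chromosome == self.chromosome and self.start <= position < self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneLocus:
    """A gene's placement on the genome.

    ``chromosome_length`` is optional until a relative position is requested.
    """

    gene_id: str
    interval: GenomicInterval
    chromosome_length: int | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.chromosome_length is not None and self.interval.end > self.chromosome_length:
            raise ValueError(
                f"{self.gene_id}: interval end {self.interval.end} exceeds "
                f"chromosome length {self.chromosome_length}"
            )


@dataclass(frozen=True)
class HomeologBlockPair:
    """Two homeologous genomic blocks created by the Ss4R duplication."""

    block_a: GenomicInterval
    block_b: GenomicInterval
    tetrasomic: bool
    label: str

    def __post_init__(self) -> None:
        if self.block_a.overlaps(self.block_b):
            raise ValueError(f"block pair {self.label!r}: blocks overlap")
        if not self.label:
            raise ValueError("block pair label must be non-empty")


class TetrasomyRegistry:
    """Registry of all homeolog block pairs, each flagged tetrasomic or disomic.

    The flagged-tetrasomic subset defines tetrasomic inheritance; in rainbow
    trout these are the eight arm pairs still forming tetravalents.
    """

    def __init__(self, blocks: Iterable[HomeologBlockPair]):
        self.blocks: list[HomeologBlockPair] = list(blocks)
        labels = [b.label for b in self.blocks]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate block-pair labels in registry")
        tet = [b for b in self.blocks if b.tetrasomic]
        for i, x in enumerate(tet):
            for y in tet[i + 1:]:
                for bx in (x.block_a, x.block_b):
                    for by in (y.block_a, y.block_b):
                        if bx.overlaps(by):
                            raise ValueError(
                                f"tetrasomic blocks overlap: {x.label!r} / {y.label!r}"
                            )

    @property
    def tetrasomic_blocks(self) -> list[HomeologBlockPair]:
        return [b for b in self.blocks if b.tetrasomic]

    @property
    def chromosomes(self) -> set[str]:
        out: set[str] = set()
        for b in self.blocks:
            out.add(b.block_a.chromosome)
            out.add(b.block_b.chromosome)
        return out

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    def block_pair_of(self, locus_a: GeneLocus, locus_b: GeneLocus) -> HomeologBlockPair | None:
        """The block pair whose opposite blocks contain the two locus midpoints.

        Containment is by locus midpoint, so a gene straddling a block edge gets
        a single unambiguous assignment.  Returns None when no block pair
        (tetrasomic or disomic) pairs the two loci.
        """
        for bp in self.blocks:
            if _in_block(locus_a, bp.block_a) and _in_block(locus_b, bp.block_b):
                return bp
            if _in_block(locus_a, bp.block_b) and _in_block(locus_b, bp.block_a):
                return bp
        return None


def _in_block(locus: GeneLocus, block: GenomicInterval) -> bool:
    return block.contains_point(locus.interval.chromosome, locus.interval.midpoint)


def classify_inheritance(
    locus_a: GeneLocus, locus_b: GeneLocus, registry: TetrasomyRegistry
) -> InheritanceMode:
    """Classify an ohnolog pair's inheritance mode from genomic position.

    Tetrasomic iff the two locus midpoints fall in the two opposite blocks of
    one flagged-tetrasomic block pair; disomic otherwise.  Symmetric in its two
    loci.  A locus on a chromosome unknown to the registry yields disomic with
    a logged warning rather than an error.
    """
    if len(registry) == 0:
        raise ValueError("registry is empty")
    known = registry.chromosomes
    for locus in (locus_a, locus_b):
        if locus.interval.chromosome not in known:
            logger.warning(
                "chromosome %r of locus %r not in registry; classifying disomic",
                locus.interval.chromosome,
                locus.gene_id,
            )
            return InheritanceMode.DISOMIC
    for bp in registry.tetrasomic_blocks:
        if (_in_block(locus_a, bp.block_a) and _in_block(locus_b, bp.block_b)) or (
            _in_block(locus_a, bp.block_b) and _in_block(locus_b, bp.block_a)
        ):
            return InheritanceMode.TETRASOMIC
    return InheritanceMode.DISOMIC


def relative_position(locus: GeneLocus) -> float:
    """Locus midpoint divided by total chromosome length, in [0, 1]."""
    if locus.chromosome_length is None:
        raise ValueError(
            f"{locus.gene_id}: chromosome_length unset; supply a chromosome-sizes "
            "table (two-column TSV: chromosome, length)"
        )
    return locus.interval.midpoint / locus.chromosome_length


# ---------------------------------------------------------------------------
# Interval-table IO


class IntervalParseError(ValueError):
    """Raised when an interval table line cannot be parsed."""


def load_gene_loci(
    path: str | Path, chrom_sizes: dict[str, int] | None = None
) -> dict[str, GeneLocus]:
    """Read gene loci from a BED file (3-6 columns; name in column 4).

    BED is 0-based half-open and consumed natively.  Strand is ignored.
    Returns a mapping gene_id -> GeneLocus; duplicate gene ids are an error.
    """
    path = Path(path)
    loci: dict[str, GeneLocus] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise IntervalParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise IntervalParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            gene_id = fields[3] if len(fields) >= 4 and fields[3] else f"{chrom}:{start}-{end}"
            try:
                interval = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise IntervalParseError(f"{path}:{lineno}: {exc}") from exc
            if gene_id in loci:
                raise IntervalParseError(
                    f"{path}:{lineno}: duplicate gene id {gene_id!r}"
                )
            length = chrom_sizes.get(chrom) if chrom_sizes else None
            loci[gene_id] = GeneLocus(gene_id, interval, length)
    if n_lines == 0:
        logger.warning("%s: no records found; returning empty locus table", path)
    return loci


def load_block_registry(path: str | Path) -> TetrasomyRegistry:
    """Read a homeolog block registry.

    Tab-separated columns: chrom_a, start_a, end_a, chrom_b, start_b, end_b,
    tetrasomic_flag (0/1 or true/false), label.  A header line starting with
    'chrom' or '#' is allowed.
    """
    path = Path(path)
    blocks: list[HomeologBlockPair] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.lower().startswith("chrom"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise IntervalParseError(
                    f"{path}:{lineno}: expected 8 columns "
                    "(chrom_a start_a end_a chrom_b start_b end_b tetrasomic label)"
                )
            try:
                block_a = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                block_b = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
            except ValueError as exc:
                raise IntervalParseError(f"{path}:{lineno}: {exc}") from exc
            flag = fields[6].strip().lower()
            if flag not in {"0", "1", "true", "false"}:
                raise IntervalParseError(
                    f"{path}:{lineno}: tetrasomic flag must be 0/1/true/false, got {flag!r}"
                )
            blocks.append(
                HomeologBlockPair(
                    block_a=block_a,
                    block_b=block_b,
                    tetrasomic=flag in {"1", "true"},
                    label=fields[7],
                )
            )
    if not blocks:
        logger.warning("%s: no block pairs found", path)
    return TetrasomyRegistry(blocks)


def load_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chromosome-sizes TSV (chromosome, length)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise IntervalParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise IntervalParseError(f"{path}:{lineno}: non-integer length") from exc
    return sizes
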