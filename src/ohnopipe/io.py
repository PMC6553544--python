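"""Readers and writers for the pipeline's tabular and sequence formats."""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .genome_model import InheritanceMode
from .ohnolog_calling import OhnologPair, SequenceRecord, bin_pid


def read_sequences(
    protein_fasta: str | Path, cds_fasta: str | Path | None = None
) -> dict[str, SequenceRecord]:
    """Load protein (and optionally CDS) FASTA into SequenceRecords keyed by id."""
    proteins = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(protein_fasta), "fasta")}
    cds: dict[str, str] = {}
    if cds_fasta is not None:
        cds = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(cds_fasta), "fasta")}
    return {
        gid: SequenceRecord(gid, seq, cds.get(gid))
        for gid, seq in proteins.items()
    }


def write_pair_table(pairs: Iterable[OhnologPair], path: str | Path) -> None:
    """Write the ohnolog pair table TSV: gene_a, gene_b, pid, mode,
    block_label, bin."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tpid\tmode\tblock_label\tbin\n")
        for p in pairs:
            pid = "" if math.isnan(p.pid) else f"{p.pid:.4f}"
            pid_bin = "" if math.isnan(p.pid) else bin_pid(p.pid)
            fh.write(
                f"{p.gene_a}\t{p.gene_b}\t{pid}\t{p.mode.value}\t{p.block_label}\t{pid_bin}\n"
            )


def read_pair_table(path: str | Path) -> list[OhnologPair]:
    """Read a pair table TSV (as written by :func:`write_pair_table`, or any
    precomputed table with columns gene_a, gene_b, pid, mode[, block_label])."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    required = {"gene_a", "gene_b", "pid", "mode"}
    if not required <= set(df.columns):
        raise ValueError(f"pair table must have columns {sorted(required)}")
    pairs = []
    for row in df.itertuples(index=False):
        ga, gb = sorted((row.gene_a, row.gene_b))
        pairs.append(
            OhnologPair(
                gene_a=ga,
                gene_b=gb,
                pid=float(row.pid) if not pd.isna(row.pid) else float("nan"),
                mode=InheritanceMode(row.mode),
                block_label=str(getattr(row, "block_label", "") or ""),
            )
        )
    return pairs


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples counts TSV (first column gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV (sample_id, cross, sex)."""
    return pd.read_csv(path, sep="\t", dtype=str)


def write_json_report(obj: Mapping, path: str | Path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
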