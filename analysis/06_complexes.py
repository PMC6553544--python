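"""Protein-complex categories by inheritance mode.

Categorizes subunit-structure texts into the five complex categories and
tests, per category, whether the proportion differs between disomic and
tetrasomic ohnologs (Yates-corrected chi-squared proportion test).
"""

import sys
from pathlib import Path

from ohnopipe import io
from ohnopipe.complex_categories import compare_modes, read_subunit_table
from ohnopipe.enrichment import mode_gene_sets

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    bundle = ROOT / "results" / "bundle"
    out = ROOT / "results"
    pairs = io.read_pair_table(out / "pairs_classified.tsv")
    annotations = read_subunit_table(bundle / "subunit.tsv")
    tet, dis = mode_gene_sets(pairs)

    table = compare_modes(annotations, tet, dis, organism="mouse")
    table.to_csv(out / "complex_categories.tsv", sep="\t", index=False)
    print(table.round(4).to_string(index=False))
    monomer = table.set_index("category").loc["monomer"]
    ratio = monomer["proportion_tetrasomic"] / monomer["proportion_disomic"]
    print(f"\nmonomer proportion ratio (tetrasomic/disomic): {ratio:.2f}, "
          f"p = {monomer['p']:.4f}")


if __name__ == "__main__":
    sys.exit(main())
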