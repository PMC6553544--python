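"""Expression divergence by inheritance mode and cross-type DE.

For each of the seven cross x sex sample subsets, computes per-pair
|log2 fold change| between ohnolog members on normalized counts and
contrasts disomic vs tetrasomic divergence with a Welch t-test; then runs
the cross-type differential-expression test (sex as cofactor, and per-sex)
at BH FDR 0.1, tagging DE genes with their ohnolog inheritance mode.
"""

import sys
from pathlib import Path

from ohnopipe import io
from ohnopipe.expression import annotate_de_with_mode, de_test, seven_contrasts

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    bundle = ROOT / "results" / "bundle"
    out = ROOT / "results"
    counts = io.read_counts(bundle / "counts.tsv")
    meta = io.read_sample_meta(bundle / "samples.tsv")
    pairs = io.read_pair_table(out / "pairs_classified.tsv")

    contrasts = seven_contrasts(counts, meta, pairs)
    contrasts.to_csv(out / "divergence_contrasts.tsv", sep="\t", index=False)
    print("per-subset |log2FC| contrast (disomic vs tetrasomic):")
    print(contrasts[["cross", "sex", "mean_disomic", "mean_tetrasomic",
                     "var_disomic", "var_tetrasomic", "t", "p"]].round(4)
          .to_string(index=False))

    for label, cofactor, sex in (("all", True, None), ("F", False, "F"), ("M", False, "M")):
        if sex is None:
            sub_counts, sub_meta = counts, meta
        else:
            sub_meta = meta[meta["sex"] == sex]
            sub_counts = counts[list(sub_meta["sample_id"])]
        de = annotate_de_with_mode(
            de_test(sub_counts, sub_meta, sex_as_cofactor=cofactor), pairs
        )
        de.to_csv(out / f"de_{label}.tsv", sep="\t")
        n_sig = int(de["significant"].sum())
        n_ohno = int((de["significant"] & (de["ohnolog_mode"] != "non-ohnolog")).sum())
        print(f"DE ({label}): {n_sig} significant at FDR 0.1 "
              f"({n_ohno} are ohnologs) of {len(de)} tested")


if __name__ == "__main__":
    sys.exit(main())
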