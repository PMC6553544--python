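# ohnopipe

Ohnolog fate after the salmonid whole-genome duplication: a tested,
reusable pipeline.

Salmonid genomes carry the signature of a whole-genome duplication (Ss4R,
~88 Mya).  Most duplicated regions have rediploidized, but eight
chromosome-arm pairs in rainbow trout (*Oncorhynchus mykiss*) still pair as
tetravalents at meiosis, and recombination between these homeologs keeps
duplicated gene pairs — *ohnologs* — sequence-similar.  `ohnopipe`
implements the comparison of disomically vs tetrasomically inherited
ohnolog pairs:

- **pair calling** from protein similarity (local alignment, coverage >= 50%,
  identity >= 85%) restricted to homeolog blocks, with greedy top-hit
  one-to-one matching;
- **inheritance classification** by genomic position against a registry of
  tetrasomic homeolog blocks;
- **DNA percent identity** (PID) per pair by global CDS alignment, binned
  <90 / 90–95 / >95%, contrasted between modes with Welch's t-test
  (t = (m̄₁ − m̄₂)/√(s₁²/n₁ + s₂²/n₂), Welch–Satterthwaite df);
- **expression divergence**: per pair, |log₂FC| between member genes on
  median-of-ratios-normalized counts across seven cross × sex sample
  subsets, plus a two-group negative-binomial Wald DE test with
  Benjamini–Hochberg FDR < 0.1;
- **GO over-representation** of tetrasomic vs disomic ohnologs (one-sided
  Fisher's exact test, p < 0.001);
- **protein-complex categories** (monomer / homomultimer / heterodimer /
  heteromultimer / other) from subunit-structure text, compared with
  Yates-corrected χ² proportion tests;
- a **synthetic-data generator** that reproduces the statistical regime of
  the rainbow trout data (28% tetrasomic pairs, disomic PID ≈ 91.3 vs
  tetrasomic ≈ 95.0 via Jukes–Cantor divergence plus gene-conversion
  tracts, negative-binomial counts for 15 samples in 4 cross × sex groups),
  so the whole pipeline runs and is testable with no downloads.

See `docs/methods.md` for the models, calibrations, and limitations.

## Worked example

Generate a trout-like synthetic dataset and run the analysis scripts:

```sh
python analysis/01_simulate.py      # writes results/bundle/
python analysis/03_similarity.py    # classification + PID statistics
python analysis/04_expression.py    # divergence contrasts + DE
```

`03_similarity.py` classifies each pair by position, recomputes PID by
global alignment, and prints (seed 0):

```
mean PID: disomic 91.25 (n=1440), tetrasomic 95.07 (n=560)
Welch t = -33.737, df = 619.6, p = 2.02e-142
```

Tetrasomic pairs are ~3.8 PID points more similar than disomic pairs — the
homogenizing effect of residual tetravalent meiosis.  n counts genes (two
per pair).  `04_expression.py` prints the seven cross × sex divergence
contrasts:

```
cross sex  mean_disomic  mean_tetrasomic  var_disomic  var_tetrasomic      t      p
  AxA   F        2.1180           1.6987       2.4676          1.6510 4.3376 0.0000
  ...
 Both All        2.0956           1.6855       2.4042          1.5601 4.3440 0.0000
```

Tetrasomic pairs diverge less in expression (mean |log₂FC| ≈ 1.7 vs ≈ 2.1)
in every subset.  `05_enrichment.py` recovers the generator's planted GO
terms at p < 0.001, and `06_complexes.py` reports the monomer-category
excess among tetrasomic ohnologs.

The same stages are available as a CLI over arbitrary input files
(FASTA + BED + block-registry + counts TSVs):

```sh
ohnopipe simulate --out bundle --seed 5 --n-pairs 200
ohnopipe report-all --bundle bundle --out report
ohnopipe show-config
```

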