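# venus

Neoantigen prioritization for personalized cancer vaccines with the **VENUS
RSUM score** (Vaccine-Encoded Neoantigens Unrestricted Selection), a weighted
rank-sum over three independent features of each tumor mutation.

A patient's tumor typically carries hundreds of somatic mutations, but a
vaccine can encode only a few dozen peptides, and only a small minority of
mutations yield peptides that are expressed, presented on MHC class-I and
recognized by T cells. Fixed-threshold funnels (e.g. *keep IC50 ≤ 500 nM and
TPM ≥ 0.5, then sort by affinity*) discard genuine neoantigens that are
strong on other axes. VENUS instead ranks every candidate peptide three
times — by tumor mutation allele frequency, by corrected transcript
abundance, and by predicted MHC-I affinity — and combines the ranks:

```
RSUM = (R_FREQ + R_EXPR + (k + R_IC50)) · WF

corrTPM = TPM(gene) · (mut + 0.1) / (mut + wt + 0.1)

k  = N (the candidate count)   if best IC50 > 1000 nM, else 0
WF ∈ {1..5}                    penalty for missing RNA support at the locus
```

Lower RSUM is better; there is no selection threshold anywhere, which is what
lets the score keep weak-affinity but clonal, well-expressed candidates.

The package covers the full desk pipeline:

- **Somatic filtering** — tumor MF ≥ 10 %, tumor/normal MF ratio ≥ 5,
  tumor mutant reads > 2, normal mutant reads < 2 (`venus.variants`).
- **Neo-peptide construction** — 25-mers centered on missense changes;
  frameshift peptides translated to the first new-frame stop, then
  "tailored" into 9-mer-anchored 25-mers guided by predicted IC50
  (`venus.peptides`).
- **Expression correction and binding summaries** (`venus.expression`,
  `venus.binding`; predictions are consumed as a table — any class-I
  predictor exporting one IC50 per epitope/allele row works, and a
  deterministic surrogate is included for dry runs).
- **Scoring and comparator strategies** (`venus.scoring`), **validation
  metrics** with a packaged reference cohort of 20 experimentally validated
  neoantigens from nine solid-tumor patients (`venus.evaluation`), and a
  **seeded synthetic cohort generator** with implanted ground truth
  (`venus.synthetic`).

## Worked example

Simulate one patient with 267 somatic variants, two of them implanted true
neoantigens, run the full pipeline, and look at the top of the list:

```bash
$ venus simulate --seed 7 --out demo --patients 1 --variants 267 --implanted 2
wrote 1 patients to demo
$ venus rank --bundle demo/P01 --out demo/ranked.tsv --report demo/report.json
ranked 239 candidates from 267 variants
$ head -4 demo/ranked.tsv | cut -f1-3,5,6,10,16,17
final_position  peptide_id     variant_id  tumor_mf  corr_tpm  best_ic50_nm  wf  rsum
1               P01_V0142|snv  P01_V0142   0.559406  9.00988   76.47         1   54
2               P01_V0231|snv  P01_V0231   0.621122  13.2278   184.749       1   54
3               P01_V0103|snv  P01_V0103   0.535285  4.40699   15.266        1   67
```

267 variants enter, 36 fail the somatic filter (each drop is logged with a
reason code in `report.json`), and the 231 survivors expand — frameshift
peptides contribute several independently ranked 25-mers — into 239 ranked
candidates. The two implanted neoantigens land at positions 4 and 7:

```python
>>> import pandas as pd
>>> from venus import load_bundle, neoantigen_positions
>>> bundle = load_bundle("demo/P01")
>>> neoantigen_positions(pd.read_csv("demo/ranked.tsv", sep="\t"), list(bundle.truth))
{'P01_V0082': 4, 'P01_V0214': 7}
```

`venus evaluate` summarizes the packaged reference cohort — 20 validated
neoantigens across nine patients, of which 14 fall in each patient's top 20
and 19 in the top 60, with a median of 5 % of candidates ranked better:

```bash
$ venus evaluate
n           20
median_pct  5
max_pct     22
capture20   14
capture60   19
```

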