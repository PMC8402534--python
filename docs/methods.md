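# Methods

## The scoring model

VENUS assigns each candidate neo-peptide a weighted rank-sum,

    RSUM = (R_FREQ + R_EXPR + (k + R_IC50)) · WF,

where the three ranks are computed *independently* over the patient's full
candidate list: R_FREQ ranks tumor mutation allele frequency (MF, higher
better — clonal mutations are present in more tumor cells), R_EXPR ranks the
corrected TPM (higher better), and R_IC50 ranks the best predicted MHC
class-I IC50 (lower better). The score's premise is that immunogenicity is
poorly predicted by any single axis: a candidate must be simultaneously
present, expressed and presentable, but need not be extreme on any one
parameter. Because ranks (not raw values) are summed, no fixed threshold is
applied anywhere and the output is a complete ordering of all candidates.

Two correction factors temper the ranks:

- **Non-binder penalty k.** When a peptide's best IC50 strictly exceeds
  1000 nM, k equals N, the patient's candidate count, effectively moving the
  peptide behind every predicted binder on the affinity axis while leaving
  its other two ranks intact. The boundary is strict: IC50 = 1000 nM carries
  no penalty.
- **RNA-coverage weighting factor WF ∈ {1..5}.** RNA-seq sometimes fails to
  cover a mutated locus for technical reasons even in an expressed gene. WF
  multiplies the whole rank-sum: 1 when mutant RNA reads are observed (this
  clause takes precedence regardless of TPM), then 2/3/4/5 over the
  combinations of wild-type locus coverage and whether the gene clears an
  expression floor of TPM ≥ 0.50 (inclusive).

**Corrected TPM.** Gene-level TPM is rescaled by the mutant allele fraction
observed in RNA at the variant locus, with a pseudocount:

    corrTPM = TPM · (mut + 0.1) / (mut + wt + 0.1).

The pseudocount placement is asymmetric by design and is implemented
literally: with zero coverage the fraction is 0.1/0.1 and corrTPM = TPM
(no evidence against expression of the mutant allele), and corrTPM = TPM
exactly when no wild-type reads cover the locus. corrTPM is monotone
non-decreasing in mutant reads and non-increasing in wild-type reads.

**Tie handling.** Within a parameter, competition ("minimum") ranking is
used: tied values share the smallest rank of their block and the next
distinct value gets 1 + the number of strictly better candidates. This
matters for FSP-derived 25-mers, which share their variant's MF and
expression values and therefore tie on two of the three axes. Final RSUM
ties are broken by lower IC50, then peptide id, so the output is a
deterministic total order and is invariant to input row permutation.
The minimum attainable RSUM is 3 (a sole candidate, or a candidate ranked
first on all three axes, with k = 0 and WF = 1).

## Somatic filtering

Candidates derive from missense SNVs and frameshift indels only (synonymous,
stop-gain and in-frame events are rejected at ingestion with a logged
reason). A mutation survives when all four criteria hold: tumor MF ≥ 10 %;
tumor/normal MF ratio ≥ 5; tumor mutant reads > 2; normal mutant reads < 2.
All boundaries follow those inequalities exactly (MF = 0.10 passes, 3 tumor
reads pass, 1 normal read passes). A normal MF of zero makes the ratio
undefined; it is treated as +∞ and the criterion passes, since absence from
the normal sample is the strongest somatic evidence. Thresholds live in
`FilterConfig` and are overridable via the YAML config.

## Peptide construction

**SNV 25-mers.** The mutant residue flanked by up to 12 wild-type residues
on each side, truncated at protein termini; untruncated peptides are 25
residues with the mutation at position 13. Truncated peptides are retained
down to 9 residues (the only length floor the method states, reused from the
FSP rule); shorter ones are dropped with a logged reason.

**Frameshift peptides.** The indel is applied to the coding sequence and the
new frame is translated; the FSP runs from the first residue that differs
from the wild-type protein to the residue before the first stop (any FSP of
≥ 1 residue is retained at this stage). When no stop occurs before the
transcript end, translation runs to the end and the record is flagged in the
log. The *modified FSP* prefixes up to 12 wild-type residues; modified FSPs
shorter than 9 residues are dropped. The stop codon's position contributes
no residue, and ambiguous nucleotides reject the transcript. Translation
uses the standard genetic code via Biopython.

Since `SomaticVariant` locates a mutation by protein position, frameshift
ref/alt alleles are interpreted in CDS orientation anchored at the first
base of that codon, and the builder validates the ref allele against the CDS
(mismatches are hard errors). Protein/peptide coordinates are 1-based
inclusive; CDS offsets are 0-based half-open internally.

**Tailoring.** Long FSPs contain stretches with no chance of presentation,
so the modified FSP is reduced to anchored 25-mers: every 9-mer containing
at least one novel residue is looked up in the prediction table (missing
9-mers are an explicit error listing them); anchors with best IC50 at or
below 1000 nM (the same threshold as the penalty k; configurable) are each
extended by up to 8 residues on both sides, truncated at the FSP boundaries,
and exact duplicate extensions are removed. When no anchor qualifies, the
single lowest-IC50 anchor is kept so a retained FSP never silently
disappears. Only 9-mer epitopes are tailored; prediction tables may carry
8–11-mers for the binding summary. All 25-mers derived from one FSP are
ranked independently downstream. Deduplication uses (variant, sequence):
identical sequences from different variants are kept apart because their
DNA/RNA evidence differs.

## Binding summaries

The per-peptide IC50 is the minimum over the peptide's mutant-containing
epitopes across all patient alleles — the standard best-binder convention
(ties broken lexicographically by epitope, then allele). Wild-type epitopes
are ignored throughout. The predictor itself is external: any table with one
IC50 per (epitope, allele) row works, and `enumerate_queries` emits the
query list for such a tool. The packaged surrogate predictor is a pure
hash-based stand-in producing log-uniform pseudo-IC50s in [1, 50000] nM; it
carries no biology and exists for deterministic dry runs and tests.

## Validation metrics

For a validated neoantigen at `position` in a list of `total` candidates,
the percentage ranked better is `round(100·position/total)` (half away from
zero). Published tables of this quantity are not always reproducible under a
single rounding convention (position vs position−1, floor vs round), so
cross-checks against external tables should use rows robust to that choice;
the packaged reference cohort of 20 validated neoantigens across nine
patients matches this convention on 19 of 20 rows. Cohorts are summarized by
the median and maximum percentage (median of middle two for even n) plus
capture counts at top-20 and top-60. A frameshift mutation is represented by
its best-ranked derived 25-mer.

## Synthetic cohorts

The generator emulates the structure of the nine-patient validation setting:
by default 267 variants per patient (the per-patient candidate median after
frameshift expansion lands near this number), 5 % frameshift indels, and
per-variant toy transcripts of 40–120 codons. Background draws: tumor MF ~
Beta(2, 5); gene TPM ~ LogNormal(µ = 1.0, σ = 1.5); RNA locus coverage ~
Poisson(0.8·TPM) with mutant reads binomial at the tumor MF; per-construct
best IC50 from a 20/10/70 % mixture of binder (10–500 nM), weak (500–1000
nM) and non-binder (1–30 µM) regimes, log-uniform within each regime, with
per-window and per-allele degradation around the construct's best value.
About 10–15 % of background variants naturally fail the somatic filter
(low MF or normal-sample contamination), leaving ≥ 200 candidates.

Implanted true neoantigens (default 2 per patient, matching the 1–4
validated epitopes per patient in the reference cohort) are missense SNVs
drawn jointly favorable: MF ~ Beta(8, 3), TPM ~ LogNormal(3.0, 0.8) with at
least one mutant RNA read, and best IC50 log-uniform in 25–450 nM. Each
implant may instead receive *one* mid-range parameter (equal probability of
none/MF/expression/IC50; mid-IC50 is a weak binder at 550–950 nM, mid-MF and
mid-expression revert to background-like draws) — validated neoantigens span
a broad range of predicted affinities and are rarely extreme on every axis,
and this heterogeneity is precisely why single-parameter selection loses to
the rank-sum. Implants always pass the somatic filter (mid-MF truncated at
0.12, ≥ 3 tumor mutant reads, clean normal), since validated neoantigens
are by construction detected somatic mutations.

Generation is a pure function of (spec, seed) — same seed, byte-identical
bundles — with per-patient substreams spawned from the root seed.

What the synthetic cohorts do **not** model: linkage between expression and
binding (real HLA haplotypes induce correlated affinities), isoform
structure, multi-gene overlaps, sequencing artifacts, inter-patient sharing
of mutations, and any real peptide biochemistry (toy proteins are random).
Passing recovery tests therefore demonstrates that the score's arithmetic
and orchestration behave as designed under the distributional assumptions
above — not that those assumptions hold in patient data.

## Problem sizes and numerical choices

The test suite and the acceptance script run the recovery experiment at 100
single-patient replicates of 267 variants with 5 implants, a scale chosen so
the whole suite completes in about a minute on one CPU while estimating
capture rates to a few percent. Rank computation uses pandas min-rank;
validation of inputs is strict (non-finite ranks, missing joins, duplicate
peptide ids, out-of-range WF are all hard errors naming the offending
records). Floating point enters only through raw parameter values; all rank
arithmetic is integer.

## Known limitations

- Class-II HLA binding is not modeled; CD4-restricted neoantigens are ranked
  only through allele frequency and expression.
- The tailoring retention rule (anchor IC50 ≤ 1000 nM with best-anchor
  fallback) is a reconstruction of an appendix-level procedure; the
  threshold is configurable.
- Aggregation over alleles/epitopes is fixed to the minimum; a median-based
  summary would need different calibration of the penalty threshold.
- The VCF reader expects a specific annotation dialect (documented on
  `read_variants_vcf`) rather than parsing arbitrary annotator output.
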