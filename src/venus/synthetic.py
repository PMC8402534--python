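"""Seeded synthetic cohorts with implanted ground-truth neoantigens.

The generator emulates the statistical structure of a multi-patient
solid-tumor candidate set: a few hundred somatic variants per patient
(mostly missense SNVs with a small frameshift fraction), tumor allele
frequencies from a beta distribution, heavy-tailed gene expression, and
predicted MHC-I affinities mixing strong binders, weak binders and
non-binders. A small number of "true" neoantigens per patient receive
jointly favorable draws — high allele frequency, expressed mutant
transcript, binding-range IC50 — while each may still carry one mid-range
parameter, reflecting the observation that genuine neoantigens are rarely
extreme on every single axis. Their variant ids are recorded in a truth
table so recovery can be scored.

Distribution families (beta for MF, log-normal for TPM, a three-regime
log-uniform mixture for IC50) are generator conventions chosen for realism,
not measurements. Generation is a pure function of (spec, seed): the same
spec writes byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .errors import ValidationError
from .expression import ExpressionEvidence, read_expression_tsv, write_expression_tsv
from .peptides import (
    ProteinContext,
    build_fsp,
    build_snv_25mer,
    load_contexts,
    mutant_9mers,
    mutant_anchor_offsets,
)
from .variants import (
    SomaticVariant,
    VariantClass,
    read_variants_tsv,
    write_variants_tsv,
)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid (stops as '*'), standard genetic code.
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
CODON_TO_AA.update({codon: "*" for codon in _STANDARD_TABLE.stop_codons})

CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_STANDARD_TABLE.forward_table.items()):
    CODONS_BY_AA.setdefault(_aa, [])
    CODONS_BY_AA[_aa].append(_codon)
CODONS_BY_AA = {aa: tuple(codons) for aa, codons in CODONS_BY_AA.items()}
STOP_CODONS = tuple(sorted(_STANDARD_TABLE.stop_codons))

AMINO_ACIDS = tuple(sorted(CODONS_BY_AA))
NUCLEOTIDE_ALPHABET = ("A", "C", "G", "T")

#: common class-I alleles a patient's six-allele haplotype is drawn from.
HLA_POOL = (
    "HLA-A*01:01",
    "HLA-A*02:01",
    "HLA-A*03:01",
    "HLA-A*24:02",
    "HLA-B*07:02",
    "HLA-B*08:01",
    "HLA-B*35:01",
    "HLA-B*44:02",
    "HLA-C*04:01",
    "HLA-C*07:01",
    "HLA-C*07:02",
)

IC50_CAP_NM = 50000.0


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort; defaults emulate a nine-patient
    solid-tumor study with ~267 candidate neo-peptides per patient.

    ``mf_low``/``mf_high`` are beta shape pairs for background and implanted
    tumor MF; ``tpm_log_*`` are (mean, sigma) of log TPM; ``ic50_weights``
    are the background mixture weights of the binder (<500 nM), weak
    (500-1000 nM) and non-binder (>1000 nM) regimes; ``implant_mid_weights``
    choose which single parameter (if any) of each implanted neoantigen is
    drawn mid-range instead of favorable.
    """

    seed: int = 0
    n_patients: int = 9
    n_variants_per_patient: int = 267
    frac_frameshift: float = 0.05
    n_implanted_true: int = 2
    mf_low: tuple = (2.0, 5.0)
    mf_high: tuple = (8.0, 3.0)
    tpm_log_background: tuple = (1.0, 1.5)
    tpm_log_implanted: tuple = (3.0, 0.8)
    tpm_log_mid: tuple = (1.2, 0.6)
    ic50_weights: dict = field(
        default_factory=lambda: {"binder": 0.2, "weak": 0.1, "nonbinder": 0.7}
    )
    ic50_bounds: dict = field(
        default_factory=lambda: {
            "binder": (10.0, 500.0),
            "weak": (500.0, 1000.0),
            "nonbinder": (1000.0, 30000.0),
        }
    )
    implant_ic50_bounds: tuple = (25.0, 450.0)
    implant_mid_ic50_bounds: tuple = (550.0, 950.0)
    implant_mid_weights: dict = field(
        default_factory=lambda: {"none": 0.25, "mf": 0.25, "expr": 0.25, "ic50": 0.25}
    )
    n_alleles: int = 6
    tumor_depth: float = 100.0
    normal_depth: int = 60
    rna_coverage_scale: float = 0.8
    contamination_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_variants_per_patient < 1:
            raise ValidationError("counts must be positive")
        if not 0.0 <= self.frac_frameshift <= 1.0:
            raise ValidationError("frac_frameshift must be a fraction in [0, 1]")
        if self.n_implanted_true < 0 or self.n_implanted_true > self.n_variants_per_patient:
            raise ValidationError("n_implanted_true outside [0, n_variants_per_patient]")


@dataclass
class PatientBundle:
    """In-memory per-patient inputs with ground truth."""

    patient_id: str
    alleles: tuple
    variants: list
    contexts: dict
    expression: dict
    predictions: pd.DataFrame
    truth: tuple

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_variants_tsv(self.variants, out / "variants.tsv")
        with open(out / "proteins.fasta", "w") as fh:
            for tx in sorted(self.contexts):
                fh.write(f">{tx}\n{self.contexts[tx].protein_seq}\n")
        with open(out / "cds.fasta", "w") as fh:
            for tx in sorted(self.contexts):
                fh.write(f">{tx}\n{self.contexts[tx].cds_seq}\n")
        write_expression_tsv(self.expression, out / "expression.tsv")
        self.predictions.to_csv(
            out / "predictions.tsv", sep="\t", index=False, float_format="%.6g"
        )
        pd.DataFrame({"variant_id": list(self.truth)}).to_csv(
            out / "truth.tsv", sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Low-level samplers (exposed for statistical checks)
# ---------------------------------------------------------------------------


def sample_mf(rng: np.random.Generator, shape: tuple, size: int) -> np.ndarray:
    return rng.beta(shape[0], shape[1], size=size)


def sample_tpm(rng: np.random.Generator, log_params: tuple, size: int) -> np.ndarray:
    return rng.lognormal(mean=log_params[0], sigma=log_params[1], size=size)


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def sample_background_ic50(
    rng: np.random.Generator, spec: CohortSpec, size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (values, regime labels) from the background IC50 mixture."""
    regimes = sorted(spec.ic50_weights)
    weights = np.array([spec.ic50_weights[r] for r in regimes], dtype=float)
    weights = weights / weights.sum()
    labels = rng.choice(regimes, size=size, p=weights)
    values = np.empty(size, dtype=float)
    for regime in regimes:
        mask = labels == regime
        lo, hi = spec.ic50_bounds[regime]
        values[mask] = _loguniform(rng, lo, hi, int(mask.sum()))
    return values, labels


def _beta_at_least(rng: np.random.Generator, shape: tuple, floor: float) -> float:
    for _ in range(1000):
        x = float(rng.beta(shape[0], shape[1]))
        if x >= floor:
            return x
    return floor


# ---------------------------------------------------------------------------
# Toy sequences and variants
# ---------------------------------------------------------------------------


def _random_context(rng: np.random.Generator, n_codons: int, transcript_id: str) -> ProteinContext:
    if n_codons < 10:
        raise ValidationError("n_codons must be >= 10")
    aa_indices = rng.integers(0, len(AMINO_ACIDS), size=n_codons - 2)
    protein = "M" + "".join(AMINO_ACIDS[i] for i in aa_indices)
    codons = []
    for aa in protein:
        choices = CODONS_BY_AA[aa]
        codons.append(choices[int(rng.integers(0, len(choices)))])
    codons.append(STOP_CODONS[int(rng.integers(0, len(STOP_CODONS)))])
    return ProteinContext(transcript_id=transcript_id, protein_seq=protein, cds_seq="".join(codons))


def generate_toy_cds(n_codons: int, seed: int = 0, transcript_id: str | None = None) -> ProteinContext:
    """A random, internally consistent CDS/protein pair (protein = n_codons - 1 aa)."""
    rng = np.random.default_rng(seed)
    return _random_context(rng, n_codons, transcript_id or f"TOY_{n_codons}_{seed}")


def _make_missense(
    rng: np.random.Generator, vid: str, ctx: ProteinContext, chrom: str, base_pos: int, **stats
) -> SomaticVariant:
    plen = len(ctx.protein_seq)
    p = int(rng.integers(2, plen + 1))
    codon = ctx.cds_seq[3 * (p - 1) : 3 * p]
    aa_old = ctx.protein_seq[p - 1]
    options = []
    for j in range(3):
        for nt in NUCLEOTIDE_ALPHABET:
            if nt == codon[j]:
                continue
            new_codon = codon[:j] + nt + codon[j + 1 :]
            aa_new = CODON_TO_AA[new_codon]
            if aa_new not in ("*", aa_old):
                options.append((j, nt, aa_new))
    j, nt, aa_new = options[int(rng.integers(0, len(options)))]
    return SomaticVariant(
        variant_id=vid,
        chrom=chrom,
        pos=base_pos + 3 * (p - 1) + j,
        ref_allele=codon[j],
        alt_allele=nt,
        variant_class=VariantClass.MISSENSE_SNV,
        protein_pos=p,
        aa_ref=aa_old,
        aa_alt=aa_new,
        callers=frozenset({"sim"}),
        **stats,
    )


def _make_frameshift(
    rng: np.random.Generator, vid: str, ctx: ProteinContext, chrom: str, base_pos: int, **stats
) -> SomaticVariant:
    plen = len(ctx.protein_seq)
    p = int(rng.integers(5, plen - 5))
    start = 3 * (p - 1)
    indel_len = int(rng.integers(1, 3))  # 1 or 2 nt, never a multiple of 3
    if rng.random() < 0.5:  # insertion
        ref = ctx.cds_seq[start]
        inserted = "".join(
            NUCLEOTIDE_ALPHABET[int(i)] for i in rng.integers(0, 4, size=indel_len)
        )
        alt = ref + inserted
    else:  # deletion
        ref = ctx.cds_seq[start : start + 1 + indel_len]
        alt = ctx.cds_seq[start]
    return SomaticVariant(
        variant_id=vid,
        chrom=chrom,
        pos=base_pos + start,
        ref_allele=ref,
        alt_allele=alt,
        variant_class=VariantClass.FRAMESHIFT_INDEL,
        protein_pos=p,
        aa_ref=None,
        aa_alt=None,
        callers=frozenset({"sim"}),
        **stats,
    )


def _construct_windows(variant: SomaticVariant, ctx: ProteinContext) -> tuple[str | None, list]:
    """(construct id, deduplicated mutant 9-mers) for the variant's construct."""
    if variant.variant_class is VariantClass.MISSENSE_SNV:
        pep = build_snv_25mer(variant, ctx)
        if pep is None:
            return None, []
        return pep.peptide_id, list(dict.fromkeys(seq for _, seq in mutant_9mers(pep)))
    fsp = build_fsp(variant, ctx)
    if fsp is None:
        return None, []
    mod = fsp.modified_seq
    seqs = [mod[i : i + 9] for i in mutant_anchor_offsets(fsp)]
    return fsp.fsp_id, list(dict.fromkeys(seqs))


# ---------------------------------------------------------------------------
# Patient and cohort generation
# ---------------------------------------------------------------------------


def generate_patient(
    spec: CohortSpec, patient_index: int = 0, rng: np.random.Generator | None = None
) -> PatientBundle:
    """Generate one patient's complete input bundle with ground truth."""
    if rng is None:
        children = np.random.SeedSequence(spec.seed).spawn(spec.n_patients)
        rng = np.random.default_rng(children[patient_index])
    patient_id = f"P{patient_index + 1:02d}"
    n = spec.n_variants_per_patient

    implant_idx = set(
        int(i) for i in rng.choice(n, size=spec.n_implanted_true, replace=False)
    )
    background = [i for i in range(n) if i not in implant_idx]
    n_fs = min(round(spec.frac_frameshift * n), len(background))
    fs_idx = set(int(i) for i in rng.choice(len(background), size=n_fs, replace=False))
    fs_variants = {background[i] for i in fs_idx}

    mid_options = sorted(spec.implant_mid_weights)
    mid_weights = np.array([spec.implant_mid_weights[k] for k in mid_options], dtype=float)
    mid_weights = mid_weights / mid_weights.sum()

    alleles = tuple(sorted(rng.choice(HLA_POOL, size=spec.n_alleles, replace=False)))

    variants: list[SomaticVariant] = []
    contexts: dict[str, ProteinContext] = {}
    expression: dict[str, ExpressionEvidence] = {}
    pred_rows: dict[str, list] = {
        "peptide_id": [],
        "epitope_seq": [],
        "allele": [],
        "ic50_nm": [],
        "contains_mutation": [],
    }
    truth: list[str] = []

    for i in range(n):
        vid = f"{patient_id}_V{i + 1:04d}"
        tx = f"TX_{vid}"
        gene = f"GENE_{vid}"
        ctx = _random_context(rng, int(rng.integers(40, 121)), tx)
        contexts[tx] = ctx

        implanted = i in implant_idx
        mid = mid_options[int(rng.choice(len(mid_options), p=mid_weights))] if implanted else "none"

        # --- DNA evidence -------------------------------------------------
        if implanted:
            shape = spec.mf_low if mid == "mf" else spec.mf_high
            mf = _beta_at_least(rng, shape, 0.12)
        else:
            mf = float(rng.beta(*spec.mf_low))
        depth = max(10, int(rng.poisson(spec.tumor_depth)))
        t_alt = int(rng.binomial(depth, mf))
        if implanted:
            t_alt = max(t_alt, 3)
        if not implanted and rng.random() < spec.contamination_rate:
            n_mf = float(rng.beta(1.5, 40.0))
            n_alt = int(rng.binomial(spec.normal_depth, n_mf))
        else:
            n_mf, n_alt = 0.0, 0

        stats = dict(
            gene_id=gene,
            transcript_id=tx,
            tumor_mf=mf,
            normal_mf=n_mf,
            tumor_alt_reads=t_alt,
            normal_alt_reads=n_alt,
        )
        base_pos = 1_000_000 + 10_000 * i
        if i in fs_variants:
            variant = _make_frameshift(rng, vid, ctx, "chr1", base_pos, **stats)
        else:
            variant = _make_missense(rng, vid, ctx, "chr1", base_pos, **stats)
        variants.append(variant)
        if implanted:
            truth.append(vid)

        # --- RNA evidence -------------------------------------------------
        if implanted:
            log_params = spec.tpm_log_mid if mid == "expr" else spec.tpm_log_implanted
        else:
            log_params = spec.tpm_log_background
        tpm = float(rng.lognormal(*log_params))
        coverage = int(rng.poisson(min(tpm, 500.0) * spec.rna_coverage_scale))
        if implanted:
            coverage = max(coverage, 2)
        mut_reads = int(rng.binomial(coverage, mf)) if coverage > 0 else 0
        if implanted:
            mut_reads = max(mut_reads, 1)
        expression[vid] = ExpressionEvidence.from_counts(
            vid, gene, tpm, mut_reads, coverage - mut_reads
        )

        # --- MHC-I predictions -------------------------------------------
        construct_id, windows = _construct_windows(variant, ctx)
        if not windows:
            continue
        if implanted:
            bounds = spec.implant_mid_ic50_bounds if mid == "ic50" else spec.implant_ic50_bounds
            base_ic50 = float(_loguniform(rng, *bounds))
        else:
            base_ic50 = float(sample_background_ic50(rng, spec, 1)[0][0])
        window_ic50 = np.minimum(
            IC50_CAP_NM, base_ic50 * 10 ** rng.uniform(0.0, 0.5, size=len(windows))
        )
        window_ic50[int(rng.integers(0, len(windows)))] = base_ic50
        for seq, ic50 in zip(windows, window_ic50):
            best_allele = int(rng.integers(0, len(alleles)))
            for ai, allele in enumerate(alleles):
                value = (
                    float(ic50)
                    if ai == best_allele
                    else float(min(IC50_CAP_NM, ic50 * 10 ** rng.uniform(0.3, 2.0)))
                )
                pred_rows["peptide_id"].append(construct_id)
                pred_rows["epitope_seq"].append(seq)
                pred_rows["allele"].append(allele)
                pred_rows["ic50_nm"].append(round(value, 3))
                pred_rows["contains_mutation"].append(True)

    predictions = pd.DataFrame(pred_rows)
    return PatientBundle(
        patient_id=patient_id,
        alleles=alleles,
        variants=variants,
        contexts=contexts,
        expression=expression,
        predictions=predictions,
        truth=tuple(truth),
    )


def generate_cohort(spec: CohortSpec, out_dir) -> dict:
    """Write a complete cohort bundle to disk; returns the manifest.

    Layout: ``<out_dir>/<patient_id>/{variants,expression,predictions,truth}.tsv``
    plus ``proteins.fasta``/``cds.fasta`` and a cohort-level ``manifest.json``
    recording the spec and seed. Same spec, same bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_patients)
    patient_ids = []
    for index in range(spec.n_patients):
        bundle = generate_patient(spec, index, rng=np.random.default_rng(children[index]))
        bundle.write(out / bundle.patient_id)
        patient_ids.append(bundle.patient_id)
    manifest = {
        "spec": dataclasses.asdict(spec),
        "patients": patient_ids,
        "files": ["variants.tsv", "proteins.fasta", "cds.fasta", "expression.tsv",
                  "predictions.tsv", "truth.tsv"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def load_bundle(patient_dir, tpm_floor: float = 0.50) -> PatientBundle:
    """Read a per-patient bundle written by :func:`generate_cohort`."""
    path = Path(patient_dir)
    variants, _ = read_variants_tsv(path / "variants.tsv")
    contexts = load_contexts(path / "proteins.fasta", path / "cds.fasta")
    expression = read_expression_tsv(path / "expression.tsv", tpm_floor)
    predictions = pd.read_csv(path / "predictions.tsv", sep="\t")
    truth = tuple(pd.read_csv(path / "truth.tsv", sep="\t")["variant_id"].astype(str))
    alleles = tuple(sorted(predictions["allele"].astype(str).unique()))
    return PatientBundle(
        patient_id=path.name,
        alleles=alleles,
        variants=variants,
        contexts=contexts,
        expression=expression,
        predictions=predictions,
        truth=truth,
    )
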