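"""Somatic variant domain model, the four-criterion somatic filter, and ingestion.

A tumor mutation is retained for neoantigen candidacy when all four DNA-level
criteria hold:

* mutation allele frequency (MF) in the tumor DNA sample >= 10%,
* ratio of tumor MF to normal MF >= 5 (a normal MF of zero counts as an
  infinite ratio: absence from the normal sample is the strongest somatic
  evidence),
* number of mutant reads in the tumor DNA strictly greater than 2,
* number of mutant reads in the normal DNA strictly fewer than 2.

Only missense SNVs and frameshift indels enter the pipeline; synonymous
changes, stop gains and in-frame indels are rejected at ingestion with a
logged reason.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: column order of the variant TSV dialect (tab-separated, header row, UTF-8,
#: 1-based coordinates, callers comma-joined).
VARIANT_TSV_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "gene_id",
    "transcript_id",
    "protein_pos",
    "aa_ref",
    "aa_alt",
    "tumor_mf",
    "normal_mf",
    "tumor_alt_reads",
    "normal_alt_reads",
    "callers",
)


class VariantClass(str, Enum):
    MISSENSE_SNV = "missense_snv"
    FRAMESHIFT_INDEL = "frameshift_indel"


class FilterCriterion(str, Enum):
    MF_TUMOR = "mf_tumor"
    MF_RATIO = "mf_ratio"
    TUMOR_READS = "tumor_reads"
    NORMAL_READS = "normal_reads"


@dataclass(frozen=True)
class FilterConfig:
    """Somatic filter thresholds; the defaults are the published values.

    ``tumor_mf_min`` and ``mf_ratio_min`` are inclusive lower bounds;
    ``tumor_alt_reads_gt`` and ``normal_alt_reads_lt`` are strict bounds
    (tumor mutant reads must exceed 2; normal mutant reads must be below 2).
    MF values are fractions in [0, 1]; the published "10%" is 0.10.
    """

    tumor_mf_min: float = 0.10
    mf_ratio_min: float = 5.0
    tumor_alt_reads_gt: int = 2
    normal_alt_reads_lt: int = 2


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic mutation with DNA allele statistics and protein annotation.

    ``protein_pos`` is the 1-based position of the first affected amino acid.
    For frameshift indels, ``ref_allele``/``alt_allele`` are given in CDS
    orientation anchored at the first base of codon ``protein_pos`` (the
    dialect the peptide builder validates against the CDS); ``aa_ref`` and
    ``aa_alt`` apply to missense SNVs only.
    """

    variant_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: VariantClass
    gene_id: str
    transcript_id: str
    protein_pos: int
    aa_ref: str | None
    aa_alt: str | None
    tumor_mf: float
    normal_mf: float
    tumor_alt_reads: int
    normal_alt_reads: int
    callers: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant_class", VariantClass(self.variant_class))
        object.__setattr__(self, "callers", frozenset(self.callers))
        for name in ("tumor_mf", "normal_mf"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and 0.0 <= value <= 1.0):
                raise ValidationError(
                    f"variant {self.variant_id!r}: {name}={value!r} is not a fraction in [0, 1]"
                )
        for name in ("tumor_alt_reads", "normal_alt_reads"):
            if getattr(self, name) < 0:
                raise ValidationError(f"variant {self.variant_id!r}: {name} is negative")
        if self.protein_pos < 1:
            raise ValidationError(f"variant {self.variant_id!r}: protein_pos must be >= 1")
        if self.variant_class is VariantClass.MISSENSE_SNV:
            if self.aa_ref not in STANDARD_AA or self.aa_alt not in STANDARD_AA:
                raise ValidationError(
                    f"variant {self.variant_id!r}: missense SNV requires standard aa_ref/aa_alt"
                )
            if self.aa_ref == self.aa_alt:
                raise ValidationError(
                    f"variant {self.variant_id!r}: missense SNV with aa_ref == aa_alt"
                )


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of the somatic filter for one variant."""

    variant_id: str
    passed: bool
    failed_criteria: tuple = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_criteria) == 0):
            raise ValidationError(
                f"decision for {self.variant_id!r}: passed must mirror empty failed_criteria"
            )


def mf_ratio(tumor_mf: float, normal_mf: float) -> float:
    """Tumor/normal MF ratio; +inf when the normal MF is zero."""
    if normal_mf == 0:
        return math.inf
    return tumor_mf / normal_mf


def evaluate_criteria(variant: SomaticVariant, thresholds: FilterConfig) -> tuple:
    """Return the tuple of criteria the variant fails (empty when it passes)."""
    failed = []
    if variant.tumor_mf < thresholds.tumor_mf_min:
        failed.append(FilterCriterion.MF_TUMOR)
    if mf_ratio(variant.tumor_mf, variant.normal_mf) < thresholds.mf_ratio_min:
        failed.append(FilterCriterion.MF_RATIO)
    if not variant.tumor_alt_reads > thresholds.tumor_alt_reads_gt:
        failed.append(FilterCriterion.TUMOR_READS)
    if not variant.normal_alt_reads < thresholds.normal_alt_reads_lt:
        failed.append(FilterCriterion.NORMAL_READS)
    return tuple(failed)


def apply_somatic_filters(
    variants: Sequence[SomaticVariant],
    thresholds: FilterConfig | None = None,
) -> list[FilterDecision]:
    """Evaluate the four somatic criteria for each variant, order-preserving."""
    thresholds = thresholds or FilterConfig()
    decisions = []
    for variant in variants:
        failed = evaluate_criteria(variant, thresholds)
        decisions.append(
            FilterDecision(variant.variant_id, passed=not failed, failed_criteria=failed)
        )
    return decisions


# ---------------------------------------------------------------------------
# TSV ingestion
# ---------------------------------------------------------------------------

_ACCEPTED_CLASSES = {c.value for c in VariantClass}


def _row_to_variant(row: Mapping) -> SomaticVariant:
    callers = row.get("callers")
    if callers is None or (isinstance(callers, float) and math.isnan(callers)):
        caller_set: frozenset = frozenset()
    else:
        caller_set = frozenset(c for c in str(callers).split(",") if c)

    def _aa(value):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        return str(value)

    return SomaticVariant(
        variant_id=str(row["variant_id"]),
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        ref_allele=str(row["ref"]),
        alt_allele=str(row["alt"]),
        variant_class=VariantClass(row["variant_class"]),
        gene_id=str(row["gene_id"]),
        transcript_id=str(row["transcript_id"]),
        protein_pos=int(row["protein_pos"]),
        aa_ref=_aa(row.get("aa_ref")),
        aa_alt=_aa(row.get("aa_alt")),
        tumor_mf=float(row["tumor_mf"]),
        normal_mf=float(row["normal_mf"]),
        tumor_alt_reads=int(row["tumor_alt_reads"]),
        normal_alt_reads=int(row["normal_alt_reads"]),
        callers=caller_set,
    )


def ingest_variant_records(df: pd.DataFrame) -> tuple[list[SomaticVariant], list[dict]]:
    """Convert a variant table into domain objects.

    Rows whose ``variant_class`` is not missense_snv/frameshift_indel are
    rejected with a logged, machine-readable reason; malformed values raise
    :class:`ValidationError`.

    Returns ``(variants, dropped)`` where each drop record carries
    ``variant_id``, ``reason`` and ``detail``.
    """
    missing = set(VARIANT_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"variant table is missing columns: {sorted(missing)}")
    variants: list[SomaticVariant] = []
    dropped: list[dict] = []
    for row in df.to_dict("records"):
        vclass = str(row["variant_class"])
        if vclass not in _ACCEPTED_CLASSES:
            record = {
                "variant_id": str(row["variant_id"]),
                "reason": "unsupported_variant_class",
                "detail": vclass,
            }
            logger.info("rejected variant %(variant_id)s: %(reason)s (%(detail)s)", record)
            dropped.append(record)
            continue
        variants.append(_row_to_variant(row))
    return variants, dropped


def read_variants_tsv(path) -> tuple[list[SomaticVariant], list[dict]]:
    """Read the variant TSV dialect; see :data:`VARIANT_TSV_COLUMNS`."""
    df = pd.read_csv(path, sep="\t")
    return ingest_variant_records(df)


def variants_to_frame(variants: Iterable[SomaticVariant]) -> pd.DataFrame:
    rows = []
    for v in variants:
        rows.append(
            {
                "variant_id": v.variant_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "variant_class": v.variant_class.value,
                "gene_id": v.gene_id,
                "transcript_id": v.transcript_id,
                "protein_pos": v.protein_pos,
                "aa_ref": v.aa_ref or "",
                "aa_alt": v.aa_alt or "",
                "tumor_mf": v.tumor_mf,
                "normal_mf": v.normal_mf,
                "tumor_alt_reads": v.tumor_alt_reads,
                "normal_alt_reads": v.normal_alt_reads,
                "callers": ",".join(sorted(v.callers)),
            }
        )
    return pd.DataFrame(rows, columns=list(VARIANT_TSV_COLUMNS))


def write_variants_tsv(variants: Iterable[SomaticVariant], path) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Optional VCF ingestion
# ---------------------------------------------------------------------------

#: INFO tags the VCF dialect requires on every record.
VCF_INFO_TAGS = ("GENE", "TRANSCRIPT", "PPOS", "AAREF", "AAALT", "VCLASS")


def read_variants_vcf(
    path,
    tumor_sample: str = "TUMOR",
    normal_sample: str = "NORMAL",
) -> tuple[list[SomaticVariant], list[dict]]:
    """Map a somatic VCF onto the variant TSV schema.

    Required dialect (validated, not guessed): per-sample FORMAT fields
    ``AF`` (allele fraction) and ``AD`` (ref,alt depths) for the named tumor
    and normal samples, plus the INFO tags GENE, TRANSCRIPT, PPOS, AAREF,
    AAALT and VCLASS carrying the protein-level annotation. Multi-allelic
    records must be split beforehand.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise SchemaError("VCF ingestion requires the optional cyvcf2 dependency") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in (tumor_sample, normal_sample):
        if name not in samples:
            raise SchemaError(f"VCF is missing required sample {name!r} (found {samples})")
    t_idx, n_idx = samples.index(tumor_sample), samples.index(normal_sample)

    rows = []
    for record in vcf:
        info = {tag: record.INFO.get(tag) for tag in VCF_INFO_TAGS}
        missing = [tag for tag, value in info.items() if value is None]
        if missing:
            raise SchemaError(
                f"VCF record {record.CHROM}:{record.POS} lacks INFO tags {missing}"
            )
        af = record.format("AF")
        ad = record.format("AD")
        if af is None or ad is None:
            raise SchemaError(
                f"VCF record {record.CHROM}:{record.POS} lacks FORMAT AF/AD fields"
            )
        rows.append(
            {
                "variant_id": record.ID or f"{record.CHROM}:{record.POS}:{record.ALT[0]}",
                "chrom": record.CHROM,
                "pos": record.POS,
                "ref": record.REF,
                "alt": record.ALT[0],
                "variant_class": str(info["VCLASS"]),
                "gene_id": str(info["GENE"]),
                "transcript_id": str(info["TRANSCRIPT"]),
                "protein_pos": int(info["PPOS"]),
                "aa_ref": str(info["AAREF"]) or None,
                "aa_alt": str(info["AAALT"]) or None,
                "tumor_mf": float(af[t_idx][0]),
                "normal_mf": float(af[n_idx][0]),
                "tumor_alt_reads": int(ad[t_idx][1]),
                "normal_alt_reads": int(ad[n_idx][1]),
                "callers": "",
            }
        )
    return ingest_variant_records(pd.DataFrame(rows, columns=list(VARIANT_TSV_COLUMNS)))
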