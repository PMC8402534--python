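"""Expression evidence: corrected TPM and the RNA-coverage weighting factor.

Gene-level TPM alone can overstate the abundance of a mutated transcript, so
the corrected TPM rescales it by the mutant read fraction observed at the
variant locus in the tumor RNA-seq data, with a pseudocount of 0.1::

    corrTPM = TPM(gene) * (mut + 0.1) / (mut + wt + 0.1)

The pseudocount placement is deliberately asymmetric (0.1 added to the
mutant count in the numerator and once to the denominator sum) and is
implemented literally; in particular corrTPM equals TPM whenever no
wild-type reads cover the locus.

The integer weighting factor WF in {1..5} penalizes candidates whose
mutation lacks RNA support, in clause order (the first matching clause
fires; mutant coverage takes precedence regardless of TPM)::

    WF = 1  if mut > 0
         2  if mut = 0, wt = 0, TPM >= 0.50
         3  if mut = 0, wt > 0, TPM >= 0.50
         4  if mut = 0, wt = 0, TPM < 0.50
         5  if mut = 0, wt > 0, TPM < 0.50
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .errors import SchemaError, ValidationError

#: column order of the expression TSV dialect.
EXPRESSION_TSV_COLUMNS = ("variant_id", "gene_id", "tpm", "rna_mut_reads", "rna_wt_reads")

PSEUDOCOUNT = 0.1


def _check_non_negative(**values) -> None:
    for name, value in values.items():
        if value is None or (isinstance(value, float) and not math.isfinite(value)) or value < 0:
            raise ValidationError(f"{name}={value!r} must be a finite non-negative number")


def corr_tpm(tpm: float, rna_mut_reads: int, rna_wt_reads: int) -> float:
    """Corrected TPM: gene TPM rescaled by the mutant read fraction at the locus."""
    _check_non_negative(tpm=tpm, rna_mut_reads=rna_mut_reads, rna_wt_reads=rna_wt_reads)
    return tpm * (rna_mut_reads + PSEUDOCOUNT) / (rna_mut_reads + rna_wt_reads + PSEUDOCOUNT)


def weighting_factor(
    tpm: float, rna_mut_reads: int, rna_wt_reads: int, tpm_floor: float = 0.50
) -> int:
    """Down-weighting factor in {1..5}; see the module docstring for the clauses."""
    _check_non_negative(tpm=tpm, rna_mut_reads=rna_mut_reads, rna_wt_reads=rna_wt_reads)
    if rna_mut_reads > 0:
        return 1
    expressed = tpm >= tpm_floor
    if rna_wt_reads == 0:
        return 2 if expressed else 4
    return 3 if expressed else 5


@dataclass(frozen=True)
class ExpressionEvidence:
    """Gene TPM plus RNA allele counts at the variant locus, with derived values."""

    variant_id: str
    gene_id: str
    tpm: float
    rna_mut_reads: int
    rna_wt_reads: int
    corr_tpm: float
    wf: int

    @classmethod
    def from_counts(
        cls,
        variant_id: str,
        gene_id: str,
        tpm: float,
        rna_mut_reads: int,
        rna_wt_reads: int,
        tpm_floor: float = 0.50,
    ) -> "ExpressionEvidence":
        return cls(
            variant_id=variant_id,
            gene_id=gene_id,
            tpm=float(tpm),
            rna_mut_reads=int(rna_mut_reads),
            rna_wt_reads=int(rna_wt_reads),
            corr_tpm=corr_tpm(tpm, rna_mut_reads, rna_wt_reads),
            wf=weighting_factor(tpm, rna_mut_reads, rna_wt_reads, tpm_floor),
        )


def ingest_expression_records(
    df: pd.DataFrame, tpm_floor: float = 0.50
) -> dict[str, ExpressionEvidence]:
    """Validate an expression table and derive corrTPM/WF per variant.

    One gene per variant is required; a variant annotated against two genes
    is surfaced as a schema error rather than silently resolved.
    """
    missing = set(EXPRESSION_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"expression table is missing columns: {sorted(missing)}")
    duplicated = df.loc[df["variant_id"].duplicated(), "variant_id"].tolist()
    if duplicated:
        raise SchemaError(
            f"expression table has multiple rows (multi-gene overlap?) for: {sorted(set(duplicated))}"
        )
    return {
        str(row["variant_id"]): ExpressionEvidence.from_counts(
            str(row["variant_id"]),
            str(row["gene_id"]),
            float(row["tpm"]),
            int(row["rna_mut_reads"]),
            int(row["rna_wt_reads"]),
            tpm_floor,
        )
        for row in df.to_dict("records")
    }


def read_expression_tsv(path, tpm_floor: float = 0.50) -> dict[str, ExpressionEvidence]:
    return ingest_expression_records(pd.read_csv(path, sep="\t"), tpm_floor)


def expression_to_frame(evidence: Mapping[str, ExpressionEvidence]) -> pd.DataFrame:
    rows = [
        {
            "variant_id": e.variant_id,
            "gene_id": e.gene_id,
            "tpm": e.tpm,
            "rna_mut_reads": e.rna_mut_reads,
            "rna_wt_reads": e.rna_wt_reads,
        }
        for e in evidence.values()
    ]
    return pd.DataFrame(rows, columns=list(EXPRESSION_TSV_COLUMNS))


def write_expression_tsv(evidence: Mapping[str, ExpressionEvidence], path) -> None:
    expression_to_frame(evidence).to_csv(path, sep="\t", index=False, float_format="%.6g")
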