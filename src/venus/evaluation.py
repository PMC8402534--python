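"""Validation metrics for ranked neo-peptide lists.

Given the position of an experimentally validated neoantigen within a
patient's ranked candidate list, the percentage of neo-peptides ranked
better is ``round(100 * position / total)`` (half away from zero), and a
cohort is summarized by the median and maximum of those percentages plus
the number of validated neoantigens captured within the top-20 and top-60
selections.

A reference cohort of 20 validated neoantigens across nine solid-tumor
patients (melanoma, rectal, colon and pancreatic cancer; 1-4 T-cell
reactivities per patient, labelled ``GENE_substitution``) ships with the
package so these metrics can be computed offline; load it with
:func:`load_validated_neoantigens`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from statistics import median
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError

VALIDATION_COLUMNS = (
    "tumor_type",
    "patient_id",
    "total_candidates",
    "neoantigen_label",
    "position",
    "pct_better",
)


@dataclass(frozen=True)
class ValidationRecord:
    """One validated neoantigen's placement within a patient's ranked list."""

    patient_id: str
    tumor_type: str
    total_candidates: int
    neoantigen_label: str
    position: int
    pct_better: int

    def __post_init__(self) -> None:
        if not 1 <= self.position <= self.total_candidates:
            raise ValidationError(
                f"{self.neoantigen_label}: position {self.position} outside "
                f"[1, {self.total_candidates}]"
            )
        if not 0 <= self.pct_better <= 100:
            raise ValidationError(f"{self.neoantigen_label}: pct_better outside [0, 100]")


def pct_ranked_better(position: int, total: int) -> int:
    """Integer percentage of the list ranked at or better than ``position``.

    Rounds half away from zero. No single rounding convention reproduces
    every published presentation of this quantity (position-1 vs position,
    floor vs round); this is the plain convention and callers comparing to
    external tables should prefer rows robust to that choice.
    """
    if total < 1 or not 1 <= position <= total:
        raise ValidationError(f"position {position} outside [1, {total}]")
    return int(math.floor(100.0 * position / total + 0.5))


def capture_at(positions: Sequence[int], cutoff: int) -> int:
    """Number of validated neoantigens ranked within the top ``cutoff``."""
    if len(positions) == 0:
        raise ValidationError("positions must be non-empty")
    return sum(1 for p in positions if p <= cutoff)


def cohort_summary(records: Iterable[ValidationRecord] | pd.DataFrame) -> dict:
    """Median/max percentile and top-20/top-60 capture for a validation cohort."""
    if isinstance(records, pd.DataFrame):
        records = records_from_frame(records)
    records = list(records)
    if not records:
        raise ValidationError("cohort_summary requires at least one record")
    positions = [r.position for r in records]
    pcts = [r.pct_better for r in records]
    median_pct = median(pcts)
    if float(median_pct).is_integer():
        median_pct = int(median_pct)
    return {
        "n": len(records),
        "median_pct": median_pct,
        "max_pct": max(pcts),
        "capture20": capture_at(positions, 20),
        "capture60": capture_at(positions, 60),
    }


def records_from_frame(df: pd.DataFrame) -> list[ValidationRecord]:
    missing = set(VALIDATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"validation table is missing columns: {sorted(missing)}")
    return [
        ValidationRecord(
            patient_id=str(row["patient_id"]),
            tumor_type=str(row["tumor_type"]),
            total_candidates=int(row["total_candidates"]),
            neoantigen_label=str(row["neoantigen_label"]),
            position=int(row["position"]),
            pct_better=int(row["pct_better"]),
        )
        for row in df.to_dict("records")
    ]


def load_validated_neoantigens() -> pd.DataFrame:
    """The packaged reference cohort of 20 validated neoantigens."""
    with resources.files("venus").joinpath("data/validated_neoantigens.tsv").open() as handle:
        return pd.read_csv(handle, sep="\t")


def neoantigen_positions(ranked: pd.DataFrame, variant_ids: Sequence[str]) -> dict[str, int | None]:
    """Best final position per variant in a ranked table (None when absent).

    A frameshift variant contributes several independently ranked 25-mers;
    its best-ranked peptide represents the mutation.
    """
    best = ranked.groupby("variant_id")["final_position"].min()
    return {vid: (int(best[vid]) if vid in best.index else None) for vid in variant_ids}
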