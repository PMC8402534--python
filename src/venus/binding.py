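"""MHC class-I binding summaries per candidate peptide.

The method consumes a prediction table (one IC50 in nM per epitope/allele
row, as exported by standard class-I predictors) rather than re-implementing
a predictor. Per peptide the summary is the best (minimum) IC50 over its
mutant-containing epitopes across the patient's alleles — the conventional
"best predicted binder" aggregation; wild-type-only epitopes never
contribute.

A deterministic surrogate predictor is provided so pipelines and tests can
run without the external tool: it maps (peptide, allele, seed) to a
pseudo-IC50 in [1, 50000] nM through a cryptographic hash, so identical
inputs give identical values on every platform.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import MissingPredictionError, SchemaError, ValidationError
from .peptides import NeoPeptide, mutant_9mers

#: column order of the prediction TSV dialect (IEDB-export-like).
PREDICTION_TSV_COLUMNS = ("peptide_id", "epitope_seq", "allele", "ic50_nm", "contains_mutation")

IC50_MIN_NM = 1.0
IC50_MAX_NM = 50000.0


@dataclass(frozen=True)
class EpitopePrediction:
    """One predicted epitope/allele IC50 for a candidate peptide."""

    peptide_id: str
    epitope_seq: str
    allele: str
    ic50_nm: float
    contains_mutation: bool

    def __post_init__(self) -> None:
        if not 8 <= len(self.epitope_seq) <= 11:
            raise ValidationError(
                f"epitope {self.epitope_seq!r}: length {len(self.epitope_seq)} outside [8, 11]"
            )
        if not (math.isfinite(self.ic50_nm) and self.ic50_nm > 0):
            raise ValidationError(
                f"epitope {self.epitope_seq!r} ({self.allele}): ic50_nm must be positive"
            )


@dataclass(frozen=True)
class BindingSummary:
    """Best mutant-containing IC50 for one peptide."""

    peptide_id: str
    best_ic50_nm: float
    best_epitope: str
    best_allele: str


def summarize_binding(predictions: Iterable[EpitopePrediction]) -> dict[str, BindingSummary]:
    """Best (minimum) mutant-containing IC50 per peptide.

    Ties are broken by the lexicographically smallest (epitope, allele) pair.
    A peptide represented only by wild-type epitopes is an upstream defect
    and raises :class:`ValidationError`.
    """
    by_peptide: dict[str, list[EpitopePrediction]] = {}
    seen: set[str] = set()
    for pred in predictions:
        seen.add(pred.peptide_id)
        if pred.contains_mutation:
            by_peptide.setdefault(pred.peptide_id, []).append(pred)
    orphans = sorted(seen - set(by_peptide))
    if orphans:
        raise ValidationError(
            f"peptides without any mutant-containing prediction: {orphans}"
        )
    summaries = {}
    for peptide_id, preds in by_peptide.items():
        best = min(preds, key=lambda p: (p.ic50_nm, p.epitope_seq, p.allele))
        summaries[peptide_id] = BindingSummary(
            peptide_id=peptide_id,
            best_ic50_nm=best.ic50_nm,
            best_epitope=best.epitope_seq,
            best_allele=best.allele,
        )
    return summaries


def surrogate_predict(peptide: str, allele: str, seed: int) -> float:
    """Deterministic pseudo-IC50 in [1, 50000] nM for tests and dry runs.

    The value is log-uniform in the IC50 range and is a pure function of
    (peptide, allele, seed) via SHA-256, hence stable across platforms.
    """
    if not 8 <= len(peptide) <= 11:
        raise ValidationError(f"peptide {peptide!r}: length outside [8, 11]")
    digest = hashlib.sha256(f"{peptide}|{allele}|{seed}".encode()).digest()
    unit = int.from_bytes(digest[:8], "big") / 2**64
    return float(10 ** (unit * math.log10(IC50_MAX_NM)))


# ---------------------------------------------------------------------------
# Prediction tables
# ---------------------------------------------------------------------------


def read_predictions_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_prediction_frame(df)


def validate_prediction_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(PREDICTION_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"prediction table is missing columns: {sorted(missing)}")
    if (df["ic50_nm"] <= 0).any():
        bad = df.loc[df["ic50_nm"] <= 0, "epitope_seq"].tolist()[:5]
        raise ValidationError(f"non-positive IC50 values for epitopes {bad}")
    df = df.copy()
    df["contains_mutation"] = df["contains_mutation"].map(
        {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
    )
    if df["contains_mutation"].isna().any():
        raise SchemaError("contains_mutation must be boolean")
    return df


def epitope_best_ic50(predictions: pd.DataFrame) -> dict[str, float]:
    """Best IC50 per epitope sequence over all alleles (tailoring input)."""
    return predictions.groupby("epitope_seq")["ic50_nm"].min().to_dict()


def enumerate_queries(
    peptides: Sequence[NeoPeptide], alleles: Sequence[str], epitope_length: int = 9
) -> pd.DataFrame:
    """The (peptide, epitope, allele) query list to submit to an external predictor.

    Only mutant-containing windows are enumerated, since wild-type epitopes
    never enter the score.
    """
    rows = []
    for pep in peptides:
        for _, seq in mutant_9mers(pep, epitope_length):
            for allele in alleles:
                rows.append({"peptide_id": pep.peptide_id, "epitope_seq": seq, "allele": allele})
    return pd.DataFrame(rows, columns=["peptide_id", "epitope_seq", "allele"])


def build_peptide_predictions(
    peptides: Sequence[NeoPeptide], predictions: pd.DataFrame
) -> list[EpitopePrediction]:
    """Attach table rows to each peptide's mutant-containing 9-mers.

    Every mutant 9-mer of every peptide must appear in the table; missing
    epitopes raise :class:`MissingPredictionError` listing them.
    """
    grouped: dict[str, list[tuple[str, float]]] = {}
    for epitope, sub in predictions.groupby("epitope_seq"):
        grouped[str(epitope)] = list(zip(sub["allele"].astype(str), sub["ic50_nm"].astype(float)))
    result: list[EpitopePrediction] = []
    missing: set[str] = set()
    for pep in peptides:
        for _, seq in mutant_9mers(pep):
            if seq not in grouped:
                missing.add(seq)
                continue
            for allele, ic50 in grouped[seq]:
                result.append(
                    EpitopePrediction(
                        peptide_id=pep.peptide_id,
                        epitope_seq=seq,
                        allele=allele,
                        ic50_nm=ic50,
                        contains_mutation=True,
                    )
                )
    if missing:
        raise MissingPredictionError(f"no predictions for mutant 9-mers: {sorted(missing)}")
    return result
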