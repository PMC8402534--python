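"""The VENUS RSUM score: weighted rank-sum prioritization of neo-peptides.

Each candidate peptide is ranked independently three times — by tumor
mutation allele frequency (higher is better), by corrected TPM (higher is
better) and by best predicted MHC-I IC50 (lower is better) — with
competition ("minimum") ranks, so ties share the smallest rank of their
block. The final score is

    RSUM = (RFREQ + REXPR + (k + RIC50)) * WF

where ``k`` equals the number of candidate peptides N when the best IC50
exceeds 1000 nM (and 0 otherwise), and WF in {1..5} is the RNA-coverage
weighting factor. Lower RSUM is better; ties are broken by lower IC50 and
then peptide_id so the output is a deterministic total order. There is no
fixed selection threshold anywhere: the output is a complete ranking.

Alternative strategies used as comparators (single-parameter orderings and a
fixed-threshold "funnel" that keeps only predicted binders, IC50 <= 500 nM,
of expressed genes, TPM >= 0.50, then sorts by IC50) are provided for
benchmarking against the full score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: columns score_patient requires on its joined candidate table.
REQUIRED_COLUMNS = ("peptide_id", "tumor_mf", "corr_tpm", "wf", "best_ic50_nm")

STRATEGIES = ("venus", "mf_only", "expr_only", "ic50_only", "funnel_then_ic50")

PENALTY_THRESHOLD_NM = 1000.0


@dataclass(frozen=True)
class ScoredPeptide:
    """Per-peptide ranks, correction factors, RSUM and final position."""

    peptide_id: str
    r_freq: int
    r_expr: int
    r_ic50: int
    k: int
    wf: int
    rsum: int
    final_position: int

    def __post_init__(self) -> None:
        if self.rsum != (self.r_freq + self.r_expr + (self.k + self.r_ic50)) * self.wf:
            raise ValidationError(f"peptide {self.peptide_id!r}: inconsistent RSUM")


def rank_parameter(
    values: Sequence[tuple[str, float]] | Mapping[str, float],
    direction: str,
) -> dict[str, int]:
    """Competition (minimum) ranks for one parameter.

    ``direction`` is ``"higher_better"`` or ``"lower_better"``. Tied values
    share the smallest rank of their block; the next distinct value gets
    1 + the count of strictly better peptides.
    """
    if direction not in ("higher_better", "lower_better"):
        raise ValidationError(f"unknown ranking direction {direction!r}")
    items = list(values.items()) if isinstance(values, Mapping) else list(values)
    series = pd.Series([v for _, v in items], index=[k for k, _ in items], dtype=float)
    bad = series.index[~np.isfinite(series.to_numpy())].tolist()
    if bad:
        raise ValidationError(f"non-finite parameter values for peptides {bad}")
    ranks = series.rank(method="min", ascending=direction == "lower_better").astype(int)
    return ranks.to_dict()


def penalty_k(
    best_ic50_nm: float, n_candidates: int, threshold_nm: float = PENALTY_THRESHOLD_NM
) -> int:
    """Rank penalty: N candidates when the best IC50 strictly exceeds the threshold."""
    if n_candidates < 1:
        raise ValidationError("n_candidates must be >= 1")
    return n_candidates if best_ic50_nm > threshold_nm else 0


def score_patient(
    candidates: pd.DataFrame, penalty_threshold_nm: float = PENALTY_THRESHOLD_NM
) -> pd.DataFrame:
    """Score and order one patient's full candidate table by RSUM.

    The input must hold one row per candidate peptide with the columns in
    :data:`REQUIRED_COLUMNS`. Returns a copy with ``r_freq``, ``r_expr``,
    ``r_ic50``, ``k``, ``wf``, ``rsum`` and ``final_position`` (1 = best),
    sorted by final position. Permuting input rows does not change any
    peptide's final position.
    """
    missing_cols = set(REQUIRED_COLUMNS) - set(candidates.columns)
    if missing_cols:
        raise ValidationError(f"candidate table is missing columns: {sorted(missing_cols)}")
    df = candidates.copy()
    dup = df.loc[df["peptide_id"].duplicated(), "peptide_id"].tolist()
    if dup:
        raise ValidationError(f"duplicate peptide_ids: {sorted(set(dup))}")
    orphan_mask = df[list(REQUIRED_COLUMNS)].isna().any(axis=1)
    if orphan_mask.any():
        raise ValidationError(
            f"peptides with missing joined inputs: {sorted(df.loc[orphan_mask, 'peptide_id'])}"
        )
    wf = df["wf"].astype(int)
    if not wf.isin(range(1, 6)).all():
        raise ValidationError("wf values must be integers in {1..5}")

    n = len(df)
    ids = df["peptide_id"].astype(str)
    r_freq = rank_parameter(list(zip(ids, df["tumor_mf"])), "higher_better")
    r_expr = rank_parameter(list(zip(ids, df["corr_tpm"])), "higher_better")
    r_ic50 = rank_parameter(list(zip(ids, df["best_ic50_nm"])), "lower_better")
    df["r_freq"] = [r_freq[i] for i in ids]
    df["r_expr"] = [r_expr[i] for i in ids]
    df["r_ic50"] = [r_ic50[i] for i in ids]
    df["k"] = [penalty_k(v, n, penalty_threshold_nm) for v in df["best_ic50_nm"]]
    df["wf"] = wf
    df["rsum"] = (df["r_freq"] + df["r_expr"] + df["k"] + df["r_ic50"]) * df["wf"]
    df = df.sort_values(
        ["rsum", "best_ic50_nm", "peptide_id"], kind="mergesort"
    ).reset_index(drop=True)
    df["final_position"] = np.arange(1, n + 1)
    return df


def scored_records(scored: pd.DataFrame) -> list[ScoredPeptide]:
    """View a scored table as a list of :class:`ScoredPeptide` records."""
    return [
        ScoredPeptide(
            peptide_id=str(row.peptide_id),
            r_freq=int(row.r_freq),
            r_expr=int(row.r_expr),
            r_ic50=int(row.r_ic50),
            k=int(row.k),
            wf=int(row.wf),
            rsum=int(row.rsum),
            final_position=int(row.final_position),
        )
        for row in scored.itertuples(index=False)
    ]


def rank_alternative(
    candidates: pd.DataFrame,
    strategy: str,
    funnel_ic50_nm: float = 500.0,
    funnel_tpm_min: float = 0.50,
    penalty_threshold_nm: float = PENALTY_THRESHOLD_NM,
) -> pd.DataFrame:
    """Order candidates by one of the comparator strategies (or the full score).

    ``funnel_then_ic50`` removes peptides failing either fixed threshold
    (best IC50 <= ``funnel_ic50_nm`` and gene TPM >= ``funnel_tpm_min``) and
    sorts the survivors by ascending IC50, so its output may be shorter than
    its input. Single-parameter strategies sort the whole table by that
    parameter alone (ties broken by peptide_id).
    """
    if strategy not in STRATEGIES:
        raise ValidationError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if strategy == "venus":
        return score_patient(candidates, penalty_threshold_nm)
    df = candidates.copy()
    if strategy == "mf_only":
        df = df.sort_values(["tumor_mf", "peptide_id"], ascending=[False, True], kind="mergesort")
    elif strategy == "expr_only":
        df = df.sort_values(["corr_tpm", "peptide_id"], ascending=[False, True], kind="mergesort")
    elif strategy == "ic50_only":
        df = df.sort_values(["best_ic50_nm", "peptide_id"], kind="mergesort")
    else:  # funnel_then_ic50
        if "tpm" not in df.columns:
            raise ValidationError("funnel_then_ic50 requires a 'tpm' column (gene TPM)")
        df = df[(df["best_ic50_nm"] <= funnel_ic50_nm) & (df["tpm"] >= funnel_tpm_min)]
        df = df.sort_values(["best_ic50_nm", "peptide_id"], kind="mergesort")
    df = df.reset_index(drop=True)
    df["final_position"] = np.arange(1, len(df) + 1)
    return df
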