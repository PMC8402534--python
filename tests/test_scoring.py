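import numpy as np
import pandas as pd
import pytest

from venus import ValidationError, penalty_k, rank_alternative, rank_parameter, score_patient
from venus.scoring import scored_records


def brute_force_score(df: pd.DataFrame, threshold: float = 1000.0) -> pd.DataFrame:
    """Independent oracle: ranks by exhaustive pairwise comparison, literal formula."""
    n = len(df)
    rows = []
    for _, row in df.iterrows():
        r_freq = 1 + int((df["tumor_mf"] > row["tumor_mf"]).sum())
        r_expr = 1 + int((df["corr_tpm"] > row["corr_tpm"]).sum())
        r_ic50 = 1 + int((df["best_ic50_nm"] < row["best_ic50_nm"]).sum())
        k = n if row["best_ic50_nm"] > threshold else 0
        rsum = (r_freq + r_expr + (k + r_ic50)) * int(row["wf"])
        rows.append(
            dict(
                peptide_id=row["peptide_id"],
                r_freq=r_freq,
                r_expr=r_expr,
                r_ic50=r_ic50,
                k=k,
                rsum=rsum,
                best_ic50_nm=row["best_ic50_nm"],
            )
        )
    out = pd.DataFrame(rows).sort_values(["rsum", "best_ic50_nm", "peptide_id"])
    out["final_position"] = np.arange(1, n + 1)
    return out.set_index("peptide_id")


def random_candidates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peptide_id": [f"P{i}" for i in range(n)],
            "tumor_mf": rng.choice([0.1, 0.25, 0.25, 0.5, 0.9], size=n),
            "corr_tpm": rng.choice([0.0, 0.5, 2.0, 2.0, 40.0], size=n),
            "wf": rng.integers(1, 6, size=n),
            "best_ic50_nm": rng.choice([20.0, 450.0, 450.0, 990.0, 1001.0, 8000.0], size=n),
            "tpm": rng.choice([0.1, 0.6, 3.0], size=n),
        }
    )


class TestRankParameter:
    def test_strict_orderings(self):
        assert rank_parameter([("a", 0.5), ("b", 0.3), ("c", 0.1)], "higher_better") == {
            "a": 1,
            "b": 2,
            "c": 3,
        }
        assert rank_parameter([("a", 30.0), ("b", 900.0), ("c", 5000.0)], "lower_better") == {
            "a": 1,
            "b": 2,
            "c": 3,
        }

    def test_competition_ties_share_smallest_rank(self):
        assert rank_parameter([("a", 0.5), ("b", 0.5), ("c", 0.2)], "higher_better") == {
            "a": 1,
            "b": 1,
            "c": 3,
        }

    def test_nan_names_the_peptide(self):
        with pytest.raises(ValidationError, match="bad"):
            rank_parameter([("ok", 1.0), ("bad", float("nan"))], "higher_better")


class TestPenalty:
    @pytest.mark.parametrize(
        "ic50, n, expected",
        [(1500.0, 300, 300), (1000.0, 300, 0), (50.0, 7, 0)],
    )
    def test_boundary_is_strictly_greater(self, ic50, n, expected):
        assert penalty_k(ic50, n) == expected


class TestScorePatient:
    def test_sole_candidate_reaches_minimum_rsum(self):
        df = pd.DataFrame(
            {
                "peptide_id": ["P1"],
                "tumor_mf": [0.4],
                "corr_tpm": [3.0],
                "wf": [1],
                "best_ic50_nm": [500.0],
            }
        )
        scored = score_patient(df)
        assert scored.loc[0, "rsum"] == 3  # (1 + 1 + (0 + 1)) * 1
        assert scored.loc[0, "final_position"] == 1

    def test_rank_sum_arithmetic_and_wf_inflation(self):
        # a candidate ranked 2, 5, 1 with k=0: rsum 8 at wf=1, 40 at wf=5
        def table(wf):
            return pd.DataFrame(
                {
                    "peptide_id": ["X", "A", "B", "C", "D"],
                    "tumor_mf": [0.5, 0.9, 0.1, 0.2, 0.3],
                    "corr_tpm": [1.0, 5.0, 4.0, 3.0, 2.0],
                    "wf": [wf, 1, 1, 1, 1],
                    "best_ic50_nm": [10.0, 20.0, 30.0, 40.0, 50.0],
                }
            )

        low = score_patient(table(1)).set_index("peptide_id")
        high = score_patient(table(5)).set_index("peptide_id")
        assert (low.loc["X", ["r_freq", "r_expr", "r_ic50"]] == [2, 5, 1]).all()
        assert low.loc["X", "rsum"] == 8
        assert high.loc["X", "rsum"] == 40
        assert high.loc["X", "final_position"] >= low.loc["X", "final_position"]

    def test_matches_brute_force_oracle_on_small_tables(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            df = random_candidates(rng, int(rng.integers(1, 7)))
            scored = score_patient(df).set_index("peptide_id")
            oracle = brute_force_score(df)
            for col in ("r_freq", "r_expr", "r_ic50", "k", "rsum", "final_position"):
                assert scored[col].to_dict() == oracle[col].to_dict(), col

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        df = random_candidates(rng, 30)
        base = score_patient(df).set_index("peptide_id")["final_position"]
        shuffled = score_patient(df.sample(frac=1, random_state=1)).set_index("peptide_id")[
            "final_position"
        ]
        assert base.to_dict() == shuffled.to_dict()

    def test_improving_one_parameter_never_worsens_rsum(self):
        rng = np.random.default_rng(7)
        df = random_candidates(rng, 20)
        scored = score_patient(df).set_index("peptide_id")
        better = df.copy()
        better.loc[better["peptide_id"] == "P0", "best_ic50_nm"] = 1.0
        rescored = score_patient(better).set_index("peptide_id")
        assert rescored.loc["P0", "rsum"] <= scored.loc["P0", "rsum"]

    def test_missing_join_lists_orphans(self):
        df = pd.DataFrame(
            {
                "peptide_id": ["P1", "P2"],
                "tumor_mf": [0.5, 0.4],
                "corr_tpm": [1.0, None],
                "wf": [1, 1],
                "best_ic50_nm": [10.0, 20.0],
            }
        )
        with pytest.raises(ValidationError, match="P2"):
            score_patient(df)

    def test_scored_records_invariant(self):
        rng = np.random.default_rng(3)
        records = scored_records(score_patient(random_candidates(rng, 10)))
        positions = sorted(r.final_position for r in records)
        assert positions == list(range(1, 11))
        for r in records:
            assert r.k in (0, 10)
            assert 1 <= r.wf <= 5
            assert r.rsum >= 3


class TestAlternativeStrategies:
    def test_funnel_excludes_weak_binders_regardless_of_expression(self):
        df = pd.DataFrame(
            {
                "peptide_id": ["P1", "P2"],
                "tumor_mf": [0.5, 0.4],
                "corr_tpm": [100.0, 1.0],
                "wf": [1, 1],
                "best_ic50_nm": [600.0, 400.0],
                "tpm": [120.0, 1.5],
            }
        )
        ranked = rank_alternative(df, "funnel_then_ic50")
        assert list(ranked["peptide_id"]) == ["P2"]

    def test_funnel_requires_expressed_gene(self):
        df = pd.DataFrame(
            {
                "peptide_id": ["P1"],
                "tumor_mf": [0.5],
                "corr_tpm": [0.0],
                "wf": [2],
                "best_ic50_nm": [100.0],
                "tpm": [0.4],
            }
        )
        assert rank_alternative(df, "funnel_then_ic50").empty

    def test_single_parameter_orderings(self):
        rng = np.random.default_rng(9)
        df = random_candidates(rng, 15)
        mf = rank_alternative(df, "mf_only")
        assert list(mf["tumor_mf"]) == sorted(mf["tumor_mf"], reverse=True)
        expr = rank_alternative(df, "expr_only")
        assert list(expr["corr_tpm"]) == sorted(expr["corr_tpm"], reverse=True)
        ic50 = rank_alternative(df, "ic50_only")
        assert list(ic50["best_ic50_nm"]) == sorted(ic50["best_ic50_nm"])

    def test_venus_strategy_delegates_to_score_patient(self):
        rng = np.random.default_rng(11)
        df = random_candidates(rng, 25)
        direct = score_patient(df)
        via_strategy = rank_alternative(df, "venus")
        pd.testing.assert_frame_equal(direct, via_strategy)

    def test_unknown_strategy_is_a_usage_error(self):
        with pytest.raises(ValidationError, match="unknown strategy"):
            rank_alternative(random_candidates(np.random.default_rng(1), 3), "magic")
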