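import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from murideconv import (
    MedianMarkerScorer,
    SignedRankScorer,
    WeightedGeneSetCollection,
    median_marker_score,
    signed_rank_score,
)
from murideconv.errors import CoverageError, ValidationError

from conftest import make_expr


def rank_score_oracle(vec, up, down=()):
    """Independent brute-force signed rank score on one expression vector."""
    vec = pd.Series(vec)
    r = pd.Series(rankdata(vec.to_numpy(), method="average"), index=vec.index)
    r = r / len(vec)
    up_mean = r[list(up)].mean()
    if down:
        return up_mean - r[list(down)].mean()
    return up_mean - 0.5


class TestMedianMarkerScore:
    def test_singleton_marker_equals_transformed_expression(self):
        expr = make_expr([[4.0, 9.0], [1.0, 1.0]], genes=["m", "x"])
        sets = WeightedGeneSetCollection({"T": [("m", 1)]})
        res = median_marker_score(expr, sets, log_transform=False)
        assert res.data.loc["T"].tolist() == [4.0, 9.0]
        res = median_marker_score(expr, sets, log_transform=True)
        assert np.allclose(res.data.loc["T"], np.log2(np.array([4.0, 9.0]) + 1))

    def test_median_by_hand(self):
        expr = make_expr([[1.0], [3.0], [100.0]], genes=["a", "b", "c"])
        sets = WeightedGeneSetCollection({"T": [("a", 1), ("b", 1), ("c", 1)]})
        res = median_marker_score(expr, sets, log_transform=False)
        assert res.data.loc["T"].item() == 3.0

    def test_marker_order_irrelevant(self):
        rng = np.random.default_rng(0)
        expr = make_expr(rng.uniform(0, 10, (5, 3)))
        genes = expr.gene_ids
        a = median_marker_score(
            expr, WeightedGeneSetCollection({"T": [(g, 1) for g in genes]})
        )
        b = median_marker_score(
            expr, WeightedGeneSetCollection({"T": [(g, 1) for g in genes[::-1]]})
        )
        assert a.data.equals(b.data)

    def test_invariant_to_non_marker_genes(self):
        rng = np.random.default_rng(1)
        expr = make_expr(rng.uniform(0, 10, (6, 2)))
        sets = WeightedGeneSetCollection({"T": [("g0", 1), ("g1", 1)]})
        before = median_marker_score(expr, sets).data
        expr2 = make_expr(
            np.vstack([expr.values[:2], rng.uniform(0, 100, (4, 2))]),
            genes=expr.gene_ids,
        )
        assert median_marker_score(expr2, sets).data.equals(before)

    def test_absent_markers_ignored_and_all_absent_row_is_nan(self):
        expr = make_expr([[2.0], [1.0]], genes=["m1", "x"])
        sets = WeightedGeneSetCollection(
            {"T": [("m1", 1), ("gone", 1)], "E": [("nope", 1)]}
        )
        res = median_marker_score(expr, sets, log_transform=False)
        assert res.data.loc["T"].item() == 2.0
        assert np.isnan(res.data.loc["E"].item())

    def test_all_types_uncovered_is_hard_error(self):
        expr = make_expr([[1.0], [1.0]], genes=["x", "y"])
        sets = WeightedGeneSetCollection({"T": [("gone", 1)]})
        with pytest.raises(CoverageError):
            median_marker_score(expr, sets)

    def test_down_weighted_genes_rejected(self):
        expr = make_expr([[1.0], [2.0]], genes=["a", "b"])
        sets = WeightedGeneSetCollection({"T": [("a", 1), ("b", -1)]})
        with pytest.raises(ValidationError, match="down-weighted"):
            median_marker_score(expr, sets)

    def test_log_input_with_log_transform_rejected(self):
        expr = make_expr([[1.0], [2.0]], genes=["a", "b"], unit="log2_TPM")
        sets = WeightedGeneSetCollection({"T": [("a", 1)]})
        with pytest.raises(ValidationError, match="log2"):
            median_marker_score(expr, sets, log_transform=True)


class TestSignedRankScore:
    def test_top_gene_scores_one_half(self):
        expr = make_expr([[1.0], [2.0], [3.0], [10.0]])
        sets = WeightedGeneSetCollection({"T": [("g3", 1)]})
        res = signed_rank_score(expr, sets)
        assert res.data.loc["T"].item() == pytest.approx(0.5)

    def test_up_and_down_sets_with_tied_expression_cancel(self):
        # g0/g1 share one value, g2/g3 another: mid-ranks make the up and
        # down means identical, so the signed score is exactly 0
        expr = make_expr([[5.0], [5.0], [1.0], [1.0], [9.0]])
        sets = WeightedGeneSetCollection(
            {"S": [("g0", 1), ("g2", 1), ("g1", -1), ("g3", -1)]}
        )
        res = signed_rank_score(expr, sets)
        assert res.data.loc["S"].item() == 0.0
        # and the oracle agrees that a literally identical up/down set cancels
        assert rank_score_oracle(expr.data["s0"], ["g0", "g4"], ["g0", "g4"]) == 0.0

    def test_matches_brute_force_oracle(self):
        vec = [7.0, 1.0, 3.0, 3.0, 12.0, 0.5, 9.0, 3.0, 2.0, 11.0]
        expr = make_expr([[v] for v in vec])
        genes = expr.gene_ids
        up = ["g0", "g4", "g6"]
        down = ["g1", "g5"]
        sets = WeightedGeneSetCollection(
            {"A": [(g, 1) for g in up],
             "B": [(g, 1) for g in up] + [(g, -1) for g in down]}
        )
        res = signed_rank_score(expr, sets)
        assert res.data.loc["A"].item() == pytest.approx(
            rank_score_oracle(dict(zip(genes, vec)), up)
        )
        assert res.data.loc["B"].item() == pytest.approx(
            rank_score_oracle(dict(zip(genes, vec)), up, down)
        )

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(2)
        expr = make_expr(rng.uniform(0.1, 50, (30, 4)))
        sets = WeightedGeneSetCollection(
            {"T": [(f"g{i}", 1) for i in range(5)] + [(f"g{i}", -1) for i in range(5, 8)]}
        )
        base = signed_rank_score(expr, sets).data
        warped = make_expr(np.log1p(expr.values) ** 3, genes=expr.gene_ids)
        assert np.allclose(signed_rank_score(warped, sets).data, base)

    def test_random_up_set_null_mean_is_near_zero(self):
        """Mean score of 1000 uniformly random up-sets is ~0."""
        rng = np.random.default_rng(7)
        expr = make_expr(rng.uniform(0, 100, (200, 1)))
        genes = np.array(expr.gene_ids)
        scores = []
        for _ in range(1000):
            up = rng.choice(genes, size=10, replace=False)
            sets = WeightedGeneSetCollection({"T": [(g, 1) for g in up]})
            scores.append(signed_rank_score(expr, sets).data.iloc[0, 0])
        assert abs(np.mean(scores)) < 0.02


class TestMonotonicity:
    @pytest.mark.parametrize("engine", ["median", "rank"])
    def test_upshifting_markers_never_decreases_score(self, engine):
        rng = np.random.default_rng(11)
        n_ok = 0
        for trial in range(20):
            trial_rng = np.random.default_rng(100 + trial)
            expr = make_expr(trial_rng.uniform(0.1, 20, (40, 1)))
            up = [f"g{i}" for i in trial_rng.choice(40, size=6, replace=False)]
            sets = WeightedGeneSetCollection({"T": [(g, 1) for g in up]})
            shifted = expr.data.copy()
            shifted.loc[up] *= 1.0 + trial_rng.uniform(0.1, 2.0)
            expr2 = make_expr(shifted.to_numpy(), genes=expr.gene_ids)
            if engine == "median":
                s1 = median_marker_score(expr, sets).data.iloc[0, 0]
                s2 = median_marker_score(expr2, sets).data.iloc[0, 0]
            else:
                s1 = signed_rank_score(expr, sets).data.iloc[0, 0]
                s2 = signed_rank_score(expr2, sets).data.iloc[0, 0]
            n_ok += s2 >= s1 - 1e-12
        assert n_ok == 20


class TestEstimatorAPI:
    def test_fit_transform_shapes_and_feature_names(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(
            rng.uniform(0, 10, (4, 6)),
            columns=[f"g{i}" for i in range(6)],
            index=[f"s{i}" for i in range(4)],
        )
        sets = WeightedGeneSetCollection(
            {"T": [("g0", 1)], "B": [("g1", 1), ("g2", 1)]}
        )
        est = MedianMarkerScorer(sets=sets, log_transform=False)
        out = est.fit_transform(X)
        assert out.shape == (4, 2)
        assert list(est.get_feature_names_out()) == ["T", "B"]

    def test_sklearn_clone_and_get_params(self):
        from sklearn.base import clone

        sets = WeightedGeneSetCollection({"T": [("g0", 1)]})
        est = SignedRankScorer(sets=sets)
        cloned = clone(est)
        assert cloned.get_params()["sets"] == sets
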