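import itertools

import numpy as np
import pandas as pd
import pytest

from murideconv import (
    CLSOptions,
    ConstrainedLSDeconvolver,
    ENOptions,
    SVROptions,
    SignatureMatrix,
    cls_deconvolve,
    elasticnet_deconvolve,
    nusvr_deconvolve,
    run_method,
)
from murideconv.errors import ConfigError, CoverageError, ValidationError

from conftest import make_expr, random_signature


def simplex_grid_oracle(S, b, step=0.01, allow_unknown=True):
    """Brute-force search over the fraction simplex at the given step.

    Enumerates all non-negative fraction vectors on the grid with
    sum ≤ 1 (or == 1) and returns the SSE-minimizing one.  Only viable
    for ≤ 3 cell types.
    """
    k = S.shape[1]
    n = round(1.0 / step)
    best, best_sse = None, np.inf
    for combo in itertools.product(range(n + 1), repeat=k - 1):
        rest = n - sum(combo)
        if rest < 0:
            continue
        choices = range(rest + 1) if allow_unknown else (rest,)
        for last in choices:
            f = np.array([*combo, last]) * step
            r = S @ f - b
            sse = r @ r
            if sse < best_sse:
                best_sse, best = sse, f
    return best


def _mixture_expr(S, fracs):
    b = S.data.to_numpy() @ np.asarray(fracs)
    return make_expr(b[:, None], genes=S.gene_ids, samples=["s1"], unit="TPM")


class TestCLS:
    def test_self_mixture_recovers_unit_fraction(self):
        rng = np.random.default_rng(0)
        sig = random_signature(rng, n_genes=20, n_types=5)
        expr = make_expr(
            sig.data.iloc[:, 2].to_numpy()[:, None], genes=sig.gene_ids, samples=["s1"]
        )
        res = cls_deconvolve(expr, sig, CLSOptions(allow_unknown=True))
        f = res.data["s1"]
        assert f["ct2"] == pytest.approx(1.0, abs=1e-6)
        assert f["uncharacterized"] == pytest.approx(0.0, abs=1e-6)

    def test_exact_two_type_mixture(self):
        rng = np.random.default_rng(1)
        sig = random_signature(rng, n_genes=20, n_types=2)
        res = cls_deconvolve(_mixture_expr(sig, [0.3, 0.7]), sig)
        f = res.data["s1"]
        assert f["ct0"] == pytest.approx(0.3, abs=1e-6)
        assert f["ct1"] == pytest.approx(0.7, abs=1e-6)

    def test_unknown_content_of_orthogonal_profile(self):
        """Half the mixture comes from a profile supported on genes where
        the signature is zero: the uncharacterized fraction is 0.5, and the
        grid oracle agrees."""
        rng = np.random.default_rng(2)
        known = rng.uniform(1, 100, size=(20, 2))
        known = known / known.sum(axis=0) * 1e6
        S = np.vstack([known, np.zeros((10, 2))])
        absent = np.concatenate([np.zeros(20), rng.uniform(1, 100, size=10)])
        absent = absent / absent.sum() * 1e6
        genes = [f"g{i}" for i in range(30)]
        sig = SignatureMatrix(pd.DataFrame(S, index=genes, columns=["A", "B"]))
        b = 0.5 * S[:, 0] + 0.5 * absent
        expr = make_expr(b[:, None], genes=genes, samples=["s1"])
        res = cls_deconvolve(expr, sig, CLSOptions(allow_unknown=True))
        f = res.data["s1"]
        assert f["uncharacterized"] == pytest.approx(0.5, abs=0.01)
        oracle = simplex_grid_oracle(S, b, step=0.01)
        assert np.abs(f[["A", "B"]].to_numpy() - oracle).max() <= 0.011

    @pytest.mark.parametrize("allow_unknown", [True, False])
    def test_matches_simplex_grid_oracle(self, allow_unknown):
        """SLSQP solution within 0.02 per fraction of the 0.01-step
        brute-force simplex search on noisy 3-type instances."""
        for seed in range(8):
            rng = np.random.default_rng(seed)
            sig = random_signature(rng, n_genes=20, n_types=3)
            S = sig.data.to_numpy()
            f_true = rng.dirichlet(np.ones(3)) * (0.8 if allow_unknown else 1.0)
            b = S @ f_true + rng.normal(0, 2000, size=20)
            b = np.clip(b, 0, None)
            expr = make_expr(b[:, None], genes=sig.gene_ids, samples=["s1"])
            res = cls_deconvolve(expr, sig, CLSOptions(allow_unknown=allow_unknown))
            est = res.known_part()["s1"].to_numpy()
            # oracle works on the same renormalized problem the solver sees
            b_norm = b / b.sum() * 1e6
            oracle = simplex_grid_oracle(S, b_norm, 0.01, allow_unknown)
            assert np.abs(est - oracle).max() <= 0.02

    def test_column_sums(self):
        rng = np.random.default_rng(3)
        sig = random_signature(rng, n_genes=30, n_types=4)
        expr = make_expr(
            rng.uniform(1, 100, size=(30, 5)), genes=sig.gene_ids,
        )
        eq = cls_deconvolve(expr, sig, CLSOptions(allow_unknown=False))
        assert np.abs(eq.values.sum(axis=0) - 1).max() < 1e-9
        ineq = cls_deconvolve(expr, sig, CLSOptions(allow_unknown=True))
        assert np.abs(ineq.values.sum(axis=0) - 1).max() < 1e-9  # incl. unknown row
        assert ineq.unknown_row

    def test_scale_invariance_per_sample(self):
        rng = np.random.default_rng(4)
        sig = random_signature(rng, n_genes=25, n_types=3)
        X = rng.uniform(1, 50, size=(25, 2))
        a = cls_deconvolve(make_expr(X, genes=sig.gene_ids), sig)
        X2 = X.copy()
        X2[:, 0] *= 37.5
        b = cls_deconvolve(make_expr(X2, genes=sig.gene_ids), sig)
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_mrna_renormalization_rescales_known_part_only(self):
        rng = np.random.default_rng(5)
        S = random_signature(rng, n_genes=20, n_types=2)
        sig = SignatureMatrix(S.data, mrna_scaling=pd.Series({"ct0": 2.0, "ct1": 1.0}))
        expr = _mixture_expr(S, [0.5, 0.5])
        res = cls_deconvolve(expr, sig, CLSOptions(allow_unknown=True,
                                                   mrna_renormalize=True))
        f = res.data["s1"]
        # equal mRNA fractions, ct0 has double mRNA per cell -> cell fractions 1/3, 2/3
        assert f["ct0"] == pytest.approx(1 / 3, abs=1e-5)
        assert f["ct1"] == pytest.approx(2 / 3, abs=1e-5)
        assert f["uncharacterized"] == pytest.approx(0.0, abs=1e-5)

    def test_low_coverage_is_fatal(self):
        rng = np.random.default_rng(6)
        sig = random_signature(rng, n_genes=30, n_types=3)
        expr = make_expr(rng.uniform(1, 5, (10, 2)),
                         genes=sig.gene_ids[:10])  # 33% coverage
        with pytest.raises(CoverageError, match="signature genes"):
            cls_deconvolve(expr, sig)

    def test_duplicate_signature_column_warns_but_solves(self, caplog):
        rng = np.random.default_rng(7)
        sig = random_signature(rng, n_genes=20, n_types=2)
        dup = SignatureMatrix(
            pd.DataFrame(
                np.column_stack([sig.data.to_numpy()] * 2)[:, :3],
                index=sig.gene_ids, columns=["A", "B", "Adup"],
            )
        )
        expr = make_expr(rng.uniform(1, 50, (20, 1)), genes=sig.gene_ids)
        import logging

        with caplog.at_level(logging.WARNING, logger="murideconv.regression"):
            res = cls_deconvolve(expr, dup)
        assert "duplicate" in caplog.text
        assert np.isfinite(res.values).all()

    def test_log_unit_input_rejected(self):
        rng = np.random.default_rng(8)
        sig = random_signature(rng)
        expr = make_expr(np.ones((20, 1)), genes=sig.gene_ids, unit="log2_TPM")
        with pytest.raises(ValidationError, match="linear"):
            cls_deconvolve(expr, sig)


class TestNuSVR:
    def test_noiseless_mixture_recovered(self):
        rng = np.random.default_rng(10)
        sig = random_signature(rng, n_genes=200, n_types=2)
        res = nusvr_deconvolve(_mixture_expr(sig, [0.3, 0.7]), sig)
        f = res.data["s1"]
        assert abs(f["ct0"] - 0.3) <= 0.05
        assert abs(f["ct1"] - 0.7) <= 0.05

    def test_pure_column_dominates(self):
        rng = np.random.default_rng(11)
        sig = random_signature(rng, n_genes=200, n_types=3)
        expr = make_expr(
            sig.data.iloc[:, 0].to_numpy()[:, None], genes=sig.gene_ids, samples=["s1"]
        )
        res = nusvr_deconvolve(expr, sig)
        assert res.data.loc["ct0", "s1"] >= 0.95

    def test_single_nu_grid_is_identity_selection(self):
        rng = np.random.default_rng(12)
        sig = random_signature(rng, n_genes=60, n_types=3)
        expr = make_expr(rng.uniform(1, 50, (60, 2)), genes=sig.gene_ids)
        res = nusvr_deconvolve(expr, sig, SVROptions(nu_grid=(0.5,)))
        assert np.abs(res.values.sum(axis=0) - 1).max() < 1e-9

    def test_invalid_nu_grid_rejected(self):
        with pytest.raises(ValidationError):
            SVROptions(nu_grid=())
        with pytest.raises(ValidationError):
            SVROptions(nu_grid=(1.5,))


class TestElasticNet:
    def test_exact_mixture_approximately_recovered(self):
        rng = np.random.default_rng(13)
        sig = random_signature(rng, n_genes=200, n_types=3)
        expr = _mixture_expr(sig, [0.2, 0.3, 0.5])
        res = elasticnet_deconvolve(
            expr, sig, ENOptions(n_repeats=1, subset_fraction=1.0, l1_ratio=0.05)
        )
        coef = res.data["s1"].to_numpy()
        # coefficients live on the z-scored scale; compare after rescaling
        coef = coef / coef.sum()
        assert np.abs(coef - np.array([0.2, 0.3, 0.5])).max() <= 0.05

    def test_seeded_determinism_is_bitwise(self):
        rng = np.random.default_rng(14)
        sig = random_signature(rng, n_genes=60, n_types=3)
        expr = make_expr(rng.uniform(1, 50, (60, 2)), genes=sig.gene_ids)
        a = elasticnet_deconvolve(expr, sig, ENOptions(seed=42, n_repeats=3))
        b = elasticnet_deconvolve(expr, sig, ENOptions(seed=42, n_repeats=3))
        assert np.array_equal(a.values, b.values)

    def test_doubling_a_type_increases_its_coefficient(self):
        """Paired simulation: raising one type's true content raises its
        elastic-net coefficient in at least 18/20 seeded trials."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            sig = random_signature(rng, n_genes=80, n_types=3)
            S = sig.data.to_numpy()
            lo = S @ np.array([0.2, 0.4, 0.4]) + rng.normal(0, 1000, 80)
            hi = S @ np.array([0.4, 0.3, 0.3]) + rng.normal(0, 1000, 80)
            expr = make_expr(
                np.clip(np.column_stack([lo, hi]), 0, None), genes=sig.gene_ids
            )
            res = elasticnet_deconvolve(
                expr, sig, ENOptions(n_repeats=2, subset_fraction=0.8, seed=seed)
            )
            wins += res.data.loc["ct0", "s1"] > res.data.loc["ct0", "s0"]
        assert wins >= 18

    def test_too_small_subsets_rejected(self):
        rng = np.random.default_rng(15)
        sig = random_signature(rng, n_genes=20, n_types=2)
        expr = make_expr(rng.uniform(1, 5, (20, 1)), genes=sig.gene_ids)
        with pytest.raises(ValidationError, match="too small"):
            elasticnet_deconvolve(expr, sig, ENOptions(subset_fraction=0.05))

    def test_scores_not_forced_to_simplex(self):
        rng = np.random.default_rng(16)
        sig = random_signature(rng, n_genes=60, n_types=3)
        expr = make_expr(rng.uniform(1, 50, (60, 1)), genes=sig.gene_ids)
        res = elasticnet_deconvolve(expr, sig)
        assert res.estimate_type == "score"


class TestRunMethod:
    def test_dispatch_transparency_for_marker_scoring(self, pipeline_run):
        from murideconv import median_marker_score, get_resource

        expr = pipeline_run["dataset"].expr
        markers = pipeline_run["markers"]
        direct = median_marker_score(expr, markers)
        via = run_method(expr, "mmcp_like", resource=markers,
                         harmonize_labels=False)
        assert np.array_equal(
            via.values[~np.isnan(via.values)], direct.values[~np.isnan(direct.values)]
        )

    def test_unknown_method_lists_registered(self):
        expr = make_expr([[1.0], [2.0]])
        with pytest.raises(ConfigError, match="mmcp_like"):
            run_method(expr, "bogus")

    def test_human_signature_method_converts_mouse_input(self, pipeline_run):
        """A murine matrix fed to a human-signature method goes through
        ortholog conversion first (uppercased gene space)."""
        from murideconv import GeneMappingTable, get_resource

        sig = get_resource("seqimmucc_like")
        genes = sig.gene_ids
        rng = np.random.default_rng(17)
        expr = make_expr(rng.uniform(1, 100, (len(genes), 2)), genes=genes)
        table = GeneMappingTable([(g, g.upper()) for g in genes])
        res = run_method(expr, "cls_human_sig", species="mouse",
                         ortholog_table=table)
        assert res.metadata["ortholog_mapping"]["n_mapped"] == len(genes)
        assert res.estimate_type == "fraction"

    def test_user_resource_required_where_declared(self):
        expr = make_expr([[1.0], [2.0]])
        with pytest.raises(ConfigError, match="user-supplied"):
            run_method(expr, "cls")
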