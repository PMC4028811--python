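import numpy as np
import pytest

from arrayimpute import (ExpressionMatrix, LeastSquaresConfig, apply_mask,
                         estimate_k_auto, ills_impute, inject_missing, lls_impute,
                         lsa_impute, make_lowrank, nrmse, slls_impute)
from arrayimpute.results import check_preserves

from conftest import random_matrix_with_missing


class TestLls:
    def test_exact_linear_dependence_is_recovered(self):
        vals = np.array([[1.0, 2.0, np.nan],
                         [2.0, 4.0, 8.0]])
        m = ExpressionMatrix(["g1", "g2"], ["s1", "s2", "s3"], vals)
        res = lls_impute(m, LeastSquaresConfig(k=1))
        assert res.imputed.values[0, 2] == pytest.approx(4.0, abs=1e-6)

    def test_two_neighbor_combination_recovered(self):
        rng = np.random.default_rng(0)
        n1 = rng.standard_normal(6)
        n2 = rng.standard_normal(6)
        t = 2.0 * n1 - 3.0 * n2
        vals = np.vstack([n1, n2, t])
        truth = vals[2, 4]
        vals[2, 4] = np.nan
        m = ExpressionMatrix(["n1", "n2", "t"], [f"s{j}" for j in range(6)], vals)
        res = lls_impute(m, LeastSquaresConfig(k=2))
        assert res.imputed.values[2, 4] == pytest.approx(truth, abs=1e-6)

    def test_matches_independent_pseudoinverse_oracle(self):
        for seed in range(20):
            m, _ = make_lowrank(30, 8, 3, noise_sd=0.0, seed=seed)
            md = inject_missing(m, 1.0 / 240, seed=seed + 100)
            mm = apply_mask(md)
            res = lls_impute(mm, LeastSquaresConfig(k=5, ridge=0.0))
            (g, s) = md.positions[0]
            # oracle: re-select neighbours by |pearson| over observed columns
            # and solve the normal system through numpy's pinv directly
            O = ~np.isnan(mm.values[g])
            cand = [c for c in range(30) if c != g]
            r = np.array([abs(np.corrcoef(mm.values[c, O], mm.values[g, O])[0, 1])
                          for c in cand])
            top = [cand[i] for i in np.argsort(-r, kind="stable")[:5]]
            A = mm.values[np.array(top)][:, O]
            B = mm.values[np.array(top)][:, ~O]
            x = np.linalg.pinv(A.T) @ mm.values[g, O]
            expected = (B.T @ x).item()
            assert res.imputed.values[g, s] == pytest.approx(expected, abs=1e-8)

    def test_no_missing_is_identity(self, complete_matrix):
        assert lls_impute(complete_matrix).imputed.equals(complete_matrix)

    def test_observed_entries_preserved(self):
        m = random_matrix_with_missing(25, 8, 0.15, seed=5)
        assert check_preserves(lls_impute(m, LeastSquaresConfig(k=5)), m)


class TestSlls:
    def test_single_incomplete_gene_reduces_to_lls(self):
        rng = np.random.default_rng(2)
        vals = rng.standard_normal((10, 6))
        vals[4, 1] = np.nan
        m = ExpressionMatrix([f"g{i}" for i in range(10)], [f"s{j}" for j in range(6)], vals)
        a = slls_impute(m, LeastSquaresConfig(k=4))
        b = lls_impute(m, LeastSquaresConfig(k=4))
        assert np.allclose(a.imputed.values, b.imputed.values)

    def test_sequential_pool_grows(self):
        rng = np.random.default_rng(3)
        vals = rng.standard_normal((8, 6))
        vals[2, 0] = np.nan
        vals[5, 0] = vals[5, 1] = np.nan
        m = ExpressionMatrix([f"g{i}" for i in range(8)], [f"s{j}" for j in range(6)], vals)
        res = slls_impute(m, LeastSquaresConfig(k=3, trace=True))
        pools = res.diagnostics["candidate_pool"]
        assert res.diagnostics["order"] == ["g2", "g5"]
        assert "g2" not in pools["g2"] and "g2" in pools["g5"]

    def test_no_missing_is_identity(self, complete_matrix):
        assert slls_impute(complete_matrix).imputed.equals(complete_matrix)


class TestIlls:
    def test_no_missing_is_identity(self, complete_matrix):
        res = ills_impute(complete_matrix)
        assert res.imputed.equals(complete_matrix) and res.n_iterations == 0

    def test_infinite_tol_is_one_pass(self):
        m = random_matrix_with_missing(15, 6, 0.1, seed=4)
        res = ills_impute(m, LeastSquaresConfig(k=5, tol=np.inf))
        assert res.n_iterations == 1 and res.converged

    def test_exact_recovery_on_noiseless_rank_two(self):
        m, _ = make_lowrank(40, 10, 2, noise_sd=0.0, seed=9)
        md = inject_missing(m, 0.05, seed=10)
        res = ills_impute(apply_mask(md), LeastSquaresConfig(k=5))
        assert nrmse(res.y_guess(md), md.y_answer) < 1e-6


class TestLsa:
    def test_proportional_genes_give_exact_gene_route(self):
        c = np.linspace(0.5, 3.0, 12)[:, None]
        base = np.array([[1.0, -2.0, 3.0, -1.0, 2.0]])
        vals = c @ base
        truth = vals[4, 2]
        vals[4, 2] = np.nan
        m = ExpressionMatrix([f"g{i}" for i in range(12)], [f"s{j}" for j in range(5)], vals)
        res = lsa_impute(m, LeastSquaresConfig())
        assert res.imputed.values[4, 2] == pytest.approx(truth, abs=1e-6)

    def test_blend_weight_prefers_better_array_route(self):
        # strong column effects + small iid noise: the array route averages
        # the noise over hundreds of genes while the gene route averages it
        # over only 10 neighbours, so the fitted blend leans to the arrays
        rng = np.random.default_rng(11)
        b = rng.standard_normal(8) * 10
        vals = b[None, :] + 0.5 * rng.standard_normal((300, 8))
        vals[3, 5] = np.nan
        m = ExpressionMatrix([f"g{i}" for i in range(300)], [f"s{j}" for j in range(8)], vals)
        res = lsa_impute(m, LeastSquaresConfig(probe_fraction=0.01, seed=1))
        assert res.diagnostics["p_gene"] <= 0.15

    def test_blend_weight_tie_resolves_to_zero(self):
        # rank-1 data: both routes are exact, every grid point ties, and the
        # minimiser takes the first grid value, p = 0
        m, _ = make_lowrank(30, 8, 1, noise_sd=0.0, seed=21)
        md = inject_missing(m, 0.02, seed=22)
        res = lsa_impute(apply_mask(md), LeastSquaresConfig(seed=2))
        assert res.diagnostics["p_gene"] == 0.0

    def test_no_missing_is_identity(self, complete_matrix):
        assert lsa_impute(complete_matrix).imputed.equals(complete_matrix)


class TestEstimateKAuto:
    def test_single_candidate_returned(self):
        m = random_matrix_with_missing(20, 6, 0.1, seed=6)
        cfg = LeastSquaresConfig(k_candidates=(7,), probe_fraction=0.05)
        assert estimate_k_auto(m, cfg, lls_impute) == 7

    def test_rank_one_data_reaches_zero_probe_error(self):
        m, _ = make_lowrank(40, 8, 1, noise_sd=0.0, seed=12)
        cfg = LeastSquaresConfig(k_candidates=(5, 10, 15), probe_fraction=0.02, seed=2)
        k = estimate_k_auto(m, cfg, lls_impute)
        assert k in (5, 10, 15)
        # zero is the global minimum: the winning k reconstructs the probes
        from dataclasses import replace
        from arrayimpute.leastsquares import _probe_positions
        from arrayimpute.masking import derive_seed
        rng = np.random.default_rng(derive_seed(cfg.seed, "auto_k"))
        probes = np.array(_probe_positions(~m.missing_mask, cfg.probe_fraction, rng))
        Xp = m.values.copy()
        Xp[probes[:, 0], probes[:, 1]] = np.nan
        res = lls_impute(m.with_values(Xp), replace(cfg, k=k))
        guess = res.imputed.values[probes[:, 0], probes[:, 1]]
        truth = m.values[probes[:, 0], probes[:, 1]]
        assert np.max(np.abs(guess - truth)) < 1e-7

    def test_returned_k_minimizes_probe_error(self):
        m, _ = make_lowrank(40, 8, 3, noise_sd=0.3, seed=13)
        md = inject_missing(m, 0.1, seed=14)
        mm = apply_mask(md)
        cfg = LeastSquaresConfig(k_candidates=(3, 5, 10, 20), probe_fraction=0.03, seed=3)
        k_star = estimate_k_auto(mm, cfg, lls_impute)
        # exhaustive re-evaluation over the candidate list is the oracle
        from dataclasses import replace
        from arrayimpute.leastsquares import _probe_positions
        from arrayimpute.masking import derive_seed
        rng = np.random.default_rng(derive_seed(cfg.seed, "auto_k"))
        probes = _probe_positions(~mm.missing_mask, cfg.probe_fraction, rng)
        pr = np.array(probes)
        Xp = mm.values.copy()
        Xp[pr[:, 0], pr[:, 1]] = np.nan
        mp = mm.with_values(Xp)
        truth = mm.values[pr[:, 0], pr[:, 1]]
        errs = {}
        for k in (3, 5, 10, 20):
            res = lls_impute(mp, replace(cfg, k=k))
            errs[k] = nrmse(res.imputed.values[pr[:, 0], pr[:, 1]], truth)
        assert errs[k_star] == min(errs.values())
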