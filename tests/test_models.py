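import numpy as np
import pandas as pd
import pytest

from nectarevol import (aicc, akaike_weights, compare_models,
                        estimate_theta_uncertainty, fit_model, model_loglik,
                        phylogenetic_half_life)
from nectarevol.models import DegenerateDataError
from nectarevol.simulate import simulate_trait, simulate_yule_tree
from nectarevol.traits import TraitVector

from conftest import small_trees, trait_from, two_regime_painting
from oracles import dense_loglik


def _y(tree, seed, spread=1.0):
    rng = np.random.default_rng(seed)
    return trait_from(tree, rng.normal(0.0, spread, tree.n_tips))


class TestModelLoglik:
    def test_ou_limit_recovers_brownian(self, yule57):
        y = _y(yule57, 0)
        bm = model_loglik(yule57, y, None, "BM.s", {"z0": 0.3, "sigma2": 0.8})
        ou = model_loglik(yule57, y, None, "OU.s",
                          {"theta": 0.3, "alpha": 1e-8, "sigma2": 0.8})
        assert ou == pytest.approx(bm, abs=1e-4)

    def test_lambda_endpoints(self, yule57):
        y = _y(yule57, 1)
        T = yule57.crown_age
        lam1 = model_loglik(yule57, y, None, "Lambda",
                            {"z0": 0.1, "sigma2": 0.5, "lam": 1.0})
        bm = model_loglik(yule57, y, None, "BM.s", {"z0": 0.1, "sigma2": 0.5})
        lam0 = model_loglik(yule57, y, None, "Lambda",
                            {"z0": 0.1, "sigma2": 0.5, "lam": 0.0})
        wn = model_loglik(yule57, y, None, "WN", {"mu": 0.1, "s2": 0.5 * T})
        assert lam1 == pytest.approx(bm, abs=1e-8)
        assert lam0 == pytest.approx(wn, abs=1e-8)

    def test_ou_multi_optimum_matches_dense_oracle(self, balanced4):
        painting = two_regime_painting(balanced4, "bird", "fly")
        y = _y(balanced4, 2)
        params = {"alpha": 0.7, "sigma2": 1.3,
                  "theta": pd.Series({"bird": 1.0, "fly": -1.0})}
        got = model_loglik(balanced4, y, painting, "OU.poll", params)
        want = dense_loglik(balanced4, y.values.to_numpy(), "OU.poll", params,
                            painting)
        assert got == pytest.approx(want, abs=1e-8)

    @pytest.mark.parametrize("name", ["WN", "BM.s", "Lambda", "BM.rate",
                                      "OU.s", "OU.poll"])
    def test_every_model_matches_dense_oracle_on_small_trees(self, name):
        for k, tree in enumerate(small_trees(n_max=6, seeds=(0, 1))):
            painting = two_regime_painting(tree, "bird", "fly")
            y = _y(tree, 100 + k)
            params = {
                "WN": {"mu": 0.2, "s2": 1.1},
                "BM.s": {"z0": -0.3, "sigma2": 0.6},
                "Lambda": {"z0": 0.0, "sigma2": 0.9, "lam": 0.4},
                "BM.rate": {"z0": 0.1,
                            "sigma2_by_regime": {"bird": 1.2, "fly": 0.3}},
                "OU.s": {"theta": 0.5, "alpha": 0.35, "sigma2": 0.8},
                "OU.poll": {"alpha": 0.5, "sigma2": 1.0,
                            "theta": pd.Series({"bird": 2.0, "fly": -2.0})},
            }[name]
            got = model_loglik(tree, y, painting, name, params)
            want = dense_loglik(tree, y.values.to_numpy(), name, params,
                                painting)
            assert got == pytest.approx(want, abs=1e-8), f"tree {k}"

    def test_nonultrametric_tree_rejected_for_ou(self):
        from nectarevol import read_newick
        t = read_newick("(A:1,B:3);")
        with pytest.raises(ValueError, match="ultrametric"):
            model_loglik(t, trait_from(t, [0.0, 1.0]), None, "OU.s",
                         {"theta": 0, "alpha": 1.0, "sigma2": 1.0})


class TestNestingIdentities:
    def test_ou_poll_with_equal_optima_is_ou_single(self, yule57):
        painting = two_regime_painting(yule57, "bird", "fly")
        y = _y(yule57, 3)
        ou_s = model_loglik(yule57, y, None, "OU.s",
                            {"theta": 0.4, "alpha": 0.9, "sigma2": 1.2})
        ou_m = model_loglik(yule57, y, painting, "OU.poll",
                            {"alpha": 0.9, "sigma2": 1.2,
                             "theta": pd.Series({"bird": 0.4, "fly": 0.4})})
        assert ou_m == pytest.approx(ou_s, abs=1e-9)

    def test_bm_rate_with_equal_rates_is_bm(self, yule57):
        painting = two_regime_painting(yule57, "bird", "fly")
        y = _y(yule57, 4)
        bm = model_loglik(yule57, y, None, "BM.s", {"z0": 0.0, "sigma2": 0.7})
        bmr = model_loglik(yule57, y, painting, "BM.rate",
                           {"z0": 0.0,
                            "sigma2_by_regime": {"bird": 0.7, "fly": 0.7}})
        assert bmr == pytest.approx(bm, abs=1e-9)


class TestInformationCriteria:
    def test_aicc_formula(self):
        assert aicc(0.0, 1, 10) == pytest.approx(2.5)

    def test_aicc_to_aic_limit(self):
        assert aicc(0.0, 2, 10**6) == pytest.approx(4.0, abs=1e-3)

    def test_aicc_increasing_in_k(self):
        vals = [aicc(-10.0, k, 57) for k in range(2, 8)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_small_sample_violation(self):
        with pytest.raises(ValueError):
            aicc(0.0, 5, 6)

    def test_equal_aiccs_give_equal_weights(self):
        w = akaike_weights([100.0] * 4)
        assert np.allclose(w, 0.25)

    def test_weights_shift_invariant_and_normalized(self):
        a = np.array([10.0, 12.5, 11.0])
        w1 = akaike_weights(a)
        w2 = akaike_weights(a + 500.0)
        assert np.allclose(w1, w2)
        assert w1.sum() == pytest.approx(1.0, abs=1e-12)

    def test_half_life(self):
        assert phylogenetic_half_life(np.log(2.0)) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            phylogenetic_half_life(0.0)

    def test_half_life_decreasing_in_alpha(self):
        hl = [phylogenetic_half_life(a) for a in (0.1, 1.0, 10.0)]
        assert hl[0] > hl[1] > hl[2] > 0


class TestFitModel:
    def test_ml_beats_generating_parameters(self, yule57):
        painting = two_regime_painting(yule57, "bird", "fly")
        truth = {"alpha": 0.6, "sigma2": 1.0,
                 "theta": pd.Series({"bird": 1.5, "fly": -1.5})}
        for rep in range(5):
            y = simulate_trait(yule57, painting, "OU.poll", truth, seed=rep)
            fit = fit_model(yule57, y, painting, "OU.poll")
            ll_true = model_loglik(yule57, y, painting, "OU.poll", truth)
            assert fit.loglik >= ll_true - 1e-6

    def test_constant_trait_rejected(self, yule57):
        y = trait_from(yule57, np.ones(57))
        with pytest.raises(DegenerateDataError):
            fit_model(yule57, y, None, "BM.s")

    def test_parameter_counts(self, yule57):
        painting = two_regime_painting(yule57, "bird", "fly")
        y = simulate_trait(yule57, painting, "OU.poll",
                           {"alpha": 0.6, "sigma2": 1.0,
                            "theta": pd.Series({"bird": 1.0, "fly": -1.0})},
                           seed=0)
        ks = {name: fit_model(yule57, y, painting, name).k
              for name in ("WN", "BM.s", "Lambda", "OU.s", "OU.poll", "BM.rate")}
        assert ks == {"WN": 2, "BM.s": 2, "Lambda": 3, "OU.s": 3,
                      "OU.poll": 4, "BM.rate": 3}  # R = 2 regimes painted

    def test_comparison_weights_sum_to_one(self, yule57):
        painting = two_regime_painting(yule57, "bird", "fly")
        y = _y(yule57, 6)
        comp = compare_models(yule57, y, painting)
        assert comp.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert comp.best == min(comp.fits, key=lambda m: comp.fits[m].aicc)


class TestThetaUncertainty:
    def _fit(self, tree, painting, seed, theta=None):
        theta = theta if theta is not None else pd.Series(
            {"bird": 2.0, "fly": -2.0})
        y = simulate_trait(tree, painting, "OU.poll",
                           {"alpha": 0.5, "sigma2": 1.0, "theta": theta},
                           seed=seed)
        fit = fit_model(tree, y, painting, "OU.poll")
        return fit, y

    def test_ci_ordering_after_back_transform(self, yule57):
        painting = two_regime_painting(yule57, "bird", "fly")
        fit, y = self._fit(yule57, painting, 7)
        y_log = TraitVector(y.values, name="v", transform="log")
        unc = estimate_theta_uncertainty(fit, yule57, y_log, painting)
        t = unc.table
        assert (t["ci_lo_natural"] < t["theta_natural"]).all()
        assert (t["theta_natural"] < t["ci_hi_natural"]).all()
        assert (t["se"] > 0).all()

    def test_se_shrinks_with_more_tips(self):
        """Quadrupling the tips per regime shrinks the optimum s.e."""
        def mean_se(n, base_seed):
            ses = []
            for rep in range(8):
                tree = simulate_yule_tree(n, 10.0, seed=base_seed + rep)
                painting = two_regime_painting(tree, "bird", "fly")
                fit, y = self._fit(tree, painting, base_seed + rep)
                unc = estimate_theta_uncertainty(fit, tree, y, painting)
                ses.append(unc.table["se"].mean())
            return float(np.mean(ses))
        small = mean_se(24, 500)
        big = mean_se(96, 600)
        assert big <= 0.8 * small
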