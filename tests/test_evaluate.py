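"""Pseudo Bayes factors, validation split, reliability, Williams test, bias."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from imprintgp.evaluate import (bias_regression, compare_models, evidence_label,
                                h2_of_corrected_phenotype,
                                hotelling_williams_test, pseudo_bayes_factor,
                                reliability, split_by_date, validate_predictions)
from imprintgp.genotypes import PhenotypeTable


class TestPseudoBayesFactor:
    def test_identical_models_give_zero(self, rng):
        cpo = rng.uniform(0.1, 1.0, 50)
        k, label = pseudo_bayes_factor(cpo, cpo)
        assert k == 0.0
        assert label == "weak"

    def test_antisymmetry(self, rng):
        a = rng.uniform(0.1, 1.0, 80)
        b = rng.uniform(0.1, 1.0, 80)
        k_ab, _ = pseudo_bayes_factor(a, b)
        k_ba, _ = pseudo_bayes_factor(b, a)
        assert k_ab == pytest.approx(-k_ba, abs=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 1000))
    def test_antisymmetry_property(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.uniform(0.01, 2.0, 20), r.uniform(0.01, 2.0, 20)
        assert pseudo_bayes_factor(a, b)[0] == pytest.approx(
            -pseudo_bayes_factor(b, a)[0], abs=1e-9)

    @pytest.mark.parametrize("value,label", [
        (-3.0, "negative"), (0.5, "weak"), (5.0, "positive"),
        (8.0, "very strong"), (11.0, "decisive")])
    def test_evidence_bands(self, value, label):
        assert evidence_label(value) == label

    def test_zero_cpo_rejected(self):
        with pytest.raises(ValueError, match="observation 1"):
            pseudo_bayes_factor(np.array([0.5, 0.0]), np.array([0.5, 0.5]))

    def test_compare_models_table(self, rng):
        cpos = {"A": rng.uniform(0.1, 1, 30), "AD": rng.uniform(0.1, 1, 30)}
        comp = compare_models(cpos)
        assert comp.two_ln_k["A"] == 0.0
        frame = comp.to_frame()
        assert set(frame["model"]) == {"A", "AD"}


def _phenotypes(dates):
    dates = pd.to_datetime(dates)
    return PhenotypeTable(pd.DataFrame({
        "id": [f"i{k}" for k in range(len(dates))],
        "y_c": np.arange(len(dates), dtype=float),
        "litter": [f"l{k}" for k in range(len(dates))],
        "birth_year": dates.year,
        "birth_date": dates,
    }))


class TestSplitByDate:
    def test_split(self):
        table = _phenotypes(["2012-01-01", "2013-03-31", "2013-04-01", "2014-01-01"])
        train, val = split_by_date(table, "2013-04-01")
        assert list(train) == ["i0", "i1"]
        assert list(val) == ["i2", "i3"]

    def test_empty_validation_raises(self):
        table = _phenotypes(["2010-01-01", "2011-01-01"])
        with pytest.raises(ValueError, match="validation"):
            split_by_date(table, "2020-01-01")

    def test_empty_training_raises(self):
        table = _phenotypes(["2010-01-01", "2011-01-01"])
        with pytest.raises(ValueError, match="training"):
            split_by_date(table, "2010-01-01")


class TestReliability:
    def test_perfect_predictions_uncapped(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert reliability(y, y, 0.25) == pytest.approx(4.0)

    def test_arithmetic(self, rng):
        # construct two vectors with correlation ~0.4, then rescale by h2
        n = 50_000
        x = rng.standard_normal(n)
        y = 0.4 * x + np.sqrt(1 - 0.16) * rng.standard_normal(n)
        r2 = reliability(x, y, 0.32)
        assert r2 == pytest.approx(0.16 / 0.32, abs=0.02)

    def test_independent_predictions_near_zero(self, rng):
        assert reliability(rng.standard_normal(5000), rng.standard_normal(5000),
                           0.3) < 0.01

    def test_affine_invariance(self, rng):
        p = rng.standard_normal(100)
        y = p + rng.standard_normal(100)
        base = reliability(p, y, 0.3)
        assert reliability(3.0 * p - 7.0, y, 0.3) == pytest.approx(base, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            reliability(np.ones(10), np.arange(10.0), 0.3)


class TestH2Yc:
    def test_simple_ratio(self):
        assert h2_of_corrected_phenotype(1.0, 0.0, 3.0) == pytest.approx(0.25)

    def test_growth_trait_additive_fit(self):
        """Additive-model components 896/424/3248 give h2_yc = 0.196."""
        h2 = h2_of_corrected_phenotype(896.0, 424.0, 3248.0)
        assert round(h2, 3) == 0.196

    def test_zero_additive(self):
        assert h2_of_corrected_phenotype(0.0, 1.0, 3.0) == 0.0


class TestHotellingWilliams:
    def test_equal_correlations_give_null(self):
        t, p = hotelling_williams_test(0.4, 0.4, 0.8, 100)
        assert t == 0.0 and p == 1.0

    def test_p_value_matches_monte_carlo_null(self, rng):
        """The analytic p-value agrees with a trivariate-normal simulation
        of the statistic's null distribution."""
        r13, r23, r12, n = 0.5, 0.3, 0.8, 100
        t_obs, p_obs = hotelling_williams_test(r13, r23, r12, n)
        rbar = 0.5 * (r13 + r23)
        cov = np.array([[1, r12, rbar], [r12, 1, rbar], [rbar, rbar, 1]])
        L = np.linalg.cholesky(cov)
        reps = 20_000
        x = rng.standard_normal((reps, n, 3)) @ L.T
        xc = x - x.mean(axis=1, keepdims=True)
        norm = np.sqrt((xc**2).sum(axis=1))
        r13s = (xc[:, :, 0] * xc[:, :, 2]).sum(axis=1) / (norm[:, 0] * norm[:, 2])
        r23s = (xc[:, :, 1] * xc[:, :, 2]).sum(axis=1) / (norm[:, 1] * norm[:, 2])
        r12s = (xc[:, :, 0] * xc[:, :, 1]).sum(axis=1) / (norm[:, 0] * norm[:, 1])
        ts = np.array([hotelling_williams_test(a, b, c, n)[0]
                       for a, b, c in zip(r13s, r23s, r12s)])
        p_mc = float((np.abs(ts) >= abs(t_obs)).mean())
        assert p_obs == pytest.approx(p_mc, abs=0.01)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            hotelling_williams_test(0.5, 0.3, 0.2, 3)

    def test_inconsistent_triple_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            hotelling_williams_test(0.99, -0.99, 0.99, 50)


class TestBiasRegression:
    def test_identity(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        out = bias_regression(y, y)
        assert out["slope"] == pytest.approx(1.0)
        assert out["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_halved_predictions_double_slope(self):
        y = np.array([2.0, 4.0, 6.0, 8.0])
        out = bias_regression(y, y / 2.0)
        assert out["slope"] == pytest.approx(2.0)

    def test_consistency_on_noisy_truth(self, rng):
        truth = rng.standard_normal(2000)
        y = truth + rng.standard_normal(2000)
        out = bias_regression(y, truth)
        assert abs(out["slope"] - 1.0) < 2 * out["slope_se"] + 0.05

    def test_slope_not_affine_invariant(self, rng):
        p = rng.standard_normal(100)
        y = p + 0.5 * rng.standard_normal(100)
        s1 = bias_regression(y, p)["slope"]
        s2 = bias_regression(y, 2.0 * p)["slope"]
        assert s2 == pytest.approx(s1 / 2.0, rel=1e-9)


class TestDominanceEvidence:
    def test_no_positive_evidence_without_dominance(self):
        """On additive-only simulations the dominance model never earns
        positive evidence (2lnK < 2) in at least 2 of 3 populations; the
        pseudo-marginal likelihood may well penalize the extra effect."""
        from imprintgp.model import SNPMixtureModel
        from imprintgp.simulate import SimulationConfig, simulate_population

        below = 0
        for seed in (4, 5, 6):
            pop = simulate_population(SimulationConfig(
                n_individuals=800, n_snps=400, seed=seed,
                target_variances={"additive": 0.30, "dominance": 0.0,
                                  "imprinting": 0.0, "litter": 0.05,
                                  "residual": 0.65}))
            fit = dict(chain_length=5000, burn_in=1500, thinning=5)
            res_a = SNPMixtureModel(pop.phenotypes, pop.genotypes,
                                    effects="A").fit(seed=seed * 10, **fit)
            res_ad = SNPMixtureModel(pop.phenotypes, pop.genotypes,
                                     effects="AD").fit(seed=seed * 10 + 1, **fit)
            if pseudo_bayes_factor(res_ad.cpo, res_a.cpo)[0] < 2.0:
                below += 1
        assert below >= 2


class TestValidateReport:
    def test_tables_and_baseline_pvalues(self, rng):
        n = 200
        y = rng.standard_normal(n)
        preds = {
            "A": {"GBV": y + rng.standard_normal(n),
                  "GTV": None},
            "AD": {"GBV": y + rng.standard_normal(n),
                   "GTV": y + rng.standard_normal(n)},
        }
        preds["A"]["GTV"] = preds["A"]["GBV"]  # single-effect model
        report = validate_predictions(preds, y, h2_yc=0.3,
                                      cutoff_date="2013-04-01", n_train=500)
        rel = report.reliability_table.set_index("model")
        assert np.isnan(rel.loc["A", "p_GTV"])
        assert 0.0 <= rel.loc["AD", "p_GTV"] <= 1.0
        # model A: GTV and GBV identical by construction
        assert rel.loc["A", "r2_GTV"] == rel.loc["A", "r2_GBV"]
        assert len(report.bias_table) == 4
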