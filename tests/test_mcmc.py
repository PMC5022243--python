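"""Gibbs sampler: conditional-distribution oracles, diagnostics, invariants."""

import numpy as np
import pytest

from imprintgp import _gibbs
from imprintgp.diagnostics import mcmc_standard_error
from imprintgp.genotypes import PhasedGenotypes, PhenotypeTable
from imprintgp.model import ModelSpec, SNPMixtureModel, initialize_chain
from imprintgp.simulate import SimulationConfig, simulate_population

import pandas as pd


def _tiny_model(pop, effects="A"):
    return SNPMixtureModel(pop.phenotypes, pop.genotypes, effects=effects)


class TestInitialization:
    def test_ordering_holds_at_start(self):
        spec = ModelSpec(effect_set=("additive",))
        y = np.random.default_rng(0).standard_normal(50)
        init = initialize_chain(spec, y, np.zeros(50, dtype=int), 1, {"additive": 20.0})
        v = init["class_vars"][0]
        assert (np.diff(v) > 0).all()

    def test_constant_phenotype_floors_residual_variance(self):
        spec = ModelSpec(effect_set=("additive",))
        y = np.full(30, 2.5)
        init = initialize_chain(spec, y, np.zeros(30, dtype=int), 1, {"additive": 10.0})
        assert init["var_e"] > 0

    def test_too_few_observations_rejected(self):
        spec = ModelSpec(effect_set=("additive",))
        y = np.arange(4.0)
        with pytest.raises(ValueError, match="observations"):
            initialize_chain(spec, y, np.arange(4) % 3, 3, {"additive": 1.0})


class TestModelSpecValidation:
    def test_additive_required(self):
        with pytest.raises(ValueError, match="additive"):
            ModelSpec(effect_set=("dominance",))

    def test_burn_in_bound(self):
        with pytest.raises(ValueError, match="burn_in"):
            ModelSpec(effect_set=("additive",), chain_length=100, burn_in=100)

    def test_mixing_sum(self):
        with pytest.raises(ValueError, match="mixing"):
            ModelSpec(effect_set=("additive",), mixing_proportions=(0.5, 0.5, 0.1, 0.1))


class TestSingleSiteConditional:
    def test_snp_effect_draws_match_closed_form(self):
        """With fixed variances and one mixture class, repeated single-site
        updates draw i.i.d. from N(r/(m'm + s2e/s2q), s2e/(m'm + s2e/s2q))."""
        rng = np.random.default_rng(42)
        n = 120
        col = rng.normal(0.0, 1.0, n)
        y = 0.3 * col + rng.normal(0.0, 1.0, n)
        MT = np.ascontiguousarray(col[None, :])
        mtm = np.array([float(col @ col)])
        var_e, var_q = 1.0, 0.05
        class_vars = np.full((1, 4), var_q)
        pi = np.array([1.0, 0.0, 0.0, 0.0])
        q = np.zeros(1)
        cls = np.zeros(1, dtype=np.int64)
        col_type = np.zeros(1, dtype=np.int64)
        e = y - col * q[0]

        lam = mtm[0] + var_e / var_q
        r0 = float(col @ e + mtm[0] * q[0])
        expected_mean = r0 / lam
        expected_sd = np.sqrt(var_e / lam)

        _gibbs.seed_kernel_rng(7)
        draws = np.empty(5000)
        for i in range(5000):
            _gibbs.update_snp_effects(e, MT, mtm, q, cls, col_type,
                                      class_vars, pi, var_e)
            draws[i] = q[0]
        assert draws.mean() == pytest.approx(expected_mean,
                                             abs=4 * expected_sd / np.sqrt(5000))
        assert draws.std() == pytest.approx(expected_sd, rel=0.06)
        # residual bookkeeping stays consistent with the closed form r
        assert float(col @ e + mtm[0] * q[0]) == pytest.approx(r0, abs=1e-8)


class TestVarianceComponentsOracle:
    def test_no_snp_chain_matches_anova(self):
        """With no SNPs the model is a one-way random-effects model; the
        chain's litter/residual variances match the analysis-of-variance
        estimator on balanced data (200 litters x 5)."""
        rng = np.random.default_rng(3)
        n_lit, k = 200, 5
        n = n_lit * k
        litter_ids = np.repeat([f"l{i}" for i in range(n_lit)], k)
        lit_eff = np.repeat(rng.normal(0, np.sqrt(0.3), n_lit), k)
        y = 1.0 + lit_eff + rng.normal(0, 1.0, n)
        genotypes = PhasedGenotypes(
            sample_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
            snp_ids=np.empty(0, dtype=object), chrom=np.empty(0, dtype=object),
            pos=np.empty(0, dtype=int),
            paternal=np.empty((n, 0), dtype=np.int8),
            maternal=np.empty((n, 0), dtype=np.int8))
        phen = PhenotypeTable(pd.DataFrame({
            "id": genotypes.sample_ids, "y_c": y, "litter": litter_ids,
            "birth_year": 2010, "birth_date": "2010-06-01"}))
        res = SNPMixtureModel(phen, genotypes, effects="A").fit(
            chain_length=4000, burn_in=1000, thinning=3, seed=11)

        groups = y.reshape(n_lit, k)
        msw = groups.var(axis=1, ddof=1).mean()
        msb = k * groups.mean(axis=1).var(ddof=1)
        anova_e = msw
        anova_l = (msb - msw) / k
        assert res.variance_components["residual"] == pytest.approx(anova_e, rel=0.10)
        assert res.variance_components["litter"] == pytest.approx(anova_l, rel=0.25)


@pytest.fixture(scope="module")
def pop():
    return simulate_population(SimulationConfig(n_individuals=250, n_snps=120, seed=21))


class TestChainMechanics:
    def test_single_saved_sample(self, pop):
        res = _tiny_model(pop).fit(chain_length=55, burn_in=50, thinning=5, seed=1)
        assert res.n_saved == 1

    def test_seed_determinism(self, pop):
        model = _tiny_model(pop, "AD")
        r1 = model.fit(chain_length=300, burn_in=100, thinning=2, seed=5)
        r2 = model.fit(chain_length=300, burn_in=100, thinning=2, seed=5)
        np.testing.assert_array_equal(r1.class_var_samples, r2.class_var_samples)
        np.testing.assert_array_equal(r1.effect_means["additive"],
                                      r2.effect_means["additive"])
        r3 = model.fit(chain_length=300, burn_in=100, thinning=2, seed=6)
        assert not np.array_equal(r1.class_var_samples, r3.class_var_samples)

    def test_ordering_constraint_in_every_saved_sample(self, pop):
        res = _tiny_model(pop, "ADI").fit(chain_length=800, burn_in=200,
                                          thinning=2, seed=2)
        diffs = np.diff(res.class_var_samples, axis=2)
        assert (diffs > 0).all()
        assert (res.class_var_samples > 0).all()

    def test_residual_resynchronization(self, pop):
        res = _tiny_model(pop, "ADI").fit(chain_length=3000, burn_in=500,
                                          thinning=5, seed=3)
        assert res.max_resync_deviation < 1e-6

    def test_model_a_gbv_equals_gtv(self, pop):
        res = _tiny_model(pop).fit(chain_length=400, burn_in=100, thinning=3, seed=4)
        np.testing.assert_array_equal(res.predict(scope="GBV"),
                                      res.predict(scope="GTV"))

    def test_predict_requires_fitted_effect(self, pop):
        res = _tiny_model(pop).fit(chain_length=200, burn_in=100, thinning=2, seed=4)
        with pytest.raises(ValueError, match="scope"):
            res.predict(scope="TOTAL")

    def test_saved_count_contract(self, pop):
        res = _tiny_model(pop).fit(chain_length=1000, burn_in=400, thinning=10, seed=1)
        assert res.n_saved == 60
        assert res.class_var_samples.shape[0] == 60

    def test_snp_order_exchangeability(self, pop):
        """Permuting SNP columns leaves posterior variance summaries
        unchanged up to MCMC error."""
        model = _tiny_model(pop, "A")
        res = model.fit(chain_length=2500, burn_in=1000, thinning=3, seed=9)
        perm = np.random.default_rng(0).permutation(pop.genotypes.n_snps)
        g_perm = pop.genotypes.subset(snps=perm)
        res_perm = SNPMixtureModel(pop.phenotypes, g_perm, effects="A").fit(
            chain_length=2500, burn_in=1000, thinning=3, seed=9)
        a, b = (res.variance_components["additive"],
                res_perm.variance_components["additive"])
        assert a == pytest.approx(b, rel=0.30)


class TestMCMCStandardError:
    def test_constant_samples(self):
        err = mcmc_standard_error(np.full(100, 3.0))
        assert err.se == 0.0 and err.converged

    def test_iid_normal_scaling(self):
        x = np.random.default_rng(8).standard_normal(10_000)
        err = mcmc_standard_error(x)
        assert err.se == pytest.approx(0.01, abs=0.003)

    def test_autocorrelated_series_inflated(self):
        rng = np.random.default_rng(9)
        T, phi = 10_000, 0.99
        x = np.empty(T)
        x[0] = 0.0
        eps = rng.standard_normal(T)
        for t in range(1, T):
            x[t] = phi * x[t - 1] + eps[t]
        ar_se = mcmc_standard_error(x).se
        iid_se = mcmc_standard_error(rng.standard_normal(T)).se
        assert ar_se > 5 * iid_se

    def test_zero_mean_uses_posterior_sd(self):
        x = np.tile([1.0, -1.0], 50)
        err = mcmc_standard_error(x)
        assert err.relative_to == "sd"

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="10"):
            mcmc_standard_error(np.arange(5.0))

    def test_batch_means_agrees_with_arviz_on_ar1(self):
        """Independent cross-check: batch-means SE within a factor of two
        of arviz's ESS-based MCSE on an autocorrelated chain."""
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(12)
        T, phi = 20_000, 0.9
        x = np.empty(T)
        x[0] = 0.0
        eps = rng.standard_normal(T) * np.sqrt(1 - phi**2)
        for t in range(1, T):
            x[t] = phi * x[t - 1] + eps[t]
        ours = mcmc_standard_error(x).se
        theirs = float(arviz.mcse(x[None, :]).item())
        assert 0.5 < ours / theirs < 2.0
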