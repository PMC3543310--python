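import numpy as np
import pytest

from gcsteroid.bayes_calibration import (CalibrationDatum, ChainSet, Condition,
                                         LikelihoodEvaluator, KINETIC_NAMES,
                                         SampledParameterVector, gelman_rubin,
                                         log_likelihood, log_prior,
                                         metropolis_hastings,
                                         posterior_summary)
from gcsteroid.model_core import default_hierarchy


def _vector(priors, hier, kin_overrides=None, **kw):
    kin = np.array([priors[n].median() if priors[n].family != "uniform"
                    else 0.5 * priors[n].args[1] for n in KINETIC_NAMES])
    for name, val in (kin_overrides or {}).items():
        kin[KINETIC_NAMES.index(name)] = val
    defaults = dict(mu0=1.0, sigma1=0.3,
                    sigma_l=np.ones(hier.n_studies), sigma2=0.5, sigma3=0.5)
    defaults.update(kw)
    return SampledParameterVector(kinetic=kin, **defaults)


class TestLogPrior:
    def test_uniform_components_are_flat(self, priors, hier10):
        hi = priors["kappa_cyp19"].args[1]
        a = _vector(priors, hier10, {"kappa_cyp19": 0.5 * hi})
        b = _vector(priors, hier10, {"kappa_cyp19": 0.25 * hi})
        assert log_prior(a, priors, hier10) == pytest.approx(
            log_prior(b, priors, hier10))

    def test_out_of_support_is_minus_infinity(self, priors, hier10):
        v = _vector(priors, hier10, {"kappa_cyp19": 2e7})  # above U(0, 1e7)
        assert log_prior(v, priors, hier10) == -np.inf

    def test_lognormal_mode_on_log_scale(self, priors, hier10):
        # density of ln(x) peaks at the geometric mean
        gm = priors["lam_cyp19_a"].args[0]
        at_gm = priors["lam_cyp19_a"].logpdf(gm) + np.log(gm)
        for y in (gm / 1.7, gm * 1.7):
            assert at_gm > priors["lam_cyp19_a"].logpdf(y) + np.log(y)

    def test_hierarchical_terms_counted_per_study(self, priors, hier10):
        near = _vector(priors, hier10, sigma_l=np.full(10, 1.0), mu0=1.0)
        far = _vector(priors, hier10, sigma_l=np.full(10, 5.0), mu0=1.0)
        assert log_prior(near, priors, hier10) > log_prior(far, priors, hier10)


@pytest.fixture(scope="module")
def single_datum_setup(table2_params, priors, hier10):
    cond = Condition(time_min=2880.0)
    probe = [CalibrationDatum(1, "mrna_protein", "mrna_Hsd17b2", cond, 1.0)]
    ev = LikelihoodEvaluator(probe, table2_params)
    v = _vector(priors, hier10)
    pred = float(ev.predict_gene(1, v.kinetic, 1.0)[0])
    return cond, pred, v


class TestLogLikelihood:
    def test_zero_residual_contribution(self, single_datum_setup,
                                        table2_params):
        cond, pred, v = single_datum_setup
        data = [CalibrationDatum(1, "mrna_protein", "mrna_Hsd17b2", cond, pred)]
        ll = log_likelihood(v, data, table2_params)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi * v.sigma2 ** 2))

    def test_two_identical_data_double_the_contribution(
            self, single_datum_setup, table2_params):
        cond, pred, v = single_datum_setup
        one = [CalibrationDatum(1, "mrna_protein", "mrna_Hsd17b2", cond,
                                pred * 1.3)]
        ll1 = log_likelihood(v, one, table2_params)
        ll2 = log_likelihood(v, one * 2, table2_params)
        assert ll2 == pytest.approx(2 * ll1)

    def test_variance_tradeoff_direction(self, single_datum_setup,
                                         table2_params):
        """Inflating the error SD helps if and only if the residual exceeds
        the density-normalisation penalty."""
        cond, pred, v = single_datum_setup
        big_resid = [CalibrationDatum(1, "mrna_protein", "mrna_Hsd17b2", cond,
                                      pred * 20)]
        tiny_resid = [CalibrationDatum(1, "mrna_protein", "mrna_Hsd17b2", cond,
                                       pred * 1.01)]
        import dataclasses
        wide = dataclasses.replace(v, sigma2=1.0)
        narrow = dataclasses.replace(v, sigma2=0.5)
        assert log_likelihood(wide, big_resid, table2_params) > \
            log_likelihood(narrow, big_resid, table2_params)
        assert log_likelihood(wide, tiny_resid, table2_params) < \
            log_likelihood(narrow, tiny_resid, table2_params)

    def test_identical_conditions_share_one_solve(self, table2_params,
                                                  priors, hier10):
        cond = Condition(initial_a_nm=200.0, time_min=600.0)
        data = [CalibrationDatum(1, "hormone", ep, cond, 1e-6)
                for ep in ("med_A", "med_E1", "med_E2")] * 2
        ev = LikelihoodEvaluator(data, table2_params)
        v = _vector(priors, hier10)
        before = ev.solve_count
        log_likelihood(v, data, table2_params, evaluator=ev)
        assert ev.solve_count - before == 1


class TestGelmanRubin:
    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(size=(3, 40)) + np.array([[0.0], [0.2], [-0.1]])
        got = gelman_rubin(arr, use_last=1.0).iloc[0]
        m, n = arr.shape
        means = arr.mean(axis=1)
        w = sum(np.var(arr[c], ddof=1) for c in range(m)) / m
        b = n * np.var(means, ddof=1)
        expected = np.sqrt(((n - 1) / n * w + b / n) / w)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_same_distribution_approaches_one(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(size=(4, 4000))
        assert gelman_rubin(arr, use_last=1.0).iloc[0] == pytest.approx(
            1.0, abs=0.02)

    def test_disjoint_chains_diverge(self):
        rng = np.random.default_rng(2)
        arr = np.stack([rng.normal(0, 0.1, 200), rng.normal(10, 0.1, 200)])
        assert gelman_rubin(arr, use_last=1.0).iloc[0] > 5

    def test_zero_within_variance_raises(self):
        arr = np.zeros((2, 50))
        with pytest.raises(ZeroDivisionError):
            gelman_rubin(arr, use_last=1.0)

    def test_requires_enough_chains_and_samples(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestSampler:
    def test_bitwise_deterministic_given_seeds(self, priors, hier10):
        a = metropolis_hastings(None, priors, hier10, n_iter=150, n_chains=2,
                                seeds=[9, 10])
        b = metropolis_hastings(None, priors, hier10, n_iter=150, n_chains=2,
                                seeds=[9, 10])
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.log_posterior, b.log_posterior)

    def test_posterior_mean_matches_importance_sampling_oracle(
            self, table2_params, priors):
        """Single-study posterior for the transcription random effect,
        cross-checked against a prior-importance-sampling estimate computed
        from the closed-form likelihood."""
        hier = default_hierarchy(n_studies=1)
        cond = Condition(time_min=2880.0)
        # at 48 h the inactivating enzyme's mRNA is sigma_L * baseline
        m0 = 7.0e-9
        rng = np.random.default_rng(123)
        true_sl = 1.5
        obs = true_sl * m0 * np.exp(rng.normal(0, 0.3, size=6))
        data = [CalibrationDatum(1, "mrna_protein", "mrna_Hsd17b2", cond, o)
                for o in obs]
        chains = metropolis_hastings(data, priors, hier, n_iter=4000,
                                     n_chains=3, seeds=[21, 22, 23],
                                     params=table2_params)
        mh_lnsl = np.log(chains.pooled()[:, chains.names.index("sigma_l_1")])

        # oracle: importance sampling from the proper joint prior
        n = 400_000
        r = np.random.default_rng(99)
        mu0 = r.lognormal(np.log(1.0), np.log(2.0), n)
        s1 = np.abs(r.normal(0, 0.5, n)) + 1e-12
        sl = np.exp(r.normal(np.log(mu0), s1))
        s2 = np.abs(r.normal(0, 0.2, n)) + 1e-12
        decay = np.exp(-table2_params.delta_mrna * 2880.0)
        pred = sl * m0 + (1 - sl) * m0 * decay
        lw = np.zeros(n)
        for o in obs:
            lw += (-np.log(s2) - 0.5 * np.log(2 * np.pi)
                   - (np.log(o) - np.log(pred)) ** 2 / (2 * s2 ** 2))
        w = np.exp(lw - lw.max())
        w /= w.sum()
        oracle_mean = float(np.sum(w * np.log(sl)))
        ess = 1.0 / np.sum(w ** 2)
        oracle_se = float(np.sqrt(np.sum(w * (np.log(sl) - oracle_mean) ** 2)
                                  / ess))
        mh_se = mh_lnsl.std() / np.sqrt(len(mh_lnsl) / 20)  # autocorr margin
        tol = 3 * np.hypot(oracle_se, mh_se)
        assert abs(mh_lnsl.mean() - oracle_mean) < tol

    def test_acceptance_rates_in_target_band(self, calibration_run):
        chains, _ = calibration_run
        for block, rates in chains.acceptance.items():
            for r in rates:
                assert 0.10 < r < 0.60, (block, rates)

    def test_seed_count_validated(self, priors, hier10):
        with pytest.raises(ValueError):
            metropolis_hastings(None, priors, hier10, n_iter=10, n_chains=2,
                                seeds=[1])


class TestSummaries:
    def test_degenerate_chain_collapses_statistics(self):
        x = np.tile(np.array([2.0, 3.0]), (2, 20, 1))
        cs = ChainSet(samples=x, log_posterior=np.zeros((2, 20)),
                      names=["a", "b"], seeds=[1, 2], n_burn=10)
        s = posterior_summary(cs)
        for col in ("mean", "map", "p0.5", "p97.5"):
            assert s[col].tolist() == [2.0, 3.0]

    def test_percentiles_monotone(self, calibration_run):
        chains, _ = calibration_run
        s = posterior_summary(chains)
        assert (s["p0.5"] <= s["p2.5"]).all()
        assert (s["p2.5"] <= s["p97.5"]).all()
        assert (s["p97.5"] <= s["p99.5"]).all()

    def test_map_is_highest_posterior_sample(self, calibration_run):
        chains, _ = calibration_run
        s = posterior_summary(chains)
        n = chains.samples.shape[1]
        lp = chains.log_posterior[:, n // 2:]
        flat = chains.samples[:, n // 2:, :].reshape(-1, len(chains.names))
        best = flat[np.argmax(lp.reshape(-1))]
        assert np.allclose(s["map"].to_numpy(), best)

    def test_chainset_round_trip(self, tmp_path, prior_only_run):
        p = tmp_path / "chains.npz"
        prior_only_run.save(p)
        back = ChainSet.load(p)
        assert np.array_equal(back.samples, prior_only_run.samples)
        assert back.names == prior_only_run.names
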