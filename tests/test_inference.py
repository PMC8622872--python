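"""Likelihood algebra, MAP recovery, posterior sampling, model comparison."""

import numpy as np
import pandas as pd
import pytest

from bcellfate import presets
from bcellfate.models import ModelConfig, KineticParams
from bcellfate.priors import PriorSpec, LogNormalPrior, NormalPrior, default_priors
from bcellfate.simulate import CohortDesign, NoiseModel, simulate_cohort
from bcellfate.inference import (
    FitResult,
    log_likelihood,
    fit_map,
    sample_posterior,
    compare_models,
    params_from_working,
    working_from_params,
)
from conftest import compact_design

ZERO = NoiseModel(0.0, 0.0, 0.0)


class TestLogLikelihood:
    def test_pointwise_sums_to_total(self, fm_ref, fm_small_cohort, default_noise):
        config, params, source = fm_ref
        total, pw = log_likelihood(params, fm_small_cohort, config, source, default_noise)
        assert total == pytest.approx(pw.sum(), rel=1e-12)
        assert pw.size == 4 * len(fm_small_cohort) - fm_small_cohort.isna().sum().sum()

    def test_invariant_to_row_order(self, fm_ref, fm_small_cohort, default_noise):
        config, params, source = fm_ref
        t1, _ = log_likelihood(params, fm_small_cohort, config, source, default_noise)
        shuffled = fm_small_cohort.sample(frac=1.0, random_state=5)
        t2, _ = log_likelihood(params, shuffled, config, source, default_noise)
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_truth_maximizes_likelihood_on_noise_free_data(self, fm_ref):
        config, params, source = fm_ref
        cohort = simulate_cohort(compact_design(4, seed=21, noise=ZERO), config, params, source)
        noise = presets.DEFAULT_NOISE
        base, _ = log_likelihood(params, cohort, config, source, noise)
        for factor in (0.9, 1.1):
            for field in ("phi0", "delta0", "beta"):
                perturbed = KineticParams(
                    **{**params.__dict__, field: getattr(params, field) * factor}
                )
                ll, _ = log_likelihood(perturbed, cohort, config, source, noise)
                assert ll < base

    def test_doubling_count_sd_changes_loglik_by_gaussian_algebra(
        self, fm_ref, fm_small_cohort
    ):
        """lp(2s) - lp(s) = -log 2 + (3/8) z^2 per count observation."""
        config, params, source = fm_ref
        sd = 0.3
        n1 = NoiseModel(sd, 0.3, 0.2)
        n2 = NoiseModel(2 * sd, 0.3, 0.2)
        _, pw1 = log_likelihood(params, fm_small_cohort, config, source, n1)
        _, pw2 = log_likelihood(params, fm_small_cohort, config, source, n2)
        # count components occupy every first slot per row (no missing counts)
        idx = np.cumsum([0] + [4] * (len(fm_small_cohort) - 1))
        z2 = -2.0 * (pw1[idx] + np.log(sd) + 0.5 * np.log(2 * np.pi)) * sd**2 / sd**2
        expected = -np.log(2.0) + (3.0 / 8.0) * z2
        assert np.allclose(pw2[idx] - pw1[idx], expected, atol=1e-10)

    def test_infeasible_parameters_get_minus_infinity(self, fm_ref, fm_small_cohort):
        config, _, source = fm_ref
        bad = KineticParams(phi0=0.01, delta0=0.01, rho0=0.05, beta=0.2, r_delta=-1e-4)
        total, pw = log_likelihood(bad, fm_small_cohort, config, source, presets.DEFAULT_NOISE)
        assert np.isneginf(total)


class TestParamPacking:
    def test_round_trip(self, fm_ref):
        config, params, _ = fm_ref
        z = working_from_params(params, config)
        back = params_from_working(z, config)
        for k, v in params.__dict__.items():
            assert getattr(back, k) == pytest.approx(v, rel=1e-12)

    def test_two_subset_relabelling_orders_loss_rates(self):
        config = ModelConfig(family="kinetic_heterogeneity", precursor="FM", n_subsets=2)
        p = KineticParams(
            phi0=1e-3, alpha=0.3, delta0=0.5, rho0=0.4, delta0_2=2.0, rho0_2=1.9, beta=0.2
        )
        z = working_from_params(p, config)
        canon = params_from_working(z, config)
        assert canon.delta0 > canon.delta0_2
        assert canon.delta0 == pytest.approx(2.0)
        assert canon.alpha == pytest.approx(0.7)


class TestMap:
    def test_recovers_truth_from_noise_free_data(self, fm_ref):
        """MAP under near-flat priors is the MLE: noise-free data return the
        generating parameters to ~1%."""
        config, params, source = fm_ref
        cohort = simulate_cohort(compact_design(7, seed=31, noise=ZERO), config, params, source)
        priors = PriorSpec(
            phi0=LogNormalPrior(0.01, 10.0),
            delta0=LogNormalPrior(0.03, 10.0),
            rho0=LogNormalPrior(0.005, 10.0),
            beta=LogNormalPrior(0.25, 10.0),
            r_delta=NormalPrior(0.0, 1.0),
        )
        fit = fit_map(
            cohort, config, source, priors, presets.DEFAULT_NOISE,
            n_starts=2, seed=0, start_params=params,
        )
        assert fit.map_params.delta0 == pytest.approx(params.delta0, rel=0.01)
        assert fit.map_params.phi0 == pytest.approx(params.phi0, rel=0.01)
        assert fit.map_params.beta == pytest.approx(params.beta, rel=0.02)

    def test_prior_dominated_limit_returns_prior_mode(self, fm_ref):
        config, params, source = fm_ref
        cohort = simulate_cohort(compact_design(2, seed=41), config, params, source)
        flat_noise = NoiseModel(50.0, 50.0, 50.0)  # data carry ~no information
        priors = PriorSpec(
            phi0=LogNormalPrior(0.01, 0.5),
            delta0=LogNormalPrior(0.03, 0.3),
            rho0=LogNormalPrior(0.004, 0.3),
            beta=LogNormalPrior(0.25, 0.3),
            r_delta=NormalPrior(0.0, 1e-3),
        )
        fit = fit_map(cohort, config, source, priors, flat_noise, n_starts=2, seed=0)
        for name in ("phi0", "delta0", "rho0", "beta"):
            assert fit.map_working[name] == pytest.approx(priors[name]._loc, abs=0.05)

    def test_empty_cohort_map_is_prior_mode(self, fm_ref):
        config, _, source = fm_ref
        empty = pd.DataFrame(
            columns=["mouse_id", "age_bmt_d", "age_d", "subset", "counts",
                     "norm_chimerism", "ki67_host", "ki67_donor"]
        )
        priors = default_priors(config, "FM")
        fit = fit_map(empty, config, source, priors, presets.DEFAULT_NOISE, n_starts=2, seed=0)
        for name in fit.param_names:
            assert fit.map_working[name] == pytest.approx(priors[name]._loc, abs=0.05)


class TestFamilyRecovery:
    """Recovery spot-checks for the remaining model families.

    Each family is fitted to one cohort simulated from itself at the default
    noise; residence time and influx are recovered tightly, while quantities
    the design only weakly identifies (inter-division time for slow pools —
    its published credible interval spans 110-1200 d) get a loose factor
    bound.
    """

    def test_time_dependent_division_family(self, fm_ref):
        _, fm_params, source = fm_ref
        config = ModelConfig(family="time_division", precursor="T1")
        truth = KineticParams(
            phi0=fm_params.phi0, delta0=1 / 35, rho0=1 / 400, beta=1 / 5.8, r_rho=0.002
        )
        cohort = simulate_cohort(presets.fm_fig_design(seed=61), config, truth, source)
        fit = fit_map(cohort, config, source, default_priors(config, "FM"),
                      presets.DEFAULT_NOISE, n_starts=3, seed=0, start_params=truth)
        assert 1 / fit.map_params.delta0 == pytest.approx(35.0, rel=0.20)
        assert fit.map_params.phi0 == pytest.approx(truth.phi0, rel=0.20)
        assert 0.5 < fit.map_params.rho0 / truth.rho0 < 2.0

    def test_incumbent_family_recovers_plateau(self, fm_ref):
        _, fm_params, source = fm_ref
        config = ModelConfig(family="incumbent", precursor="T1")
        pool = fm_params.phi0 * float(source.size(75.0)) / (1 / 35 - 1 / 400)
        truth = KineticParams(
            phi0=fm_params.phi0, delta0=1 / 35, rho0=1 / 400, beta=1 / 5.8,
            incumbent_size=0.25 * pool,
        )
        cohort = simulate_cohort(presets.fm_fig_design(seed=62), config, truth, source)
        fit = fit_map(cohort, config, source, default_priors(config, "FM"),
                      presets.DEFAULT_NOISE, n_starts=3, seed=0, start_params=truth)
        share_true = truth.incumbent_size / (pool + truth.incumbent_size)
        pool_fit = fit.map_params.phi0 * float(source.size(75.0)) / (
            fit.map_params.delta0 - fit.map_params.rho0
        )
        share_fit = fit.map_params.incumbent_size / (pool_fit + fit.map_params.incumbent_size)
        assert share_fit == pytest.approx(share_true, abs=0.10)
        assert 1 / fit.map_params.delta0 == pytest.approx(35.0, rel=0.20)


class TestSampler:
    def test_posterior_matches_prior_given_no_data(self, fm_ref):
        """Zero-length data: posterior quantiles equal the (normal) prior's
        closed-form quantiles within Monte-Carlo error."""
        config, _, source = fm_ref
        empty = pd.DataFrame(
            columns=["mouse_id", "age_bmt_d", "age_d", "subset", "counts",
                     "norm_chimerism", "ki67_host", "ki67_donor"]
        )
        priors = PriorSpec(
            phi0=LogNormalPrior(0.01, 0.8),
            delta0=LogNormalPrior(0.03, 0.5),
            rho0=LogNormalPrior(0.004, 0.5),
            beta=LogNormalPrior(0.25, 0.5),
        )
        fit = sample_posterior(
            empty, ModelConfig(family="homogeneous"), source, priors,
            presets.DEFAULT_NOISE, seed=3, n_walkers=16, n_steps=600, n_burn=200,
            map_starts=2,
        )
        flat = fit.samples_working.reshape(-1, len(fit.param_names))
        for j, name in enumerate(fit.param_names):
            mu, sd = priors[name]._loc, priors[name].sdlog
            assert np.mean(flat[:, j]) == pytest.approx(mu, abs=0.12 * sd + 0.02)
            assert np.std(flat[:, j]) == pytest.approx(sd, rel=0.15)

    def test_credible_interval_coverage_of_residence_time(self, fm_ref):
        """95% intervals cover the generating residence time in >= 85% of
        replicates (17 of 20)."""
        config, params, source = fm_ref
        priors = default_priors(config, "FM")
        covered = 0
        for rep in range(20):
            cohort = simulate_cohort(
                compact_design(5, seed=500 + rep), config, params, source
            )
            fit = sample_posterior(
                cohort, config, source, priors, presets.DEFAULT_NOISE,
                seed=rep, n_walkers=12, n_steps=250, n_burn=100,
                map_starts=2, n_pointwise=2,
            )
            ns = fit.natural_samples()
            res = 1.0 / (ns["delta0"] * np.exp(ns["r_delta"] * 0.0))  # residence at t_ref
            lo, hi = np.percentile(res, [2.5, 97.5])
            covered += lo <= 35.0 <= hi
        assert covered >= 17


class TestModelComparison:
    @staticmethod
    def _fake_fit(pointwise, labels):
        config = ModelConfig(family="homogeneous")
        return FitResult(
            config=config, param_names=["x"], map_working={"x": 0.0},
            map_params=KineticParams(), log_post=0.0,
            pointwise=pointwise, obs_labels=labels,
        )

    def test_identical_models_share_weight_equally(self):
        rng = np.random.default_rng(0)
        pw = rng.normal(-1.0, 0.3, size=(200, 40))
        labels = [f"{i}:counts" for i in range(40)]
        comp = compare_models([self._fake_fit(pw, labels), self._fake_fit(pw.copy(), labels)])
        assert np.allclose(comp.weights, [0.5, 0.5], atol=1e-6)
        assert comp.weights.sum() == pytest.approx(1.0)

    def test_weights_invariant_to_constant_shift(self):
        rng = np.random.default_rng(1)
        labels = [f"{i}:counts" for i in range(40)]
        a = rng.normal(-1.0, 0.3, size=(200, 40))
        b = rng.normal(-1.3, 0.3, size=(200, 40))
        w1 = compare_models([self._fake_fit(a, labels), self._fake_fit(b, labels)]).table
        w2 = compare_models(
            [self._fake_fit(a + 7.0, labels), self._fake_fit(b + 7.0, labels)]
        ).table
        assert np.allclose(
            w1["weight"].sort_index().to_numpy(), w2["weight"].sort_index().to_numpy(), atol=1e-9
        )

    def test_mismatched_observation_sets_rejected(self):
        rng = np.random.default_rng(2)
        a = self._fake_fit(rng.normal(size=(50, 10)), [f"{i}:counts" for i in range(10)])
        b = self._fake_fit(rng.normal(size=(50, 10)), [f"{i}:ki67_host" for i in range(10)])
        with pytest.raises(ValueError, match="identical observation set"):
            compare_models([a, b])

    def test_recovers_kinetic_heterogeneity(self, fm_ref):
        """Cohorts from a pool whose two equal-sized subsets replace at
        tenfold different net rates prefer the two-subset model over the
        homogeneous one in >= 8/10 replicates (LOO-IC weights)."""
        _, _, source = fm_ref
        cfg_het = ModelConfig(family="kinetic_heterogeneity", precursor="T1", n_subsets=2)
        cfg_hom = ModelConfig(family="homogeneous", precursor="T1")
        truth = KineticParams(
            phi0=0.02, alpha=0.909, delta0=0.205, rho0=0.005,
            delta0_2=0.025, rho0_2=0.005, beta=1 / 5.8,
        )
        noise = presets.DEFAULT_NOISE
        pri_het = default_priors(cfg_het, "FM")
        pri_hom = default_priors(cfg_hom, "FM")
        groups = ((42.0, 42.0, 20), (70.0, 70.0, 20), (98.0, 98.0, 20))
        ages = np.arange(77.0, 601.0, 7.0)
        wins = 0
        for rep in range(10):
            cohort = simulate_cohort(
                CohortDesign(groups, ages, noise, seed=700 + rep), cfg_het, truth, source
            )
            m_het = fit_map(cohort, cfg_het, source, pri_het, noise, n_starts=1,
                            seed=rep, start_params=truth, maxiter=1000)
            f_het = sample_posterior(
                cohort, cfg_het, source, pri_het, noise, seed=rep,
                n_walkers=16, n_steps=260, n_burn=110, map_result=m_het, n_pointwise=150,
            )
            f_hom = sample_posterior(
                cohort, cfg_hom, source, pri_hom, noise, seed=rep,
                n_walkers=10, n_steps=260, n_burn=110, map_starts=2, n_pointwise=150,
            )
            comp = compare_models([f_het, f_hom], names=["het", "hom"])
            wins += comp.table.loc["het", "weight"] > comp.table.loc["hom", "weight"]
        assert wins >= 8

    def test_complexity_penalty_keeps_true_simple_model_competitive(self, fm_ref):
        """Fitting a two-subset model to homogeneous data must not wipe out
        the simpler true model's weight (>= 0.3) on a small cohort."""
        config, params, source = fm_ref
        cfg_hom = ModelConfig(family="homogeneous", precursor="T1")
        p_hom = KineticParams(phi0=params.phi0, delta0=params.delta0,
                              rho0=params.rho0, beta=params.beta)
        cfg_het = ModelConfig(family="kinetic_heterogeneity", precursor="T1", n_subsets=2)
        noise = presets.DEFAULT_NOISE
        cohort = simulate_cohort(compact_design(4, seed=900), cfg_hom, p_hom, source)
        fits = []
        for cfg, n_walk in ((cfg_hom, 10), (cfg_het, 16)):
            pri = default_priors(cfg, "FM")
            fits.append(
                sample_posterior(
                    cohort, cfg, source, pri, noise, seed=1,
                    n_walkers=n_walk, n_steps=260, n_burn=110,
                    map_starts=3, n_pointwise=150,
                )
            )
        comp = compare_models(fits, names=["hom", "het"])
        assert comp.table.loc["hom", "weight"] >= 0.3
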