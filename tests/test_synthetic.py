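"""The synthetic world: hierarchy draws, tracks, rasters, Argos fixes."""

import numpy as np
import pytest

from bearmove import (
    ClassParams,
    GridSpec,
    IndividualParams,
    default_class_params,
    make_covariate_stack,
    observe_argos,
    sample_individual_params,
    simulate_crw,
    simulate_ssf_track,
    stack_normalizer,
)
from bearmove.distributions import mean_step_length
from bearmove.synthetic import TruePath, ellipse_covariance


class TestClassParams:
    def test_invalid_sigma_phi_rejected(self):
        with pytest.raises(ValueError, match="sigma_phi"):
            ClassParams("AF", 1.8, 6e4, 0.2, 0.1, 5000.0, sigma_phi=0.45)

    def test_table_like_defaults_valid(self):
        p = default_class_params()
        assert set(p) == {"AF", "AM", "SA"}
        assert p["AM"].gamma_c > p["AF"].gamma_c  # males travel further


class TestSampleIndividualParams:
    def test_degenerate_limit(self, rng):
        cp = ClassParams("AF", 1.8, 6e4, 0.2, 1e-6, 1e-3, 1e-6)
        inds = sample_individual_params(cp, 20, rng)
        assert all(abs(i.k_i - 1.8) < 1e-4 for i in inds)
        assert all(abs(i.g_i - 6e4) < 1.0 for i in inds)
        assert all(abs(i.r_i - 0.2) < 1e-4 for i in inds)

    def test_seed_reproducibility(self, af_params):
        a = sample_individual_params(af_params, 5, np.random.default_rng(3))
        b = sample_individual_params(af_params, 5, np.random.default_rng(3))
        assert a == b

    def test_law_of_large_numbers(self, af_params, rng):
        n = 10_000
        inds = sample_individual_params(af_params, n, rng)
        k = np.array([i.k_i for i in inds])
        g = np.array([i.g_i for i in inds])
        r = np.array([i.r_i for i in inds])
        assert abs(k.mean() - af_params.kappa_c) < 3 * af_params.sigma_kappa / np.sqrt(n)
        assert abs(g.mean() - af_params.gamma_c) < 3 * af_params.sigma_gamma / np.sqrt(n)
        assert abs(r.mean() - af_params.phi_c) < 3 * af_params.sigma_phi / np.sqrt(n)


class TestSimulateCRW:
    def test_high_persistence_is_nearly_straight(self, rng):
        ip = IndividualParams("a", "AF", 1.8, 6e4, 0.999)
        p = simulate_crw(ip, 50, start_bearing=0.4, rng=rng)
        dev = np.diff(p.bearings)
        assert np.max(np.abs(np.arctan2(np.sin(dev), np.cos(dev)))) < 0.15

    def test_mean_step_length_identity(self, rng):
        ip = IndividualParams("a", "AF", 1.79, 6.7e4, 0.2)
        p = simulate_crw(ip, 10_000, rng=rng)
        lengths = np.hypot(*np.diff(p.xy, axis=0).T)
        mu = mean_step_length(ip.k_i, ip.g_i)
        sd = lengths.std()
        assert abs(lengths.mean() - mu) < 3 * sd / np.sqrt(lengths.size)

    def test_zero_persistence_turns_uniformly(self, rng):
        from scipy.stats import kstest

        ip = IndividualParams("a", "AF", 1.8, 6e4, 1e-12)
        p = simulate_crw(ip, 10_000, rng=rng)
        dev = np.arctan2(np.sin(np.diff(p.bearings)), np.cos(np.diff(p.bearings)))
        assert kstest((dev + np.pi) / (2 * np.pi), "uniform").pvalue > 0.01

    def test_regular_four_day_spacing(self, rng, af_params):
        ip = sample_individual_params(af_params, 1, rng)[0]
        p = simulate_crw(ip, 7, rng=rng)
        dt = np.diff(p.times) / np.timedelta64(1, "D")
        assert np.allclose(dt, 4.0)


class TestCovariateStackGeneration:
    def test_invariants(self, small_stack):
        s = small_stack
        assert s.ice_conc.min() >= 0 and s.ice_conc.max() <= 100
        assert s.land_mask.any() and (~s.land_mask).any()
        assert np.all(s.depth[~s.land_mask] <= 0)
        for d in range(s.n_days):
            assert (s.ice_conc[d] < 10).any() and (s.ice_conc[d] >= 10).any()

    def test_seed_determinism(self):
        g = GridSpec(0, 0, 25_000, 50, 50)
        a = make_covariate_stack(g, 5, np.random.default_rng(7))
        b = make_covariate_stack(g, 5, np.random.default_rng(7))
        assert np.array_equal(a.ice_conc, b.ice_conc)
        assert np.array_equal(a.depth, b.depth)

    def test_rejects_tiny_grid(self, rng):
        with pytest.raises(ValueError, match="50x50"):
            make_covariate_stack(GridSpec(0, 0, 25_000, 30, 30), 5, rng)


class TestSimulateSSFTrack:
    def test_null_selection_matches_crw_scale(self, small_stack, rng):
        # beta = 0: step lengths statistically match the plain kernel
        ip = IndividualParams("a", "AF", 1.79, 4.0e4, 0.2)
        p = simulate_ssf_track(
            ip, np.zeros(8), small_stack, n_steps=9, n_candidates=40, rng=rng
        )
        lengths = np.hypot(*np.diff(p.xy, axis=0).T)
        mu = mean_step_length(ip.k_i, ip.g_i)
        assert 0.2 * mu < lengths.mean() < 3.0 * mu

    def test_positive_coefficient_biases_choice(self, small_stack, rng):
        # strong selection for concentration pushes the track into denser ice
        norm = stack_normalizer(small_stack, rng)
        ip = IndividualParams("a", "AF", 1.79, 4.0e4, 0.2)
        beta = np.zeros(8)
        beta[1] = 4.0
        sel, nul = [], []
        for seed in range(4):
            r1 = np.random.default_rng(seed)
            r2 = np.random.default_rng(seed)
            p1 = simulate_ssf_track(ip, beta, small_stack, n_steps=9, rng=r1, normalizer=norm)
            p0 = simulate_ssf_track(ip, np.zeros(8), small_stack, n_steps=9, rng=r2, normalizer=norm)
            from bearmove.covariates import extract_covariates_batch

            day = small_stack.dates[4]
            sel.append(extract_covariates_batch(p1.xy[1:], day, small_stack)[:, 1].mean())
            nul.append(extract_covariates_batch(p0.xy[1:], day, small_stack)[:, 1].mean())
        assert np.mean(sel) > np.mean(nul)

    def test_track_stays_on_ocean_grid(self, small_stack, rng, af_params):
        ip = sample_individual_params(af_params, 1, rng)[0]
        p = simulate_ssf_track(ip, np.zeros(8), small_stack, n_steps=9, rng=rng)
        assert small_stack.grid.in_bounds(p.xy).all()
        assert not small_stack.is_land(p.xy[1:]).any()

    def test_seed_determinism(self, small_stack, af_params):
        ip = sample_individual_params(af_params, 1, np.random.default_rng(0))[0]
        a = simulate_ssf_track(ip, np.zeros(8), small_stack, n_steps=6, rng=np.random.default_rng(5))
        b = simulate_ssf_track(ip, np.zeros(8), small_stack, n_steps=6, rng=np.random.default_rng(5))
        assert np.array_equal(a.xy, b.xy)

    def test_grid_too_small_raises(self, small_stack, rng):
        ip = IndividualParams("a", "AF", 1.8, 9.0e5, 0.2)
        with pytest.raises(ValueError, match="grid too small|gamma_c"):
            simulate_ssf_track(ip, np.zeros(8), small_stack, n_steps=3, rng=rng)


class TestObserveArgos:
    def _path(self, rng, n=30):
        ip = IndividualParams("a", "AF", 1.79, 6.7e4, 0.2)
        return simulate_crw(ip, n, rng=rng)

    def test_noiseless_limit_lies_on_path(self, rng):
        p = self._path(rng)
        obs = observe_argos(p, error_scale=0.0, rng=rng)
        t_days = (p.times - p.times[0]) / np.timedelta64(1, "D")
        for o in obs:
            td = (np.datetime64(o.timestamp) - p.times[0]) / np.timedelta64(1, "D")
            assert o.x == pytest.approx(np.interp(td, t_days, p.xy[:, 0]), abs=1e-6)
            assert o.y == pytest.approx(np.interp(td, t_days, p.xy[:, 1]), abs=1e-6)

    def test_failure_time_truncates(self, rng):
        p = self._path(rng)
        obs = observe_argos(p, failure_time=30.0, rng=rng)
        assert obs
        last = (np.datetime64(obs[-1].timestamp) - p.times[0]) / np.timedelta64(1, "D")
        assert last <= 30.0

    def test_error_covariance_reconstruction(self, rng):
        # fixed point observed many times: empirical error covariance matches
        # the mean of the per-fix ellipse-implied covariances
        t0 = np.datetime64("2015-03-01")
        times = t0 + np.arange(4000) * np.timedelta64(1, "D")
        p = TruePath("a", "AF", times, np.full((4000, 2), 5e5), np.zeros(3999))
        obs = observe_argos(p, duty_cycle_days=1.0, p_extra_locations=0.0, rng=rng)
        err = np.array([[o.x - 5e5, o.y - 5e5] for o in obs])
        implied = np.mean(
            [ellipse_covariance(o.semi_major, o.semi_minor, o.orientation) for o in obs],
            axis=0,
        )
        emp = np.cov(err.T)
        # MC error on covariance entries is ~ var/sqrt(n/2)
        tol = 5 * np.max(np.diag(implied)) / np.sqrt(len(obs) / 2)
        assert np.all(np.abs(emp - implied) < tol)

    def test_duty_cycles_sometimes_repeat(self, rng):
        p = self._path(rng)
        obs = observe_argos(p, duty_cycle_days=2.0, p_extra_locations=0.5, rng=rng)
        ids = [o.duty_cycle_id for o in obs]
        assert len(ids) > len(set(ids))  # deduplication has something to do
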