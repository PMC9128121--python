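"""Filtering rules, CTCRW fitting, imputation, and step geometry."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from bearmove import (
    FilterConfig,
    IndividualParams,
    assemble_datasets,
    filter_observations,
    fit_ctcrw,
    simulate_crw,
    simulate_paths,
    steps_and_angles,
)
from bearmove.preprocess import (
    PathRealization,
    _obs_arrays,
    _trans,
    ctcrw_loglik,
    initial_state,
)
from bearmove.synthetic import ArgosObservation, observe_argos

T0 = np.datetime64("2015-03-10T00:00:00")


def obs_at(days, x=0.0, y=0.0, smaj=3000.0, smin=1000.0, orient=0.3, cycle=None, aid="b1"):
    return ArgosObservation(
        animal_id=aid,
        class_label="AF",
        timestamp=T0 + np.timedelta64(int(days * 86400 * 1e9), "ns"),
        x=x,
        y=y,
        semi_major=smaj,
        semi_minor=smin,
        orientation=orient,
        duty_cycle_id=int(days) if cycle is None else cycle,
    )


class TestFiltering:
    def test_post_capture_gap(self):
        obs = [obs_at(4.0, cycle=1), obs_at(5.1, cycle=2), obs_at(6.0, cycle=3),
               obs_at(7.0, cycle=4)]
        res = filter_observations(obs, T0, FilterConfig())
        days = [(np.datetime64(o.timestamp) - T0) / np.timedelta64(1, "D")
                for o in res.observations]
        assert days == pytest.approx([5.1, 6.0, 7.0])

    def test_smallest_ellipse_wins_within_cycle(self):
        keep = obs_at(5.5, cycle=9, smaj=3000, smin=1000)
        drop = obs_at(5.6, cycle=9, smaj=4000, smin=1000)
        filler = [obs_at(6.5, cycle=10), obs_at(7.5, cycle=11)]
        res = filter_observations([keep, drop] + filler, T0, FilterConfig())
        kept_cycle9 = [o for o in res.observations if o.duty_cycle_id == 9]
        assert kept_cycle9 == [keep]

    def test_seasonal_window(self):
        late = ArgosObservation(
            "b1", "AF", np.datetime64("2015-07-02T00:00:00"), 0, 0, 3000, 1000, 0.1, 99
        )
        obs = [obs_at(6, cycle=1), obs_at(7, cycle=2), obs_at(8, cycle=3), late]
        res = filter_observations(obs, T0, FilterConfig())
        assert len(res.observations) == 3
        assert all(o.duty_cycle_id != 99 for o in res.observations)

    def test_too_few_locations_excluded(self):
        obs = [obs_at(6, cycle=1), obs_at(7, cycle=2)]
        res = filter_observations(obs, T0, FilterConfig())
        assert res.excluded and res.reason == "min_locations"

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            filter_observations([obs_at(7), obs_at(6)], T0, FilterConfig())

    def test_idempotent(self):
        obs = [obs_at(5.5, cycle=1), obs_at(5.9, cycle=1, smaj=9000), obs_at(6.5, cycle=2),
               obs_at(7.5, cycle=3), obs_at(9.0, cycle=4)]
        once = filter_observations(obs, T0, FilterConfig()).observations
        twice = filter_observations(once, T0, FilterConfig()).observations
        assert once == twice

    def test_day_grouping_fallback(self):
        # duty_cycle_id of None on any fix triggers calendar-day grouping
        a = obs_at(5.25, cycle=None, smaj=2000)
        b = obs_at(5.75, cycle=None, smaj=5000)
        a = ArgosObservation(a.animal_id, a.class_label, a.timestamp, a.x, a.y,
                             a.semi_major, a.semi_minor, a.orientation, None)
        b = ArgosObservation(b.animal_id, b.class_label, b.timestamp, b.x, b.y,
                             b.semi_major, b.semi_minor, b.orientation, None)
        filler = [obs_at(6.5, cycle=None), obs_at(7.5, cycle=None), obs_at(8.5, cycle=None)]
        filler = [ArgosObservation(o.animal_id, o.class_label, o.timestamp, o.x, o.y,
                                   o.semi_major, o.semi_minor, o.orientation, None)
                  for o in filler]
        res = filter_observations([a, b] + filler, T0, FilterConfig())
        same_day = [o for o in res.observations
                    if np.datetime64(o.timestamp, "D") == np.datetime64("2015-03-15")]
        assert len(same_day) == 1 and same_day[0].semi_major == 2000


def _dense_gaussian_loglik(obs, beta, sigma2):
    """Joint multivariate-normal density of the fixes, built by propagating
    means and covariances through the state transitions (no Kalman filter)."""
    _, t, xy, R = _obs_arrays(obs)
    n = t.size
    m0, P0 = initial_state(beta, sigma2, xy[0])
    means, V, Ts = [m0], [P0], [None]
    for i in range(1, n):
        T, Q = _trans(beta, sigma2, float(t[i] - t[i - 1]))
        means.append(T @ means[-1])
        V.append(T @ V[-1] @ T.T + Q)
        Ts.append(T)
    Sig = np.zeros((4 * n, 4 * n))
    for i in range(n):
        Sig[4 * i : 4 * i + 4, 4 * i : 4 * i + 4] = V[i]
        for j in range(i + 1, n):
            A = np.eye(4)
            for k in range(i + 1, j + 1):
                A = Ts[k] @ A
            C = A @ V[i]
            Sig[4 * j : 4 * j + 4, 4 * i : 4 * i + 4] = C
            Sig[4 * i : 4 * i + 4, 4 * j : 4 * j + 4] = C.T
    H = np.zeros((2 * n, 4 * n))
    for i in range(n):
        H[2 * i, 4 * i] = 1.0
        H[2 * i + 1, 4 * i + 2] = 1.0
    S = H @ Sig @ H.T
    for i in range(n):
        S[2 * i : 2 * i + 2, 2 * i : 2 * i + 2] += R[i]
    return float(multivariate_normal.logpdf(xy.ravel(), H @ np.concatenate(means), S))


class TestCTCRW:
    def _obs(self, rng, n=5, err=1.0):
        ip = IndividualParams("b1", "AF", 1.79, 6.7e4, 0.25)
        path = simulate_crw(ip, 10, rng=rng)
        obs = observe_argos(path, duty_cycle_days=2.0, error_scale=err, rng=rng)
        return obs[:n]

    @pytest.mark.parametrize("n", [4, 6])
    def test_kalman_equals_dense_gaussian(self, rng, n):
        obs = self._obs(rng, n=n)
        _, t, xy, R = _obs_arrays(obs)
        for beta, sigma2 in [(0.7, 2e8), (0.15, 8e8)]:
            kf = ctcrw_loglik(t, xy, R, beta, sigma2)
            dense = _dense_gaussian_loglik(obs, beta, sigma2)
            assert kf == pytest.approx(dense, abs=1e-8)

    def test_fit_returns_valid_parameters(self, rng):
        obs = self._obs(rng, n=12)
        fit = fit_ctcrw(obs)
        assert fit.beta > 0 and fit.sigma2 > 0
        assert np.isfinite(fit.loglik)
        assert fit.converged

    def test_near_noiseless_smoother_tracks_observations(self, rng):
        obs = self._obs(rng, n=8, err=1e-4)
        fit = fit_ctcrw(obs)
        sm_xy = fit.smoothed_mean[:, [0, 2]]
        assert np.max(np.abs(sm_xy - fit.obs_xy)) < 10.0  # meters

    def test_inflating_errors_shrinks_smoother_toward_prior(self, rng):
        obs = self._obs(rng, n=10)
        big = [
            ArgosObservation(o.animal_id, o.class_label, o.timestamp, o.x, o.y,
                             o.semi_major * 20, o.semi_minor * 20, o.orientation,
                             o.duty_cycle_id)
            for o in obs
        ]
        f1, f2 = fit_ctcrw(obs), fit_ctcrw(big)
        rms1 = np.sqrt(np.mean((f1.smoothed_mean[:, [0, 2]] - f1.obs_xy) ** 2))
        rms2 = np.sqrt(np.mean((f2.smoothed_mean[:, [0, 2]] - f2.obs_xy) ** 2))
        assert rms2 > rms1

    def test_too_few_observations(self, rng):
        with pytest.raises(ValueError, match="3 observations"):
            fit_ctcrw(self._obs(rng, n=2))


class TestSimulatePaths:
    def test_near_zero_error_realizations_pin_to_observations(self, rng):
        # fixes already on the 4-day grid with tiny ellipses: every
        # realization reproduces them (imputation consistency)
        ip = IndividualParams("b1", "AF", 1.79, 6.7e4, 0.25)
        path = simulate_crw(ip, 6, rng=rng)
        obs = []
        for i, t in enumerate(path.times):
            obs.append(ArgosObservation("b1", "AF", t, path.xy[i, 0], path.xy[i, 1],
                                        1e-3, 1e-3, 0.0, i))
        fit = fit_ctcrw(obs)
        for p in simulate_paths(fit, m=5, rng=rng):
            assert p.xy.shape == path.xy.shape
            assert np.max(np.abs(p.xy - path.xy)) < 5.0

    def test_mid_gap_variance_exceeds_near_obs_variance(self, rng):
        ip = IndividualParams("b1", "AF", 1.79, 6.7e4, 0.25)
        path = simulate_crw(ip, 10, rng=rng)
        obs = observe_argos(path, duty_cycle_days=2.0, rng=rng)
        # carve a long gap: drop fixes between day 8 and day 28
        t0 = path.times[0]
        kept = [o for o in obs
                if not (8 < (np.datetime64(o.timestamp) - t0) / np.timedelta64(1, "D") < 28)]
        fit = fit_ctcrw(kept)
        reals = simulate_paths(fit, m=200, rng=rng)
        arr = np.stack([p.xy for p in reals])
        var = arr.var(axis=0).sum(axis=1)
        t_grid = (np.asarray(reals[0].times) - t0) / np.timedelta64(1, "D")
        mid_gap = np.argmin(np.abs(t_grid - 18.0))
        near_obs = np.argmin(np.abs(t_grid - 4.0))
        assert var[mid_gap] > var[near_obs]

    def test_ensemble_mean_matches_smoother(self, rng):
        ip = IndividualParams("b1", "AF", 1.79, 6.7e4, 0.25)
        path = simulate_crw(ip, 5, rng=rng)
        obs = observe_argos(path, duty_cycle_days=3.0, rng=rng)
        fit = fit_ctcrw(obs)
        reals = simulate_paths(fit, m=1000, rng=rng)
        arr = np.stack([p.xy for p in reals])
        # analytic smoother mean at the output grid
        from bearmove.preprocess import _kalman, _merged_timeline

        t_all, obs_at_, t_grid, grid_at = _merged_timeline(fit, 4.0)
        m0, P0 = initial_state(fit.beta, fit.sigma2, fit.obs_xy[0])
        _, ms, Ps = _kalman(t_all, obs_at_, fit.obs_xy, fit.obs_R, fit.beta,
                            fit.sigma2, m0, P0, smooth=True)
        target = ms[grid_at][:, [0, 2]]
        sd = np.sqrt(Ps[grid_at][:, [0, 2], [0, 2]])
        assert np.all(np.abs(arr.mean(axis=0) - target) < 5 * sd / np.sqrt(1000) + 1.0)


class TestAssembleDatasets:
    def _reals(self, rng, n_animals=3, m=25):
        out = {}
        for a in range(n_animals):
            out[f"a{a}"] = [
                PathRealization(f"a{a}", "AF", 0,
                                np.datetime64("2015-03-01") + np.arange(3) * np.timedelta64(4, "D"),
                                rng.normal(size=(3, 2)))
                for _ in range(m)
            ]
        return out

    def test_partition_property(self, rng):
        reals = self._reals(rng)
        datasets = assemble_datasets(reals, rng)
        assert len(datasets) == 25
        assert all(len(ds) == 3 for ds in datasets)
        seen = set()
        for j, ds in enumerate(datasets):
            for r in ds:
                assert r.dataset_index == j + 1
                key = (r.animal_id, r.xy.tobytes())
                assert key not in seen
                seen.add(key)
        assert len(seen) == 75

    def test_seed_determinism(self, rng):
        reals = self._reals(np.random.default_rng(0))
        a = assemble_datasets(reals, np.random.default_rng(5))
        b = assemble_datasets(reals, np.random.default_rng(5))
        for da, db in zip(a, b):
            for ra, rb in zip(da, db):
                assert np.array_equal(ra.xy, rb.xy)


class TestStepsAndAngles:
    def _path(self, pts):
        pts = np.asarray(pts, float)
        times = np.datetime64("2015-03-01") + np.arange(len(pts)) * np.timedelta64(4, "D")
        return PathRealization("a", "AF", 1, times, pts)

    def test_collinear_zero_deviation(self):
        s = steps_and_angles(self._path([(0, 0), (1000, 0), (2000, 0)]))
        assert np.allclose(s.bearings, 0.0)
        dev, _ = s.deviations()
        assert np.allclose(dev, 0.0)

    def test_right_angle(self):
        s = steps_and_angles(self._path([(0, 0), (1000, 0), (1000, 1000)]))
        assert s.bearings == pytest.approx([0.0, np.pi / 2])
        dev, _ = s.deviations()
        assert dev == pytest.approx([np.pi / 2])

    def test_three_four_five(self):
        s = steps_and_angles(self._path([(0, 0), (3000, 4000), (6000, 8000)]))
        assert s.lengths == pytest.approx([5000.0, 5000.0])

    def test_too_short_path(self):
        with pytest.raises(ValueError, match="3 locations"):
            steps_and_angles(self._path([(0, 0), (1, 1)]))

    def test_on_ice_mask(self, small_stack):
        # a step ending on the land strip (east edge) is flagged invalid
        land_x = small_stack.grid.width - small_stack.grid.cell_size
        pts = [(6e5, 6e5), (7e5, 6e5), (land_x, 6e5), (7e5, 7e5)]
        s = steps_and_angles(self._path(pts), stack=small_stack, on_ice=True)
        assert s.step_valid.tolist() == [True, False, False]
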