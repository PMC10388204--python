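"""Steered-pulling toy: steering mechanics, Langevin integration,
rupture and changepoint detection, synchrony reporting."""

import numpy as np
import pytest

from fretscope import smd
from fretscope._changepoint import binary_segmentation


class TestSteeringEnergyForce:
    def test_origin_is_zero(self):
        s = smd.PullSettings()
        U, F = smd.steering_energy_force(s.x0, 0.0, s)
        assert U == 0.0 and F == 0.0

    def test_reference_displacement_arithmetic(self):
        """k = 5 (kcal/mol)/A^2, v = 1.5 A/ns, coordinate held at x0 for
        2 ns: U = 1/2 * 5 * 3^2 = 22.5 kcal/mol and F = 15 kcal/mol/A."""
        s = smd.PullSettings(k=5.0, v=1.5)
        U, F = smd.steering_energy_force(s.x0, 2.0, s)
        assert U == pytest.approx(22.5)
        assert F == pytest.approx(15.0)

    def test_force_is_negative_energy_gradient(self, rng):
        """Central finite differences recover F = -dU/dx at random points."""
        s = smd.PullSettings(k=3.7, v=0.9, x0=0.4)
        h = 1e-6
        for _ in range(20):
            x, t = rng.uniform(-5, 5), rng.uniform(0, 10)
            U_p, _ = smd.steering_energy_force(x + h, t, s)
            U_m, _ = smd.steering_energy_force(x - h, t, s)
            _, F = smd.steering_energy_force(x, t, s)
            assert F == pytest.approx(-(U_p - U_m) / (2 * h), abs=1e-4)
            U, _ = smd.steering_energy_force(x, t, s)
            assert U >= 0


class TestIntegratePull:
    def test_force_identity_machine_precision(self):
        traj = smd.integrate_pull(smd.two_well_landscape(), smd.PullSettings(seed=1))
        s = traj.settings
        assert np.max(np.abs(traj.force - s.k * (traj.reference - traj.x))) == 0.0

    def test_flat_landscape_zero_temperature_steady_force(self):
        """Overdamped response: x lags the reference by gamma*v/k, so the
        steady-state force equals gamma*v analytically."""
        s = smd.PullSettings(temperature=0.0, n_steps=8000, seed=0)
        traj = smd.integrate_pull(smd.flat_landscape(), s)
        assert traj.force[-2000:].mean() == pytest.approx(s.friction * s.v, rel=1e-3)

    def test_hookean_ramp_slope_in_deep_well(self):
        """Stiff trapping: before escape the force ramps linearly at
        k*v softened by the series compliance of spring and well,
        k*v * k_w / (k + k_w) with k_w the well curvature."""
        land = smd.Landscape(terms=[(-200.0, 0.0, 0.5)])
        s = smd.PullSettings(temperature=0.0, dt=0.0002, n_steps=20000, seed=0)
        traj = smd.integrate_pull(land, s)
        t = traj.times[2000:18000]
        slope = np.polyfit(t, traj.force[2000:18000], 1)[0]
        k_w = 200.0 / 0.5**2
        assert slope == pytest.approx(s.k * s.v * k_w / (s.k + k_w), rel=0.01)
        assert slope == pytest.approx(s.k * s.v, rel=0.05)

    def test_seed_determinism(self):
        a = smd.integrate_pull(smd.two_well_landscape(), smd.PullSettings(seed=9))
        b = smd.integrate_pull(smd.two_well_landscape(), smd.PullSettings(seed=9))
        assert np.array_equal(a.x, b.x)

    def test_unstable_dt_rejected(self):
        with pytest.raises(ValueError, match="dt too large"):
            smd.integrate_pull(smd.two_well_landscape(),
                               smd.PullSettings(dt=0.5, friction=0.1))

    def test_zero_temperature_rupture_force_matches_max_slope(self):
        """Stiff-spring quasi-static limit: the T -> 0 peak force equals
        the landscape's maximum resisting slope within 5%."""
        land = smd.two_well_landscape()
        grid = np.linspace(*land.x_range, 40000)
        max_slope = float(np.max(land.gradient(grid)))
        s = smd.PullSettings(k=50.0, v=0.2, dt=0.0005, n_steps=40000,
                             temperature=0.0, seed=0)
        traj = smd.integrate_pull(land, s)
        assert traj.force.max() == pytest.approx(max_slope, rel=0.05)


class TestDetectTurningPoint:
    def test_ramp_with_hard_drop(self):
        f = np.concatenate([np.linspace(0, 10, 2000), np.zeros(2000)])
        ev = smd.detect_turning_point(f)
        assert ev is not None
        assert abs(ev.turning_index - 2000) <= 201
        assert ev.post_drop_mean < 0.2 * ev.peak_force

    def test_pure_noise_returns_none(self, rng):
        assert smd.detect_turning_point(rng.normal(0, 1, 4000)) is None

    def test_monotone_ramp_returns_none(self):
        assert smd.detect_turning_point(np.linspace(0, 10, 4000)) is None

    def test_rupture_detected_on_simulated_pulls(self):
        detected = 0
        for seed in range(25):
            traj = smd.integrate_pull(smd.two_well_landscape(), smd.PullSettings(seed=seed))
            ev = smd.detect_turning_point(traj.force, times=traj.times)
            if ev is not None:
                detected += 1
                assert 0.5 < ev.turning_time < 10.0
        assert detected >= 24  # >= 95%

    def test_matches_first_passage_oracle(self):
        """Coordinate-based oracle: the turning point lies between first
        passage over the instability point (maximum resisting slope) and
        first passage over the barrier top, and agrees with the latter
        to 2% of trajectory length on average."""
        land = smd.two_well_landscape()
        grid = np.linspace(*land.x_range, 40000)
        x_star = float(grid[np.argmax(land.gradient(grid))])  # instability point
        offsets = []
        for seed in range(20):
            traj = smd.integrate_pull(land, smd.PullSettings(seed=seed))
            ev = smd.detect_turning_point(traj.force, times=traj.times)
            assert ev is not None
            fp_star = int(np.argmax(traj.x > x_star))
            fp_top = int(np.argmax(traj.x > 3.0))
            assert fp_star <= ev.turning_index <= fp_top
            offsets.append(abs(ev.turning_index - fp_top))
        assert np.mean(offsets) <= 0.02 * len(traj.x)


class TestDetectDistanceSteps:
    def test_constant_series_empty(self):
        assert smd.detect_distance_steps(np.full(500, 3.0)) == []

    def test_two_step_series_located(self, rng):
        x = np.concatenate([np.full(300, 5.0), np.full(400, 12.0), np.full(300, 25.0)])
        x = x + rng.normal(0, 0.5, 1000)
        cps = smd.detect_distance_steps(x)
        assert len(cps) == 2
        assert abs(cps[0] - 300) <= 3 and abs(cps[1] - 700) <= 3

    def test_matches_exhaustive_two_changepoint_scan(self, rng):
        """Oracle: grid search over all (i, j) pairs minimizing the
        three-segment SSE."""
        x = np.concatenate([np.full(60, 5.0), np.full(80, 12.0), np.full(60, 25.0)])
        x = x + rng.normal(0, 0.5, 200)
        cps = smd.detect_distance_steps(x, min_seg=5)
        best, best_cost = None, np.inf
        for i in range(5, 190):
            for j in range(i + 5, 196):
                cost = (np.var(x[:i]) * i + np.var(x[i:j]) * (j - i)
                        + np.var(x[j:]) * (200 - j))
                if cost < best_cost:
                    best_cost, best = cost, (i, j)
        assert len(cps) == 2
        assert abs(cps[0] - best[0]) <= 3 and abs(cps[1] - best[1]) <= 3

    def test_stability_under_added_noise(self, rng):
        base = np.concatenate([np.full(300, 5.0), np.full(400, 12.0), np.full(300, 25.0)])
        x1 = base + rng.normal(0, 0.4, 1000)
        cps1 = smd.detect_distance_steps(x1)
        x2 = x1 + np.random.default_rng(99).normal(0, 0.5, 1000)  # < 10% of min step
        cps2 = smd.detect_distance_steps(x2)
        assert len(cps1) == len(cps2) == 2
        assert all(abs(a - b) <= 1 for a, b in zip(cps1, cps2))

    def test_binary_segmentation_penalty_blocks_noise(self, rng):
        noise = rng.normal(0, 1, 400)
        assert binary_segmentation(noise, penalty=10 * np.log(400), min_seg=10) == []


class TestSynchronyReport:
    def _event(self, idx=1000):
        return smd.RuptureEvent(turning_time=idx * 0.002, turning_index=idx,
                                peak_force=10.0, post_drop_mean=0.5)

    def test_exact_coincidence(self):
        rep = smd.synchrony_report(self._event(), {"d1": [1000]}, tolerance=50)
        row = rep.iloc[0]
        assert row["synchronous"] and row["lag_frames"] == 0

    def test_early_step_negative_lag_not_synchronous(self):
        rep = smd.synchrony_report(self._event(), {"d1": [850]}, tolerance=50)
        row = rep.iloc[0]
        assert not row["synchronous"] and row["lag_frames"] == -150

    def test_three_stage_pattern(self):
        """Constructed three-stage trajectory: one early (negative-lag)
        distance step plus two rupture-coincident steps."""
        event = self._event(1500)
        steps = {"d_early": [900], "d_a": [1495], "d_b": [1510]}
        rep = smd.synchrony_report(event, steps, tolerance=50).set_index("distance")
        assert not rep.loc["d_early", "synchronous"]
        assert rep.loc["d_early", "lag_frames"] < 0
        assert rep.loc["d_a", "synchronous"] and rep.loc["d_b", "synchronous"]

    def test_empty_steps_reported_unmatched(self):
        rep = smd.synchrony_report(self._event(), {"d1": []}, tolerance=50)
        assert not rep.iloc[0]["synchronous"] and rep.iloc[0]["n_steps"] == 0


class TestMonotonicityProperties:
    def test_turning_time_increases_with_barrier_height(self):
        means = []
        for bh in (4.0, 6.0, 8.0):
            tt = []
            for seed in range(25):
                traj = smd.integrate_pull(smd.two_well_landscape(barrier_height=bh),
                                          smd.PullSettings(seed=seed))
                ev = smd.detect_turning_point(traj.force, times=traj.times)
                if ev:
                    tt.append(ev.turning_time)
            means.append(np.mean(tt))
        assert means[0] < means[1] < means[2]

    def test_peak_force_increases_with_velocity(self):
        means = []
        for v in (0.75, 1.5, 3.0):
            pf = []
            for seed in range(25):
                traj = smd.integrate_pull(smd.two_well_landscape(),
                                          smd.PullSettings(v=v, seed=seed))
                ev = smd.detect_turning_point(traj.force, times=traj.times)
                if ev:
                    pf.append(ev.peak_force)
            means.append(np.mean(pf))
        assert means[0] < means[1] < means[2]
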