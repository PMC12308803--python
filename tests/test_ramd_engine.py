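"""Integrator physics and the adaptive random-force protocol logic."""

import math

import numpy as np
import pytest

from ramdpath.ramd_engine import (KB, LangevinParams, RAMDParams, Trajectory,
                                  equilibrate, run_protocol, run_ramd_trajectory,
                                  step_langevin, unit_convert_force, _seed_for)
from ramdpath.toy_system import (ChannelSpec, TetherSpec, ToySystem,
                                 build_archetype)

from conftest import LANG, PROTOCOL_RAMD


def _flat_system():
    """No well, no wall: free diffusion (for closed-form drift checks)."""
    theta = math.radians(52.5)
    axes = [np.array([math.sin(theta), 0, math.cos(theta)]),
            np.array([math.sin(theta), 0, -math.cos(theta)])]
    return ToySystem(
        label="flat", well_center=np.zeros(3), well_depth=0.0, well_width=0.35,
        channels=[ChannelSpec("external", axes[0], 0.0),
                  ChannelSpec("internal", axes[1], 0.0)],
        markers={"reference_atom": np.zeros(3),
                 "external_marker": 2.0 * axes[0], "internal_marker": 2.0 * axes[1],
                 "gate_external": axes[0], "gate_internal": axes[1]},
        wall_height=0.0)


def _harmonic_system(k=1000.0):
    """Pure isotropic harmonic trap via a rest-length-zero tether."""
    s = _flat_system()
    s.tether = TetherSpec(anchor=np.zeros(3), spring_constant=k, rest_length=0.0,
                          breakable_at=1e6, switch_width=1.0)
    return s


class TestUnitConversion:
    def test_protocol_force_magnitude(self):
        assert unit_convert_force(9.0) == pytest.approx(376.56, abs=1e-9)

    @pytest.mark.parametrize("value,expected", [(0.0, 0.0), (1.0, 41.84)])
    def test_linear(self, value, expected):
        assert unit_convert_force(value) == pytest.approx(expected, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            unit_convert_force(-1.0)


class TestStepLangevin:
    def test_stationary_at_zero_temperature_and_force(self):
        s = build_archetype("symmetric", 1)
        params = LangevinParams(temperature=0.0)
        rng = np.random.default_rng(0)
        x = s.well_center.copy()
        for _ in range(5):
            x = step_langevin(x, s, np.zeros(3), params, 0.002, rng)
        np.testing.assert_allclose(x, s.well_center, atol=1e-12)

    def test_deterministic_drift_in_flat_potential(self):
        s = _flat_system()
        params = LangevinParams(temperature=0.0, mobility=0.01)
        rng = np.random.default_rng(0)
        f = np.array([50.0, 0.0, 0.0])
        x = np.zeros(3)
        for _ in range(10):
            x = step_langevin(x, s, f, params, 0.002, rng)
        np.testing.assert_allclose(x, [10 * 0.01 * 50.0 * 0.002, 0, 0], atol=1e-12)

    def test_equipartition_variance_in_harmonic_well(self):
        # long sampled run: Var(x_i) = kB*T/k per coordinate
        k = 1000.0
        s = _harmonic_system(k)
        params = LangevinParams(temperature=313.0, mobility=0.1)
        dt = 2e-4  # relaxation time 1/(mu*k) = 50 steps
        rng = np.random.default_rng(12345)
        x = np.zeros((256, 3))
        for _ in range(500):  # burn-in, 10 relaxation times
            x = step_langevin(x, s, np.zeros(3), params, dt, rng)
        samples = []
        for _ in range(500):
            x = step_langevin(x, s, np.zeros(3), params, dt, rng)
            samples.append(x.copy())
        samples = np.concatenate(samples, axis=0)  # 128k frames
        assert samples.shape[0] >= 1e5
        expected = KB * 313.0 / k
        var = samples.var(axis=0).mean()
        assert var == pytest.approx(expected, rel=0.05)

    def test_blowup_raises(self):
        s = _flat_system()
        params = LangevinParams(temperature=0.0)
        with pytest.raises(FloatingPointError):
            step_langevin(np.array([1e300, 0, 0]), s, np.array([1e300, 0, 0]),
                          params, 1e6, np.random.default_rng(0))


class TestRAMDWindowLogic:
    def run_flat(self, force_magnitude, threshold, n_windows=6):
        s = _flat_system()
        ramd = RAMDParams(force_magnitude=force_magnitude,
                          threshold_distance=threshold, max_time=n_windows * 0.05)
        lang = LangevinParams(temperature=0.0, mobility=0.01)
        return run_ramd_trajectory(s, ramd, lang, seed=5, log_events=True)

    def test_direction_kept_above_threshold(self):
        # drift per 50 fs window = mobility*F*window = 0.003 nm > 0.0025 nm
        traj = self.run_flat(force_magnitude=6.0, threshold=0.0025)
        assert traj.events and all(not e.redrawn for e in traj.events)
        dirs = np.array([e.direction for e in traj.events])
        assert np.ptp(dirs, axis=0).max() == 0  # never re-drawn

    def test_direction_redrawn_below_threshold(self):
        # zero force, zero temperature: window displacement exactly 0
        traj = self.run_flat(force_magnitude=0.0, threshold=0.0025)
        assert traj.events and all(e.redrawn for e in traj.events)

    def test_redraw_iff_displacement_below_threshold(self):
        # audited on a real system with thermal noise
        s = build_archetype("neutral_like", 1)
        traj = run_ramd_trajectory(s, PROTOCOL_RAMD, LANG, seed=11, log_events=True)
        assert len(traj.events) > 5
        for e in traj.events:
            assert e.redrawn == (e.displacement < PROTOCOL_RAMD.threshold_distance)

    def test_random_force_directions_are_unit(self):
        traj = self.run_flat(force_magnitude=0.0, threshold=1.0, n_windows=20)
        norms = [np.linalg.norm(e.direction) for e in traj.events]
        np.testing.assert_allclose(norms, 1.0, rtol=1e-9)

    def test_no_driving_force_censors(self):
        s = build_archetype("agonist_like", 1)
        ramd = RAMDParams(force_magnitude=0.0, max_time=1.0)
        traj = run_ramd_trajectory(s, ramd, LANG, seed=3)
        assert not traj.dissociated and traj.dissociation_time is None
        assert traj.ground_truth_channel == "none"

    def test_evaluation_window_must_divide_into_steps(self):
        with pytest.raises(ValueError, match="integer multiple"):
            RAMDParams(evaluation_window=0.005, time_step=0.002)


class TestTrajectoryContract:
    def test_times_evenly_spaced_and_dissociation_consistent(self, cationic_protocol):
        ramd = PROTOCOL_RAMD
        for traj in cationic_protocol.trajectories[:10]:
            dt = np.diff(traj.times)
            np.testing.assert_allclose(dt, dt[0], rtol=1e-9)
            dist = np.linalg.norm(traj.positions, axis=1)
            first = np.nonzero(dist > ramd.dissociation_distance)[0]
            assert traj.dissociated
            assert traj.dissociation_time == pytest.approx(traj.times[first[0]])

    def test_uneven_times_rejected(self):
        with pytest.raises(ValueError, match="constant spacing"):
            Trajectory(positions=np.zeros((3, 3)), times=np.array([0.0, 1.0, 3.0]),
                       replica_id=0, run_id=0, dissociated=False,
                       dissociation_time=None, ground_truth_channel="none", rng_seed=0)


class TestProtocol:
    def test_full_protocol_yields_100_runs(self, neutral_protocol):
        assert len(neutral_protocol.trajectories) == 100
        ids = {(t.replica_id, t.run_id) for t in neutral_protocol.trajectories}
        assert len(ids) == 100

    def test_same_seed_reproduces_dissociation_times(self):
        s = build_archetype("symmetric", 1)
        ramd = RAMDParams(max_time=500.0)
        times = []
        for _ in range(2):
            res = run_protocol(s, ramd, LANG, n_replicas=2, n_runs=3, base_seed=99)
            times.append([t.dissociation_time for t in res.trajectories])
        assert times[0] == times[1]

    def test_single_run_reproducible_in_isolation(self):
        # the counter-based seed scheme makes each run independent of order
        s = build_archetype("symmetric", 1)
        ramd = RAMDParams(max_time=500.0)
        res = run_protocol(s, ramd, LANG, n_replicas=2, n_runs=3, base_seed=99)
        target = res.trajectories[4]  # replica 1, run 1
        start = equilibrate(s, LANG, _seed_for(99, 0xE9, 1), n_steps=10_000, dt=ramd.time_step)
        alone = run_ramd_trajectory(s, ramd, LANG, seed=target.rng_seed,
                                    start_position=start, replica_id=1, run_id=1)
        np.testing.assert_array_equal(alone.positions, target.positions)
        assert alone.dissociation_time == target.dissociation_time

    def test_replicas_start_from_distinct_equilibrated_positions(self):
        s = build_archetype("symmetric", 1)
        starts = [equilibrate(s, LANG, _seed_for(1, 0xE9, r)) for r in range(3)]
        for i in range(3):
            assert np.linalg.norm(starts[i]) < 0.5  # still in the well
            for j in range(i + 1, 3):
                assert np.linalg.norm(starts[i] - starts[j]) > 1e-6

    def test_symmetric_archetype_exits_balanced(self, symmetric_protocol):
        chans = [t.ground_truth_channel for t in symmetric_protocol.trajectories
                 if t.dissociated]
        n_ext = chans.count("external")
        frac = n_ext / len(chans)
        assert len(chans) >= 190
        assert 0.40 <= frac <= 0.60  # binomial 99% interval around 0.5

    def test_agonist_and_cationic_are_channel_selective(self, agonist_protocol,
                                                        cationic_protocol):
        for result, channel in ((agonist_protocol, "external"),
                                (cationic_protocol, "internal")):
            chans = [t.ground_truth_channel for t in result.trajectories if t.dissociated]
            assert len(chans) >= 95
            assert chans.count(channel) / len(chans) >= 0.95

    def test_force_monotonicity_of_mean_dissociation_time(self, force_scan):
        def mean_time(result, max_time=2000.0):
            return np.mean([t.dissociation_time if t.dissociated else max_time
                            for t in result.trajectories])
        m = {mult: mean_time(res) for mult, res in force_scan.items()}
        assert m[0.5] >= m[1.0] >= m[2.0]
        assert m[0.5] > m[2.0]  # strict across the extreme levels
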