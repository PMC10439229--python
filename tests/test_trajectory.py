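"""RMSF, descriptor distributions, omega unwrapping/smoothing/rotation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mhcgroove.errors import ValidationError
from mhcgroove.interactions import AtomSite, InteractionDescriptor, PeptideSite, RingProbe
from mhcgroove.structure_io import PeptideMap, Trajectory
from mhcgroove.synthetic import ScaffoldSpec, TrajectorySpec, make_scaffold, make_trajectory
from mhcgroove.trajectory import (
    DihedralTrace,
    compute_rmsf,
    descriptor_series,
    detect_canonical_rotation,
    omega_trace,
    smooth_trace,
    summarize_distribution,
    unwrap_dihedral,
)


def brute_force_unwrap(raw):
    """Independent oracle: per step, try every +-k*360 shift and keep the
    one with step magnitude < 180 (180 resolved positively)."""
    out = [float(raw[0])]
    for v in raw[1:]:
        candidates = [v + 360.0 * k for k in range(-10, 11)]
        best = None
        for cand in candidates:
            step = cand - out[-1]
            if -180.0 < step <= 180.0:
                best = cand
        out.append(best)
    return np.array(out)


class TestUnwrap:
    def test_constant_series_unchanged(self):
        x = np.full(10, -73.0)
        assert np.array_equal(unwrap_dihedral(x), x)

    def test_single_forced_shift(self):
        assert np.allclose(unwrap_dihedral([179.0, -179.0]), [179.0, 181.0])

    def test_tie_at_180_resolved_positively(self):
        assert np.allclose(unwrap_dihedral([0.0, 180.0]), [0.0, 180.0])
        assert np.allclose(unwrap_dihedral([10.0, -170.0]), [10.0, 190.0])

    def test_output_congruent_to_input_mod_360(self, rng):
        raw = rng.uniform(-180.0, 180.0, size=500)
        out = unwrap_dihedral(raw)
        residual = (out - raw + 180.0) % 360.0 - 180.0
        assert np.allclose(residual, 0.0, atol=1e-9)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_recovers_wrapped_random_walk(self, seed):
        """Wrapping a free random walk into the principal range and
        unwrapping must recover the walk (branch fixed by the start)."""
        r = np.random.default_rng(seed)
        walk = np.cumsum(r.uniform(-170.0, 170.0, size=100))
        walk = walk - walk[0] + r.uniform(-180.0, 180.0)
        wrapped = np.mod(walk + 180.0, 360.0) - 180.0
        wrapped[wrapped == -180.0] = 180.0
        out = unwrap_dihedral(wrapped)
        assert np.allclose(out - out[0], walk - walk[0], atol=1e-8)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            raw = rng.uniform(-180.0, 180.0, size=200)
            assert np.allclose(unwrap_dihedral(raw), brute_force_unwrap(raw),
                               atol=1e-9)


class TestSmoothing:
    def test_constant_series_unchanged(self):
        t = np.arange(100) * 20.0
        y = np.full(100, 5.0)
        assert np.allclose(smooth_trace(y, t, window=1.0), y)

    def test_linear_ramp_is_fixed_point_in_interior(self):
        t = np.arange(500) * 20.0
        y = 0.3 * t - 40.0
        sm = smooth_trace(y, t, window=2.0)  # 2 ns -> 50 frames half-width
        assert np.allclose(sm[50:-50], y[50:-50], atol=1e-9)

    def test_outlier_attenuated_by_window_size(self):
        n = 2001
        t = np.arange(n) * 20.0
        y = np.zeros(n)
        y[1000] = 100.0
        sm = smooth_trace(y, t, window=10.0)  # 10 ns -> 500 frames in window
        assert sm[1000] <= 100.0 / 100.0  # >= 100x attenuation
        assert sm[1000] == pytest.approx(100.0 / 501.0)

    def test_tiny_window_returns_input_with_warning(self):
        t = np.arange(10) * 20.0
        y = np.sin(t)
        with pytest.warns(UserWarning):
            out = smooth_trace(y, t, window=0.001)  # 1 ps < 20 ps interval
        assert np.array_equal(out, y)

    def test_nonuniform_times_rejected(self):
        with pytest.raises(ValidationError):
            smooth_trace([1.0, 2.0, 3.0], [0.0, 1.0, 5.0], window=1.0)


class TestDistribution:
    def test_degenerate_single_value(self):
        summary = summarize_distribution([6.0] * 10)
        assert summary.peak_location == pytest.approx(6.1, abs=0.11)
        assert summary.width_metric == 0.0
        assert summary.probabilities.sum() == pytest.approx(1.0)

    def test_gaussian_peak_recovered(self):
        from mhcgroove.synthetic import sample_descriptor_population
        x = sample_descriptor_population({"kind": "gaussian", "mean": 6.0,
                                          "sd": 0.5}, 50_000, seed=11)
        summary = summarize_distribution(x, bin_width=0.2)
        assert abs(summary.peak_location - 6.0) <= 0.2

    def test_majority_mode_of_bimodal_mixture(self):
        from mhcgroove.synthetic import sample_descriptor_population
        x = sample_descriptor_population(
            {"kind": "mixture", "components": [
                {"weight": 0.7, "mean": 5.0, "sd": 0.3},
                {"weight": 0.3, "mean": 10.0, "sd": 0.3}]}, 20_000, seed=4)
        summary = summarize_distribution(x, bin_width=0.2)
        assert abs(summary.peak_location - 5.0) <= 0.2

    def test_peak_converges_with_sample_size(self):
        """The modal-bin estimate at n=50,000 must be at least as close to
        the true mode as at n=500 (sampling-oracle convergence)."""
        from mhcgroove.synthetic import sample_descriptor_population
        dist = {"kind": "gaussian", "mean": 6.0, "sd": 0.5}
        small = summarize_distribution(
            sample_descriptor_population(dist, 500, seed=8), 0.2)
        big = summarize_distribution(
            sample_descriptor_population(dist, 50_000, seed=8), 0.2)
        assert abs(big.peak_location - 6.0) <= abs(small.peak_location - 6.0) + 1e-9
        assert abs(big.peak_location - 6.0) <= 0.2

    def test_probabilities_normalised(self, rng):
        summary = summarize_distribution(rng.normal(size=1000), bin_width=0.1)
        assert summary.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert len(summary.probabilities) == len(summary.bin_edges) - 1

    def test_empty_series_rejected(self):
        with pytest.raises(ValidationError):
            summarize_distribution([])


class TestRmsf:
    def test_static_trajectory_rmsf_zero(self, scaffold):
        spec = TrajectorySpec(n_frames=5, frame_interval=20.0)
        traj, _ = make_trajectory(scaffold, spec)
        profile = compute_rmsf(traj, "A")
        assert np.allclose(profile.values, 0.0, atol=1e-9)

    def test_isotropic_noise_matches_closed_form(self, scaffold):
        """Isotropic sigma per coordinate gives RMSF = sqrt(3)*sigma."""
        sigma = 0.5
        spec = TrajectorySpec(n_frames=800, frame_interval=20.0,
                              positional_noise_sigma=sigma, seed=13)
        traj, _ = make_trajectory(scaffold, spec)
        profile = compute_rmsf(traj, "A")
        expected = np.sqrt(3.0) * sigma
        assert abs(profile.values.mean() - expected) / expected < 0.05

    def test_high_noise_region_is_profile_maximum(self, scaffold):
        sigma_map = {"default": 0.3}
        sigma_map.update({n: 1.5 for n in range(52, 63)})
        spec = TrajectorySpec(n_frames=300, frame_interval=20.0,
                              positional_noise_sigma=sigma_map, seed=21)
        traj, _ = make_trajectory(scaffold, spec)
        profile = compute_rmsf(traj, "A")
        assert 52 <= profile.argmax_residue() <= 62

    def test_invariant_under_global_rigid_motion(self, scaffold, rng):
        """Applying one rigid transform to every frame cannot change RMSF."""
        spec = TrajectorySpec(n_frames=60, frame_interval=20.0,
                              positional_noise_sigma=0.4, seed=2)
        traj, _ = make_trajectory(scaffold, spec)
        base = compute_rmsf(traj, "A").values
        from conftest import random_rigid_transform
        R, t = random_rigid_transform(rng)
        moved = Trajectory(traj.topology.copy(), traj.coords @ R.T + t,
                           traj.frame_interval)
        assert np.allclose(compute_rmsf(moved, "A").values, base, atol=1e-6)

    def test_single_frame_rejected(self, scaffold):
        traj = Trajectory(scaffold.copy(), scaffold.coords()[None], 20.0)
        with pytest.raises(ValidationError):
            compute_rmsf(traj, "A")


class TestDescriptorSeries:
    def test_static_trajectory_constant_series(self, scaffold, peptide_map, ledger):
        spec = TrajectorySpec(n_frames=4, frame_interval=20.0)
        traj, _ = make_trajectory(scaffold, spec, peptide_map)
        d = InteractionDescriptor("P1..Y59", PeptideSite("P1"),
                                  RingProbe("A", 59), "center_distance")
        series = descriptor_series(traj, d, peptide_map)
        assert np.allclose(series, ledger["descriptors"]["P1..Y59"], atol=1e-9)

    def test_scheduled_distance_recovered(self, scaffold, peptide_map):
        n = 50
        schedule = 6.0 + 2.0 * np.sin(np.linspace(0, 2 * np.pi, n))
        spec = TrajectorySpec(n_frames=n, frame_interval=20.0,
                              descriptor_schedules={"P1..Y59": schedule})
        traj, tledger = make_trajectory(scaffold, spec, peptide_map)
        d = InteractionDescriptor("P1..Y59", PeptideSite("P1"),
                                  RingProbe("A", 59), "center_distance")
        series = descriptor_series(traj, d, peptide_map)
        assert np.allclose(series, schedule, atol=1e-9)
        assert np.allclose(series,
                           tledger["descriptor_schedules"]["P1..Y59"], atol=1e-9)

    def test_scheduled_distance_with_noise(self, scaffold, peptide_map):
        n = 200
        schedule = np.linspace(5.0, 9.0, n)
        spec = TrajectorySpec(n_frames=n, frame_interval=20.0,
                              descriptor_schedules={"P1..I52": schedule},
                              positional_noise_sigma=0.05, seed=9)
        traj, _ = make_trajectory(scaffold, spec, peptide_map)
        d = InteractionDescriptor("P1..I52", PeptideSite("P1"),
                                  AtomSite("A", 52, "CD1"), "center_distance")
        series = descriptor_series(traj, d, peptide_map)
        assert np.sqrt(np.mean((series - schedule) ** 2)) < 0.2

    def test_discard_initial_drops_frames(self, scaffold, peptide_map):
        spec = TrajectorySpec(n_frames=10, frame_interval=20.0)
        traj, _ = make_trajectory(scaffold, spec, peptide_map)
        d = InteractionDescriptor("P1..Y59", PeptideSite("P1"),
                                  RingProbe("A", 59), "center_distance")
        assert len(descriptor_series(traj, d, peptide_map,
                                     discard_initial=100.0)) == 5


class TestOmegaTrace:
    def test_static_fixture_constant_trace(self, peptide_map):
        s, led = make_scaffold(ScaffoldSpec(omega_deg=-73.0))
        spec = TrajectorySpec(n_frames=20, frame_interval=20.0)
        traj, _ = make_trajectory(s, spec, peptide_map)
        trace = omega_trace(traj, peptide_map, "A", window=0.04)
        assert np.allclose(trace.omega_raw, -73.0, atol=1e-6)
        assert np.allclose(trace.omega_unwrapped, -73.0, atol=1e-6)

    def test_linear_ramp_unwrapped_span(self, peptide_map):
        """A -100 -> 460 ramp wraps twice in the raw trace but unwraps to
        the full 560-degree span."""
        s, _ = make_scaffold(ScaffoldSpec(omega_deg=-100.0))
        spec = TrajectorySpec(n_frames=300, frame_interval=20.0,
                              omega_schedule={"kind": "linear_ramp",
                                              "start": -100.0, "end": 460.0})
        traj, tledger = make_trajectory(s, spec, peptide_map)
        trace = omega_trace(traj, peptide_map, "A", window=0.04)
        schedule = np.asarray(tledger["omega_schedule"])
        assert np.allclose(trace.omega_unwrapped, schedule, atol=0.01)
        assert trace.omega_unwrapped[-1] - trace.omega_unwrapped[0] == pytest.approx(
            560.0, abs=0.01)
        # the principal-range trace jumps once, where the ramp crosses 180
        n_wraps = np.sum(np.abs(np.diff(trace.omega_raw)) > 180.0)
        assert n_wraps == 1

    def test_invariants_on_trace(self, peptide_map):
        s, _ = make_scaffold(ScaffoldSpec(omega_deg=170.0))
        spec = TrajectorySpec(n_frames=100, frame_interval=20.0,
                              omega_schedule={"kind": "linear_ramp",
                                              "start": 170.0, "end": 400.0},
                              positional_noise_sigma=0.02, seed=5)
        traj, _ = make_trajectory(s, spec, peptide_map)
        trace = omega_trace(traj, peptide_map, "A")
        assert trace.omega_unwrapped[0] == trace.omega_raw[0]
        assert np.all(np.abs(np.diff(trace.omega_unwrapped)) < 180.0)
        assert np.allclose((trace.omega_unwrapped - trace.omega_raw) % 360.0,
                           0.0, atol=1e-9)


class TestCanonicalRotation:
    def make_trace(self, values, dt=20.0, window=1.0):
        values = np.asarray(values, float)
        times = np.arange(values.size) * dt
        return DihedralTrace(times=times, omega_raw=values,
                             omega_unwrapped=values, omega_smoothed=values,
                             window=window)

    def test_constant_up_orientation_not_reached(self):
        trace = self.make_trace(np.full(400, -73.0))
        verdict = detect_canonical_rotation(trace, dwell=5.0)
        assert not verdict.reached
        assert verdict.first_time is None

    def test_trace_ending_canonical_reached(self):
        values = np.concatenate([np.linspace(-100, 100, 500),
                                 np.full(5000, 100.0)])
        verdict = detect_canonical_rotation(self.make_trace(values), dwell=50.0)
        assert verdict.reached
        assert verdict.first_time is not None

    def test_periodic_equivalents_detected(self):
        """-260 and 460 are the same orientation as 100 modulo 360."""
        for end in (-260.0, 460.0):
            values = np.full(5000, end)
            verdict = detect_canonical_rotation(self.make_trace(values),
                                                dwell=50.0)
            assert verdict.reached, end

    def test_invariant_to_global_360_offset(self):
        values = np.concatenate([np.linspace(-100, 100, 500),
                                 np.full(5000, 100.0)])
        base = detect_canonical_rotation(self.make_trace(values), dwell=50.0)
        for k in (-2, -1, 1, 3):
            shifted = detect_canonical_rotation(
                self.make_trace(values + 360.0 * k), dwell=50.0)
            assert shifted.reached == base.reached
            assert shifted.first_time == base.first_time

    def test_transient_crossing_below_dwell_ignored(self):
        values = np.concatenate([np.full(100, -73.0), np.full(20, 100.0),
                                 np.full(100, -73.0)])
        verdict = detect_canonical_rotation(self.make_trace(values), dwell=50.0)
        assert not verdict.reached

    def test_end_to_end_ramp_fixture(self, peptide_map):
        s, _ = make_scaffold(ScaffoldSpec(omega_deg=-100.0))
        spec = TrajectorySpec(n_frames=400, frame_interval=20.0,
                              omega_schedule={"kind": "piecewise",
                                              "points": [[0.0, -100.0],
                                                         [3000.0, 460.0],
                                                         [7980.0, 460.0]]})
        traj, _ = make_trajectory(s, spec, peptide_map)
        trace = omega_trace(traj, peptide_map, "A", window=0.2)
        verdict = detect_canonical_rotation(trace, dwell=2.0)
        assert verdict.reached
        # the ramp reaches the 97+-45 band (i.e. 412 unwrapped) around
        # 0.83 of the way through the 3 ns ramp
        assert verdict.first_time == pytest.approx(2500.0, abs=300.0)
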