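"""Water penetration counting, displacement series, smoothing, refolding time."""

import numpy as np
import pytest

from rodstab import (
    NOT_REFOLDED,
    SolvatedFrame,
    average_penetration_series,
    brute_force_count,
    count_penetrating_waters,
    displacement_series,
    frames_from_csv,
    frames_to_csv,
    gen_bundle_trajectory,
    penetration_series,
    refold_time,
    sliding_average,
)
from rodstab.structure import DEFAULT_HELIX_RANGES


def square_prism_frame(side_nm=0.6, waters=None, time_ns=0.0):
    """Four vertical dummy-atom chains at the corners of a square."""
    corners = {"H1": (0, 0), "H2": (side_nm, 0), "H3": (side_nm, side_nm), "H4": (0, side_nm)}
    atoms = {}
    for hid, (lo, hi) in DEFAULT_HELIX_RANGES.items():
        cx, cy = corners[hid]
        for num in range(lo, hi + 1):
            atoms[num] = {"CA": np.array([cx, cy, (num - lo) * 0.15])}
    waters = np.zeros((0, 3)) if waters is None else np.asarray(waters, dtype=float)
    return SolvatedFrame(time_ns, atoms, waters)


def random_solvated_frame(rng, n_waters=None, n_atoms_per_helix=None):
    n_waters = n_waters or rng.integers(1, 500)
    n_atoms = n_atoms_per_helix or rng.integers(1, 100)
    atoms = {}
    for hid, (lo, hi) in DEFAULT_HELIX_RANGES.items():
        base = rng.uniform(-1, 1, 3)
        nums = range(lo, lo + min(n_atoms, hi - lo + 1))
        for num in nums:
            atoms[num] = {"CA": base + rng.normal(scale=0.5, size=3)}
    waters = rng.uniform(-2, 2, size=(n_waters, 3))
    return SolvatedFrame(0.0, atoms, waters)


class TestPenetrationCount:
    def test_zero_waters(self):
        assert count_penetrating_waters(square_prism_frame()) == 0

    def test_centroid_water_counts_distant_waters_do_not(self, rng):
        core = [[0.3, 0.3, 1.5]]
        far = np.column_stack(
            [3 + rng.uniform(0, 2, 50), 3 + rng.uniform(0, 2, 50), rng.uniform(0, 3, 50)]
        )
        frame = square_prism_frame(waters=np.vstack([core, far]))
        assert count_penetrating_waters(frame) == 1
        assert brute_force_count(frame) == 1

    def test_rigid_motion_invariance(self, rng):
        frame = random_solvated_frame(rng, n_waters=200)
        base = count_penetrating_waters(frame)
        # random rotation + translation
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        t = rng.uniform(-5, 5, 3)
        moved = SolvatedFrame(
            frame.time_ns,
            {n: {a: R @ xyz + t for a, xyz in d.items()} for n, d in frame.atoms.items()},
            frame.water_oxygens @ R.T + t,
        )
        assert count_penetrating_waters(moved) == base

    def test_water_permutation_invariance_and_increment(self, rng):
        frame = random_solvated_frame(rng, n_waters=100)
        base = count_penetrating_waters(frame)
        perm = rng.permutation(len(frame.water_oxygens))
        shuffled = SolvatedFrame(0.0, frame.atoms, frame.water_oxygens[perm])
        assert count_penetrating_waters(shuffled) == base
        # add one water that satisfies the criterion: at an H1 atom position,
        # then check it is within cutoff of all helices, else skip placement
        probe = square_prism_frame(waters=[[0.3, 0.3, 1.5]])
        assert count_penetrating_waters(probe) == 1
        extra = np.vstack([probe.water_oxygens, [[0.3, 0.31, 1.5]]])
        assert count_penetrating_waters(SolvatedFrame(0.0, probe.atoms, extra)) == 2

    def test_matches_brute_force_on_random_configurations(self, rng):
        for _ in range(50):
            frame = random_solvated_frame(rng)
            cutoff = rng.uniform(0.2, 1.5)
            assert count_penetrating_waters(frame, cutoff_nm=cutoff) == brute_force_count(
                frame, cutoff_nm=cutoff
            )

    def test_monotone_in_cutoff(self, rng):
        frame = random_solvated_frame(rng, n_waters=300)
        cutoffs = np.sort(rng.uniform(0.1, 2.0, 8))
        counts = [count_penetrating_waters(frame, cutoff_nm=c) for c in cutoffs]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_invalid_inputs_rejected(self):
        frame = square_prism_frame()
        with pytest.raises(ValueError):
            count_penetrating_waters(frame, cutoff_nm=0.0)
        empty_helix = {k: v for k, v in frame.atoms.items() if k > 820}
        with pytest.raises(ValueError, match="H1"):
            count_penetrating_waters(SolvatedFrame(0.0, empty_helix, frame.water_oxygens))


class TestSlidingAverage:
    def test_constant_series_fixed_point(self):
        assert np.allclose(sliding_average([4.0] * 25, 10), 4.0)

    def test_window_one_is_identity(self, rng):
        v = rng.normal(size=30)
        assert np.allclose(sliding_average(v, 1), v)

    def test_trailing_and_centered_conventions(self):
        assert np.allclose(sliding_average([0.0, 10.0], 2, mode="trailing"), [0.0, 5.0])
        assert np.allclose(sliding_average([0.0, 10.0], 2, mode="centered"), [5.0, 5.0])

    def test_bounded_by_input_range(self, rng):
        v = rng.normal(size=50)
        s = sliding_average(v, 10)
        assert s.min() >= v.min() - 1e-12 and s.max() <= v.max() + 1e-12

    def test_empty_and_bad_window(self):
        assert sliding_average([], 10).size == 0
        with pytest.raises(ValueError):
            sliding_average([1.0], 0)


class TestPenetrationSeries:
    def test_constant_core_schedule(self):
        frames, _ = gen_bundle_trajectory(20, n_core_waters=3, seed=1)
        s = penetration_series(frames)
        assert np.all(s.counts == 3)
        assert np.allclose(s.smoothed, 3.0)

    def test_monotone_entering_waters(self):
        frames, truth = gen_bundle_trajectory(
            15, n_core_waters=lambda t: int(round(t / 0.02)), seed=2
        )
        s = penetration_series(frames)
        assert np.all(np.diff(s.counts) > 0)
        assert list(s.counts) == truth["core_water_schedule"]
        # per-frame oracle agreement
        for frame, k in zip(frames, truth["core_water_schedule"]):
            assert brute_force_count(frame) == k

    def test_replicate_average_of_identical_series(self):
        frames, _ = gen_bundle_trajectory(12, n_core_waters=2, seed=3)
        s = penetration_series(frames)
        avg = average_penetration_series([s, s, s, s, s])
        assert np.allclose(avg.counts, s.counts)
        assert np.allclose(avg.times_ns, s.times_ns)

    def test_replicate_average_interpolates_unequal_grids(self):
        a, _ = gen_bundle_trajectory(10, n_core_waters=2, seed=4, dt_ns=0.02)
        b, _ = gen_bundle_trajectory(19, n_core_waters=2, seed=5, dt_ns=0.01)
        avg = average_penetration_series(
            [penetration_series(a), penetration_series(b)]
        )
        assert np.allclose(avg.counts, 2.0)


class TestDisplacementSeries:
    def test_static_trajectory_constant(self):
        frames, _ = gen_bundle_trajectory(5, seed=1)
        ds = displacement_series(frames)
        for d in ds.distances.values():
            assert np.allclose(d, d[0])

    def test_translation_invariance(self):
        frames, _ = gen_bundle_trajectory(2, seed=1)
        shifted = SolvatedFrame(
            frames[1].time_ns,
            {n: {a: xyz + 1.0 for a, xyz in d.items()} for n, d in frames[0].atoms.items()},
            frames[1].water_oxygens,
        )
        ds = displacement_series([frames[0], shifted])
        for d in ds.distances.values():
            assert d[0] == pytest.approx(d[1])

    def test_d3_is_direct_euclidean_distance(self):
        frame = square_prism_frame()
        frame.atoms[808]["CA"] = np.array([0.0, 0.0, 0.0])
        frame.atoms[896]["CA"] = np.array([0.0, 2.5, 0.0])
        ds = displacement_series([frame])
        assert ds.distances["d3"][0] == pytest.approx(2.5)

    def test_symmetry_against_recomputation(self, rng):
        frames, _ = gen_bundle_trajectory(4, open_rate_nm_per_ns=0.2, dt_ns=0.5, seed=6)
        ds = displacement_series(frames)
        for vid, (a, b) in {"d1": (800, 904), "d2": (804, 900), "d3": (808, 896), "d4": (815, 888)}.items():
            for i, f in enumerate(frames):
                d_ab = np.linalg.norm(f.alpha_carbon(b) - f.alpha_carbon(a))
                d_ba = np.linalg.norm(f.alpha_carbon(a) - f.alpha_carbon(b))
                assert ds.distances[vid][i] == pytest.approx(d_ab) == pytest.approx(d_ba)

    def test_missing_anchor_names_frame_and_residue(self):
        frames, _ = gen_bundle_trajectory(3, seed=1)
        broken = dict(frames[1].atoms)
        del broken[896]
        frames[1] = SolvatedFrame(frames[1].time_ns, broken, frames[1].water_oxygens)
        with pytest.raises(ValueError, match="frame 1.*896"):
            displacement_series(frames)


class TestRefoldTime:
    def test_already_at_baseline(self):
        t = np.linspace(0, 10, 50)
        assert refold_time(t, np.full(50, 0.6), 0.6) == 0.0

    def test_monotone_decay_enters_band_and_stays(self):
        t = np.arange(0, 20.5, 0.5)
        # decays into the 0.05 nm band between t=6.5 (0.0503 above baseline)
        # and t=7 (0.04 above baseline) and stays
        d3 = 0.6 + 1.0 * np.exp(-t * np.log(25) / 7.0)
        t_star = refold_time(t, d3, 0.6, tol_nm=0.05)
        assert t_star == pytest.approx(7.0)

    def test_transient_touch_does_not_count(self):
        t = np.arange(8.0)
        d3 = np.array([1.0, 0.62, 1.0, 1.0, 0.62, 0.61, 0.60, 0.60])
        assert refold_time(t, d3, 0.6, tol_nm=0.05) == 4.0

    def test_not_refolded_sentinel(self):
        t = np.arange(5.0)
        assert refold_time(t, np.full(5, 1.5), 0.6, tol_nm=0.05) is NOT_REFOLDED

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            refold_time([], [], 0.6)
        with pytest.raises(ValueError):
            refold_time([0.0], [0.6], -1.0)
        with pytest.raises(ValueError):
            refold_time([0.0], [0.6], 0.6, tol_nm=0.0)


class TestFrameCsvRoundTrip:
    def test_round_trip_preserves_metrics(self, tmp_path):
        frames, _ = gen_bundle_trajectory(5, n_core_waters=2, seed=7)
        path = tmp_path / "traj.csv"
        frames_to_csv(frames, path)
        back = frames_from_csv(path)
        assert len(back) == len(frames)
        assert penetration_series(back).counts.tolist() == [2] * 5
        orig = displacement_series(frames).distances["d3"]
        assert np.allclose(displacement_series(back).distances["d3"], orig)
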