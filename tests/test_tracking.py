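"""Single-cell segmentation, overlap linking and the dual-control test."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from pktscreen.datatypes import MotilityParams, Trajectory
from pktscreen.synthetic import TimelapseConfig, generate_timelapse
from pktscreen.synthetic.motility import simulate_prw_path
from pktscreen.tracking import (build_trajectories, compare_to_controls,
                                dunn_test, link_by_overlap, median_ci,
                                segment_cells_frame, track_movie,
                                trajectory_stats)


def blob_frame(centers, shape=(256, 256), sigma=10.0, amp=3000.0, bg=100.0,
               noise=0.0, seed=0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.full(shape, bg, float)
    for cx, cy in centers:
        img += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma ** 2))
    if noise:
        img += np.random.default_rng(seed).normal(0, noise, shape)
    return np.clip(img, 0, 65535).astype(np.uint16)


def square_labels(positions, size=8, shape=(64, 64)):
    lab = np.zeros(shape, dtype=np.int32)
    cents = []
    for i, (x, y) in enumerate(positions, start=1):
        lab[y:y + size, x:x + size] = i
        cents.append((x + size / 2 - 0.5, y + size / 2 - 0.5))
    return lab, np.asarray(cents)


class TestFrameSegmentation:
    def test_single_blob_centroid_accuracy(self):
        img = blob_frame([(120.3, 90.7)], noise=15, seed=1)
        labels, cents = segment_cells_frame(img)
        assert labels.max() == 1
        assert np.hypot(cents[0, 0] - 120.3, cents[0, 1] - 90.7) < 1.0

    def test_two_separated_blobs(self):
        img = blob_frame([(60, 60), (180, 180)], sigma=10)
        labels, cents = segment_cells_frame(img)
        assert labels.max() == 2

    def test_blank_frame_yields_no_cells(self):
        flat = np.full((128, 128), 100, dtype=np.uint16)
        labels, cents = segment_cells_frame(flat)
        assert labels.max() == 0 and len(cents) == 0
        noisy = (100 + np.random.default_rng(0).normal(0, 20, (128, 128))
                 ).astype(np.uint16)
        labels, _ = segment_cells_frame(noisy)
        assert labels.max() == 0


class TestOverlapLinking:
    def test_identical_masks_identity_match(self):
        lab, _ = square_labels([(10, 10), (40, 40)])
        assert link_by_overlap(lab, lab) == {1: 1, 2: 2}

    def test_small_translation_links_large_jump_does_not(self):
        a, _ = square_labels([(10, 10)])
        b, _ = square_labels([(13, 12)])     # overlap remains
        assert link_by_overlap(a, b) == {1: 1}
        c, _ = square_labels([(40, 40)])     # far beyond the diameter
        assert link_by_overlap(a, c) == {}

    def test_greedy_prefers_largest_overlap(self):
        a, _ = square_labels([(10, 10)])
        b = np.zeros((64, 64), dtype=np.int32)
        b[10:18, 12:20] = 1      # overlap 6x8
        b[10:18, 8:11] = 2       # overlap 3x8... build competing partials
        m = link_by_overlap(a, b)
        assert m[1] == 1

    def test_crossing_cells_keep_identities(self):
        # two cells pass each other on distinct rows; neither mask ever
        # overlaps the other's previous-frame mask
        frames, cents = [], []
        xs_a = [5, 10, 15, 20, 25]
        xs_b = [25, 20, 15, 10, 5]
        for xa, xb in zip(xs_a, xs_b):
            lab, c = square_labels([(xa, 10), (xb, 30)])
            frames.append(lab)
            cents.append(c)
        trajs = build_trajectories(frames, cents, dt=12.0, min_duration=0.0)
        assert len(trajs) == 2
        xs = sorted([t.samples[:, 1].tolist() for t in trajs])
        assert xs[0] == [x + 3.5 for x in xs_a]
        assert xs[1] == [x + 3.5 for x in xs_b]


class TestTrajectoryBuilding:
    def chain_frames(self, n_present):
        """One stationary square present in the first n frames of 15."""
        frames, cents = [], []
        for f in range(15):
            if f < n_present:
                lab, c = square_labels([(20, 20)])
            else:
                lab, c = np.zeros((64, 64), dtype=np.int32), np.empty((0, 2))
            frames.append(lab)
            cents.append(c)
        return frames, cents

    def test_two_hour_boundary_is_inclusive(self):
        frames, cents = self.chain_frames(11)   # duration 120 min
        assert len(build_trajectories(frames, cents)) == 1
        frames, cents = self.chain_frames(10)   # duration 108 min
        assert len(build_trajectories(frames, cents)) == 0

    def test_nine_samples_discarded(self):
        frames, cents = self.chain_frames(9)
        assert build_trajectories(frames, cents) == []

    def test_empty_input_empty_output(self):
        assert build_trajectories([], []) == []

    def test_filter_matches_brute_force_duration_scan(self):
        rng = np.random.default_rng(5)
        lengths = rng.integers(2, 20, size=12)
        kept = 0
        for n in lengths:
            frames, cents = self.chain_frames(int(n))
            kept += len(build_trajectories(frames, cents))
        expected = sum(1 for n in lengths if (int(n) - 1) * 12.0 >= 120.0)
        assert kept == expected

    def test_gap_terminates_track(self):
        frames, cents = [], []
        for f in range(30):
            if f == 14:   # one missed detection in the middle
                frames.append(np.zeros((64, 64), dtype=np.int32))
                cents.append(np.empty((0, 2)))
            else:
                lab, c = square_labels([(20, 20)])
                frames.append(lab)
                cents.append(c)
        trajs = build_trajectories(frames, cents)
        assert len(trajs) == 2
        assert sorted(t.n_samples for t in trajs) == [14, 15]


class TestTrajectoryStats:
    def test_stationary_cell_zero_speed_zero_directionality(self):
        t = Trajectory(0, [(0, 5, 5), (12, 5, 5), (24, 5, 5)])
        s = trajectory_stats(t)
        assert s.speed == 0 and s.directionality == 0

    def test_straight_path_arithmetic(self):
        samples = [(12 * k, float(k), 0.0) for k in range(11)]
        s = trajectory_stats(Trajectory(1, samples))
        assert s.speed == pytest.approx(1 / 12, rel=1e-9)
        assert s.directionality == pytest.approx(1.0, rel=1e-9)
        assert s.path_length >= s.displacement

    def test_prw_ensemble_speed_recovery(self):
        """Median estimated speed within 10% of the generative speed."""
        p = MotilityParams(speed=0.8, persistence_time=120.0)
        speeds = []
        for s in range(50):
            path = simulate_prw_path(p, 60, 12.0, rng_seed=s)
            samples = np.column_stack([np.arange(61) * 12.0, path])
            speeds.append(trajectory_stats(Trajectory(s, samples)).speed)
        assert np.median(speeds) == pytest.approx(0.8, rel=0.10)

    def test_too_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            Trajectory(0, [(0.0, 1.0, 2.0)])


class TestTimelapseGeneration:
    def test_default_acquisition_geometry(self):
        cfg = TimelapseConfig(n_cells=1, image_shape=(256, 256),
                              params=MotilityParams(speed=0.0))
        mov = generate_timelapse(cfg, rng_seed=0)
        assert mov.stack.shape[0] == 61
        assert np.array_equal(mov.timestamps, np.arange(61) * 12.0)
        assert mov.timestamps[-1] == 720.0

    def test_stationary_cell_fixed_centroid(self):
        cfg = TimelapseConfig(n_cells=1, image_shape=(256, 256),
                              params=MotilityParams(speed=0.0), noise_sd=5.0)
        mov = generate_timelapse(cfg, rng_seed=1)
        cents = []
        for f in (0, 20, 40, 60):
            _, c = segment_cells_frame(mov.stack[f])
            assert len(c) == 1
            cents.append(c[0])
        cents = np.asarray(cents)
        assert np.ptp(cents, axis=0).max() < 0.5

    def test_confined_cells_never_touch(self):
        cfg = TimelapseConfig(n_cells=2, image_shape=(256, 512),
                              confine_grid=(2, 1), n_frames=10)
        mov = generate_timelapse(cfg, rng_seed=4)
        for f in range(10):
            labels, _ = segment_cells_frame(mov.stack[f])
            assert labels.max() == 2

    def test_oversized_cell_rejected(self):
        with pytest.raises(ValueError, match="image extent"):
            TimelapseConfig(n_cells=1, image_shape=(64, 64),
                            blob_sigma_px=10.0)


@pytest.fixture(scope="module")
def small_movie():
    cfg = TimelapseConfig(n_cells=4, image_shape=(256, 256),
                          confine_grid=(2, 2), n_frames=15,
                          blob_sigma_px=10.0, noise_sd=0.0,
                          params=MotilityParams(speed=0.5,
                                                persistence_time=60.0))
    return generate_timelapse(cfg, rng_seed=6)


class TestStackInvariances:
    def speeds(self, stack):
        trajs = track_movie(stack, dt=12.0, min_duration=120.0,
                            um_per_px=0.33)
        return sorted(trajectory_stats(t).speed for t in trajs)

    def test_speed_invariant_under_translation(self, small_movie):
        base = self.speeds(small_movie.stack)
        rolled = np.roll(small_movie.stack, shift=(7, -5), axis=(1, 2))
        assert np.allclose(self.speeds(rolled), base, atol=1e-9)

    def test_speed_invariant_under_rotation(self, small_movie):
        base = self.speeds(small_movie.stack)
        rot = np.rot90(small_movie.stack, k=1, axes=(1, 2))
        assert np.allclose(self.speeds(rot), base, atol=1e-9)


def kruskal_oracle(groups):
    """Brute-force rank statistic with tie correction."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    idx = 0
    h = 0.0
    for g in groups:
        r = ranks[idx:idx + len(g)]
        h += r.sum() ** 2 / len(g)
        idx += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, t = np.unique(pooled, return_counts=True)
    denom = 1 - ((t ** 3 - t).sum()) / (n ** 3 - n)
    return h / denom


class TestGroupStatistics:
    def test_kruskal_matches_rank_oracle_exhaustively(self):
        """scipy's statistic equals the rank formula on all 8-value tables."""
        values = np.arange(1.0, 9.0)
        for combo in itertools.combinations(range(8), 3):
            rest = [i for i in range(8) if i not in combo]
            for combo2 in itertools.combinations(rest, 3):
                g1 = values[list(combo)]
                g2 = values[list(combo2)]
                g3 = values[[i for i in rest if i not in combo2]]
                h_scipy, _ = stats.kruskal(g1, g2, g3)
                assert h_scipy == pytest.approx(kruskal_oracle([g1, g2, g3]),
                                                rel=1e-12)

    def test_kruskal_oracle_with_ties(self):
        g = [np.array([1.0, 2.0, 2.0]), np.array([2.0, 3.0]),
             np.array([1.0, 3.0, 3.0])]
        h_scipy, _ = stats.kruskal(*g)
        assert h_scipy == pytest.approx(kruskal_oracle(g), rel=1e-12)

    def test_dunn_detects_separated_group(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0, 1, 40)
        c = rng.normal(5, 1, 40)
        p = dunn_test([a, b, c])
        assert p[0, 1] > 0.05
        assert p[0, 2] < 1e-6 and p[1, 2] < 1e-6

    def test_median_ci_brackets_median(self):
        x = np.random.default_rng(1).normal(10, 2, 200)
        lo, hi = median_ci(x)
        assert lo <= np.median(x) <= hi
        assert lo < hi


class TestDualControlComparison:
    def test_identical_groups_not_significant(self):
        x = np.random.default_rng(0).normal(1, 0.2, 60)
        r = compare_to_controls(x, x.copy(), x.copy())
        assert not r.significant and r.direction == 0

    def test_halved_median_detected_as_decrease(self):
        rng = np.random.default_rng(1)
        lo = np.exp(rng.normal(0, 0.3, 100))
        hi = np.exp(rng.normal(0, 0.3, 100))
        kd = np.exp(rng.normal(math.log(0.5), 0.3, 100))
        r = compare_to_controls(kd, lo, hi)
        assert r.significant and r.direction == -1
        assert "decrease" in r.summary()

    def test_small_group_is_inconclusive(self):
        r = compare_to_controls(np.ones(3), np.ones(30), np.ones(30))
        assert not r.significant
        assert "inconclusive" in r.reason

    def test_single_control_difference_is_not_enough(self):
        rng = np.random.default_rng(2)
        kd = rng.normal(0, 1, 80)
        lo = rng.normal(0, 1, 80)     # same as knockdown
        hi = rng.normal(4, 1, 80)     # far away
        r = compare_to_controls(kd, lo, hi)
        assert not r.significant
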