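"""Tracklet extraction, speeds, KS test correctness, coordination epochs."""

import itertools

import numpy as np
import pandas as pd
import pytest

from urbanrat.tracks import (CoordinationEpoch, Tracklet, detect_coordination,
                             extract_and_filter_tracklets, instantaneous_speeds,
                             ks_two_sample, normalize_sizes,
                             participant_size_comparison,
                             quartile_speed_comparison, tracklet_speed)


def brute_force_ks(a, b):
    """Exhaustive permutation oracle: D and P(D_perm >= D_obs) over all orderings."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n, m = len(a), len(b)
    pooled = np.sort(np.concatenate([a, b]))

    def stat_for(a_positions):
        ca = cb = 0
        best = 0.0
        a_set = set(a_positions)
        for i in range(n + m):
            if i in a_set:
                ca += 1
            else:
                cb += 1
            best = max(best, abs(ca / n - cb / m))
        return best

    # D of the observed labeling: positions of a's values in the pooled order
    order = np.argsort(np.concatenate([a, b]), kind="stable")
    obs_positions = {i for i, idx in enumerate(order) if idx < n}
    d_obs = stat_for(obs_positions)
    count = total = 0
    for combo in itertools.combinations(range(n + m), n):
        total += 1
        if stat_for(combo) >= d_obs - 1e-12:
            count += 1
    return d_obs, count / total


def make_tracklet(tid, positions, frame_rate=30.0, size=None, start=0):
    positions = np.asarray(positions, dtype=float)
    return Tracklet(id=tid, track_id=tid,
                    frames=start + np.arange(len(positions)),
                    positions=positions, frame_rate=frame_rate,
                    relative_size=size)


def walk(n, step=0.0, start=(0.0, 0.0)):
    out = np.zeros((n, 2))
    out[:, 0] = start[0] + step * np.arange(n)
    out[:, 1] = start[1]
    return out


class TestExtraction:
    def _tracks(self, spec):
        """spec: {id: list of frame numbers}; positions are dummies."""
        return {
            tid: pd.DataFrame({"frame": frames,
                               "g1": np.zeros(len(frames)),
                               "g2": np.zeros(len(frames))})
            for tid, frames in spec.items()
        }

    def test_five_second_boundary(self):
        tracks = self._tracks({"short": range(147), "kept": range(150)})
        got = extract_and_filter_tracklets(tracks, 30.0)
        assert [t.track_id for t in got] == ["kept"]
        assert got[0].duration == pytest.approx(5.0)

    def test_contiguous_track_is_one_tracklet(self):
        got = extract_and_filter_tracklets(self._tracks({"a": range(300)}), 30.0)
        assert len(got) == 1 and got[0].n_frames == 300

    def test_hand_counted_gap_structure(self):
        # 7 ids; gaps > 30 frames split; fragments < 150 frames at 30 fps drop
        spec = {
            "a": list(range(200)),                                   # 1 tracklet
            "b": list(range(160)) + list(range(400, 560)),           # 2 tracklets
            "c": list(range(100)),                                   # too short
            "d": list(range(160)) + list(range(260, 300)),           # 1 (2nd short)
            "e": list(range(0, 320, 2)),                             # 1 (gaps of 2)
            "f": list(range(149)),                                   # too short
            "g": list(range(150)) + list(range(1000, 1150)),         # 2 tracklets
        }
        got = extract_and_filter_tracklets(self._tracks(spec), 30.0)
        assert len(got) == 7

    def test_empty_input(self):
        assert extract_and_filter_tracklets({}, 30.0) == []

    def test_raising_min_duration_is_monotone(self):
        tracks = self._tracks({c: range(n) for c, n in
                               zip("abcdef", (150, 180, 210, 300, 400, 160))})
        counts = [len(extract_and_filter_tracklets(tracks, 30.0, min_duration_s=s))
                  for s in (5.0, 6.0, 7.0, 10.0, 14.0)]
        assert counts == sorted(counts, reverse=True)


class TestSpeeds:
    def test_constant_velocity(self):
        t = make_tracklet("a", walk(30, step=0.1))
        assert tracklet_speed(t) == pytest.approx(3.0)

    def test_static(self):
        assert tracklet_speed(make_tracklet("a", walk(30))) == 0.0

    def test_median_robust_to_one_outlier(self):
        pos = walk(21, step=0.1)
        pos[10:] += 5.0  # a single teleporting jump
        t = make_tracklet("a", pos)
        assert tracklet_speed(t) == pytest.approx(3.0)

    def test_single_frame_errors(self):
        with pytest.raises(ValueError):
            tracklet_speed(make_tracklet("a", walk(1)))


class TestNormalizeSizes:
    def test_mean_one(self):
        np.testing.assert_allclose(normalize_sizes([1.0, 2.0, 3.0]),
                                   [0.5, 1.0, 1.5])
        np.testing.assert_allclose(normalize_sizes([7.0, 7.0]), [1.0, 1.0])

    def test_outlier_exclusion(self):
        sizes = [1.0, 1.0, 1.0, 10.0]
        got = normalize_sizes(sizes, exclude_outliers=True)
        np.testing.assert_allclose(got, [1.0, 1.0, 1.0, 10.0])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            normalize_sizes([])
        with pytest.raises(ValueError):
            normalize_sizes([1.0, -2.0])


class TestKS:
    def test_identical_samples(self):
        r = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], method="asymp")
        assert r.statistic == 0.0 and r.pvalue == pytest.approx(1.0)

    def test_fully_separated(self):
        r = ks_two_sample([1.0, 2.0], [10.0, 11.0, 12.0])
        assert r.statistic == 1.0

    @pytest.mark.parametrize("n1,n2", [(2, 3), (4, 4), (5, 3), (6, 2)])
    def test_exact_p_matches_enumeration(self, n1, n2, rng):
        a = rng.standard_normal(n1)
        b = 0.5 + rng.standard_normal(n2)
        got = ks_two_sample(a, b, method="exact")
        d_oracle, p_oracle = brute_force_ks(a, b)
        assert got.statistic == pytest.approx(d_oracle, abs=1e-12)
        assert got.pvalue == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_scipy(self, rng):
        from scipy.stats import ks_2samp
        a = rng.standard_normal(12)
        b = rng.standard_normal(15) + 0.8
        ours = ks_two_sample(a, b, method="exact")
        ref = ks_2samp(a, b, method="exact")
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_ties_rejected_for_exact(self):
        with pytest.raises(ValueError, match="ties"):
            ks_two_sample([1.0, 2.0], [2.0, 3.0], method="exact")


class TestQuartileComparison:
    def test_speed_tracking_size_separates(self, rng):
        tl = []
        for i in range(24):
            size = 0.5 + i * 0.1
            speed_step = size / 30.0  # speed == size exactly
            tl.append(make_tracklet(f"t{i}", walk(160, step=speed_step), size=size))
        r = quartile_speed_comparison(tl)
        assert r.statistic == 1.0
        # full separation at n1 = n2 = 6: exact p is its floor 2 / C(12, 6)
        assert r.pvalue == pytest.approx(2 / 924, abs=1e-12)

    def test_hand_computed_fixture(self):
        sizes = [1, 2, 3, 4, 5, 6, 7, 8]
        speeds = [0.9, 0.1, 0.5, 0.6, 0.4, 0.7, 0.8, 1.0]
        tl = [make_tracklet(f"t{i}", walk(160, step=sp / 30.0), size=sz)
              for i, (sz, sp) in enumerate(zip(sizes, speeds))]
        r = quartile_speed_comparison(tl)
        # lower quartile sizes {1,2}: speeds {0.9, 0.1}; upper {7,8}: {0.8, 1.0}
        assert r.statistic == pytest.approx(0.5)

    def test_too_few_tracklets(self):
        with pytest.raises(ValueError):
            quartile_speed_comparison([make_tracklet("a", walk(160), size=1.0)])


class TestCoordination:
    def test_all_static_no_epochs(self):
        tl = [make_tracklet(f"t{i}", walk(100), size=1.0) for i in range(5)]
        counts, epochs = detect_coordination(tl, speed_threshold=1.0,
                                             count_threshold=2, frame_rate=30.0)
        assert counts.sum() == 0 and epochs == []

    def test_joint_acceleration_one_epoch(self):
        tl = []
        for i in range(5):
            pos = walk(300)
            if i < 3:  # three animals sprint during frames 100-160 (2 s)
                pos[100:160, 0] += np.cumsum(np.full(60, 0.2))
                pos[160:, 0] = pos[159, 0]
            tl.append(make_tracklet(f"t{i}", pos, size=1.0))
        counts, epochs = detect_coordination(tl, speed_threshold=1.0,
                                             count_threshold=3, frame_rate=30.0)
        assert len(epochs) == 1
        assert len(epochs[0].participants) == 3
        assert epochs[0].peak_count == 3

    def test_two_separated_bursts_two_epochs(self):
        tl = []
        for i in range(3):
            pos = walk(600)
            for lo, hi in ((50, 110), (400, 460)):  # bursts 290 frames apart
                pos[lo:hi, 0] += np.cumsum(np.full(60, 0.2))
                pos[hi:, 0] = pos[hi - 1, 0]
            tl.append(make_tracklet(f"t{i}", pos, size=1.0))
        _, epochs = detect_coordination(tl, speed_threshold=1.0,
                                        count_threshold=3, frame_rate=30.0,
                                        merge_gap_s=1.0)
        assert len(epochs) == 2

    def test_counts_bounded_by_concurrent_tracklets(self, rng):
        tl = [make_tracklet(f"t{i}", rng.normal(0, 0.3, (100, 2)), size=1.0,
                            start=i * 40) for i in range(4)]
        counts, _ = detect_coordination(tl, speed_threshold=0.01,
                                        count_threshold=1, frame_rate=30.0)
        for frame, c in counts.items():
            concurrent = sum(t.frames[0] <= frame <= t.frames[-1] for t in tl)
            assert c <= concurrent


class TestParticipantComparison:
    def _cohort(self, part_sizes, rest_sizes):
        tl, epochs_members = [], []
        for i, s in enumerate(part_sizes):
            pos = walk(200)
            pos[50:80, 0] += np.cumsum(np.full(30, 0.2))
            pos[80:, 0] = pos[79, 0]
            t = make_tracklet(f"p{i}", pos, size=s)
            tl.append(t)
            epochs_members.append(t.id)
        for i, s in enumerate(rest_sizes):
            tl.append(make_tracklet(f"r{i}", walk(200), size=s))
        epochs = [CoordinationEpoch(start=50, end=80,
                                    participants=frozenset(epochs_members),
                                    peak_count=len(epochs_members))]
        return tl, epochs

    def test_strictly_larger_participants(self):
        tl, epochs = self._cohort([3.0, 3.5, 4.0], [1.0, 1.2, 1.4])
        r = participant_size_comparison(tl, epochs)
        assert r.statistic == 1.0

    def test_hand_enumerated_fixture(self):
        tl, epochs = self._cohort([1.0, 2.0, 3.0, 4.0], [2.5, 3.5, 4.5, 5.5])
        r = participant_size_comparison(tl, epochs)
        d, p = brute_force_ks([1.0, 2.0, 3.0, 4.0], [2.5, 3.5, 4.5, 5.5])
        assert r.statistic == pytest.approx(d, abs=1e-12)
        assert r.pvalue == pytest.approx(p, abs=1e-12)

    def test_empty_group_errors(self):
        tl, epochs = self._cohort([1.0, 2.0], [])
        with pytest.raises(ValueError):
            participant_size_comparison(tl, epochs)
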