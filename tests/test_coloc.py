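"""Two-channel colocalization, recruitment timing and partner-class summaries."""

import numpy as np
import pytest

from myddo.coloc import (colocalize, compare_partner_classes, fill_recruitment_times,
                         recruitment_time)
from myddo.core import Track
from myddo.metrics import TrackMetrics


def make_track(tid, frames, xs, ys, channel="C0"):
    return Track(tid, np.array(frames), np.array(xs, float), np.array(ys, float),
                 channel=channel)


def oracle_longest_run(ta, tb, max_dist):
    """Independent brute force: scan every frame index, count consecutive
    common frames within distance, python loops only."""
    a = {int(f): (ta.x_um[i], ta.y_um[i]) for i, f in enumerate(ta.frames)}
    b = {int(f): (tb.x_um[i], tb.y_um[i]) for i, f in enumerate(tb.frames)}
    best = 0
    frames = sorted(a)
    for start in frames:
        run = 0
        f = start
        while f in a and f in b:
            dx = a[f][0] - b[f][0]
            dy = a[f][1] - b[f][1]
            if (dx * dx + dy * dy) ** 0.5 <= max_dist:
                run += 1
                best = max(best, run)
                f += 1
            else:
                break
        # runs starting later are found from their own start frame
    return best


class TestColocalize:
    def test_identical_tracks_fully_overlap(self):
        a = make_track(0, range(5), [1.0] * 5, [2.0] * 5)
        b = make_track(0, range(5), [1.0] * 5, [2.0] * 5, "C1")
        rec = colocalize([a], [b])[0]
        assert rec.colocalized and rec.n_consecutive_overlap == 5

    def test_single_frame_overlap_not_colocalized(self):
        a = make_track(0, [3], [1.0], [1.0])
        b = make_track(0, [3], [1.0], [1.0], "C1")
        assert not colocalize([a], [b])[0].colocalized

    def test_distance_exactly_at_threshold_inclusive(self):
        a = make_track(0, range(3), [1.0] * 3, [1.0] * 3)
        b = make_track(0, range(3), [1.25] * 3, [1.0] * 3, "C1")  # exactly 0.25 um
        rec = colocalize([a], [b], max_dist_um=0.25)[0]
        assert rec.colocalized and rec.n_consecutive_overlap == 3

    def test_gap_in_either_channel_breaks_the_run(self):
        a = make_track(0, [0, 1, 2, 3, 4], [0.0] * 5, [0.0] * 5)
        b = make_track(0, [0, 1, 3, 4], [0.0] * 4, [0.0] * 4, "C1")
        rec = colocalize([a], [b], min_consecutive=3)[0]
        assert not rec.colocalized  # longest unbroken run is 2

    def test_one_to_one_assignment_best_run_wins(self):
        b = make_track(0, range(10), [0.0] * 10, [0.0] * 10, "C1")
        a_short = make_track(0, range(5, 8), [0.0] * 3, [0.0] * 3)
        a_long = make_track(1, range(10), [0.0] * 10, [0.0] * 10)
        recs = colocalize([a_short, a_long], [b])
        by_id = {r.trackA_id: r for r in recs}
        assert by_id[1].colocalized and not by_id[0].colocalized

    def test_matches_bruteforce_oracle_on_randomized_pairs(self, rng):
        """200 random track pairs, boundary distances and overlaps included."""
        mism = 0
        for _ in range(200):
            fa = sorted(rng.choice(20, size=rng.integers(2, 12), replace=False))
            fb = sorted(rng.choice(20, size=rng.integers(2, 12), replace=False))
            a = make_track(0, fa, rng.uniform(0, 2, len(fa)), rng.uniform(0, 2, len(fa)))
            b = make_track(0, fb, rng.uniform(0, 2, len(fb)), rng.uniform(0, 2, len(fb)), "C1")
            rec = colocalize([a], [b], max_dist_um=0.8, min_consecutive=2)[0]
            run = oracle_longest_run(a, b, 0.8)
            assert rec.colocalized == (run >= 2)
            if rec.colocalized:
                assert rec.n_consecutive_overlap == run

    def test_translation_invariance(self, rng):
        a = make_track(0, range(6), rng.uniform(0, 3, 6), rng.uniform(0, 3, 6))
        b = make_track(0, range(6), a.x_um + 0.1, a.y_um, "C1")
        r1 = colocalize([a], [b])[0]
        a2 = make_track(0, range(6), a.x_um + 5.0, a.y_um - 2.0)
        b2 = make_track(0, range(6), b.x_um + 5.0, b.y_um - 2.0, "C1")
        r2 = colocalize([a2], [b2])[0]
        assert (r1.colocalized, r1.n_consecutive_overlap) == (r2.colocalized, r2.n_consecutive_overlap)

    def test_saturation_limit(self, rng):
        """With max_dist -> inf and min_consecutive=1, any temporal overlap
        colocalizes."""
        a = make_track(0, [4], [0.0], [0.0])
        b = make_track(0, [4], [50.0], [50.0], "C1")
        assert colocalize([a], [b], max_dist_um=np.inf, min_consecutive=1)[0].colocalized


class TestRecruitmentTime:
    def _pair(self, a_start, b_start):
        frames_a = list(range(a_start, a_start + 20))
        frames_b = list(range(b_start, b_start + 20))
        a = make_track(0, frames_a, [0.0] * 20, [0.0] * 20)
        b = make_track(0, frames_b, [0.0] * 20, [0.0] * 20, "C1")
        return a, b

    def test_fourteen_second_delay(self):
        a, b = self._pair(10, 24)
        rec = colocalize([a], [b])[0]
        assert recruitment_time(rec, [a], [b], 1.0) == 14.0

    def test_simultaneous_nucleation_is_zero(self):
        a, b = self._pair(5, 5)
        rec = colocalize([a], [b])[0]
        assert recruitment_time(rec, [a], [b], 1.0) == 0.0

    def test_negative_delay_flagged(self):
        a, b = self._pair(10, 4)
        rec = colocalize([a], [b])[0]
        dt = recruitment_time(rec, [a], [b], 1.0)
        assert dt == -6.0 and rec.negative_delay

    def test_non_colocalized_record_raises(self):
        a = make_track(0, [0], [0.0], [0.0])
        b = make_track(0, [0], [5.0], [0.0], "C1")
        rec = colocalize([a], [b])[0]
        with pytest.raises(ValueError):
            recruitment_time(rec, [a], [b])


class TestComparePartnerClasses:
    def _metrics(self, sizes, lifetimes=None):
        lifetimes = lifetimes or [10.0] * len(sizes)
        return [TrackMetrics(i, lt, "long" if lt >= 50 else "short", s,
                             "large" if s >= 4.5 else "small", None)
                for i, (s, lt) in enumerate(zip(sizes, lifetimes))]

    def test_all_negative_gives_absent_positive_mean(self):
        a = [make_track(i, range(5), [10.0 * i] * 5, [0.0] * 5) for i in range(3)]
        recs = colocalize(a, [])
        summary = compare_partner_classes(recs, self._metrics([1.0, 2.0, 3.0]))
        assert summary.mean_size_positive is None
        assert summary.pct_colocalized == 0.0

    def test_constructed_means(self):
        """Positives sized (10,12,11), negatives (3,3.4): means 11.0 and 3.2."""
        a = [make_track(i, range(5), [10.0 * i] * 5, [0.0] * 5) for i in range(5)]
        b = [make_track(i, range(5), [10.0 * i] * 5, [0.0] * 5, "C1") for i in range(3)]
        recs = colocalize(a, b)
        summary = compare_partner_classes(recs, self._metrics([10, 12, 11, 3, 3.4]))
        assert summary.mean_size_positive == pytest.approx(11.0)
        assert summary.mean_size_negative == pytest.approx(3.2)
        assert summary.pct_colocalized == pytest.approx(60.0)

    def test_partners_recruited_to_large_puncta_only(self, rng):
        """When partners sit only on puncta of size >= 6, the positive-class
        mean exceeds the negative-class mean."""
        sizes = list(rng.uniform(1, 3, 20)) + list(rng.uniform(6, 12, 8))
        a = [make_track(i, range(5), [2.0 * i] * 5, [0.0] * 5) for i in range(28)]
        b = [make_track(i, range(5), [2.0 * (20 + i)] * 5, [0.0] * 5, "C1") for i in range(8)]
        recs = colocalize(a, b)
        s = compare_partner_classes(recs, self._metrics(sizes))
        assert s.mean_size_positive > s.mean_size_negative
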