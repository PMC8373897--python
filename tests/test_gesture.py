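"""Gesture kinematic feature extraction."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from lombardkit import gesture
from lombardkit.synthetic import REST_POSE, generate_gesture_track
from lombardkit.types import BodyTrack

FS = 30.0


def body_with_hand(hand_path, fs=FS, hand="hand_r"):
    n = len(hand_path)
    t = np.arange(n) / fs
    points = {nm: np.tile(p, (n, 1)) for nm, p in REST_POSE.items()}
    points[hand] = np.asarray(hand_path, dtype=float)
    return BodyTrack(t, points)


class TestVelocityProfile:
    def test_stationary_hand_is_zero(self):
        track = body_with_hand(np.tile(REST_POSE["hand_r"], (20, 1)))
        _, p = gesture.velocity_profile(track, "hand_r", (0, 20 / FS))
        np.testing.assert_allclose(p, 0.0, atol=1e-12)

    def test_constant_velocity_linear_motion(self):
        v = 0.5
        n = 31
        path = np.tile(REST_POSE["hand_r"], (n, 1))
        path[:, 2] += v * np.arange(n) / FS
        track = body_with_hand(path)
        _, p = gesture.velocity_profile(track, "hand_r", (0, n / FS))
        np.testing.assert_allclose(p, v, rtol=1e-9)

    def test_unknown_hand_label_raises(self):
        track = body_with_hand(np.tile(REST_POSE["hand_r"], (5, 1)))
        with pytest.raises(KeyError, match="tentacle"):
            gesture.velocity_profile(track, "tentacle", (0, 5 / FS))

    def test_frame_rate_refinement_on_smooth_pulse(self):
        """Doubling the frame rate changes the profile maximum < 5%."""
        maxima = []
        for fs in (30.0, 60.0):
            track, span, _ = generate_gesture_track(1, 0.0, 0.8, 0.4, 1, fs)
            _, p = gesture.velocity_profile(track, "hand_r", span)
            maxima.append(np.nanmax(p))
        assert abs(maxima[1] - maxima[0]) / maxima[0] < 0.05


class TestPeakVelocityAndDistance:
    def test_two_hands_take_the_maximum(self):
        assert gesture.peak_velocity([np.array([0.1, 0.6]), np.array([0.2, 0.9])]) == 0.9

    def test_still_hand_excluded_from_involved_set(self):
        """A hand that never crosses the movement threshold does not carry
        the peak, but a fully still gesture falls back to the plain max."""
        still = np.array([0.01, 0.02])
        moving = np.array([0.1, 0.5])
        assert gesture.peak_velocity([still, moving]) == 0.5
        assert gesture.peak_velocity([still, still / 2]) == 0.02

    def test_pulse_peak_round_trip(self):
        track, span, truth = generate_gesture_track(1, 0.0, 0.8, 0.4, 1, FS)
        _, p = gesture.velocity_profile(track, "hand_r", span)
        assert gesture.peak_velocity([p]) == pytest.approx(0.8, rel=0.05)

    def test_straight_reach_distance(self):
        track, span, truth = generate_gesture_track(1, 0.0, 0.8, 0.4, 1, FS)
        got = gesture.max_distance(track, "hand_r", span)
        assert got == pytest.approx(truth["max_distance_m"], abs=0.01)

    def test_hand_returning_to_start_keeps_mid_gesture_maximum(self):
        n = 61
        path = np.tile(REST_POSE["hand_r"], (n, 1))
        excursion = 0.3 * np.sin(np.pi * np.arange(n) / (n - 1)) ** 2
        path[:, 2] += excursion
        track = body_with_hand(path)
        got = gesture.max_distance(track, "hand_r", (0, n / FS))
        assert got == pytest.approx(0.3, rel=0.01)

    def test_static_hand_distance_zero(self):
        track = body_with_hand(np.tile(REST_POSE["hand_r"], (10, 1)))
        assert gesture.max_distance(track, "hand_r", (0, 10 / FS)) == 0.0


class TestVerticalAmplitude:
    @pytest.mark.parametrize("height,expected", [
        (1.05, 0),   # below torso middle
        (1.28, 1),   # torso middle .. upper quarter
        (1.40, 2),   # within the upper quarter
        (1.53, 3),   # above shoulders, below mid-face
        (1.70, 4),   # above mid-face, below head
        (1.90, 5),   # above the head
    ])
    def test_band_assignment(self, height, expected):
        n = 5
        path = np.tile(REST_POSE["hand_r"], (n, 1))
        path[2, 1] = height
        track = body_with_hand(path)
        assert gesture.vertical_amplitude(track, (0, n / FS)) == expected

    def test_missing_reference_landmark_raises(self):
        n = 5
        t = np.arange(n) / FS
        pts = {"hand_r": np.tile(REST_POSE["hand_r"], (n, 1))}
        with pytest.raises(KeyError, match="spine_base"):
            gesture.vertical_amplitude(BodyTrack(t, pts), (0, n / FS))


class TestHoldtime:
    def test_no_subthreshold_frames_is_zero(self):
        p = np.full(30, 0.5)
        assert gesture.holdtime([p], 1 / FS) == 0.0

    def test_scripted_mid_gesture_plateau(self):
        track, span, truth = generate_gesture_track(3, 0.4, 0.8, 0.4, 2, FS)
        _, p = gesture.velocity_profile(track, "hand_r", span)
        got = gesture.holdtime([p], 1 / FS)
        assert got == pytest.approx(0.4, abs=2 / FS)

    def test_infinite_threshold_limit_is_full_duration(self):
        p = np.abs(np.sin(np.arange(30)))
        got = gesture.holdtime([p], 1 / FS, threshold=np.inf, min_hold=0.0)
        assert got == pytest.approx(30 / FS)

    def test_short_runs_below_min_hold_excluded(self):
        p = np.full(30, 0.5)
        p[10:12] = 0.01  # 2 frames < 0.1 s
        assert gesture.holdtime([p], 1 / FS) == 0.0

    def test_all_hands_must_be_simultaneously_still(self):
        still = np.zeros(30)
        moving = np.full(30, 0.5)
        assert gesture.holdtime([still, moving], 1 / FS) == 0.0


class TestSubmovements:
    def brute_force(self, p, thr, prom):
        """Oracle: scan supra-threshold segments; count interior local maxima
        whose prominence (against the higher neighbouring minimum until a
        higher peak) reaches the criterion; at least one per segment."""
        from scipy.signal import find_peaks

        above = p > thr
        total = 0
        i = 0
        while i < len(p):
            if above[i]:
                j = i
                while j < len(p) and above[j]:
                    j += 1
                peaks, _ = find_peaks(p[i:j], prominence=prom)
                total += max(1, len(peaks))
                i = j
            else:
                i += 1
        return total

    def test_single_pulse_is_one(self):
        track, span, _ = generate_gesture_track(1, 0.0, 0.8, 0.4, 1, FS)
        _, p = gesture.velocity_profile(track, "hand_r", span)
        assert gesture.submovements(p) == 1

    @pytest.mark.parametrize("n_sub", [2, 3, 5])
    def test_constructed_pulse_counts(self, n_sub):
        track, span, _ = generate_gesture_track(n_sub, 0.0, 0.8, 0.45, 1, FS)
        _, p = gesture.velocity_profile(track, "hand_r", span)
        assert gesture.submovements(p) == n_sub

    def test_merged_pulses_with_supra_threshold_saddle_counted_by_prominence(self):
        t = np.arange(0, 1.0, 1 / FS)
        p = 0.6 * np.exp(-((t - 0.3) ** 2) / 0.006) + 0.6 * np.exp(
            -((t - 0.7) ** 2) / 0.006) + 0.2
        assert p.min() > gesture.DEFAULT_HOLD_THRESHOLD  # never drops below
        assert gesture.submovements(p) == 2

    @given(st.lists(st.floats(0, 1.2), min_size=5, max_size=60),
           st.sampled_from([0.05, 0.1, 0.2]))
    def test_oracle_equivalence_on_arbitrary_profiles(self, vals, prom):
        p = np.asarray(vals)
        got = gesture.submovements(p, prominence=prom)
        assert got == self.brute_force(p, gesture.DEFAULT_HOLD_THRESHOLD, prom)

    @given(st.integers(0, 999))
    def test_non_increasing_in_prominence(self, seed):
        r = np.random.default_rng(seed)
        p = np.abs(np.cumsum(r.normal(0, 0.15, 40)))
        c1 = gesture.submovements(p, threshold=0.1, prominence=0.02)
        c2 = gesture.submovements(p, threshold=0.1, prominence=0.2)
        assert c2 <= c1

    @given(st.integers(0, 999))
    def test_non_increasing_in_threshold_for_profiles_rising_from_rest(self, seed):
        """Physical profiles start and end at rest; with every interior peak
        counted, raising the stillness threshold never adds submovements.
        (Profiles whose maxima sit on a segment edge can violate this, which
        is why the guarantee is stated for rest-bounded profiles.)"""
        r = np.random.default_rng(seed)
        core = np.abs(np.cumsum(r.normal(0, 0.15, 40)))
        p = np.concatenate([[0.0], core, [0.0]])
        c1 = gesture.submovements(p, threshold=0.1, prominence=0.0)
        c3 = gesture.submovements(p, threshold=0.3, prominence=0.0)
        assert c3 <= c1


class TestAggregation:
    def g(self, **kw):
        base = dict(peak_velocity=0.5, max_distance=0.3, vertical_amplitude=2,
                    holdtime=0.2, submovements=2, duration_s=1.0)
        base.update(kw)
        return base

    def test_single_gesture_identity(self):
        out = gesture.aggregate_attempt("a", [self.g()])
        assert (out.peak_velocity, out.submovements, out.holdtime) == (0.5, 2, 0.2)

    def test_sums_for_additive_maxima_for_extremal(self):
        out = gesture.aggregate_attempt(
            "a", [self.g(submovements=2, vertical_amplitude=2),
                  self.g(submovements=1, vertical_amplitude=4, holdtime=0.3)])
        assert out.submovements == 3
        assert out.vertical_amplitude == 4
        assert out.holdtime == pytest.approx(0.5)
        assert out.peak_velocity == 0.5

    def test_no_gestures_is_error(self):
        with pytest.raises(ValueError):
            gesture.aggregate_attempt("a", [])


class TestInvariances:
    def test_translation_invariance_of_features(self):
        track, span, _ = generate_gesture_track(3, 0.3, 0.8, 0.4, 2, FS)
        shift = np.array([0.5, 0.0, -0.3])  # horizontal translation
        moved = BodyTrack(track.times,
                          {nm: p + shift for nm, p in track.points.items()})
        f1 = gesture.gesture_unit_features(track, span)
        f2 = gesture.gesture_unit_features(moved, span)
        for key in ("peak_velocity", "max_distance", "holdtime", "submovements",
                    "vertical_amplitude"):
            assert f1[key] == pytest.approx(f2[key], rel=1e-9)

    def test_holdtime_plus_movement_bounded_by_duration(self):
        track, span, _ = generate_gesture_track(4, 0.5, 0.8, 0.45, 2, FS)
        _, p = gesture.velocity_profile(track, "hand_r", span)
        dt = 1 / FS
        hold = gesture.holdtime([p], dt)
        supra = np.sum(p > gesture.DEFAULT_HOLD_THRESHOLD) * dt
        assert hold + supra <= (span[1] - span[0]) + 2 * dt
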