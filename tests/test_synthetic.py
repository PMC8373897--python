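"""The synthetic study generator: determinism, design arithmetic, and the
round trip from rendered signals back through the extractors."""
import math

import numpy as np
import pandas as pd
import pytest

from lombardkit import face, gesture
from lombardkit.acoustics import attempt_acoustics
from lombardkit.annotations import build_rounds, first_attempts
from lombardkit.extract import feature_table
from lombardkit.synthetic import (
    CONDITIONS,
    GeneratorConfig,
    InfeasibleGestureError,
    generate_acoustic_contour,
    generate_dataset,
    generate_gesture_track,
    generate_latent_table,
    generate_lip_track,
    write_session,
)

FS = 30.0


class TestGestureTrackGeneration:
    def test_single_pulse_extracts_one_submovement(self):
        track, span, truth = generate_gesture_track(1, 0.0, 0.8, 0.4, 1, FS)
        feats = gesture.gesture_unit_features(track, span)
        assert feats["submovements"] == 1
        assert feats["holdtime"] == 0.0

    def test_three_pulses_with_planted_hold_round_trip(self):
        track, span, truth = generate_gesture_track(3, 0.4, 0.8, 0.4, 2, FS)
        feats = gesture.gesture_unit_features(track, span)
        assert feats["submovements"] == 3
        assert feats["holdtime"] == pytest.approx(0.4, abs=2 / FS)

    def test_peak_velocity_within_5_percent(self):
        track, span, truth = generate_gesture_track(1, 0.0, 0.8, 0.4, 1, FS)
        feats = gesture.gesture_unit_features(track, span)
        assert feats["peak_velocity"] == pytest.approx(0.8, rel=0.05)

    @pytest.mark.parametrize("bin_", [0, 2, 3, 5])
    def test_amplitude_bin_round_trip(self, bin_):
        track, span, truth = generate_gesture_track(2, 0.0, 0.9, 0.5, bin_, FS)
        feats = gesture.gesture_unit_features(track, span)
        assert feats["vertical_amplitude"] == bin_

    def test_infeasible_parameters_raise(self):
        with pytest.raises(InfeasibleGestureError):
            generate_gesture_track(0, 0.0, 0.8, 0.4, 1, FS)
        with pytest.raises(InfeasibleGestureError):
            generate_gesture_track(1, -0.1, 0.8, 0.4, 1, FS)
        with pytest.raises(InfeasibleGestureError):
            generate_gesture_track(1, 0.0, 0.2, 0.4, 1, FS)  # too slow to segment
        with pytest.raises(InfeasibleGestureError):
            generate_gesture_track(2, 5.0, 0.8, 0.4, 1, FS, max_duration_s=2.0)


class TestLipTrackGeneration:
    def test_closed_mouth_means_no_lip_movement(self):
        track, truth = generate_lip_track(0.0, 0.0, 1.0, FS)
        got = face.mean_lip_movement(track, (0, 1.0))
        assert got == pytest.approx(0.0, abs=1e-9)
        assert truth["mean_lip_movement_mm_s"] == 0.0

    def test_opening_round_trip(self):
        track, truth = generate_lip_track(25.0, 60.0, 1.5, FS, peak_velocity_mm_s=150.0)
        got = face.max_mouth_opening(track, (0, 1.5)) * 1000
        assert got == pytest.approx(25.0, rel=0.04)

    def test_movement_rate_and_peak_round_trip(self):
        track, truth = generate_lip_track(25.0, 60.0, 1.5, FS, peak_velocity_mm_s=150.0)
        rate = face.mean_lip_movement(track, (0, 1.5)) * 1000
        peak = face.peak_lip_velocity(track, (0, 1.5)) * 1000
        assert rate == pytest.approx(truth["mean_lip_movement_mm_s"], rel=0.06)
        assert peak == pytest.approx(truth["peak_lip_velocity_mm_s"], rel=0.05)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_lip_track(20.0, 50.0, -1.0, FS)


class TestAcousticContourGeneration:
    def test_zero_shift_zero_noise_exact_maximum(self):
        c = generate_acoustic_contour(72.0, 0.0, 220.0, [(0.5, 1.5)], 3.0)
        a = attempt_acoustics(c, [(0.5, 1.5)])
        assert a.max_intensity_db == pytest.approx(72.0, abs=1e-9)
        assert a.max_f0_hz == pytest.approx(220.0, abs=1e-9)

    def test_attempt_maximum_over_two_intervals_is_the_larger(self):
        c = generate_acoustic_contour(
            70.0, 0.0, 200.0, [(0.2, 0.8), (1.2, 1.8)], 3.0,
            relative_levels_db=[0.0, 2.5])
        a = attempt_acoustics(c, [(0.2, 0.8), (1.2, 1.8)])
        assert a.max_intensity_db == pytest.approx(72.5)

    def test_noise_sd_controls_spread_of_maxima(self, rng):
        """Monte Carlo: with per-utterance noise SD 1 dB, the sample SD of
        extracted maxima over many draws is 1 +- 0.1."""
        maxima = []
        for _ in range(1000):
            c = generate_acoustic_contour(70.0, 0.0, 200.0, [(0.1, 0.6)], 1.0,
                                          rng=rng, noise_sd_db=1.0)
            maxima.append(attempt_acoustics(c, [(0.1, 0.6)]).max_intensity_db)
        assert np.std(maxima) == pytest.approx(1.0, abs=0.1)

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError):
            generate_acoustic_contour(70, 0, 200, [(0.0, 1.0), (0.5, 1.5)], 2.0)

    def test_f0_defined_only_inside_utterances(self):
        c = generate_acoustic_contour(70.0, 0.0, 220.0, [(0.5, 1.0)], 2.0)
        inside = c.frame_mask((0.5, 1.0))
        assert np.all(~np.isnan(c.f0_hz[inside]))
        assert np.all(np.isnan(c.f0_hz[~inside]))


class TestDatasetGeneration:
    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        cfg = GeneratorConfig(n_participants=2, n_items=3, seed=99)
        s1, t1 = generate_dataset(cfg)
        s2, t2 = generate_dataset(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        p1 = write_session(s1[0], tmp_path / "a")
        p2 = write_session(s2[0], tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_design_arithmetic_58_by_20_gives_1160_rounds(self):
        tab = generate_latent_table(GeneratorConfig(seed=0))
        assert len(tab) == 1160
        assert tab["participant"].nunique() == 58
        assert tab["item"].nunique() == 20

    def test_zero_effects_and_zero_sds_collapse_latent_features(self):
        cfg = GeneratorConfig(
            n_participants=3, n_items=4, seed=1,
            intensity_effect_db=(0, 0, 0), intensity_resid_sd=0.0,
            participant_sd={}, item_sd={}, participant_slope_sd={},
        )
        tab = generate_latent_table(cfg)
        vals = tab["max_intensity_db"].dropna().unique()
        assert vals.size == 1

    def test_modality_proportions_follow_config(self):
        cfg = GeneratorConfig(n_participants=58, n_items=20, seed=4)
        tab = generate_latent_table(cfg)
        for cond in CONDITIONS:
            sub = tab[tab.condition == cond]
            p_mm = (sub.modality == "multimodal").mean()
            target = cfg.modality_probs[cond][2]
            se = math.sqrt(target * (1 - target) / len(sub))
            assert abs(p_mm - target) < 4 * se

    def test_feature_presence_matches_modality(self):
        tab = generate_latent_table(GeneratorConfig(n_participants=6, n_items=5, seed=2))
        speech_rows = tab.modality.isin(["speech_only", "multimodal"])
        gesture_rows = tab.modality.isin(["gesture_only", "multimodal"])
        assert tab.loc[~speech_rows, "max_intensity_db"].isna().all()
        assert tab.loc[speech_rows, "max_intensity_db"].notna().all()
        assert tab.loc[~gesture_rows, "submovements"].isna().all()
        assert (tab.loc[gesture_rows, "submovements"] >= 1).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(conditions=("a", "a", "b"))
        with pytest.raises(ValueError):
            GeneratorConfig(modality_probs={c: (0.5, 0.2, 0.2) for c in CONDITIONS})
        with pytest.raises(ValueError):
            GeneratorConfig(participant_sd={"max_intensity_db": -1.0})


ROUNDTRIP_TOL = {
    "max_intensity_db": dict(abs=1e-6),
    "max_f0_hz": dict(abs=1e-6),
    "max_mouth_opening_mm": dict(abs=0.8),
    "mean_lip_movement_mm_s": dict(abs=6.0),
    "peak_lip_velocity_mm_s": dict(abs=7.0),
    "peak_velocity_m_s": dict(rel=0.07),
    "max_distance_m": dict(abs=0.01),
    "vertical_amplitude": dict(abs=0),
    "holdtime_s": dict(abs=0.22),
    "submovements": dict(abs=0),
}


def test_full_round_trip_extraction_matches_ground_truth(small_dataset):
    """Rendered sessions, re-segmented and re-extracted, reproduce the
    ground-truth table within the generator's documented rendering accuracy."""
    cfg, sessions, truth = small_dataset
    parts = []
    for s in sessions:
        events = [e for evs in s.tiers.values() for e in evs]
        rounds = build_rounds(events, s.round_meta)
        parts.append(feature_table(first_attempts(rounds), s.body_track,
                                   s.face_track, s.contour))
    got = pd.concat(parts, ignore_index=True)
    merged = got.merge(truth, on=["participant", "item"], suffixes=("_x", "_t"))
    assert len(merged) == len(truth)
    assert (merged.modality_x == merged.modality_t).all()
    assert (merged.condition_x == merged.condition_t).all()
    for col, tol in ROUNDTRIP_TOL.items():
        x, t = merged[f"{col}_x"], merged[f"{col}_t"]
        assert (x.isna() == t.isna()).all(), col
        d = (x - t).abs().dropna()
        if "rel" in tol:
            assert (d <= tol["rel"] * t.abs().dropna()).all(), (col, d.max())
        else:
            assert (d <= tol["abs"] + 1e-12).all(), (col, d.max())
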