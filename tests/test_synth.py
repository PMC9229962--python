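"""Synthetic-signal generator: plateau placement, protocol scripts, noise."""

import itertools
from dataclasses import replace

import numpy as np
import pytest

from fuzzymotion import (
    FuzzymotionError,
    MotionScript,
    SignalModel,
    all_motion_sequences,
    build_grid,
    calibration_signal_model,
    canonical_signal_model,
    default_calibration,
    fuzzify,
    infer_step,
    make_sequence_script,
    simulate,
)
from fuzzymotion.vocab import (
    ACTIVE_MOTIONS,
    REST,
    SEGMENT_LABELS,
    ULNAR_DEVIATION,
    WRIST_EXTENSION,
    truth_to_state,
)


class TestCanonicalModel:
    def test_rest_sits_at_the_off_anchor(self, calib):
        model = canonical_signal_model(calib)
        assert model.levels[REST] == (0.0, 0.0)

    def test_ulnar_deviation_sits_at_low_off(self, calib):
        model = canonical_signal_model(calib)
        assert model.levels[ULNAR_DEVIATION] == (0.5, 0.0)

    def test_every_plateau_classifies_to_its_motion(self, table):
        """Noise-free plateau levels land on each motion's dominant rule."""
        from fuzzymotion import CalibrationConstants

        for anchors in [(-1.0, 0.0, 1.0), (-0.4, 0.1, 0.9), (-2.0, -0.5, 3.0)]:
            calib = CalibrationConstants(*anchors)
            grid = build_grid(calib)
            model = canonical_signal_model(calib, noise_sd=0.0)
            for motion, (v1, v2) in model.levels.items():
                _, decision = infer_step(fuzzify(v1, grid), fuzzify(v2, grid), table)
                assert decision == truth_to_state(motion), (anchors, motion)

    def test_default_noise_floor_scales_with_dynamic_range(self, calib):
        assert canonical_signal_model(calib).noise_sd == pytest.approx(0.1)  # 0.1 * (1 - 0)
        wide = canonical_signal_model(type(calib)(-2.0, 0.0, 3.0))
        assert wide.noise_sd == pytest.approx(0.3)
        assert canonical_signal_model(calib, noise_sd=0.05).noise_sd == 0.05


class TestSimulate:
    def test_duration_times_rate_samples(self, calib):
        script = make_sequence_script(ACTIVE_MOTIONS)  # rest 5 + 4 x 5 + rest 5 = 30 s
        rec = simulate(script, canonical_signal_model(calib, noise_sd=0.0))
        assert rec.n_samples == 30_000
        assert rec.duration_s == pytest.approx(30.0)

    def test_degenerate_generator_is_piecewise_constant(self, calib):
        model = canonical_signal_model(calib, noise_sd=0.0, ramp_s=0.0)
        script = make_sequence_script(ACTIVE_MOTIONS, rest_s=0.5, motion_s=0.5)
        rec = simulate(script, model)
        for motion in SEGMENT_LABELS:
            sel = rec.labels == motion
            assert np.all(rec.channel_1[sel] == model.levels[motion][0])
            assert np.all(rec.channel_2[sel] == model.levels[motion][1])

    def test_seeded_runs_are_bit_identical(self, calib):
        model = canonical_signal_model(calib, seed=123)
        script = make_sequence_script(ACTIVE_MOTIONS, rest_s=0.5, motion_s=0.5)
        a, b = simulate(script, model), simulate(script, model)
        np.testing.assert_array_equal(a.channel_1, b.channel_1)
        np.testing.assert_array_equal(a.channel_2, b.channel_2)
        c = simulate(script, replace(model, seed=124))
        assert not np.array_equal(a.channel_1, c.channel_1)

    def test_ramp_interpolates_between_plateaus(self, calib):
        model = canonical_signal_model(calib, noise_sd=0.0, ramp_s=0.2)
        script = MotionScript(((REST, 1.0), (WRIST_EXTENSION, 1.0)))
        rec = simulate(script, model)
        we_level = model.levels[WRIST_EXTENSION][0]
        # halfway through the 200-sample ramp the signal is near the midpoint
        assert rec.channel_1[1100] == pytest.approx(we_level / 2, abs=abs(we_level) * 0.02)
        assert rec.channel_1[1199] == pytest.approx(we_level)
        # ramp samples carry the incoming segment's label
        assert rec.labels[1000] == WRIST_EXTENSION

    def test_segment_means_recover_plateau_levels_under_noise(self, calib):
        """With sd = 0.1*(x_p - x_o) and 5 s segments, each segment's sample
        mean is within 3*sd/sqrt(n) of its plateau level."""
        model = canonical_signal_model(calib, seed=5, ramp_s=0.0)  # default noise floor
        script = make_sequence_script(ACTIVE_MOTIONS)
        rec = simulate(script, model)
        for motion in SEGMENT_LABELS:
            sel = rec.labels == motion
            n = int(sel.sum())
            tol = 3 * model.noise_sd / np.sqrt(n)
            assert rec.channel_1[sel].mean() == pytest.approx(model.levels[motion][0], abs=tol)
            assert rec.channel_2[sel].mean() == pytest.approx(model.levels[motion][1], abs=tol)

    def test_stress_only_degrades_ud_after_we(self, calib):
        model = canonical_signal_model(calib, noise_sd=0.0, ramp_s=0.0, we_ud_stress=0.9)
        after_we = simulate(MotionScript(((WRIST_EXTENSION, 0.1), (ULNAR_DEVIATION, 0.1))), model)
        after_rest = simulate(MotionScript(((REST, 0.1), (ULNAR_DEVIATION, 0.1))), model)
        ud_level = model.levels[ULNAR_DEVIATION][0]
        assert after_rest.channel_1[-1] == ud_level
        assert after_we.channel_1[-1] == pytest.approx(0.1 * ud_level)  # pulled toward rest
        assert after_we.channel_2[-1] == model.levels[ULNAR_DEVIATION][1]  # channel 2 untouched

    def test_invalid_model_parameters_rejected(self, calib):
        with pytest.raises(FuzzymotionError):
            canonical_signal_model(calib, noise_sd=-0.1)
        with pytest.raises(FuzzymotionError):
            canonical_signal_model(calib, we_ud_stress=1.0)
        with pytest.raises(FuzzymotionError):
            SignalModel(levels={REST: (0.0, 0.0)})  # missing motions


class TestCalibrationModel:
    def test_plateaus_sit_at_the_anchors(self, calib):
        model = calibration_signal_model(calib)
        assert model.levels[WRIST_EXTENSION] == (calib.x_n, calib.x_n)
        assert model.levels[REST] == (calib.x_o, calib.x_o)
        assert model.levels[ULNAR_DEVIATION] == (calib.x_p, calib.x_p)
        assert model.ramp_s == 0.0


class TestSequenceScripts:
    def test_twenty_four_distinct_orderings_cover_all_permutations(self):
        scripts = all_motion_sequences()
        assert len(scripts) == 24
        orderings = {tuple(m for m, _ in s.segments if m != REST) for s in scripts}
        assert orderings == set(itertools.permutations(ACTIVE_MOTIONS))

    def test_protocol_structure(self):
        for script in all_motion_sequences():
            assert len(script.segments) == 6
            assert script.segments[0] == (REST, 5.0)
            assert script.segments[-1] == (REST, 5.0)
            assert script.duration_s == pytest.approx(30.0)

    def test_scripts_are_named_in_enumeration_order(self):
        scripts = all_motion_sequences()
        assert scripts[0].name == "seq_01"
        assert [m for m, _ in scripts[0].segments][1:5] == list(ACTIVE_MOTIONS)
        assert scripts[-1].name == "seq_24"

    def test_script_validation(self):
        with pytest.raises(FuzzymotionError):
            MotionScript(())
        with pytest.raises(FuzzymotionError):
            MotionScript(((REST, -1.0),))
        with pytest.raises(FuzzymotionError):
            MotionScript((("handstand", 1.0),))
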