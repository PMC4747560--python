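"""Distance features, trial statistics and normalization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from facemark.features import (
    FEATURE_NAMES,
    DistanceFeatures,
    FeatureError,
    NormalizationSpec,
    baseline_from,
    cmd_series,
    fit_apply_normalization,
    md_series,
    read_trials,
    trial_statistics,
    trials_to_frame,
    write_trials,
)
from facemark.geometry import MARKER_IDS
from facemark.lktrack import CENTER_ID, TrackState
from facemark.synthface import default_emotion_fields, simulate_trajectory_collection


def make_state(frame, positions, center=(0.0, 0.0)):
    pos = dict(positions)
    pos[CENTER_ID] = center
    return TrackState(frame, pos)


def uniform_state(frame, xy, center=(0.0, 0.0)):
    return make_state(frame, {mid: xy for mid in MARKER_IDS}, center)


class TestMdSeries:
    def test_all_markers_at_center_gives_zero_vector(self):
        st0 = uniform_state(0, (5.0, 5.0), center=(5.0, 5.0))
        (df,) = md_series([st0])
        assert df.values == pytest.approx(np.zeros(9))

    def test_pythagorean_distance_and_mouth_width(self):
        pos = {mid: (0.0, 0.0) for mid in MARKER_IDS}
        pos["p_m1"] = (3.0, 4.0)
        (df,) = md_series([make_state(0, pos)])
        assert df.values[FEATURE_NAMES.index("m1")] == pytest.approx(5.0)
        # m5 = distance between the mouth corners
        pos["p_m1"], pos["p_m2"] = (-10.0, 0.0), (10.0, 0.0)
        (df,) = md_series([make_state(0, pos)])
        assert df.values[FEATURE_NAMES.index("m5")] == pytest.approx(20.0)

    def test_missing_marker_is_structural_error(self):
        pos = {mid: (1.0, 1.0) for mid in MARKER_IDS if mid != "p_e2"}
        with pytest.raises(FeatureError, match="p_e2"):
            md_series([make_state(0, pos)])

    def test_explicit_centers_override_tracked_center(self):
        st0 = uniform_state(0, (3.0, 4.0), center=(99.0, 99.0))
        (df,) = md_series([st0], centers=[(0.0, 0.0)])
        assert df.values[0] == pytest.approx(5.0)

    @given(tx=st.floats(-50, 50), ty=st.floats(-50, 50))
    def test_translation_invariance(self, tx, ty):
        pos = {mid: (i * 3.0, i * 2.0) for i, mid in enumerate(MARKER_IDS)}
        base = md_series([make_state(0, pos, center=(1.0, 2.0))])
        moved = {mid: (x + tx, y + ty) for mid, (x, y) in pos.items()}
        shifted = md_series([make_state(0, moved, center=(1.0 + tx, 2.0 + ty))])
        assert shifted[0].values == pytest.approx(base[0].values, abs=1e-9)


class TestCmdSeries:
    def test_identical_frames_give_zero_series(self):
        states = [uniform_state(i, (10.0, 0.0)) for i in range(4)]
        for df in cmd_series(states):
            assert df.values == pytest.approx(np.zeros(9))

    def test_signed_difference_contract(self):
        s0 = uniform_state(0, (50.0, 0.0))
        s1 = uniform_state(1, (47.0, 0.0))
        series = cmd_series([s0, s1])
        assert series[1].values[:8] == pytest.approx(np.full(8, -3.0))

    def test_absolute_mode(self):
        s0 = uniform_state(0, (50.0, 0.0))
        s1 = uniform_state(1, (47.0, 0.0))
        series = cmd_series([s0, s1], absolute=True)
        assert series[1].values[:8] == pytest.approx(np.full(8, 3.0))

    def test_baseline_constant_offset_invariance(self):
        """Adding a constant to every frame's distances leaves CMD
        unchanged."""
        states = [uniform_state(i, (10.0 + i, 0.0)) for i in range(3)]
        base = [df.values for df in cmd_series(states)]
        md = md_series(states)
        shifted = [DistanceFeatures(d.frame_index, d.values + 7.0) for d in md]
        bl = baseline_from(shifted)
        again = [s.values - bl.values for s in shifted]
        for got, ref in zip(again, base):
            assert got == pytest.approx(ref)

    def test_surprise_template_signs_at_apex(self):
        """The brow-raise/jaw-drop template moves eyebrow markers and the
        lower-mouth marker away from the centre."""
        recs = simulate_trajectory_collection(
            default_emotion_fields(), n_subjects=1, trials_per_emotion=1,
            sigma_marker=0.0, sigma_scale=0.0, n_frames=11, seed=0,
        )
        rec = next(r for r in recs if r.label == "surprise")
        apex = cmd_series(rec.states)[-1].values
        for feat in ("e1", "e2", "e3", "e4", "m4"):
            assert apex[FEATURE_NAMES.index(feat)] > 0, feat


class TestTrialStatistics:
    def _series(self, per_frame_values):
        return [DistanceFeatures(i, np.full(9, v))
                for i, v in enumerate(per_frame_values)]

    def test_constant_series(self):
        series = self._series([5.0, 5.0, 5.0])
        assert trial_statistics(series, "mean").values == pytest.approx(np.full(9, 5.0))
        assert trial_statistics(series, "rms").values == pytest.approx(np.full(9, 5.0))
        assert trial_statistics(series, "variance").values == pytest.approx(np.zeros(9))

    def test_rms_of_3_4(self):
        got = trial_statistics(self._series([3.0, 4.0]), "rms").values
        assert got == pytest.approx(np.full(9, np.sqrt(12.5)))

    def test_signed_series_mean_rms_variance(self):
        series = self._series([1.0, -1.0])
        assert trial_statistics(series, "mean").values == pytest.approx(np.zeros(9))
        assert trial_statistics(series, "rms").values == pytest.approx(np.ones(9))
        assert trial_statistics(series, "variance").values == pytest.approx(
            np.full(9, 2.0))

    def test_variance_needs_two_frames(self):
        with pytest.raises(FeatureError, match="variance"):
            trial_statistics(self._series([1.0]), "variance")

    @given(vals=st.lists(st.floats(-20, 20), min_size=2, max_size=12))
    def test_rms_identities(self, vals):
        series = self._series(vals)
        rms = trial_statistics(series, "rms").values
        mean = trial_statistics(series, "mean").values
        assert rms[0] ** 2 == pytest.approx(np.mean(np.square(vals)), abs=1e-9)
        assert (rms >= np.abs(mean) - 1e-9).all()


class TestNormalization:
    def test_binary_and_bipolar_midpoint(self):
        train = np.array([[2.0], [6.0]])
        x = np.array([[4.0]])
        tr_b, te_b, _ = fit_apply_normalization(train, x, "binary")
        assert te_b[0, 0] == pytest.approx(0.5)
        _, te_p, _ = fit_apply_normalization(train, x, "bipolar")
        assert te_p[0, 0] == pytest.approx(0.0)

    def test_training_min_maps_to_lower_bound(self):
        train = np.array([[2.0], [6.0]])
        _, te_b, _ = fit_apply_normalization(train, np.array([[2.0]]), "binary")
        assert te_b[0, 0] == 0.0
        _, te_p, _ = fit_apply_normalization(train, np.array([[2.0]]), "bipolar")
        assert te_p[0, 0] == -1.0

    def test_constant_dimension_maps_to_zero(self):
        train = np.array([[3.0, 1.0], [3.0, 2.0]])
        tr, te, _ = fit_apply_normalization(train, train, "bipolar")
        assert np.all(tr[:, 0] == 0.0)

    def test_statistics_come_from_training_only(self):
        train = np.array([[0.0], [1.0]])
        test = np.array([[2.0]])
        _, te, _ = fit_apply_normalization(train, test, "binary")
        assert te[0, 0] == pytest.approx(2.0)  # outside [0,1]: no leakage

    def test_idempotent_on_training_range(self):
        rng = np.random.default_rng(0)
        train = rng.uniform(-5, 5, size=(20, 9))
        tr1, _, _ = fit_apply_normalization(train, train, "binary")
        tr2, _, _ = fit_apply_normalization(tr1, tr1, "binary")
        assert tr2 == pytest.approx(tr1)

    def test_unfit_spec_rejected(self):
        with pytest.raises(FeatureError):
            NormalizationSpec("binary").apply(np.zeros((2, 9)))


def test_trial_table_round_trip(tmp_path):
    series = [DistanceFeatures(i, np.arange(9.0) + i) for i in range(3)]
    tf = trial_statistics(series, "mean", mode="MD", label="anger",
                          subject_id="S01", trial_id="t1")
    path = tmp_path / "trials.csv"
    write_trials(path, [tf])
    (back,) = read_trials(path)
    assert back.values == pytest.approx(tf.values)
    assert (back.label, back.subject_id, back.statistic) == ("anger", "S01", "mean")
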