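"""Frame censoring, FD/DVARS, band-pass and residualization checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biotypeflow import motion


def _trace_from(dx=None, alpha=None, n=20):
    z = np.zeros(n)
    return motion.MotionTrace(
        dx=z if dx is None else dx, dy=z, dz=z,
        alpha=z if alpha is None else alpha, beta=z, gamma=z,
    )


class TestFramewiseDisplacement:
    def test_constant_trace_is_zero(self, flat_trace):
        assert np.all(motion.framewise_displacement(flat_trace) == 0)

    def test_single_translation_step(self):
        dx = np.zeros(20)
        dx[5:] += 0.1
        fd = motion.framewise_displacement(_trace_from(dx=dx))
        assert fd[5] == pytest.approx(0.1, abs=1e-15)
        assert np.all(np.delete(fd, 5) == 0)

    def test_rotation_converted_to_arc_length(self):
        # 0.004 rad step on a 50 mm sphere is a 0.2 mm displacement
        alpha = np.zeros(20)
        alpha[5:] += 0.004
        fd = motion.framewise_displacement(_trace_from(alpha=alpha))
        assert fd[5] == pytest.approx(0.2, abs=1e-12)

    def test_literal_mode_sums_raw_angles(self):
        alpha = np.zeros(20)
        alpha[5:] += 0.004
        fd = motion.framewise_displacement(_trace_from(alpha=alpha), rotation_radius_mm=None)
        assert fd[5] == pytest.approx(0.004, abs=1e-15)

    def test_scale_covariance(self, rng):
        mat = rng.standard_normal((30, 6)) * 0.01
        t1 = motion.MotionTrace(*(mat[:, j] for j in range(6)))
        t3 = motion.MotionTrace(*(3 * mat[:, j] for j in range(6)))
        np.testing.assert_allclose(
            motion.framewise_displacement(t3),
            3 * motion.framewise_displacement(t1),
            atol=1e-12,
        )

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            motion.MotionTrace(*(np.zeros(1),) * 6)


class TestDvars:
    def test_constant_panel_is_zero(self):
        panel = motion.TimeSeriesPanel(np.ones((10, 4)))
        assert np.all(motion.dvars(panel) == 0)

    def test_two_unit_hand_value(self):
        panel = motion.TimeSeriesPanel(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert motion.dvars(panel)[1] == pytest.approx(np.sqrt((9 + 16) / 2), abs=1e-12)

    def test_single_unit_reduces_to_abs_diff(self):
        panel = motion.TimeSeriesPanel(np.array([[1.0], [6.0]]))
        assert motion.dvars(panel)[1] == pytest.approx(5.0, abs=1e-15)

    def test_scale_covariance(self, rng):
        data = rng.standard_normal((25, 6))
        d1 = motion.dvars(motion.TimeSeriesPanel(data))
        d2 = motion.dvars(motion.TimeSeriesPanel(2.5 * data))
        np.testing.assert_allclose(d2, 2.5 * d1, atol=1e-12)


class TestCensorFrames:
    def test_no_crossings_keeps_everything(self):
        mask = motion.censor_frames(np.zeros(100), np.zeros(100))
        assert mask.n_kept == 100 and mask.n_censored == 0

    def test_single_outlier_neighbourhood(self):
        # outlier at 10 censors 9-12; runs of 9 and 7 frames survive
        fd = np.zeros(20)
        fd[10] = 0.5
        mask = motion.censor_frames(fd, np.zeros(20))
        assert mask.n_kept == 16
        assert not mask.kept[9:13].any()
        assert mask.kept[:9].all() and mask.kept[13:].all()

    def test_short_segment_rule_can_censor_all(self):
        # outliers at 4 and 10 leave runs of 3, 2 and 1 frames: all short
        fd = np.zeros(14)
        fd[[4, 10]] = 0.5
        mask = motion.censor_frames(fd, np.zeros(14))
        assert mask.n_kept == 0

    def test_dvars_rule_triggers_too(self):
        dv = np.zeros(30)
        dv[15] = 100.0
        mask = motion.censor_frames(np.zeros(30), dv)
        assert not mask.kept[14:18].any()

    def test_mask_is_fixed_point_of_the_rules(self, rng):
        fd = rng.uniform(0, 0.4, size=60)
        mask = motion.censor_frames(fd, np.zeros(60))
        kept_idx = np.flatnonzero(mask.kept)
        # rule 1+2: no kept frame lies in any outlier's [t-1, t+2] window
        for t in np.flatnonzero(fd > 0.2):
            assert not np.any((kept_idx >= t - 1) & (kept_idx <= t + 2))
        # rule 3: every kept run has at least 5 contiguous frames
        if len(kept_idx):
            runs = np.split(kept_idx, np.flatnonzero(np.diff(kept_idx) > 1) + 1)
            assert min(len(r) for r in runs) >= 5

    def test_padding_invariance(self, rng):
        fd = rng.uniform(0, 0.35, size=40)
        base = motion.censor_frames(fd, np.zeros(40))
        padded = motion.censor_frames(
            np.concatenate([fd, np.zeros(10)]), np.zeros(50)
        )
        assert np.array_equal(padded.kept[:40], base.kept)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            motion.censor_frames(np.zeros(5), np.zeros(6))


class TestBandpass:
    @pytest.mark.parametrize(
        "freq,bound,kind",
        [(0.04, 0.9, "pass"), (0.2, 0.2, "stop")],
    )
    def test_frequency_response(self, freq, bound, kind):
        t = np.arange(1200) * 0.72
        x = np.sin(2 * np.pi * freq * t)
        out = motion.bandpass(motion.TimeSeriesPanel(x[:, None], tr=0.72)).data[:, 0]
        # compare amplitudes away from filtfilt edge transients
        ratio = np.abs(out[200:-200]).max() / np.abs(x[200:-200]).max()
        if kind == "pass":
            assert ratio >= bound
        else:
            assert ratio <= bound

    def test_dc_removed(self):
        panel = motion.TimeSeriesPanel(np.full((500, 3), 7.0), tr=0.72)
        out = motion.bandpass(panel).data
        assert np.abs(out).max() < 1e-6 * 7.0

    def test_band_above_nyquist_rejected(self):
        panel = motion.TimeSeriesPanel(np.zeros((100, 2)) + 1.0, tr=10.0)
        with pytest.raises(ValueError):
            motion.bandpass(panel)


class TestFcVector:
    def test_length_identity_268(self):
        assert motion.n_fc_features(268) == 35778

    def test_duplicated_roi_correlates_perfectly(self, rng):
        x = rng.standard_normal(50)
        panel = motion.TimeSeriesPanel(np.column_stack([x, x, rng.standard_normal(50)]))
        fc = motion.fc_vector(panel)
        assert fc[0] == pytest.approx(1.0, abs=1e-12)

    def test_all_kept_matches_full_series_correlation(self, rng):
        data = rng.standard_normal((60, 5))
        panel = motion.TimeSeriesPanel(data)
        mask = motion.CensorMask(kept=np.ones(60, dtype=bool))
        iu, ju = np.triu_indices(5, k=1)
        oracle = np.corrcoef(data, rowvar=False)[iu, ju]
        np.testing.assert_allclose(motion.fc_vector(panel, mask), oracle, atol=1e-12)

    def test_masked_equals_manual_slice(self, rng):
        data = rng.standard_normal((40, 4))
        kept = rng.random(40) > 0.3
        panel = motion.TimeSeriesPanel(data)
        fc = motion.fc_vector(panel, motion.CensorMask(kept=kept))
        iu, ju = np.triu_indices(4, k=1)
        oracle = np.corrcoef(data[kept], rowvar=False)[iu, ju]
        np.testing.assert_allclose(fc, oracle, atol=1e-12)

    def test_too_few_kept_frames_excluded(self):
        panel = motion.TimeSeriesPanel(np.random.default_rng(0).standard_normal((10, 3)))
        kept = np.zeros(10, dtype=bool)
        kept[:2] = True
        with pytest.raises(motion.InsufficientFramesError):
            motion.fc_vector(panel, motion.CensorMask(kept=kept))


class TestResidualModel:
    def test_uncorrelated_covariates_leave_feature_alone(self, rng):
        n = 200
        fc = rng.standard_normal((n, 3))
        cov = np.column_stack([np.arange(n) % 2, np.zeros(n), np.ones(n) * 5])
        cov = rng.permutation(cov)
        model = motion.fit_residual_model(fc, cov)
        adj = model.transform(fc, cov)
        # empirical correlation is small but non-zero; removal is slight
        assert np.abs(adj - fc).max() < 0.5

    def test_pure_covariate_feature_residualizes_to_training_mean(self, rng):
        n = 120
        age = rng.uniform(22, 36, n)
        cov = np.column_stack([age, rng.integers(0, 2, n), rng.poisson(100, n)])
        fc = (2.0 * age)[:, None]
        model = motion.fit_residual_model(fc, cov)
        adj = model.transform(fc, cov)
        np.testing.assert_allclose(adj, np.full_like(adj, fc.mean()), atol=1e-8)

    def test_training_residuals_orthogonal_to_covariates(self, rng):
        n = 150
        cov = rng.standard_normal((n, 3))
        fc = rng.standard_normal((n, 10)) + cov @ rng.standard_normal((3, 10))
        model = motion.fit_residual_model(fc, cov)
        adj = model.transform(fc, cov)
        centred_cov = cov - cov.mean(axis=0)
        dots = centred_cov.T @ (adj - adj.mean(axis=0))
        assert np.abs(dots).max() < 1e-8 * np.abs(fc).max() * n

    def test_apply_is_equivariant_under_subject_permutation(self, rng):
        model = motion.fit_residual_model(
            rng.standard_normal((80, 4)), rng.standard_normal((80, 3))
        )
        fc_val = rng.standard_normal((30, 4))
        cov_val = rng.standard_normal((30, 3))
        perm = rng.permutation(30)
        np.testing.assert_allclose(
            model.transform(fc_val, cov_val)[perm],
            model.transform(fc_val[perm], cov_val[perm]),
            atol=1e-12,
        )

    def test_unfitted_model_rejects_transform(self):
        with pytest.raises(RuntimeError):
            motion.ResidualModel().transform(np.zeros((3, 2)), np.zeros((3, 3)))


@settings(max_examples=30, deadline=None)
@given(
    steps=st.lists(st.integers(min_value=2, max_value=57), min_size=0, max_size=5, unique=True)
)
def test_censoring_covers_every_outlier_neighbourhood(steps):
    """Every outlier and its [t-1, t+2] window is censored; FD spikes only there."""
    n = 60
    fd = np.zeros(n)
    for t in steps:
        fd[t] = 0.5
    mask = motion.censor_frames(fd, np.zeros(n))
    for t in steps:
        assert not mask.kept[max(0, t - 1) : min(n, t + 3)].any()
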