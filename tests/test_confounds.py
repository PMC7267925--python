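import numpy as np
import pytest

from restconn.confounds import (
    ConfoundModel,
    OutlierSeries,
    acompcor,
    assemble_confounds,
    detect_outliers,
    framewise_displacement,
    mean_fd,
    scrub_regressors,
)
from restconn.volumes import BoldRun, MotionTrace


def _motion(params):
    return MotionTrace(params=np.asarray(params, dtype=float))


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        fd = framewise_displacement(_motion(np.zeros((10, 6))))
        np.testing.assert_array_equal(fd, np.zeros(10))

    def test_translation_step(self):
        params = np.zeros((10, 6))
        params[5:, 0] = 0.5
        fd = framewise_displacement(_motion(params))
        assert fd[5] == pytest.approx(0.5)
        assert fd[0] == 0.0
        assert np.count_nonzero(fd) == 1

    def test_rotation_step_projected(self):
        params = np.zeros((10, 6))
        params[3:, 4] = 0.01
        fd = framewise_displacement(_motion(params))
        assert fd[3] == pytest.approx(0.5)  # 50 mm * 0.01 rad

    def test_invariant_to_constant_offset(self, random_motion):
        fd1 = framewise_displacement(random_motion)
        shifted = _motion(random_motion.params + np.array([5, -3, 1, 0.1, -0.2, 0.05]))
        fd2 = framewise_displacement(shifted)
        np.testing.assert_allclose(fd1, fd2, atol=1e-12)

    def test_mean_excludes_first_frame(self):
        params = np.zeros((3, 6))
        params[1:, 0] = 1.0  # single FD of 1.0 at frame 1
        assert mean_fd(_motion(params)) == pytest.approx(0.5)


class TestDetectOutliers:
    def test_percentile_bounds(self, identity_run, random_motion):
        with pytest.raises(ValueError, match="percentile"):
            detect_outliers(identity_run, random_motion, percentile=40)

    def test_clean_data_flag_count(self, rng):
        t = 100
        data = rng.normal(100, 1, (5, 5, 4, t))
        run = BoldRun(data=data, tr_seconds=2.0, affine=np.eye(4))
        steps = np.column_stack([rng.normal(0, 0.02, (t, 3)), rng.normal(0, 4e-4, (t, 3))])
        steps[0] = 0
        out = detect_outliers(run, _motion(np.cumsum(steps, axis=0)))
        # strict 97th percentile of 100 values flags at most 3 per series
        assert out.flags.sum() <= 6

    def test_constant_image_zero_motion_flags_nothing(self):
        run = BoldRun(data=np.full((4, 4, 4, 30), 7.0), tr_seconds=2.0, affine=np.eye(4))
        out = detect_outliers(run, _motion(np.zeros((30, 6))))
        assert out.flags.sum() == 0
        np.testing.assert_array_equal(out.composite_motion, 0)
        np.testing.assert_array_equal(out.global_signal_change, 0)

    def test_absolute_thresholds_override(self, rng):
        t = 50
        data = rng.normal(0, 1, (4, 4, 4, t))
        run = BoldRun(data=data, tr_seconds=2.0, affine=np.eye(4))
        params = np.zeros((t, 6))
        params[20:, 0] = 2.0
        out = detect_outliers(run, _motion(params), motion_threshold_mm=1.0,
                              global_z_threshold=np.inf)
        assert list(out.flagged_indices) == [20]

    def test_synthetic_spikes_flagged(self, small_cohort):
        config, (runs, masks, motions, _, truth) = small_cohort
        for run, motion, spikes in zip(runs, motions, truth.spike_indices):
            out = detect_outliers(run, motion, brain_mask=masks.brain)
            assert set(spikes).issubset(set(out.flagged_indices))

    def test_over_half_flagged_rejected(self):
        flags = np.ones(10, dtype=bool)
        with pytest.raises(ValueError, match="50%"):
            OutlierSeries(flags=flags, composite_motion=np.zeros(10),
                          global_signal_change=np.zeros(10))


class TestScrubRegressors:
    def _series(self, t, flagged):
        flags = np.zeros(t, dtype=bool)
        flags[list(flagged)] = True
        return OutlierSeries(flags=flags, composite_motion=np.zeros(t),
                             global_signal_change=np.zeros(t))

    def test_two_flags(self):
        cols = scrub_regressors(self._series(12, [4, 9]))
        assert cols.shape == (12, 2)
        np.testing.assert_array_equal(cols.sum(axis=0), [1, 1])
        assert cols[4, 0] == 1 and cols[9, 1] == 1

    def test_no_flags(self):
        assert scrub_regressors(self._series(12, [])).shape == (12, 0)

    def test_columns_orthogonal(self):
        cols = scrub_regressors(self._series(20, [1, 5, 17]))
        gram = cols.T @ cols
        np.testing.assert_array_equal(gram, np.eye(3))


class TestACompCor:
    def test_rank_one_structure(self, rng):
        t = 40
        s = np.sin(np.linspace(0, 6 * np.pi, t))
        data = np.zeros((5, 5, 2, t))
        mask = np.zeros((5, 5, 2), dtype=bool)
        mask[:3, :3, 0] = True
        data[mask] = s[None, :] * rng.uniform(0.5, 2.0, (int(mask.sum()), 1))
        data[mask] += rng.normal(0, 1e-4, (int(mask.sum()), t))
        run = BoldRun(data=data + 100, tr_seconds=2.0, affine=np.eye(4))
        comps = acompcor(run, mask, n_components=2)
        from scipy.signal import detrend
        assert abs(np.corrcoef(comps[:, 0], detrend(s))[0, 1]) > 0.999

    def test_components_orthogonal(self, identity_run, identity_masks):
        comps = acompcor(identity_run, identity_masks.wm, n_components=5)
        corr = np.corrcoef(comps.T)
        off_diag = corr[~np.eye(5, dtype=bool)]
        assert np.max(np.abs(off_diag)) < 1e-8

    def test_unit_variance(self, identity_run, identity_masks):
        comps = acompcor(identity_run, identity_masks.wm, n_components=3)
        np.testing.assert_allclose(comps.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_matches_eigendecomposition_oracle(self, rng):
        # 10 voxels x 20 frames: compare against brute-force eigh of the
        # time-covariance of the detrended series
        from scipy.signal import detrend

        t, v = 20, 10
        data = rng.normal(0, 1, (v, 1, 1, t)) + 50
        mask = np.ones((v, 1, 1), dtype=bool)
        run = BoldRun(data=data, tr_seconds=2.0, affine=np.eye(4))
        comps = acompcor(run, mask, n_components=3)

        x = detrend(data.reshape(v, t), axis=1, type="linear")
        evals, evecs = np.linalg.eigh(x.T @ x)
        order = np.argsort(evals)[::-1]
        oracle = evecs[:, order[:3]]
        oracle = oracle / oracle.std(axis=0, ddof=1)
        for j in range(3):
            sign = np.sign(oracle[:, j] @ comps[:, j])
            np.testing.assert_allclose(comps[:, j], sign * oracle[:, j], atol=1e-8)

    def test_small_mask_rejected(self, identity_run):
        mask = np.zeros(identity_run.shape, dtype=bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError, match="voxels"):
            acompcor(identity_run, mask, n_components=5)

    def test_rank_deficient_names_achievable_rank(self):
        t = 30
        data = np.zeros((6, 1, 1, t))
        data[:, 0, 0, :] = np.sin(np.linspace(0, 4 * np.pi, t))  # rank 1
        run = BoldRun(data=data + 1, tr_seconds=2.0, affine=np.eye(4))
        with pytest.raises(ValueError, match="only [12] component"):
            acompcor(run, np.ones((6, 1, 1), dtype=bool), n_components=5)

    def test_invariant_to_spatial_smoothing_elsewhere(self, identity_run, identity_masks):
        # components must come from the unsmoothed input: smoothing a copy
        # used for connectivity leaves them untouched
        from restconn.denoise import smooth_gaussian

        before = acompcor(identity_run, identity_masks.wm, 3)
        _ = smooth_gaussian(identity_run, 6.0, 3.0)
        after = acompcor(identity_run, identity_masks.wm, 3)
        np.testing.assert_array_equal(before, after)


class TestAssembleConfounds:
    @pytest.fixture()
    def outliers(self, identity_run, random_motion, identity_masks):
        return detect_outliers(identity_run, random_motion,
                               brain_mask=identity_masks.brain)

    def _no_outliers(self, t):
        return OutlierSeries(flags=np.zeros(t, dtype=bool),
                             composite_motion=np.zeros(t),
                             global_signal_change=np.zeros(t))

    def test_acompcor_column_census(self, identity_run, random_motion, identity_masks):
        model = assemble_confounds(random_motion, self._no_outliers(40), identity_run,
                                   identity_masks, strategy="acompcor")
        assert model.n_columns == 22
        assert model.column_sources.count("compcor_wm") == 5
        assert model.column_sources.count("compcor_csf") == 5

    def test_gsr_column_census(self, identity_run, random_motion, identity_masks):
        model = assemble_confounds(random_motion, self._no_outliers(40), identity_run,
                                   identity_masks, strategy="gsr")
        assert model.n_columns == 15
        assert model.column_sources[-3:] == ["global_signal", "wm_mean", "csf_mean"]

    def test_outliers_add_columns(self, identity_run, random_motion, identity_masks):
        flags = np.zeros(40, dtype=bool)
        flags[[7, 21]] = True
        outliers = OutlierSeries(flags=flags, composite_motion=np.zeros(40),
                                 global_signal_change=np.zeros(40))
        model = assemble_confounds(random_motion, outliers, identity_run,
                                   identity_masks, strategy="acompcor")
        assert model.n_columns == 24

    def test_derivative_first_frame_zero(self, identity_run, random_motion, identity_masks):
        model = assemble_confounds(random_motion, self._no_outliers(40), identity_run,
                                   identity_masks, strategy="acompcor")
        deriv_cols = [i for i, s in enumerate(model.column_sources)
                      if s == "motion_derivative"]
        np.testing.assert_array_equal(model.matrix[0, deriv_cols], 0.0)

    def test_unknown_strategy(self, identity_run, random_motion, identity_masks):
        with pytest.raises(ValueError, match="strategy"):
            assemble_confounds(random_motion, self._no_outliers(40), identity_run,
                               identity_masks, strategy="ica")

    def test_labels_align(self, identity_run, random_motion, identity_masks):
        model = assemble_confounds(random_motion, self._no_outliers(40), identity_run,
                                   identity_masks, strategy="gsr")
        assert len(model.column_labels) == model.n_columns
        frame = model.to_frame()
        assert list(frame.columns) == model.column_labels


def test_spike_recovery_rate(small_cohort):
    """>= 95% of injected spike frames flagged at default settings."""
    config, (runs, masks, motions, _, truth) = small_cohort
    total, hit = 0, 0
    for run, motion, spikes in zip(runs, motions, truth.spike_indices):
        out = detect_outliers(run, motion, brain_mask=masks.brain)
        flagged = set(out.flagged_indices)
        total += len(spikes)
        hit += sum(1 for s in spikes if s in flagged)
    assert total > 0
    assert hit / total >= 0.95
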