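"""Motion metrics, censoring rules, nuisance regression and filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pnvf import preproc
from pnvf.preproc import (
    BoldRun,
    CensorMask,
    MotionTrace,
    PreprocError,
    apply_retention_rules,
    bandpass,
    bandpass_timecourses,
    censor_frames,
    dvars,
    effective_frames,
    framewise_displacement,
    normalize_global,
    nuisance_regress,
)


def _trace(n=10, trans=None, rot=None):
    t = np.zeros((n, 3)) if trans is None else trans
    r = np.zeros((n, 3)) if rot is None else rot
    return MotionTrace(translations=t, rotations=r)


def _run(data2d, tr=2.0):
    V, T = data2d.shape
    return BoldRun(data=data2d.reshape(V, 1, 1, T), tr=tr)


class TestFramewiseDisplacement:
    def test_zero_trace_gives_zero_fd(self):
        fd = framewise_displacement(_trace(5))
        assert np.array_equal(fd, np.zeros(5))

    def test_translation_step_sums_absolute_differences(self):
        trans = np.zeros((3, 3))
        trans[1] = [0.1, 0.1, 0.1]
        fd = framewise_displacement(_trace(3, trans=trans))
        assert fd[0] == 0.0
        assert np.isclose(fd[1], 0.3)
        assert np.isclose(fd[2], 0.3)  # returning to zero is also motion

    def test_rotation_converted_to_arc_length(self):
        rot = np.zeros((2, 3))
        rot[1, 0] = 0.002
        fd = framewise_displacement(_trace(2, rot=rot), head_radius_mm=50.0)
        assert np.isclose(fd[1], 0.1)

    def test_single_frame_rejected(self):
        with pytest.raises(PreprocError):
            framewise_displacement(_trace(1))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 5000))
    def test_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        trans = rng.normal(0, 0.1, (6, 3))
        rot = rng.normal(0, 0.002, (6, 3))
        fd = framewise_displacement(_trace(6, trans, rot), head_radius_mm=50.0)
        for t in range(1, 6):
            expect = (np.abs(trans[t] - trans[t - 1]).sum()
                      + 50.0 * np.abs(rot[t] - rot[t - 1]).sum())
            assert np.isclose(fd[t], expect)


class TestDvars:
    def test_identical_frames_give_zero(self):
        run = _run(np.ones((4, 3)) * 1000)
        assert np.array_equal(dvars(run, np.ones((4, 1, 1), bool)), np.zeros(3))

    def test_uniform_difference_equals_its_magnitude(self):
        data = np.ones((5, 2)) * 1000
        data[:, 1] += 10.0
        run = _run(data)
        dv = dvars(run, np.ones((5, 1, 1), bool))
        assert np.isclose(dv[1], 10.0)

    def test_monotone_in_disturbance(self):
        out = []
        for step in (5.0, 10.0, 20.0):
            data = np.ones((5, 2)) * 1000
            data[:, 1] += step
            out.append(dvars(_run(data), np.ones((5, 1, 1), bool))[1])
        assert out[0] < out[1] < out[2]

    def test_empty_mask_rejected(self):
        with pytest.raises(PreprocError):
            dvars(_run(np.ones((2, 2))), np.zeros((2, 1, 1), bool))


class TestNormalize:
    def test_mean_500_doubles(self):
        run = _run(np.full((3, 4), 500.0))
        out = normalize_global(run, 1000.0)
        assert np.allclose(out.data, 1000.0)
        assert out.norm_target == 1000.0

    def test_already_normalized_unchanged(self):
        run = _run(np.full((3, 4), 1000.0))
        assert np.allclose(normalize_global(run, 1000.0).data, run.data)

    def test_grand_mean_exact_for_random_input(self, rng):
        run = _run(rng.uniform(100, 900, (20, 10)))
        out = normalize_global(run, 1000.0)
        assert abs(out.data.mean() - 1000.0) < 1e-9

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(PreprocError):
            normalize_global(_run(np.zeros((2, 2))), 1000.0)


class TestCensoring:
    def test_fd_above_threshold_drops_frame(self):
        mask = censor_frames(np.array([0.0, 0.25]), np.array([10.0, 10.0]))
        assert mask.keep.tolist() == [True, False]

    def test_boundary_values_kept(self):
        # strict inequality: FD = 0.2 and DVARS = 25 exactly are retained
        mask = censor_frames(np.array([0.2]), np.array([25.0]))
        assert mask.keep.tolist() == [True]

    def test_clean_frames_all_kept(self):
        mask = censor_frames(np.zeros(10), np.zeros(10))
        assert mask.n_retained == 10

    def test_either_criterion_suffices(self):
        mask = censor_frames(np.array([0.0, 0.0]), np.array([26.0, 24.0]))
        assert mask.keep.tolist() == [False, True]

    def test_length_mismatch_rejected(self):
        with pytest.raises(PreprocError):
            censor_frames(np.zeros(3), np.zeros(4))

    def test_censoring_idempotent(self):
        fd = np.array([0.0, 0.3, 0.1])
        dv = np.array([0.0, 1.0, 30.0])
        m1 = censor_frames(fd, dv)
        m2 = censor_frames(fd[m1.keep], dv[m1.keep])
        assert m2.keep.all()


class TestRetentionRules:
    def _mask(self, retained, total=150):
        keep = np.zeros(total, bool)
        keep[:retained] = True
        return CensorMask(keep=keep)

    def test_run_with_49_frames_discarded(self):
        rep = apply_retention_rules([self._mask(49), self._mask(120)])
        assert rep.run_valid == [False, True]

    def test_subject_at_149_total_excluded(self):
        rep = apply_retention_rules([self._mask(80), self._mask(69)])
        assert rep.run_valid == [True, True]
        assert rep.total_retained == 149
        assert not rep.subject_valid

    def test_subject_at_150_total_retained(self):
        rep = apply_retention_rules([self._mask(75), self._mask(75)])
        assert rep.subject_valid

    def test_discarded_run_frames_do_not_count(self):
        rep = apply_retention_rules([self._mask(49), self._mask(149)])
        assert not rep.subject_valid


class TestNuisanceRegression:
    def test_motion_timecourse_fully_removed(self, rng):
        T = 60
        trace = _trace(T, trans=rng.normal(0, 0.1, (T, 3)),
                       rot=rng.normal(0, 0.001, (T, 3)))
        data = np.tile(trace.translations[:, 0], (4, 1)) * 7.0 + 100.0
        out = nuisance_regress(_run(data), trace)
        assert np.abs(out.data).max() < 1e-8

    def test_linear_drift_removed(self):
        T = 40
        gen = np.random.default_rng(0)
        data = np.tile(np.linspace(0, 5, T), (3, 1))
        trace = _trace(T, trans=gen.normal(0, 0.05, (T, 3)),
                       rot=gen.normal(0, 0.001, (T, 3)))
        out = nuisance_regress(_run(data), trace)
        assert np.abs(out.data).max() < 1e-8

    def test_orthogonal_signal_preserved(self, rng):
        T = 80
        trace = _trace(T, trans=rng.normal(0, 0.05, (T, 3)),
                       rot=rng.normal(0, 0.001, (T, 3)))
        X, _ = preproc.nuisance_design(trace, drift_order=2)
        q, _ = np.linalg.qr(np.column_stack([X, rng.normal(size=(T, 3))]))
        signal = q[:, -1]  # orthogonal to all nuisance columns by QR
        data = np.tile(signal, (2, 1))
        out = nuisance_regress(_run(data), trace)
        assert np.abs(out.data[..., :] - data.reshape(2, 1, 1, T)).max() < 1e-8

    def test_residuals_orthogonal_to_design_on_retained_frames(self, rng):
        T = 50
        trace = _trace(T, trans=rng.normal(0, 0.05, (T, 3)),
                       rot=rng.normal(0, 0.001, (T, 3)))
        keep = np.ones(T, bool)
        keep[5:9] = False
        run = _run(rng.normal(1000, 10, (6, T)))
        out = nuisance_regress(run, trace, CensorMask(keep=keep))
        X, _ = preproc.nuisance_design(trace, 2)
        resid = out.data.reshape(6, T)[:, keep]
        proj = np.abs(X[keep].T @ resid.T)
        assert proj.max() < 1e-8 * np.linalg.norm(resid)

    def test_collinear_design_names_columns(self):
        T = 30
        trans = np.zeros((T, 3))
        trans[:, 0] = np.linspace(0, 1, T)  # collinear with drift
        trace = _trace(T, trans=trans)
        with pytest.raises(PreprocError, match="collinear"):
            nuisance_regress(_run(np.ones((2, T))), trace)


def _rand_trace(T):
    return np.random.default_rng(0).normal(0, 0.05, (T, 3))


class TestBandpass:
    def _sinusoid(self, f, T=150, tr=2.0):
        t = np.arange(T) * tr
        return np.sin(2 * np.pi * f * t)

    def test_inband_sinusoid_retained(self):
        sig = self._sinusoid(0.04)
        out = bandpass_timecourses(sig[None], 2.0, 0.009, 0.08)[0]
        ratio = out.std() / sig.std()
        assert ratio >= 0.9

    def test_out_of_band_sinusoid_suppressed(self):
        sig = self._sinusoid(0.15)
        out = bandpass_timecourses(sig[None], 2.0, 0.009, 0.08)[0]
        assert out.std() / sig.std() <= 0.1

    def test_constant_signal_removed(self):
        out = bandpass_timecourses(np.full((1, 100), 7.0), 2.0, 0.009, 0.08)
        assert np.abs(out).max() < 1e-10

    def test_invalid_band_rejected(self):
        with pytest.raises(PreprocError):
            bandpass_timecourses(np.zeros((1, 50)), 2.0, 0.08, 0.009)
        with pytest.raises(PreprocError):
            bandpass_timecourses(np.zeros((1, 50)), 2.0, 0.01, 0.3)

    def test_censored_frames_interpolated_and_redropped(self):
        T = 150
        sig = self._sinusoid(0.04, T)
        keep = np.ones(T, bool)
        keep[60:64] = False
        corrupted = sig.copy()
        corrupted[60:64] = 50.0  # censored junk must not leak through
        run = BoldRun(data=corrupted.reshape(1, 1, 1, T), tr=2.0)
        out = bandpass(run, 0.009, 0.08, CensorMask(keep=keep))
        assert np.array_equal(out.keep, keep)
        clean = bandpass_timecourses(sig[None], 2.0, 0.009, 0.08)[0]
        # retained frames stay close to the uncorrupted filter output
        # (interpolation over a 4-frame gap leaves a small local residual,
        # nothing like the amplitude-50 junk that was censored)
        err = np.abs(out.data.ravel()[keep] - clean[keep]).max()
        assert err < 0.15
        assert np.abs(out.data).max() < 2.0  # the amplitude-50 junk is gone

    def test_regression_then_filter_near_identity_for_clean_inband_signal(self, rng):
        """A nuisance-free in-band signal — one carrying no component of
        the nuisance subspace — passes regression + band-pass almost
        unchanged.  (Any OLS fit removes the signal's projection onto the
        design, so 'nuisance-free' is the orthogonal-complement sense.)"""
        T = 150
        raw = bandpass_timecourses(rng.normal(0, 1.0, (3, T)), 2.0, 0.018, 0.08)
        trace = _trace(T, trans=np.cumsum(rng.normal(0, 0.01, (T, 3)), axis=0),
                       rot=np.cumsum(rng.normal(0, 1e-4, (T, 3)), axis=0))
        X, _ = preproc.nuisance_design(trace, drift_order=2)
        Q, _ = np.linalg.qr(X)
        sig = raw - (raw @ Q) @ Q.T  # strip any nuisance content
        out = bandpass(nuisance_regress(_run(sig), trace), 0.009, 0.08)
        expected = bandpass_timecourses(sig, 2.0, 0.009, 0.08)
        resid = out.data.reshape(3, T) - expected
        rel = np.linalg.norm(resid) / np.linalg.norm(expected)
        assert rel < 0.05


class TestEffectiveFrames:
    def test_counts_retained_spectral_bins(self):
        # 150 frames at TR=2 s: bins every 1/300 Hz; band 0.02-0.04 Hz
        # keeps bins 6..12 -> 7 bins on each spectral side
        n_eff = effective_frames(150, 2.0, 0.02, 0.04)
        assert np.isclose(n_eff, 14.0)

    def test_wider_band_gives_more_effective_frames(self):
        narrow = effective_frames(150, 2.0, 0.02, 0.04)
        wide = effective_frames(150, 2.0, 0.009, 0.08)
        assert wide > narrow
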