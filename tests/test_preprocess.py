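"""Temporal preprocessing: discard, detrend, band filters, nuisance
regression, FD/DVARS and the censoring policy."""

import logging

import numpy as np
import pytest

import dmnfc
from dmnfc.bands import CANONICAL_BANDS, LFO, SLOW2, SLOW3, SLOW4, SLOW5, BandSpec
from dmnfc.preprocess import (
    PreprocessedSession,
    SubjectSession,
    qc_evaluate,
)

TR = 2.0


def make_session(data, motion=None, subject_id="sub-t", group="NC"):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    T = data.shape[1]
    if motion is None:
        motion = np.zeros((T, 6))
    return SubjectSession(
        subject_id=subject_id,
        group=group,
        data=data,
        tr_seconds=TR,
        motion=motion,
        wm_signal=np.zeros(T),
        csf_signal=np.zeros(T),
    )


def sine(freq, T=500, tr=TR, phase=0.0):
    t = np.arange(T) * tr
    return np.sin(2 * np.pi * freq * t + phase)


def projected_amplitude(x, freq, tr=TR):
    t = np.arange(x.size) * tr
    c = np.cos(2 * np.pi * freq * t)
    s = np.sin(2 * np.pi * freq * t)
    return np.hypot(2 * np.mean(x * c), 2 * np.mean(x * s))


class TestBandSpec:
    def test_canonical_intervals(self):
        assert (SLOW5.low_hz, SLOW5.high_hz) == (0.01, 0.027)
        assert (SLOW4.low_hz, SLOW4.high_hz) == (0.027, 0.073)
        assert (SLOW3.low_hz, SLOW3.high_hz) == (0.073, 0.198)
        assert (SLOW2.low_hz, SLOW2.high_hz) == (0.198, 0.25)
        assert (LFO.low_hz, LFO.high_hz) == (0.01, 0.08)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            BandSpec("bad", 0.05, 0.01)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            BandSpec("toohigh", 0.1, 0.3).validate_for_tr(2.0)


class TestDiscard:
    @pytest.mark.parametrize("T,n_discard,expected", [(200, 4, 196), (10, 4, 6)])
    def test_lengths(self, T, n_discard, expected):
        s = make_session(np.random.default_rng(0).normal(size=(3, T)))
        out = dmnfc.discard_initial_volumes(s, n_discard)
        assert out.n_volumes == expected
        assert out.motion.shape[0] == expected
        assert out.wm_signal.size == expected

    def test_discard_all_is_error(self):
        s = make_session(np.zeros((2, 4)))
        with pytest.raises(ValueError):
            dmnfc.discard_initial_volumes(s, 4)

    def test_keeps_tail_values(self):
        data = np.arange(20, dtype=float).reshape(2, 10)
        out = dmnfc.discard_initial_volumes(make_session(data), 4)
        np.testing.assert_array_equal(out.data, data[:, 4:])


class TestDetrend:
    def test_exact_line_removed(self):
        t = np.arange(100, dtype=float)
        np.testing.assert_allclose(
            dmnfc.linear_detrend(2 + 3 * t), 0.0, atol=1e-9
        )

    def test_constant_becomes_zero(self):
        np.testing.assert_allclose(
            dmnfc.linear_detrend(np.full(50, 7.0)), 0.0, atol=1e-9
        )

    def test_matches_direct_least_squares(self, rng):
        x = sine(0.05, T=196) + 0.3 * rng.normal(size=196)
        t = np.arange(196, dtype=float)
        X = np.column_stack([np.ones(196), t])
        beta, *_ = np.linalg.lstsq(X, x, rcond=None)
        np.testing.assert_allclose(
            dmnfc.linear_detrend(x), x - X @ beta, atol=1e-9
        )


class TestBandpassFilter:
    @pytest.mark.parametrize("mode", ["butterworth", "fft"])
    def test_inband_sine_preserved(self, mode):
        x = sine(0.05)
        y = dmnfc.bandpass_filter(x, SLOW4, TR, mode=mode)
        assert projected_amplitude(y, 0.05) == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("mode", ["butterworth", "fft"])
    def test_outofband_sine_suppressed(self, mode):
        x = sine(0.15)
        y = dmnfc.bandpass_filter(x, SLOW4, TR, mode=mode)
        assert projected_amplitude(y, 0.15) <= 0.10

    @pytest.mark.parametrize("band", list(CANONICAL_BANDS.values()),
                             ids=lambda b: b.name)
    def test_dc_removed(self, band):
        y = dmnfc.bandpass_filter(np.full(500, 5.0), band, TR)
        assert np.max(np.abs(y)) < 1e-6

    def test_zero_phase(self):
        """Cross-correlation of an in-band sine with its output peaks at
        lag zero."""
        x = sine(0.05, T=1000)
        y = dmnfc.bandpass_filter(x, SLOW4, TR)
        lags = range(-5, 6)
        cc = [np.dot(x[200:800], np.roll(y, k)[200:800]) for k in lags]
        assert list(lags)[int(np.argmax(cc))] == 0

    @pytest.mark.parametrize("band", list(CANONICAL_BANDS.values()),
                             ids=lambda b: b.name)
    def test_energy_not_created(self, band, rng):
        x = rng.normal(size=2000)
        y = dmnfc.bandpass_filter(x, band, TR)
        assert y.var() <= x.var() * 1.05

    def test_disjoint_band_outputs_near_orthogonal(self, rng):
        """The four slow-band decompositions of one series are mutually
        near-orthogonal: exactly so for the ideal filter; within tolerance
        for non-adjacent Butterworth bands (adjacent bands share skirt
        energy at their common edge)."""
        x = rng.normal(size=5000)
        bands = [SLOW5, SLOW4, SLOW3, SLOW2]
        for mode in ("fft", "butterworth"):
            outs = [dmnfc.bandpass_filter(x, b, TR, mode=mode) for b in bands]
            for i in range(4):
                for j in range(i + 1, 4):
                    if mode == "butterworth" and j == i + 1:
                        continue
                    r = np.corrcoef(outs[i], outs[j])[0, 1]
                    assert abs(r) < 0.1, (mode, bands[i].name, bands[j].name)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            dmnfc.bandpass_filter(np.zeros(100), BandSpec("x", 0.1, 0.4), TR)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            dmnfc.bandpass_filter(np.zeros(10), SLOW4, TR)


class TestNuisanceRegress:
    def test_confound_itself_removed(self, rng):
        c = rng.normal(size=(100, 1))
        resid = dmnfc.nuisance_regress(c[:, 0] * 2.5, c)
        np.testing.assert_allclose(resid, 0.0, atol=1e-9)

    def test_intercept_only_demeans(self, rng):
        x = rng.normal(size=80) + 5
        resid = dmnfc.nuisance_regress(x, np.zeros((80, 0)))
        np.testing.assert_allclose(resid, x - x.mean(), atol=1e-9)

    def test_matches_normal_equations(self, rng):
        T, k = 196, 8
        x = rng.normal(size=T)
        C = rng.normal(size=(T, k))
        X = np.column_stack([C, np.ones(T)])
        beta = np.linalg.solve(X.T @ X, X.T @ x)
        np.testing.assert_allclose(
            dmnfc.nuisance_regress(x, C), x - X @ beta, atol=1e-8
        )
        # residual orthogonal to every confound column
        resid = dmnfc.nuisance_regress(x, C)
        assert np.max(np.abs(C.T @ resid)) < 1e-8

    def test_rank_deficient_confounds_warn_and_work(self, rng, caplog):
        T = 60
        c = rng.normal(size=(T, 1))
        C = np.column_stack([c, 2 * c])
        with caplog.at_level(logging.WARNING, logger="dmnfc.preprocess"):
            resid = dmnfc.nuisance_regress(rng.normal(size=T), C)
        assert "rank deficient" in caplog.text
        assert np.max(np.abs(C.T @ resid)) < 1e-8


class TestFd:
    def test_zero_motion(self):
        np.testing.assert_array_equal(
            dmnfc.compute_fd(np.zeros((10, 6))), np.zeros(10)
        )

    def test_single_translation_jump(self):
        m = np.zeros((5, 6))
        m[3:, 0] = 0.5
        fd = dmnfc.compute_fd(m)
        np.testing.assert_allclose(fd, [0, 0, 0, 0.5, 0])

    def test_rotation_converted_at_head_radius(self):
        m = np.zeros((3, 6))
        m[2, 4] = 0.01  # radians
        fd = dmnfc.compute_fd(m)
        assert fd[2] == pytest.approx(0.5)  # 0.01 rad * 50 mm

    def test_invariant_to_constant_offset(self, rng):
        m = rng.normal(size=(30, 6))
        np.testing.assert_allclose(
            dmnfc.compute_fd(m), dmnfc.compute_fd(m + 3.0), atol=1e-12
        )

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            dmnfc.compute_fd(np.zeros((10, 5)))


class TestDvars:
    def test_constant_data(self):
        assert dmnfc.compute_dvars(np.full((4, 10), 3.0)).max() == 0

    def test_single_roi_step(self):
        data = np.zeros((10, 5))
        data[0, 3:] = 3.0
        dv = dmnfc.compute_dvars(data)
        assert dv[3] == pytest.approx(np.sqrt(9 / 10))
        assert dv[4] == 0

    def test_homogeneity_and_offset_invariance(self, rng):
        x = rng.normal(size=(6, 40))
        np.testing.assert_allclose(
            dmnfc.compute_dvars(3 * x), 3 * dmnfc.compute_dvars(x)
        )
        np.testing.assert_allclose(
            dmnfc.compute_dvars(x + 100.0), dmnfc.compute_dvars(x), atol=1e-9
        )


class TestQcPolicy:
    def test_quiet_subject_not_censored(self):
        s = make_session(np.random.default_rng(0).normal(size=(3, 50)))
        qc = qc_evaluate(s)
        assert qc.n_censored == 0 and not qc.excluded

    def test_censored_count(self):
        m = np.zeros((3, 6))
        m[1:, 0] = 0.6  # single 0.6 mm step, held afterwards
        s = make_session(np.random.default_rng(0).normal(size=(2, 3)), motion=m)
        qc = qc_evaluate(s, fd_threshold_mm=0.5)
        assert qc.n_censored == 1
        np.testing.assert_allclose(qc.fd, [0.0, 0.6, 0.0])

    def test_mover_subject_excluded(self):
        """A simulated high-motion subject trips the exclusion policy."""
        cfg = dmnfc.CohortConfig(
            n_group_a=2, n_group_b=2, n_volumes=120, n_movers=1, seed=3
        )
        sessions, _, _ = dmnfc.generate_cohort(cfg)
        qcs = [qc_evaluate(s) for s in sessions]
        assert qcs[0].excluded  # the mover
        assert not any(q.excluded for q in qcs[1:])
        assert qcs[0].mean_fd > qcs[1].mean_fd


class TestPreprocessSession:
    def test_residual_orthogonal_to_filtered_confounds(self, toy_cohort):
        sessions, _, _ = toy_cohort
        s = sessions[0]
        pp = dmnfc.preprocess_session(s, SLOW4)
        assert isinstance(pp, PreprocessedSession)
        trimmed = dmnfc.discard_initial_volumes(s, 4)
        confounds = np.column_stack(
            [trimmed.motion, trimmed.wm_signal, trimmed.csf_signal]
        )
        confounds = dmnfc.linear_detrend(confounds.T).T
        confounds = dmnfc.bandpass_filter(
            confounds.T, SLOW4, s.tr_seconds
        ).T
        proj = confounds.T @ pp.session.data.T
        assert np.max(np.abs(proj)) < 1e-6

    def test_pure_inband_signal_passes_through(self):
        x = sine(0.05, T=200)
        s = make_session(np.tile(x, (2, 1)))
        pp = dmnfc.preprocess_session(s, SLOW4, regress_confounds=False)
        expected = dmnfc.bandpass_filter(
            dmnfc.linear_detrend(x[4:]), SLOW4, TR
        )
        np.testing.assert_allclose(pp.session.data[0], expected, atol=1e-9)
        # and the band-limited content itself survives nearly unchanged
        assert np.corrcoef(pp.session.data[0], x[4:])[0, 1] > 0.99

    def test_deterministic(self, toy_cohort):
        sessions, _, _ = toy_cohort
        a = dmnfc.preprocess_session(sessions[0], SLOW5)
        b = dmnfc.preprocess_session(sessions[0], SLOW5)
        np.testing.assert_array_equal(a.session.data, b.session.data)
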