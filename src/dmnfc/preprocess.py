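"""Temporal preprocessing of ROI BOLD time series.

The pipeline stages mirror standard resting-state practice: discard the
first volumes acquired before magnetisation equilibrium, remove per-ROI
linear trends, band-pass filter into one of the five analysis bands, then
regress out nuisance signals (six rigid-body motion parameters plus white
matter and CSF mean signals; the global whole-brain signal is deliberately
NOT removed).  Motion quality control uses framewise displacement (FD) and
DVARS; frames with FD above 0.5 mm are censored and high-motion subjects
are excluded.

Two filter realisations are provided.  The default is a zero-phase
forward-backward Butterworth (order 2 per pass, effective order 4) with
reflective padding of at least three periods of the lowest passband
frequency.  An ideal FFT filter ("fft" mode) zeroes all Fourier bins
outside the band and serves as an analytically transparent oracle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import signal

from .bands import BandSpec

logger = logging.getLogger(__name__)

FilterMode = Literal["butterworth", "fft"]

#: Conventional head radius used to convert rotations to arc displacement.
DEFAULT_HEAD_RADIUS_MM = 50.0
#: Frames moving more than this between volumes are censored.
DEFAULT_FD_THRESHOLD_MM = 0.5
#: Number of dummy volumes discarded before analysis.
DEFAULT_N_DISCARD = 4


@dataclass
class SubjectSession:
    """One subject's ROI-by-time data plus confound traces and covariates.

    ``data`` is (n_rois, T); ``motion`` is (T, 6) with translations in mm
    and rotations in radians; ``wm_signal``/``csf_signal`` are length-T
    nuisance traces.  ``covariates`` holds at least MMSE, age and sex.
    """

    subject_id: str
    group: str
    data: np.ndarray
    tr_seconds: float
    motion: np.ndarray
    wm_signal: np.ndarray
    csf_signal: np.ndarray
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        self.wm_signal = np.asarray(self.wm_signal, dtype=float)
        self.csf_signal = np.asarray(self.csf_signal, dtype=float)
        T = self.data.shape[1]
        if self.motion.shape != (T, 6):
            raise ValueError(
                f"{self.subject_id}: motion shape {self.motion.shape} does "
                f"not match {T} volumes x 6 parameters"
            )
        if self.wm_signal.shape != (T,) or self.csf_signal.shape != (T,):
            raise ValueError(f"{self.subject_id}: nuisance trace length != T")
        if not np.isfinite(self.data).all():
            raise ValueError(f"{self.subject_id}: non-finite values in data")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]


@dataclass
class QcMetrics:
    """Per-subject motion QC: FD/DVARS traces, censoring and exclusion."""

    subject_id: str
    fd: np.ndarray
    dvars: np.ndarray
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM
    n_censored: int = 0
    excluded: bool = False

    @property
    def mean_fd(self) -> float:
        return float(np.mean(self.fd))

    @property
    def mean_dvars(self) -> float:
        return float(np.mean(self.dvars))

    @property
    def censored_mask(self) -> np.ndarray:
        """Boolean mask over frames, True where FD exceeds the threshold."""
        return self.fd > self.fd_threshold_mm


def discard_initial_volumes(
    session: SubjectSession, n_discard: int = DEFAULT_N_DISCARD
) -> SubjectSession:
    """Drop the first ``n_discard`` volumes from data and all confounds."""
    T = session.n_volumes
    if n_discard >= T:
        raise ValueError(
            f"cannot discard {n_discard} of {T} volumes for "
            f"{session.subject_id}"
        )
    return replace(
        session,
        data=session.data[:, n_discard:].copy(),
        motion=session.motion[n_discard:].copy(),
        wm_signal=session.wm_signal[n_discard:].copy(),
        csf_signal=session.csf_signal[n_discard:].copy(),
    )


def linear_detrend(series: np.ndarray) -> np.ndarray:
    """Subtract the least-squares line (intercept + slope*t), per row.

    Accepts a 1-D series or an (n, T) array (detrended along the last
    axis).  Constant input returns zeros.
    """
    series = np.asarray(series, dtype=float)
    T = series.shape[-1]
    if T < 3:
        raise ValueError("need at least 3 time points to detrend")
    return signal.detrend(series, axis=-1, type="linear")


def _butter_sos(band: BandSpec, tr_seconds: float):
    fs = 1.0 / tr_seconds
    nyq = 0.5 * fs
    if band.high_hz >= nyq * (1 - 1e-9):
        # Upper edge at Nyquist: a band-pass is degenerate, realize as
        # high-pass preserving the nominal lower edge.
        return signal.butter(2, band.low_hz, btype="highpass", fs=fs,
                             output="sos")
    return signal.butter(2, [band.low_hz, band.high_hz], btype="bandpass",
                         fs=fs, output="sos")


def bandpass_filter(
    series: np.ndarray,
    band: BandSpec,
    tr_seconds: float,
    mode: FilterMode = "butterworth",
) -> np.ndarray:
    """Zero-phase band-pass filter along the last axis.

    ``mode="butterworth"`` applies an order-2 Butterworth forwards and
    backwards (sosfiltfilt) with reflective padding of at least three
    periods of the band's lower edge.  ``mode="fft"`` zeroes every Fourier
    bin strictly outside [low_hz, high_hz] (an ideal filter used as an
    oracle).  Both remove DC exactly.
    """
    band.validate_for_tr(tr_seconds)
    series = np.asarray(series, dtype=float)
    T = series.shape[-1]
    if T < 32:
        raise ValueError(f"need at least 32 time points to filter, got {T}")
    if mode == "fft":
        freqs = np.fft.rfftfreq(T, d=tr_seconds)
        spec = np.fft.rfft(series, axis=-1)
        keep = (freqs >= band.low_hz - 1e-12) & (freqs <= band.high_hz + 1e-12)
        spec = np.where(keep, spec, 0.0)
        return np.fft.irfft(spec, n=T, axis=-1)
    if mode != "butterworth":
        raise ValueError(f"unknown filter mode {mode!r}")
    sos = _butter_sos(band, tr_seconds)
    padlen = min(T - 1, int(np.ceil(3.0 / (band.low_hz * tr_seconds))))
    return signal.sosfiltfilt(sos, series, axis=-1, padlen=padlen)


def nuisance_regress(series: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """OLS residual of ``series`` on ``confounds`` plus an intercept.

    ``series`` may be 1-D (length T) or (n, T).  ``confounds`` is (T, k);
    an intercept column is always appended.  Rank-deficient confound sets
    are handled by the minimum-norm least-squares solution, with a logged
    warning.  The residual is orthogonal to every confound column.
    """
    series = np.asarray(series, dtype=float)
    one_d = series.ndim == 1
    Y = np.atleast_2d(series).T  # (T, n)
    T = Y.shape[0]
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[0] != T:
        raise ValueError(
            f"confounds have {confounds.shape[0]} rows, series has {T}"
        )
    X = np.column_stack([confounds, np.ones(T)])
    if X.shape[1] >= T:
        raise ValueError("more confounds than time points")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning(
            "confound matrix is rank deficient (rank %d < %d columns); "
            "using minimum-norm solution", rank, X.shape[1],
        )
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return resid.ravel() if one_d else resid.T


def compute_fd(
    motion: np.ndarray, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """Framewise displacement from (T, 6) rigid-body parameters.

    fd[0] = 0; fd[t] sums the absolute backward differences of the three
    translations (mm) and of the three rotations converted to arc length
    at ``head_radius_mm`` (rotations are in radians).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be (T, 6), got {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames for FD")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def compute_dvars(data: np.ndarray) -> np.ndarray:
    """DVARS: RMS over ROIs of the backward temporal difference.

    dvars[0] = 0; no normalisation is applied.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("data must be (n_rois, T) with T >= 2")
    diff = np.diff(data, axis=1)
    dvars = np.sqrt(np.mean(diff**2, axis=0))
    return np.concatenate([[0.0], dvars])


def qc_evaluate(
    session: SubjectSession,
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    max_censored_fraction: float = 0.25,
    max_mean_fd_mm: float = DEFAULT_FD_THRESHOLD_MM,
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
) -> QcMetrics:
    """Compute FD/DVARS and apply the censoring and exclusion policy.

    Frames with FD above ``fd_threshold_mm`` are censored.  A subject is
    excluded when more than ``max_censored_fraction`` of frames are
    censored or mean FD exceeds ``max_mean_fd_mm``.
    """
    fd = compute_fd(session.motion, head_radius_mm)
    dvars = compute_dvars(session.data)
    qc = QcMetrics(session.subject_id, fd, dvars, fd_threshold_mm)
    qc.n_censored = int(np.sum(fd > fd_threshold_mm))
    frac = qc.n_censored / len(fd)
    qc.excluded = frac > max_censored_fraction or qc.mean_fd > max_mean_fd_mm
    return qc


@dataclass
class PreprocessedSession:
    """A band-limited, confound-regressed session plus its QC metrics."""

    session: SubjectSession
    band: BandSpec
    qc: QcMetrics


def preprocess_session(
    session: SubjectSession,
    band: BandSpec,
    n_discard: int = DEFAULT_N_DISCARD,
    filter_mode: FilterMode = "butterworth",
    regress_confounds: bool = True,
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    max_censored_fraction: float = 0.25,
    max_mean_fd_mm: float = DEFAULT_FD_THRESHOLD_MM,
) -> PreprocessedSession:
    """Run discard -> detrend -> band-pass -> nuisance regression.

    Confound columns (6 motion parameters, WM, CSF) are detrended and
    band-pass filtered with the identical filter before regression so that
    regression cannot reintroduce out-of-band variance.  QC metrics are
    computed on the retained volumes; the caller decides what to do with
    censored frames (the connectivity stage drops them).
    """
    trimmed = discard_initial_volumes(session, n_discard)
    qc = qc_evaluate(
        trimmed,
        fd_threshold_mm=fd_threshold_mm,
        max_censored_fraction=max_censored_fraction,
        max_mean_fd_mm=max_mean_fd_mm,
    )
    data = linear_detrend(trimmed.data)
    data = bandpass_filter(data, band, trimmed.tr_seconds, mode=filter_mode)
    if regress_confounds:
        confounds = np.column_stack(
            [trimmed.motion, trimmed.wm_signal, trimmed.csf_signal]
        )
        confounds = linear_detrend(confounds.T).T
        confounds = bandpass_filter(
            confounds.T, band, trimmed.tr_seconds, mode=filter_mode
        ).T
        # Near-constant filtered confounds (e.g. zero motion) are dropped to
        # keep the design well conditioned; the intercept covers them.
        keep = confounds.std(axis=0) > 1e-12
        if not keep.all():
            logger.debug(
                "dropping %d constant confound columns", int((~keep).sum())
            )
        data = nuisance_regress(data, confounds[:, keep])
    out = replace(trimmed, data=data)
    return PreprocessedSession(session=out, band=band, qc=qc)


def qc_report(qcs: list[QcMetrics], groups: dict[str, str]) -> "object":
    """Tabulate per-subject QC (mean FD, mean DVARS, censoring, exclusion).

    ``groups`` maps subject_id -> group label.  Returns a pandas DataFrame
    suitable for a two-sample group comparison of head motion.
    """
    import pandas as pd

    rows = [
        {
            "participant_id": q.subject_id,
            "group": groups.get(q.subject_id, ""),
            "mean_fd": q.mean_fd,
            "mean_dvars": q.mean_dvars,
            "n_censored": q.n_censored,
            "excluded": q.excluded,
        }
        for q in qcs
    ]
    return pd.DataFrame(rows)


def qc_group_compare(report, value: str = "mean_fd") -> tuple[float, float]:
    """Pooled two-sample t test of a QC value between the two groups."""
    from scipy import stats

    labels = report["group"].unique()
    if len(labels) != 2:
        raise ValueError("QC group comparison needs exactly two groups")
    a = report.loc[report["group"] == labels[0], value]
    b = report.loc[report["group"] == labels[1], value]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
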