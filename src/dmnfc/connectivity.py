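"""Per-subject, per-band DMN connectivity matrices.

Functional connectivity between two regions is the Pearson correlation of
their (preprocessed, band-limited) mean time series, Fisher r-to-z
transformed to stabilise the variance for group statistics.  Censored
high-motion frames are removed with the same frame set for every ROI of a
subject, so each subject has a single correlation sample size per band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .atlas import RoiAtlas, load_atlas
from .bands import BandSpec
from .preprocess import FilterMode, SubjectSession, preprocess_session

#: Correlations are clipped to +/-(1 - R_CLIP_EPS) before atanh so that
#: degenerate (perfectly collinear) synthetic inputs stay finite.
R_CLIP_EPS = 1e-7

MIN_FRAMES = 10


@dataclass
class ConnectivityMatrix:
    """Symmetric per-subject x band correlation and Fisher-z matrices."""

    subject_id: str
    band: str
    r: np.ndarray
    z: np.ndarray
    n_timepoints_used: int

    @property
    def n_rois(self) -> int:
        return self.r.shape[0]


def correlation_matrix(
    roi_ts: np.ndarray,
    censored_frames: Iterable[int] | None = None,
    min_frames: int = MIN_FRAMES,
) -> np.ndarray:
    """Pearson correlation over uncensored frames of an (n_rois, T) array.

    Raises if fewer than ``min_frames`` frames remain or any ROI has zero
    variance (the error names the offending ROI row).
    """
    roi_ts = np.asarray(roi_ts, dtype=float)
    if roi_ts.ndim != 2:
        raise ValueError("roi_ts must be (n_rois, T)")
    T = roi_ts.shape[1]
    mask = np.ones(T, dtype=bool)
    if censored_frames is not None:
        idx = np.asarray(list(censored_frames), dtype=int)
        if idx.size:
            mask[idx] = False
    kept = roi_ts[:, mask]
    if kept.shape[1] < min_frames:
        raise ValueError(
            f"only {kept.shape[1]} uncensored frames; need >= {min_frames}"
        )
    sd = kept.std(axis=1)
    scale = np.maximum(1.0, np.abs(kept).max(axis=1))
    zero = np.flatnonzero(sd <= 1e-12 * scale)
    if zero.size:
        raise ValueError(f"zero-variance ROI(s) at row index {zero.tolist()}")
    r = np.corrcoef(kept)
    np.fill_diagonal(r, 1.0)
    return (r + r.T) / 2.0


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher r-to-z: atanh of the off-diagonal correlations, 0 on diagonal.

    Input magnitudes above 1 (beyond numerical tolerance) are rejected;
    values within tolerance are clipped so z stays finite.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0 + 1e-9):
        raise ValueError("correlations must satisfy |r| <= 1")
    z = np.arctanh(np.clip(r, -(1 - R_CLIP_EPS), 1 - R_CLIP_EPS))
    if z.ndim == 2 and z.shape[0] == z.shape[1]:
        np.fill_diagonal(z, 0.0)
    return z


def connectivity_from_timeseries(
    subject_id: str,
    band: str,
    roi_ts: np.ndarray,
    censored_frames: Iterable[int] | None = None,
) -> ConnectivityMatrix:
    """Correlate, Fisher-transform and package one subject x band matrix."""
    censored = list(censored_frames) if censored_frames is not None else []
    r = correlation_matrix(roi_ts, censored)
    z = fisher_z(r)
    return ConnectivityMatrix(
        subject_id=subject_id,
        band=band,
        r=r,
        z=z,
        n_timepoints_used=roi_ts.shape[1] - len(set(censored)),
    )


def cohort_connectivity(
    sessions: Sequence[SubjectSession],
    bands: Sequence[BandSpec],
    atlas: RoiAtlas | None = None,
    n_discard: int = 4,
    filter_mode: FilterMode = "butterworth",
    drop_excluded: bool = True,
    **preprocess_kwargs,
) -> tuple[list[ConnectivityMatrix], pd.DataFrame]:
    """Preprocess and correlate every subject in every band.

    Returns one ConnectivityMatrix per retained subject x band plus a QC
    report DataFrame (one row per subject).  Subjects failing motion QC
    are dropped from the matrix list when ``drop_excluded``.
    """
    if atlas is not None:
        for s in sessions:
            if s.n_rois != atlas.n_rois:
                raise ValueError(
                    f"{s.subject_id}: {s.n_rois} ROIs != atlas {atlas.n_rois}"
                )
    from .preprocess import qc_report

    matrices: list[ConnectivityMatrix] = []
    qcs = []
    groups = {s.subject_id: s.group for s in sessions}
    for s in sessions:
        per_subject_qc = None
        for band in bands:
            pp = preprocess_session(
                s, band, n_discard=n_discard, filter_mode=filter_mode,
                **preprocess_kwargs,
            )
            per_subject_qc = pp.qc
            if drop_excluded and pp.qc.excluded:
                continue
            censored = np.flatnonzero(pp.qc.censored_mask)
            matrices.append(
                connectivity_from_timeseries(
                    s.subject_id, band.name, pp.session.data, censored
                )
            )
        qcs.append(per_subject_qc)
    return matrices, qc_report(qcs, groups)


def extract_roi_timeseries(volume4d, label_img, atlas: RoiAtlas) -> np.ndarray:
    """Mean time series per labelled ROI from a 4-D volume.

    ``volume4d`` and ``label_img`` may be nibabel images or arrays on the
    same (x, y, z[, t]) grid.  Row i of the output is the mean over voxels
    whose label equals the i-th atlas ROI number, per time point.
    """
    vol = np.asarray(
        volume4d.get_fdata() if hasattr(volume4d, "get_fdata") else volume4d,
        dtype=float,
    )
    lab = np.asarray(
        label_img.get_fdata() if hasattr(label_img, "get_fdata") else label_img
    ).astype(int)
    if vol.ndim != 4:
        raise ValueError("volume must be 4-D (x, y, z, t)")
    if lab.shape != vol.shape[:3]:
        raise ValueError(
            f"label grid {lab.shape} != volume grid {vol.shape[:3]}"
        )
    T = vol.shape[3]
    out = np.empty((atlas.n_rois, T))
    flat = vol.reshape(-1, T)
    lab_flat = lab.ravel()
    for i, num in enumerate(atlas.table["number"]):
        sel = lab_flat == int(num)
        if not sel.any():
            name = atlas.table["name"].iloc[i]
            raise ValueError(f"label {num} ({name}) absent from label image")
        out[i] = flat[sel].mean(axis=0)
    return out


def matrices_to_long(matrices: Sequence[ConnectivityMatrix],
                     atlas: RoiAtlas | None = None) -> pd.DataFrame:
    """Cohort-level long table: subject, band, roi_i, roi_j, r, z."""
    names = (atlas or load_atlas()).names if atlas is not None else None
    rows = []
    for m in matrices:
        p = m.n_rois
        iu, ju = np.triu_indices(p, k=1)
        for i, j in zip(iu, ju):
            rows.append(
                {
                    "subject_id": m.subject_id,
                    "band": m.band,
                    "roi_i": int(i + 1),
                    "roi_j": int(j + 1),
                    "roi_i_name": names[i] if names else str(i + 1),
                    "roi_j_name": names[j] if names else str(j + 1),
                    "r": m.r[i, j],
                    "z": m.z[i, j],
                    "n_timepoints_used": m.n_timepoints_used,
                }
            )
    return pd.DataFrame(rows)
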