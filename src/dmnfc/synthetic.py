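"""Synthetic multi-subject BOLD cohorts with band-confined group effects.

The generator emulates a two-group resting-state study (patients vs
controls) at the ROI level.  Each subject's signal is a sum over frequency
bands of band-limited components.  Within a band, the inter-ROI
correlation structure is imposed by mixing white Gaussian noise through
the Cholesky factor of a target correlation matrix and then band-limiting
every row with the same zero-phase filter used by the analysis pipeline;
because the mixing is frequency-flat and the filter is applied identically
to every ROI, the population correlation of the band component equals the
target exactly.  Group differences are implanted by modifying designated
edges of the target matrix in designated bands only.

On top of the neural-like components the generator adds: a common-mode
physiological trace with spectral content confined to a configurable
range (emulating respiratory/cardiac contamination of the 0.073-0.25 Hz
range), white-matter- and CSF-like nuisance traces coupled into every
ROI, white measurement noise, a linear drift, and bounded-random-walk
motion parameters calibrated to a mean framewise displacement near
0.3 mm.  An MMSE-like covariate is drawn as
intercept + sum(slope_e * realized edge coupling) + noise, with positive
slopes on decreased edges and negative slopes on increased edges, so that
severity correlates with connectivity in the implanted directions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import BandSpec, SLOW_BANDS, get_band
from .preprocess import FilterMode, SubjectSession, bandpass_filter


@dataclass(frozen=True)
class EffectSpec:
    """A band-confined group difference on one edge.

    ``edge`` uses 1-based ROI numbers; ``delta`` is the coupling change of
    group A (patients) relative to the shared baseline: subtracted for
    ``direction="decrease"``, added for ``"increase"``.
    """

    edge: tuple[int, int]
    band: str
    direction: str
    delta: float

    def __post_init__(self) -> None:
        i, j = self.edge
        if i == j:
            raise ValueError("effect edge endpoints must be distinct")
        if self.direction not in ("decrease", "increase"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.delta < 0:
            raise ValueError("delta is a magnitude; must be >= 0")

    @property
    def signed_delta(self) -> float:
        return -self.delta if self.direction == "decrease" else self.delta


@dataclass(frozen=True)
class CovariateModel:
    """MMSE-like covariate coupled to realized edge coupling.

    MMSE = intercept + slope * mean_e[sign_e * (proxy_e - healthy_e)] +
    Gaussian noise, where proxy_e is the subject's realized band-limited
    sample correlation on tagged edge e, healthy_e the control-group
    population coupling, and sign_e is +1 for decreased and -1 for
    increased edges.  Severity therefore tracks connectivity loss:
    decreased edges correlate positively and increased edges negatively
    with the score, and the healthy group centres on the intercept.
    """

    intercept: float = 28.5
    slope: float = 20.0
    noise_sd: float = 1.5


@dataclass(frozen=True)
class PhysioModel:
    """Common-mode respiratory/cardiac-like contamination."""

    amplitude: float = 0.4
    low_hz: float = 0.073
    high_hz: float = 0.25


@dataclass(frozen=True)
class MotionModel:
    """Bounded random-walk rigid-body motion (mm, radians)."""

    trans_step_sd_mm: float = 0.08
    rot_step_sd_rad: float = 0.0008
    trans_bound_mm: float = 2.0
    rot_bound_rad: float = 0.02
    mover_scale: float = 4.0


def default_effects() -> list[EffectSpec]:
    """The implanted effect pattern emulated by default.

    Two connected decreased long-range edges plus two connected increased
    short-range edges in slow-5, and two connected decreased edges in
    slow-4; no effect in slow-3 or slow-2.
    """
    return [
        EffectSpec((2, 20), "slow-5", "decrease", 0.4),
        EffectSpec((2, 6), "slow-5", "decrease", 0.4),
        EffectSpec((11, 12), "slow-5", "increase", 0.3),
        EffectSpec((12, 14), "slow-5", "increase", 0.3),
        EffectSpec((6, 20), "slow-4", "decrease", 0.4),
        EffectSpec((11, 20), "slow-4", "decrease", 0.4),
    ]


def _default_band_correlations() -> dict[str, float]:
    return {name: 0.45 for name in SLOW_BANDS}


#: A connected path of long-range DMN edges (left angular gyrus - right
#: angular gyrus - right middle frontal - precuneus - left IPL - left PCC -
#: precuneus(7)) used by the band-specific recovery study.
RECOVERY_PATH_EDGES: list[tuple[int, int]] = [
    (2, 6), (6, 20), (20, 4), (4, 12), (12, 14), (14, 11),
]


def band_recovery_config(
    effect_band: str = "slow-5",
    delta: float = 0.4,
    baseline: float = 0.25,
    hub_coupling: float = 0.6,
    seed: int = 0,
    **overrides,
) -> "CohortConfig":
    """Cohort configuration for the band-specific recovery study.

    Implants a connected six-edge decreased subnetwork (a path of
    long-range DMN edges) confined to ``effect_band``.  The implanted
    edges are hub connections, stronger than the background coupling in
    both groups (``hub_coupling``), and the patient group loses exactly
    ``delta`` of that coupling; both target matrices remain positive
    semidefinite without repair, so the generated population couplings
    equal the configured values exactly.  Recovery is assessed with the
    one-sided (decrease) network test.
    """
    return CohortConfig(
        band_correlations={name: baseline for name in SLOW_BANDS},
        baseline_overrides={
            effect_band: {e: hub_coupling for e in RECOVERY_PATH_EDGES}
        },
        effects=[
            EffectSpec(e, effect_band, "decrease", delta)
            for e in RECOVERY_PATH_EDGES
        ],
        seed=seed,
        **overrides,
    )


def null_cohort_config(
    n_per_group: int = 10, band: str = "lfo", seed: int = 0, **overrides
) -> "CohortConfig":
    """A no-effect cohort (single analysis band) for calibration studies."""
    return CohortConfig(
        n_group_a=n_per_group,
        n_group_b=n_per_group,
        band_correlations={band: 0.45},
        band_amplitudes={band: 1.0},
        effects=[],
        seed=seed,
        **overrides,
    )


def _default_band_amplitudes() -> dict[str, float]:
    # Roughly 1/f: lower bands carry more BOLD power.
    return {"slow-5": 1.0, "slow-4": 0.8, "slow-3": 0.5, "slow-2": 0.35}


@dataclass
class CohortConfig:
    """Full specification of a simulated two-group cohort.

    Defaults reproduce the emulated study conditions: 35 patients (AD) vs
    27 controls (NC), 200 volumes at TR = 2 s, 22 ROIs, baseline coupling
    0.45 in each slow band, effects per :func:`default_effects`.
    """

    n_group_a: int = 35
    n_group_b: int = 27
    group_a: str = "AD"
    group_b: str = "NC"
    n_rois: int = 22
    n_volumes: int = 200
    tr_seconds: float = 2.0
    band_correlations: dict = field(default_factory=_default_band_correlations)
    band_amplitudes: dict = field(default_factory=_default_band_amplitudes)
    #: band name -> {edge: coupling}; per-edge baseline shared by both
    #: groups, overriding the band's scalar baseline (models hub edges
    #: that are stronger than average in health)
    baseline_overrides: dict = field(default_factory=dict)
    effects: list = field(default_factory=default_effects)
    covariate: CovariateModel = field(default_factory=CovariateModel)
    physio: PhysioModel = field(default_factory=PhysioModel)
    motion: MotionModel = field(default_factory=MotionModel)
    noise_sd: float = 0.2
    wm_coupling: float = 0.2
    csf_coupling: float = 0.2
    drift_amplitude: float = 0.5
    signal_scale: float = 25.0
    signal_baseline: float = 1000.0
    n_movers: int = 0
    filter_mode: FilterMode = "butterworth"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_volumes <= 4:
            raise ValueError("n_volumes must exceed the 4 discarded volumes")
        nyq = 0.5 / self.tr_seconds
        for name in self.band_correlations:
            b = get_band(name)
            if not (0 < b.low_hz < b.high_hz <= nyq + 1e-12):
                raise ValueError(f"band {name} outside (0, Nyquist]")
        for name, rho in self.band_correlations.items():
            if not (0 <= rho < 1):
                raise ValueError(f"baseline coupling for {name} not in [0,1)")
        for band, overrides in self.baseline_overrides.items():
            if band not in self.band_correlations:
                raise ValueError(f"override band {band!r} not configured")
            for edge, rho in overrides.items():
                if not (-1 < rho < 1):
                    raise ValueError(
                        f"baseline override {rho} on {edge} outside (-1, 1)"
                    )
        for e in self.effects:
            i, j = e.edge
            if not (1 <= i <= self.n_rois and 1 <= j <= self.n_rois):
                raise ValueError(f"effect edge {e.edge} outside 1..{self.n_rois}")
            if e.band not in self.band_correlations:
                raise ValueError(f"effect band {e.band!r} not configured")
            base = self.baseline_overrides.get(e.band, {}).get(
                e.edge, self.band_correlations[e.band]
            )
            rho = base + e.signed_delta
            if not (-1 < rho < 1):
                raise ValueError(
                    f"effect on {e.edge} pushes coupling to {rho}, "
                    "outside (-1, 1)"
                )
        if not (0 < self.physio.low_hz < self.physio.high_hz <= nyq + 1e-12):
            raise ValueError("physio frequency range outside (0, Nyquist]")

    @property
    def bands(self) -> list[BandSpec]:
        return [get_band(name) for name in self.band_correlations]


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort, for recovery testing."""

    config: CohortConfig
    #: band name -> group label -> (n_rois, n_rois) population correlation
    correlations: dict
    #: (edge, band, slope) triples actually used for the covariate
    covariate_coefficients: list
    seed_used: int

    def correlation(self, band: str, group: str) -> np.ndarray:
        return self.correlations[band][group]

    def effect_edges(self, band: str | None = None,
                     direction: str | None = None):
        return [
            e
            for e in self.config.effects
            if (band is None or e.band == band)
            and (direction is None or e.direction == direction)
        ]


def _nearest_correlation(R: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and restore the unit diagonal."""
    w, V = np.linalg.eigh(R)
    if w.min() >= 1e-8:
        return R
    w = np.clip(w, 1e-6, None)
    R2 = (V * w) @ V.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return R2


def build_truth(config: CohortConfig) -> CohortTruth:
    """Assemble per-band, per-group population correlation matrices."""
    p = config.n_rois
    correlations: dict[str, dict[str, np.ndarray]] = {}
    for name, rho in config.band_correlations.items():
        base = np.full((p, p), rho)
        np.fill_diagonal(base, 1.0)
        for edge, val in config.baseline_overrides.get(name, {}).items():
            i, j = edge[0] - 1, edge[1] - 1
            base[i, j] = base[j, i] = val
        mats = {config.group_a: base.copy(), config.group_b: base.copy()}
        for e in config.effects:
            if e.band != name:
                continue
            i, j = e.edge[0] - 1, e.edge[1] - 1
            val = base[i, j] + e.signed_delta
            mats[config.group_a][i, j] = val
            mats[config.group_a][j, i] = val
        correlations[name] = {
            g: _nearest_correlation(m) for g, m in mats.items()
        }
    n_tagged = max(len(config.effects), 1)
    coeffs = [
        (e.edge, e.band,
         config.covariate.slope / n_tagged
         * (1 if e.direction == "decrease" else -1))
        for e in config.effects
    ]
    return CohortTruth(
        config=config,
        correlations=correlations,
        covariate_coefficients=coeffs,
        seed_used=config.seed,
    )


def generate_physio_contamination(
    n_volumes: int,
    tr_seconds: float,
    amplitude: float,
    freq_range: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited common-mode trace with >=95% spectral mass in range.

    Built by masking the Fourier transform of white noise to the range,
    so the periodogram mass outside the range is numerically zero.  The
    trace is scaled to standard deviation ``amplitude``; amplitude 0
    returns an exact zero trace.
    """
    lo, hi = freq_range
    nyq = 0.5 / tr_seconds
    if not (0 < lo < hi <= nyq + 1e-12):
        raise ValueError(f"invalid frequency range ({lo}, {hi}) Hz")
    # Draw even when amplitude == 0 to keep the RNG stream layout stable.
    x = rng.standard_normal(n_volumes)
    if amplitude == 0:
        return np.zeros(n_volumes)
    freqs = np.fft.rfftfreq(n_volumes, d=tr_seconds)
    spec = np.fft.rfft(x)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    out = np.fft.irfft(spec, n=n_volumes)
    sd = out.std()
    if sd == 0:
        raise ValueError("no Fourier bins inside the frequency range")
    return out * (amplitude / sd)


def _ar1(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    e = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = e[0]
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    return x / x.std()


def _bounded_walk(steps: np.ndarray, bound: float) -> np.ndarray:
    """Random walk reflected into [-bound, bound] (triangular folding)."""
    walk = np.cumsum(steps, axis=0)
    m = np.mod(walk + bound, 4 * bound)
    return np.where(m <= 2 * bound, m - bound, 3 * bound - m)


def generate_subject(
    config: CohortConfig,
    group: str,
    truth: CohortTruth,
    rng: np.random.Generator,
    subject_id: str = "sub-000",
    mover: bool = False,
) -> SubjectSession:
    """Simulate one subject's session given the cohort ground truth."""
    if group not in (config.group_a, config.group_b):
        raise ValueError(f"group {group!r} not in truth")
    p, T, tr = config.n_rois, config.n_volumes, config.tr_seconds
    total = np.zeros((p, T))
    proxies: dict[tuple[tuple[int, int], str], float] = {}
    for band in config.bands:
        R = truth.correlation(band.name, group)
        L = np.linalg.cholesky(R)
        E = rng.standard_normal((p, T))
        S = bandpass_filter(L @ E, band, tr, mode=config.filter_mode)
        sd = S.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        amp = config.band_amplitudes.get(band.name, 1.0)
        S = S / sd * amp
        for e in config.effects:
            if e.band == band.name:
                i, j = e.edge[0] - 1, e.edge[1] - 1
                proxies[(e.edge, e.band)] = float(
                    np.corrcoef(S[i], S[j])[0, 1]
                )
        total += S
    physio = generate_physio_contamination(
        T, tr, config.physio.amplitude,
        (config.physio.low_hz, config.physio.high_hz), rng,
    )
    wm = _ar1(T, 0.6, rng)
    csf = _ar1(T, 0.6, rng)
    total += physio + config.wm_coupling * wm + config.csf_coupling * csf
    total += config.noise_sd * rng.standard_normal((p, T))
    slopes = rng.normal(0.0, config.drift_amplitude, size=p)
    ramp = np.linspace(-0.5, 0.5, T)
    total += slopes[:, None] * ramp[None, :]
    data = config.signal_baseline + config.signal_scale * total

    mm = config.motion
    scale = mm.mover_scale if mover else 1.0
    steps = np.column_stack(
        [
            rng.normal(0.0, mm.trans_step_sd_mm * scale, size=(T, 3)),
            rng.normal(0.0, mm.rot_step_sd_rad * scale, size=(T, 3)),
        ]
    )
    steps[0] = 0.0
    motion = np.column_stack(
        [
            _bounded_walk(steps[:, :3], mm.trans_bound_mm * scale),
            _bounded_walk(steps[:, 3:], mm.rot_bound_rad * scale),
        ]
    )

    cov = config.covariate
    mmse = cov.intercept + rng.normal(0.0, cov.noise_sd)
    healthy = truth.correlations  # control-group population couplings
    for (edge, band, slope) in truth.covariate_coefficients:
        e = tuple(edge)
        base = healthy[band][config.group_b][e[0] - 1, e[1] - 1]
        mmse += slope * (proxies.get((e, band), base) - base)
    age_mu, age_sd = (71.8, 9.8) if group == config.group_a else (69.4, 6.7)
    age = float(np.clip(rng.normal(age_mu, age_sd), 55, 95))
    p_male = 12 / 35 if group == config.group_a else 15 / 27
    sex = "M" if rng.random() < p_male else "F"
    return SubjectSession(
        subject_id=subject_id,
        group=group,
        data=data,
        tr_seconds=tr,
        motion=motion,
        wm_signal=wm,
        csf_signal=csf,
        covariates={"MMSE": float(mmse), "age": age, "sex": sex,
                    "mover": mover},
    )


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SubjectSession], pd.DataFrame, CohortTruth]:
    """Simulate the full cohort: sessions, participants table, truth.

    Subject RNG streams are spawned from the cohort seed, so the same
    config and seed reproduce the cohort bit for bit across processes.
    ``config.n_movers`` subjects of group A are generated with inflated
    motion to exercise the exclusion policy.
    """
    truth = build_truth(config)
    n_total = config.n_group_a + config.n_group_b
    children = np.random.SeedSequence(config.seed).spawn(n_total)
    sessions = []
    rows = []
    for k in range(n_total):
        in_a = k < config.n_group_a
        group = config.group_a if in_a else config.group_b
        mover = in_a and k < config.n_movers
        sid = f"sub-{k + 1:03d}"
        s = generate_subject(
            config, group, truth, np.random.default_rng(children[k]),
            subject_id=sid, mover=mover,
        )
        sessions.append(s)
        rows.append(
            {
                "participant_id": sid,
                "group": group,
                "MMSE": s.covariates["MMSE"],
                "age": s.covariates["age"],
                "sex": s.covariates["sex"],
            }
        )
    return sessions, pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Serialization

_FLOAT_FMT = "%.10g"


def _roi_names(n_rois: int) -> list[str]:
    if n_rois == 22:
        from .atlas import load_atlas

        return load_atlas().names
    return [f"roi_{i + 1:02d}" for i in range(n_rois)]


def _truth_to_jsonable(truth: CohortTruth) -> dict:
    cfg = asdict(truth.config)
    cfg["effects"] = [asdict(e) for e in truth.config.effects]
    cfg["baseline_overrides"] = {
        band: [[int(i), int(j), float(rho)]
               for (i, j), rho in overrides.items()]
        for band, overrides in truth.config.baseline_overrides.items()
    }
    return {
        "config": cfg,
        "correlations": {
            band: {g: m.tolist() for g, m in groups.items()}
            for band, groups in truth.correlations.items()
        },
        "covariate_coefficients": [
            {"edge": list(edge), "band": band, "slope": slope}
            for edge, band, slope in truth.covariate_coefficients
        ],
        "seed_used": truth.seed_used,
    }


def _truth_from_jsonable(doc: dict) -> CohortTruth:
    cfg = dict(doc["config"])
    cfg["effects"] = [
        EffectSpec(tuple(e["edge"]), e["band"], e["direction"], e["delta"])
        for e in cfg["effects"]
    ]
    cfg["covariate"] = CovariateModel(**cfg["covariate"])
    cfg["physio"] = PhysioModel(**cfg["physio"])
    cfg["motion"] = MotionModel(**cfg["motion"])
    cfg["baseline_overrides"] = {
        band: {(int(i), int(j)): rho for i, j, rho in triples}
        for band, triples in cfg.get("baseline_overrides", {}).items()
    }
    config = CohortConfig(**cfg)
    correlations = {
        band: {g: np.asarray(m) for g, m in groups.items()}
        for band, groups in doc["correlations"].items()
    }
    coeffs = [
        (tuple(c["edge"]), c["band"], c["slope"])
        for c in doc["covariate_coefficients"]
    ]
    return CohortTruth(config, correlations, coeffs, doc["seed_used"])


def write_cohort(
    sessions: list[SubjectSession],
    participants: pd.DataFrame,
    truth: CohortTruth,
    out_dir: str | Path,
    volumes: bool = False,
) -> list[Path]:
    """Write the cohort as TSV files (plus optional NIfTI volumes).

    Per subject: ``<id>_timeseries.tsv`` (T rows x n_rois columns, header =
    ROI names), ``<id>_motion.tsv`` (T x 6, mm and radians) and
    ``<id>_nuisance.tsv`` (wm, csf).  Cohort level: ``participants.tsv``
    and ``truth.json``.  With ``volumes=True`` each subject additionally
    gets a small 4-D NIfTI rendering (every ROI a 2x2x2 voxel block) and
    the cohort a 3-D integer label image on the same grid.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    names = _roi_names(sessions[0].n_rois) if sessions else []
    for s in sessions:
        ts = pd.DataFrame(s.data.T, columns=names)
        path = out / f"{s.subject_id}_timeseries.tsv"
        ts.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        written.append(path)
        mo = pd.DataFrame(
            s.motion,
            columns=["trans_x", "trans_y", "trans_z",
                     "rot_x", "rot_y", "rot_z"],
        )
        path = out / f"{s.subject_id}_motion.tsv"
        mo.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        written.append(path)
        nu = pd.DataFrame({"wm": s.wm_signal, "csf": s.csf_signal})
        path = out / f"{s.subject_id}_nuisance.tsv"
        nu.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        written.append(path)
    path = out / "participants.tsv"
    participants.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    written.append(path)
    path = out / "truth.json"
    path.write_text(json.dumps(_truth_to_jsonable(truth), indent=1,
                               sort_keys=True))
    written.append(path)
    if volumes:
        written.extend(_write_volumes(sessions, out))
    return written


def _block_layout(n_rois: int) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Assign each ROI a 2x2x2 voxel block on a compact grid."""
    nx = int(np.ceil(np.sqrt(n_rois)))
    ny = int(np.ceil(n_rois / nx))
    shape = (2 * nx, 2 * ny, 2)
    labels = np.zeros(shape, dtype=np.int16)
    for i in range(n_rois):
        bx, by = divmod(i, ny)
        labels[2 * bx:2 * bx + 2, 2 * by:2 * by + 2, :] = i + 1
    return labels, shape


def _write_volumes(sessions: list[SubjectSession], out: Path) -> list[Path]:
    import nibabel as nib

    written = []
    labels, shape = _block_layout(sessions[0].n_rois)
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    lab_path = out / "dmn_labels.nii.gz"
    nib.save(nib.Nifti1Image(labels, affine), lab_path)
    written.append(lab_path)
    for s in sessions:
        vol = np.zeros(shape + (s.n_volumes,), dtype=np.float32)
        for i in range(s.n_rois):
            vol[labels == i + 1] = s.data[i]
        path = out / f"{s.subject_id}_bold.nii.gz"
        nib.save(nib.Nifti1Image(vol, affine), path)
        written.append(path)
    return written


def read_cohort(
    in_dir: str | Path,
) -> tuple[list[SubjectSession], pd.DataFrame, CohortTruth]:
    """Load a cohort written by :func:`write_cohort` (TSV mode)."""
    src = Path(in_dir)
    participants = pd.read_csv(src / "participants.tsv", sep="\t")
    truth = _truth_from_jsonable(json.loads((src / "truth.json").read_text()))
    sessions = []
    for row in participants.itertuples():
        sid = row.participant_id
        data = pd.read_csv(src / f"{sid}_timeseries.tsv", sep="\t").to_numpy().T
        motion = pd.read_csv(src / f"{sid}_motion.tsv", sep="\t").to_numpy()
        nuis = pd.read_csv(src / f"{sid}_nuisance.tsv", sep="\t")
        sessions.append(
            SubjectSession(
                subject_id=sid,
                group=row.group,
                data=data,
                tr_seconds=truth.config.tr_seconds,
                motion=motion,
                wm_signal=nuis["wm"].to_numpy(),
                csf_signal=nuis["csf"].to_numpy(),
                covariates={"MMSE": row.MMSE, "age": row.age, "sex": row.sex},
            )
        )
    return sessions, participants, truth
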