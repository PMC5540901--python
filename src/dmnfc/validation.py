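"""In-silico validation studies of the pipeline.

Because the emulated patient cohort is not publicly available, the
package's claims are validated on simulated cohorts whose ground truth is
known: familywise-error calibration of the network test under null
cohorts, band-specific recovery of implanted effects, sign recovery of
the covariate coupling, agreement of sampled permutation p-values with
exact enumeration, and the band-filter passband/stopband contract.  Each
study returns plain numbers so it can be asserted in tests or reported by
the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import clinical, connectivity, nbs, synthetic
from .bands import CANONICAL_BANDS, get_band
from .preprocess import bandpass_filter


def _seed_offset(seed: int, offset: int) -> int:
    return int((seed * 100_003 + offset) % (2**31 - 1))


def fwe_calibration_study(
    n_cohorts: int = 200,
    n_per_group: int = 10,
    n_permutations: int = 200,
    seed: int = 0,
    band: str = "lfo",
) -> dict:
    """Familywise false-positive rate of the one-sided network test.

    Generates no-effect cohorts, runs the full pipeline (preprocess,
    connectivity, NBS at threshold 3.2) and counts cohorts in which any
    component reaches p_fwe < 0.05.  Under a valid procedure the rate is
    at most the nominal 0.05 up to binomial noise.
    """
    bspec = get_band(band)
    flagged = 0
    for k in range(n_cohorts):
        cfg = synthetic.null_cohort_config(
            n_per_group=n_per_group, band=band,
            seed=_seed_offset(seed, 10_000 + k),
        )
        sessions, part, _ = synthetic.generate_cohort(cfg)
        labels = dict(zip(part["participant_id"], part["group"]))
        mats, _ = connectivity.cohort_connectivity(sessions, [bspec])
        res = nbs.run_nbs(
            [m.z for m in mats],
            [labels[m.subject_id] for m in mats],
            nbs.NbsConfig(n_permutations=n_permutations, tail="less",
                          seed=_seed_offset(seed, k)),
            group_a=cfg.group_a,
        )
        flagged += bool(res.significant_components())
    se = float(np.sqrt(0.05 * 0.95 / n_cohorts))
    return {
        "false_positive_rate": flagged / n_cohorts,
        "n_cohorts": n_cohorts,
        "bound": 0.05 + 2 * se,
    }


def band_recovery_study(
    n_runs: int = 50,
    n_permutations: int = 1000,
    seed: int = 0,
    effect_band: str = "slow-5",
    null_band: str = "slow-3",
) -> dict:
    """Recovery of a band-confined connectivity decrease.

    Each run simulates a study-sized cohort with the six-edge decreased
    subnetwork implanted only in ``effect_band`` and runs the one-sided
    (decrease) network test in both ``effect_band`` and ``null_band``.
    Reports the fraction of runs with a significant component in each.
    """
    eband, nband = get_band(effect_band), get_band(null_band)
    hits_effect = hits_null = 0
    for k in range(n_runs):
        cfg = synthetic.band_recovery_config(
            effect_band=effect_band, seed=_seed_offset(seed, 20_000 + k)
        )
        sessions, part, _ = synthetic.generate_cohort(cfg)
        labels = dict(zip(part["participant_id"], part["group"]))
        mats, _ = connectivity.cohort_connectivity(sessions, [eband, nband])
        for band, is_effect in ((effect_band, True), (null_band, False)):
            ms = [m for m in mats if m.band == band]
            res = nbs.run_nbs(
                [m.z for m in ms],
                [labels[m.subject_id] for m in ms],
                nbs.NbsConfig(n_permutations=n_permutations, tail="less",
                              seed=_seed_offset(seed, k)),
                group_a=cfg.group_a,
            )
            sig = bool(res.significant_components())
            if is_effect:
                hits_effect += sig
            else:
                hits_null += sig
    return {
        "effect_band_rate": hits_effect / n_runs,
        "null_band_rate": hits_null / n_runs,
        "n_runs": n_runs,
    }


def covariate_sign_study(n_runs: int = 50, seed: int = 0) -> dict:
    """Sign recovery of the MMSE coupling on a decreased edge.

    With a positive covariate slope on decreased edges, the pooled
    (patients + controls) Pearson correlation between the edge's Fisher z
    and MMSE should come out positive in nearly every simulated cohort.
    """
    band = get_band("slow-5")
    positive = 0
    for k in range(n_runs):
        cfg = synthetic.CohortConfig(seed=_seed_offset(seed, 30_000 + k))
        sessions, part, truth = synthetic.generate_cohort(cfg)
        mats, _ = connectivity.cohort_connectivity(sessions, [band])
        edge = truth.effect_edges(band="slow-5", direction="decrease")[0].edge
        mmse = dict(zip(part["participant_id"], part["MMSE"]))
        z = [m.z[edge[0] - 1, edge[1] - 1] for m in mats]
        scores = [mmse[m.subject_id] for m in mats]
        assoc = clinical.mmse_correlation(z, scores)
        positive += assoc.r_pearson > 0
    return {"positive_sign_rate": positive / n_runs, "n_runs": n_runs}


def exact_vs_sampled_gap(
    seed: int = 0, n_sampled: int = 5000, t_threshold: float = 3.2
) -> dict:
    """Agreement of sampled permutation p with exact enumeration.

    Builds a 4+4-subject toy (eight-node graphs with a mean shift on a
    connected edge pair), computes the FWE p of the largest observed
    component under exact enumeration of all C(8,4) = 70 label
    assignments, and under ``n_sampled`` random permutations.
    """
    rng = np.random.default_rng(_seed_offset(seed, 40_000))
    p = 8
    iu = np.triu_indices(p, 1)
    shift = np.zeros(len(iu[0]))
    idx = {(a, b): k for k, (a, b) in enumerate(zip(*iu))}
    for e in ((0, 1), (1, 2)):
        shift[idx[e]] = 1.2
    z_all = []
    for grp in range(2):
        for _ in range(4):
            vec = rng.normal(0, 0.4, size=len(shift))
            if grp == 0:
                vec = vec + shift
            m = np.zeros((p, p))
            m[iu] = vec
            z_all.append(m + m.T)
    labels = ["a"] * 4 + ["b"] * 4
    stats = nbs.edge_t_tests(z_all[:4], z_all[4:])
    adj = nbs.suprathreshold_graph(stats, t_threshold, "greater")
    comps = nbs.connected_components(adj)
    k_obs = comps[0].size_k if comps else 0
    exact = nbs.permutation_null(
        z_all, labels,
        nbs.NbsConfig(t_threshold=t_threshold, exact_enumeration=True),
        tail="greater",
    )
    sampled = nbs.permutation_null(
        z_all, labels,
        nbs.NbsConfig(t_threshold=t_threshold, n_permutations=n_sampled,
                      seed=_seed_offset(seed, 41_000)),
        tail="greater",
    )
    p_exact = nbs.fwe_pvalue(k_obs, exact)
    p_sampled = nbs.fwe_pvalue(k_obs, sampled)
    return {
        "p_exact": p_exact,
        "p_sampled": p_sampled,
        "gap": abs(p_exact - p_sampled),
        "n_assignments": int(exact.size),
        "observed_k": k_obs,
    }


def filter_contract_metrics(
    tr_seconds: float = 2.0, n_volumes: int = 2000
) -> dict:
    """Passband gain and one-octave stopband attenuation per band.

    Probes each zero-phase band filter with pure sinusoids: a mid-band
    tone (which must pass within 5% of unity) and tones one octave
    outside each finite band edge (which must be attenuated by at least
    20 dB).  The top band reaches Nyquist, so only its lower edge has an
    outside octave; its passband is probed in the flat region above the
    -6 dB band edge.
    """
    t = np.arange(n_volumes) * tr_seconds
    nyq = 0.5 / tr_seconds

    def gain(band, freq):
        x = np.sin(2 * np.pi * freq * t)
        y = bandpass_filter(x, band, tr_seconds)
        c = np.cos(2 * np.pi * freq * t)
        s = np.sin(2 * np.pi * freq * t)
        return float(np.hypot(2 * np.mean(y * c), 2 * np.mean(y * s)))

    worst_gain_err = 0.0
    min_atten_db = np.inf
    for band in CANONICAL_BANDS.values():
        if band.high_hz >= nyq * (1 - 1e-9):
            center = 0.235  # flat passband region of the half-open band
        else:
            center = band.center_hz
        worst_gain_err = max(worst_gain_err, abs(gain(band, center) - 1.0))
        for probe in (band.low_hz / 2, band.high_hz * 2):
            if probe < nyq:
                g = max(gain(band, probe), 1e-12)
                min_atten_db = min(min_atten_db, -20 * np.log10(g))
    return {
        "max_passband_gain_error": worst_gain_err,
        "min_octave_attenuation_db": float(min_atten_db),
    }
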