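# dmnfc — frequency-dependent default-mode-network connectivity

`dmnfc` is a tested, reusable pipeline for studying how resting-state
functional connectivity of the default mode network (DMN) differs between
two groups — e.g. Alzheimer's disease (AD) patients versus normal controls
(NC) — **as a function of BOLD frequency band**. It is aimed at
neuroimaging researchers who work with ROI-level resting-state fMRI time
series and want a transparent, fully scriptable alternative to GUI
toolboxes, plus a synthetic-cohort simulator so that every stage can be
validated in silico with known ground truth.

## What it computes

Given per-subject ROI-by-time BOLD matrices (or small 4-D NIfTI volumes
with an integer label image), motion parameters and WM/CSF nuisance
traces, the pipeline:

1. **Preprocesses** each session per frequency band: discards the first 4
   equilibration volumes, removes linear trends, applies a zero-phase
   band-pass filter into one of five bands — LFO (0.01–0.08 Hz),
   slow-5 (0.01–0.027), slow-4 (0.027–0.073), slow-3 (0.073–0.198),
   slow-2 (0.198–0.25 Hz at TR = 2 s) — and regresses out the six
   rigid-body motion parameters plus WM and CSF signals (band-filtered
   with the same filter; the global signal is deliberately *not*
   removed). Motion QC computes framewise displacement
   FD_t = Σ|Δd| + r·Σ|Δθ| (r = 50 mm) and DVARS; frames with
   FD > 0.5 mm are censored and high-motion subjects excluded.
2. **Builds connectomes**: for each subject × band, the Pearson
   correlation r_ij between every pair of the 22 DMN ROIs (packaged
   atlas: dorsal DMN, ventral DMN and precuneus subnetworks with MNI
   coordinates), Fisher-transformed to z_ij = atanh(r_ij).
3. **Tests group differences with a network-based statistic (NBS)**:
   pooled-variance two-sample t per edge over all (22·21)/2 ROI pairs;
   edges with t above an uncorrected threshold (default 3.2) form a
   suprathreshold graph; its connected components are scored by extent
   (edge count k), and the familywise error is controlled weakly by the
   permutation null of the maximal component extent (default 10,000
   label exchanges; exact enumeration available for small cohorts):
   p_FWE(k) = #{null max ≥ k} / n_perm. Increased and decreased
   connectivity are two separate one-sided runs.
4. **Associates connectivity with severity**: per-subject composite Z
   (mean z over a component's edges), pooled-group Pearson correlation of
   edge/component Z with MMSE, with exact t-transform p-values (df = n−2).

The **simulator** (`dmnfc.synthetic`) generates cohorts with band-confined
inter-ROI coupling (mixing white noise through the Cholesky factor of a
target correlation matrix, then band-limiting with the analysis filter),
implanted group effects on chosen edges in chosen bands, common-mode
physiological contamination in 0.073–0.25 Hz, WM/CSF nuisance, bounded
random-walk motion (mean FD ≈ 0.3 mm) and an MMSE-like covariate coupled
to realized edge coupling. The ground truth is returned for recovery
testing.

## Worked example

Simulate a study-sized cohort (35 AD vs 27 NC, 200 volumes at TR = 2 s)
in which a connected six-edge subnetwork loses Δρ = 0.4 of its coupling
in the slow-5 band only, then test for decreased connectivity:

```python
import dmnfc
from dmnfc.bands import SLOW5

cfg = dmnfc.band_recovery_config(seed=7)
sessions, participants, truth = dmnfc.generate_cohort(cfg)
mats, qc = dmnfc.cohort_connectivity(sessions, [SLOW5])
labels = dict(zip(participants["participant_id"], participants["group"]))
res = dmnfc.run_nbs([m.z for m in mats],
                    [labels[m.subject_id] for m in mats],
                    dmnfc.NbsConfig(n_permutations=1000, tail="less", seed=1),
                    group_a="AD")
for tail, comp in res.significant_components():
    print(f"decreased component: k={comp.size_k} edges, p_fwe={comp.p_fwe:.4f}")
assoc = dmnfc.associate_all({"slow-5": res}, mats, participants)
```

Output:

```
cohort: 62 subjects; MMSE {'AD': 21.1, 'NC': 27.5}
excluded: 0 | mean FD: 0.29 mm
decreased component: k=5 edges, p_fwe=0.0000
  edges: [(4, 12), (4, 20), (6, 20), (11, 14), (12, 14)]
  band            target     r   p  n
slow-5 component_less_k5 0.802 0.0 62
```

Five of the six implanted edges survive the t > 3.2 threshold and form a
single component whose extent is never reached in 1000 permutations
(p_FWE < 0.001); the composite Z of that component correlates positively
(r = 0.80) with the MMSE-like severity score pooled over both groups —
lower connectivity, lower cognition, mirroring the implanted coupling.
Running the same test in slow-3 finds nothing, as the effect is confined
to slow-5.

The same flow is available from the shell:

```bash
dmnfc run-all --config examples/toy.cfg --seed 7     # or any INI config
dmnfc simulate / preprocess / connect / nbs / associate --help
```

Each run writes per-stage TSV artifacts (QC report, long-format
connectivity, per-band NBS components/null/t-matrix, associations) and a
`manifest.txt` with the config hash, seed and per-file checksums; a rerun
with the same config and seed is byte-identical.

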