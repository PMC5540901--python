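# Methods

This note documents the statistical model behind `dmnfc`, the choices
made where the procedure admits more than one reasonable realization, the
design of the synthetic-cohort simulator, and what simulator-based
validation does and does not establish.

## 1. Band-specific preprocessing

Each subject contributes an ROI-by-time matrix (22 DMN regions × T
volumes, TR = 2 s by default), six rigid-body motion parameters
(translations in mm, rotations in radians) and WM/CSF mean signals.
Stages, in order:

1. **Volume discard.** The first 4 volumes are dropped (magnetisation
   equilibration); data and all confound traces are truncated together,
   so a 200-volume acquisition analyses 196 frames.
2. **Linear detrend**, per ROI (ordinary least squares on an intercept
   plus linear term).
3. **Band-pass filter.** Five bands: LFO 0.01–0.08 Hz, slow-5
   0.01–0.027, slow-4 0.027–0.073, slow-3 0.073–0.198, slow-2
   0.198–0.25 Hz. Default realization: Butterworth of order 2 applied
   forwards and backwards (`sosfiltfilt`, zero phase, effective order 4)
   with odd-reflection padding of at least three periods of the band's
   lower edge. The filtfilt band edge is the −6 dB point; measured on
   pure tones, passband gain is within 0.7% at band centre and
   one-octave-out attenuation is ≥ 27 dB for every finite edge. slow-2's
   upper edge coincides with Nyquist, so it is realized as a high-pass at
   0.198 Hz; its gain reaches unity only above ≈ 0.23 Hz, which is where
   the passband contract is probed. An ideal FFT filter (`mode="fft"`,
   bins outside [low, high] zeroed) is provided as an analytically
   transparent oracle.
4. **Nuisance regression.** OLS residualisation on the 6 motion
   parameters + WM + CSF + intercept. The global mean signal is *not* a
   regressor. Confound columns are detrended and band-filtered with the
   identical filter before regression, so regression cannot reintroduce
   out-of-band variance. A consequence worth knowing: a narrow band at
   T = 196 carries few effective degrees of freedom (slow-5 spans ~7
   complex Fourier bins), and projecting out 9 in-band regressors
   roughly doubles the sampling noise of subsequent correlation
   estimates. This is inherent to the filter-then-regress order and is
   the main power limit of the narrowest bands at this scan length.

**Motion QC.** FD_t = Σ|Δtranslations| + 50 mm · Σ|Δrotations|
(FD_0 = 0); DVARS_t = RMS over ROIs of the backward difference
(DVARS_0 = 0, unnormalised). Frames with FD > 0.5 mm are censored and
removed (the same frame set for all ROIs of a subject) before
correlation. A subject is excluded when more than 25% of frames are
censored or mean FD exceeds 0.5 mm; both thresholds are configurable.
The exclusion rule is a package choice — a per-subject rule had to be
fixed, and this one reproduces the intended behaviour (a high-motion
"mover" is excluded, ordinary subjects are not).

## 2. Connectivity

Pearson correlation over uncensored frames (at least 10 required),
Fisher z = atanh(r) with |r| clipped at 1 − 1e−7 so degenerate synthetic
inputs stay finite. Matrices are symmetric; the z diagonal is stored as
0 and never used. In volume mode, ROI series are voxel means over an
integer label image; the packaged atlas defines 6 mm spheres at the 22
MNI centres for constructing such label images.

## 3. Network-based statistic

Per edge, a pooled-variance two-sample t (df = n_A + n_B − 2; positive t
means group A > group B; a Welch option exists but is not the default).
Edges with t strictly above the threshold (default 3.2) form the
suprathreshold graph; connected components are found by union-find and
scored by extent k (edge count). The null of the maximal extent is built
by randomly permuting the group-membership vector (group sizes
preserved, duplicates allowed, the observed labelling not
force-included); each permutation's labels derive deterministically from
the seed and the permutation index, so results are reproducible and
permutation-parallelisable, and relabelling the groups exchanges the two
one-sided runs exactly. p_FWE(k) is the plain proportion of null maxima
≥ k (an add-one smoothing option exists, off by default — with it, a
component beyond every null maximum reports 1/(n+1) instead of 0).
Exact enumeration of all C(n, n_A) assignments replaces sampling on
request (refused above 200,000 assignments). Increased and decreased
connectivity are tested as two one-sided runs at t > 3.2, each against
its own max-extent null, mirroring separate reporting of decreases and
increases; note the familywise rate across *both* runs is then bounded
by 0.10, not 0.05, so calibration statements are per run.

With 22 ROIs the enumerator tests (22·21)/2 = 231 unordered pairs.

## 4. Clinical association

For each significant component, per-subject composite Z = mean z over
its edges; group comparison by pooled t; association with MMSE by
Pearson correlation pooled over both groups (per-group optional), p from
the exact t transform with df = n − 2. No multiple-comparison
correction is applied at this stage: the targets were already selected
by the FWE-controlled network test, and the association p-values are
descriptive.

## 5. The simulator

**Signal model.** For band b with target correlation matrix R_b (unit
diagonal), the band component is S_b = filter_b(L_b E), where
L_b L_bᵀ = R_b (Cholesky) and E is white Gaussian noise per ROI. Because
the mixing is frequency-flat and every ROI is filtered identically, the
population correlation of the band component equals R_b exactly — with
the ideal filter the confinement is exact; with the Butterworth default,
adjacent bands share a few percent of skirt energy at their common edge.
Rows are rescaled to per-band amplitudes (1.0, 0.8, 0.5, 0.35 for
slow-5…slow-2 — a 1/f-like profile; the true amplitude ratios of real
data are unknown, and these are free parameters, not estimates).
Cross-band components are independent. On top of the band components the
generator adds, per subject:

- a common-mode physiological trace (FFT-masked white noise, ≥ 95% of
  spectral mass confined to 0.073–0.25 Hz by construction, amplitude
  0.4) added identically to all ROIs — this inflates slow-3/slow-2
  correlations and models respiratory/cardiac contamination;
- WM- and CSF-like AR(1) traces coupled into every ROI (weight 0.2),
  white measurement noise (SD 0.2), and a random per-ROI linear drift;
- bounded random-walk motion: step SD 0.08 mm (translations) and
  0.0008 rad (rotations), reflected at ±2 mm / ±0.02 rad, calibrated to
  mean FD ≈ 0.29 mm (the emulated study reports ≈ 0.27–0.35 mm); a
  "mover" option scales steps ×4 to exercise exclusion;
- signal scaling to BOLD-like units (baseline 1000, scale 25), which
  puts DVARS near 30.

**Group effects.** Effects modify designated edges of R_b in designated
bands for group A only (decrease or increase by Δρ). Baselines default
to 0.45 in every band; per-edge baseline overrides model hub edges that
are stronger than background in both groups. The target matrices are
eigenvalue-clipped to the nearest correlation matrix if an implant
violates positive semidefiniteness; the truth object always records the
*actually generated* couplings. Geometry constrains implants: an exact
Δρ decrease on k edges sharing a node needs baseline < 1 − Δρ·√k.

**Default effect pattern** (the emulated study conditions): in slow-5,
two decreased long-range edges sharing the left angular gyrus and two
increased short-range edges sharing the left inferior parietal lobule
(Δρ = 0.4 / 0.3); in slow-4, two decreased edges sharing the right
middle frontal gyrus (Δρ = 0.4); nothing in slow-3/slow-2.

**Recovery-study configuration** (`band_recovery_config`): a connected
six-edge path of long-range hub edges (coupling 0.6 in both groups
against a 0.25 background) loses exactly Δρ = 0.4 in patients, confined
to one band. Rationale: with T = 196 and the filter-then-regress
pipeline, per-edge detection power at t > 3.2 is ≈ 0.7–0.8, so reliable
(> 90%) component recovery needs an extended effect; a several-edge
decreased subnetwork is realistic for the emulated disease contrast,
and the elevated healthy coupling encodes that it is the strong
long-range connections that decline. Recovery is assessed with the
one-sided (decrease) run, matching the implanted direction.

**Covariate.** MMSE = 28.5 + 20 · mean_e[sign_e · (proxy_e −
healthy_e)] + N(0, 1.5²), where proxy_e is the subject's realized
band-limited sample correlation on tagged edge e, healthy_e the
control-group population coupling, and sign_e is +1 for decreased / −1
for increased edges. Healthy subjects centre near 28.5; patients lose
≈ 7–8 points through their connectivity deficit, and the pooled edge-z ↔
MMSE correlation has the implanted sign (positive on decreased edges,
negative on increased ones). This is the generic "severity tracks
connectivity loss" coupling in an affine parameterisation whose
intercept is the healthy mean.

**Determinism.** Per-subject RNG streams are spawned from the cohort
seed (`SeedSequence.spawn`), so the same config + seed reproduces a
cohort bit-for-bit across processes; neighbouring seeds give independent
cohorts.

## 6. What the validation studies show — and what they do not

The validation suite (also run by `scripts/acceptance.py`) establishes,
on simulated cohorts:

- **Calibration**: across 200 null cohorts (10 + 10 subjects, 200
  permutations, one-sided run) the familywise false-positive rate stays
  within binomial tolerance of the nominal 0.05.
- **Oracle agreement**: sampled permutation p matches exact enumeration
  (C(8,4) = 70 assignments) within 0.03; component extents match
  brute-force transitive closure on all random 6-node graphs tried.
- **Band-specific recovery**: the slow-5-confined decrease is detected
  in ≈ 95–100% of 50 study-sized cohorts and essentially never in
  slow-3.
- **Covariate sign recovery**: the pooled MMSE–z correlation on a
  decreased edge is positive in ≈ 100% of cohorts.
- **Filter contract**: ≤ 5% passband gain error, ≥ 20 dB one-octave
  attenuation.

Problem sizes (200/50/50 cohorts, 200–1000 permutations) were chosen so
the whole suite runs in minutes on one core while leaving the binomial
tolerances meaningful.

These results show the *procedure* is correct and calibrated under the
generative model. They do not show that real AD cohorts have such
effects: the simulator's between-subject variance is purely sampling
noise (no biological heterogeneity), its nuisance structure is a
caricature (no hemodynamic response convolution, spatial autocorrelation,
scanner drift beyond a linear term, or realistic motion artifacts in
volume space), the covariate coupling is exact by construction, and the
ROI atlas stands in spheres for the original probabilistic masks.
Findings on real data additionally depend on acquisition and
registration choices that are out of scope here.

## 7. Numerical details

- Correlations clipped at |r| ≤ 1 − 1e−7 before atanh.
- Edges whose pooled variance is zero up to floating-point noise
  (se² ≤ 1e−14 · max(1, m_A² + m_B²)) get t = 0 with a warning.
- Ties at exactly t = threshold are excluded (strict inequality).
- Rank-deficient confound matrices fall back to the minimum-norm OLS
  solution with a logged warning; constant filtered confound columns are
  dropped.
- PSD repair of target correlation matrices clips eigenvalues at 1e−6
  and renormalises the diagonal.
- TSV floats are written with `%.10g`, making repeated runs
  byte-identical; the manifest records SHA-256 checksums per artifact.
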