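# Methods

This note records the models, conventions and design decisions behind
`boldqc`, in the order data flows through the package.

## Data model and conventions

All voxel-indexed arrays share one ordering: the C-order raveled indices of
the brain mask's `True` voxels. A `Timeseries4D` is the dense
`(voxel, frame)` array over that ordering, with voxel spacing in mm and the
repetition time (TR) in seconds. TR precedence is explicit override first,
NIfTI header second — rodent headers frequently carry wrong or zero TR.
Rotations are radians internally; degree input is converted at read time.
Censoring state is a full-length boolean `TemporalMask`; composing two
masks is logical AND, which is commutative and idempotent, so no step
ordering can silently double-censor.

## Confound correction workflow

Steps are applied strictly in the order: censoring → detrending →
ICA-based motion-component removal → (simulation of censored frames +
Butterworth filtering + edge trimming + re-censoring) → nuisance
regression → intensity scaling (→ optional variance standardisation) →
spatial smoothing. Censoring runs first so signal spikes cannot bias the
later fits; filtering runs on a full-length series with censored frames
simulated so the IIR filter never sees gaps, and the censoring mask is
re-applied afterwards. Every step except linear detrending is optional.

**Framewise displacement.** The motion trace is summarised as the sum of
absolute backward differences of the six rigid parameters, with rotations
converted to arc length at a configurable head radius (default 5 mm, a
rodent-scale head). The censoring rule masks each supra-threshold frame
together with 1 preceding and 2 following frames; out-of-range neighbours
at the series boundaries are simply omitted. The baseline preset threshold
is 0.05 mm; there is deliberately no silent default — the value is always
explicit in the options and echoed to the manifest.

**DVARS.** Root-mean-square over in-mask voxels of the backward temporal
difference, computed on the data as it enters censoring (no percent
normalisation — downstream use z-scores it anyway). Frame 0 carries the
artificial value 0, is excluded from the z-scoring population and is never
censored by the DVARS rule. Censoring is iterative: z-score the retained
frames, drop z > 2.5, repeat until a pass removes nothing; a zero standard
deviation terminates the loop.

**Detrending.** Per-voxel OLS on {1, t_c} (plus t_c² for quadratic), with
the time regressor mean-centered over the *retained* frames, so the fitted
intercept equals the voxel's retained-frame mean. That intercept is reused
for mean-based intensity scaling. The trend prediction is subtracted at all
frames, keeping the full-length series consistent for the later simulation
step.

**Simulation of censored frames.** Per voxel, the retained samples'
spectral content is estimated with the Lomb-Scargle per-frequency
amplitude estimates (the classical tau-shifted cosine/sine projections) on
a frequency grid from 1/(span·oversampling) up to Nyquist, oversampling
factor 4 by default. The summed sinusoid reconstruction is rescaled so its
standard deviation over retained frames matches the observed one (the
per-frequency estimates alone underestimate broadband power), the mean is
restored, and retained frames keep their observed values exactly. The
procedure is deterministic given the data — no random phases are drawn —
which keeps whole-workflow runs reproducible without seed bookkeeping.

**Filtering.** Zero-phase (forward-backward) 3rd-order Butterworth via
second-order sections; zero-phase application avoids phase-distorting
network timecourses. After filtering, `floor(30 s / TR)` frames are
trimmed at each end against edge ringing (25 frames at TR = 1.2 s). Edge
trimming is tied to filtering: with no cutoffs requested the values pass
through unchanged and no frames are trimmed.

**Nuisance regression.** β = OLS(X, Y), Y_CR = Xβ, Ŷ = Y − Y_CR per voxel.
Motion-derived columns are built full-length and pushed through the
identical censoring/detrending/filtering as the data; tissue-derived
columns (WM/CSF/global means, aCompCor) are extracted from the processed
data itself, which already carries that state. aCompCor takes the first 5
principal components of the combined WM+CSF voxel timeseries; components
are unit-normed, mutually orthogonal, sign-fixed by positive loading sum.
A rank-deficient design raises an error naming the collinear columns.

**Intensity scaling.** Grand-mean: divide by the brain-wide mean of the
detrending intercepts, ×100 (%BOLD). Voxelwise-mean: the same per voxel.
Global-SD: divide by the total SD over all in-mask values. Voxelwise
z-scoring: divide each voxel by its own SD (zero-SD voxels are carried as
zeros and excluded from denominators).

**Variance standardisation** (distinct from z-scoring): each voxel is
divided by its SD, then the whole series is rescaled so the total 4D SD
equals its pre-operation value — the variance distribution is flattened
without changing the overall intensity scale.

**Smoothing.** Per-frame 3D Gaussian with σ = FWHM/2.3548 per axis in
voxel units; the kernel is renormalised inside the brain mask
(`smooth(data·mask)/smooth(mask)`), conserving in-mask mass near the
boundary.

**Bookkeeping.** Scans whose censoring removes more than 1/3 of frames are
flagged excluded. Temporal degrees of freedom are recorded as
`retained frames (after censoring and edge trimming) − regressor count −
detrending order − 1`; tDOF is used only as a QC covariate, so this
accounting convention is stated rather than derived.

## Rodent motion-component classification

Works on any spatial ICA decomposition providing maps and timecourses; a
FastICA backend (spatial sources, seeded) is included for tests and small
studies. Four features per component: maximum absolute correlation of the
component timecourse with the 6 motion parameters and their backward
differences; fraction of (DC-excluded) spectral power above a
high-frequency cutoff; fraction of absolute spatial weight inside the CSF
mask; the same inside the brain-edge mask (mask minus its k-fold erosion,
k = 1 by default). A component is motion iff
`csf_fraction > θ_csf OR hf_fraction > θ_hf OR w·(edge_fraction,
motion_corr) + b > 0`. Removal is non-aggressive: all component
timecourses are regressed jointly and only the motion-labelled
contribution is subtracted, which leaves variance along non-motion
timecourses untouched when timecourses are orthogonal.

Defaults: high-frequency cutoff 0.2 Hz (rodents express higher BOLD
frequencies than humans, particularly under medetomidine), θ_csf = 0.10,
θ_hf = 0.35, hyperplane (1, 0)·x − 0.5 (flagging components with more than
half their weight at the brain edge). These are conservative shipped
defaults, not trained weights; they are echoed into every manifest and
users with labelled components should retrain and supply their own.

## Connectivity

Seed maps are plain Pearson r of each voxel against the unweighted mean
seed timecourse; parcel matrices cross-correlate unweighted parcel mean
timecourses, ordered by label, with empty parcels dropped with a warning.
Dual regression: stage 1 regresses the prior maps (plus intercept,
restricted to in-mask voxels) against each frame, giving one timecourse
per component; stage 2 scales those timecourses to unit SD and regresses
them (plus intercept) against each voxel, so the β maps carry network
amplitude. Intercepts are included at both stages. With orthonormal priors
and noise-free mixtures the two stages invert the mixing exactly. Group
ICA concatenates corrected scans in time and runs the pluggable ICA
backend; component labels start as "other" for manual assignment.
Canonical maps are built as the voxelwise median across scans.

## Quality control

Scan level: network specificity smooths both the scan map and the
canonical map at 0.3 mm FWHM, thresholds each to the top 4% of in-mask
voxels (`ceil(0.04·N)`, ties broken by voxel index; absolute values for
dual-regression maps, signed values optional for seed maps) and takes the
Dice overlap. Confound correlation is the mean absolute Pearson r between
the network timecourse and each confound-component timecourse from the
same dual regression. Inclusion gates: retained fraction ≥ 2/3, Dice
> 0.4, correlation < 0.25; then amplitude outliers are removed with the
iterative modified z-score (0.6745·(x − median)/MAD > 3.5; MAD = 0 stops
the loop). All thresholds are presets, overridable, and recorded.

Group level: when at least 8 scans pass the scan gates, group measures use
the passers (`thresholds_applied = True`); otherwise all scans, flagged.
The variability map is the voxelwise cross-scan SD of connectivity,
smoothed, top-4% thresholded and compared with the canonical network by
Dice (preset gate 0.38). Effect maps correlate connectivity across scans
with mean FD (scalar), tDOF (scalar) and the confound-regression SD map
(voxel-matched); the summary is the maximum absolute mean correlation
inside the thresholded canonical network (preset gate 0.25). The in-network
mean uses the smoothed-and-thresholded canonical mask — the same object the
variability Dice uses — rather than a raw-map mask.

The stepwise optimiser starts from the minimal baseline (FD censoring at
0.05 mm + 6 motion parameters; detrending and grand-mean scaling always
on) and tries candidates in a priority order (variance standardisation,
DVARS censoring, 24-parameter motion regression, WM/CSF regression,
aCompCor, global signal regression, highpass, ICA-based removal), keeping
a candidate only if its score tuple strictly improves; evaluator failures
skip the candidate and are logged. The evaluator is caller-supplied — the
package deliberately does not hard-code what "better" means beyond the
default (number of scans passing inclusion).

## Synthetic phantoms

Default conditions: 16×16×8 voxels at 0.2 mm, TR 1.2 s, 200 frames —
small enough for seconds-scale tests, large enough for 0.3 mm-FWHM
smoothing to span multiple voxels. The brain is an ellipsoid with a
central CSF "ventricle", a WM ring and a 1-voxel edge band; parcellation
is by quadrant. Networks are compact Gaussian blobs (σ = 1.5 voxels) with
band-limited 0.01–0.1 Hz unit-SD timecourses at amplitude 3 on a baseline
of 100 — about 3% BOLD, the upper end of realistic rodent network
amplitudes — over ~1% thermal noise. Linear drift (±2 intensity units per
scan) and brain-wide smooth-field structured noise (coherent
physiological/scanner fluctuations) complete the background.

Motion is stationary white jitter around a fixed restrained pose (position
SD 0.0008 mm / 0.00015 rad) plus a permanent step displacement of 0.08 mm
at each spike frame, so framewise displacement exceeds the 0.05 mm preset
at exactly the planted frames; a one-frame intensity artefact accompanies
each spike. A random-walk background was deliberately rejected: regressing
random-walk motion traces spuriously removes genuine low-frequency network
variance, which is an artefact of that motion model rather than of the
data regime being emulated.

Confound components come in four archetypes sharing three idealised prior
signatures (CSF indicator, edge band, radially graded global profile):
CSF- and edge-localised components are modulated by a smooth random field
(planted expression ≠ prior), the "global" archetype is grey-matter
weighted (physiological fluctuations express in tissue, while the prior is
the crude brain-wide profile), and "global_uniform" is the brain-wide
profile modulated by a smooth field (a scanner-level artefact). The
prior/planted mismatch is essential: dual regression separates a confound
perfectly when its prior matches its expression exactly, which real
atlas-derived priors never do, and the mismatch is what lets confound
variance leak into network read-outs in spurious scans.

The four category fixtures differ in which components are planted *and* in
noise structure, because the categories are distinct data-quality regimes:
"specific" plants networks over modest structured noise; "absent" plants
no networks and strong structured noise (scans with undetectable networks
are dominated by coherent physiological fluctuations — with purely i.i.d.
noise, dual regression would still return the prior's shape, a known bias
of the method); "spurious" plants confounds at amplitude 4 over a quiet
background; "mixed" plants both.

What the phantoms do **not** emulate: biophysical hemodynamics (no balloon
model), scanner noise spectra and drifts beyond linear, spatial
autocorrelation of thermal noise, susceptibility distortion, and any
registration error — the package assumes registration upstream. Passing
tests on phantoms therefore validate the *computational contracts* (rules,
estimators, orderings, thresholds), not end-to-end performance on real
scanner data.

The group-level fixture plants connectivity linear in mean FD
(`map_i = canonical·(1 + g·(FD_i − mean FD)) + noise`); its permutation
null uses the matching g = 0 fixture, in which the across-scan variation
is independent noise — the condition under which the in-network mean
effect correlation should concentrate near zero.

## Numerical choices and degenerate inputs

OLS solves use `lstsq` (SVD); rank checks precede regressions that promise
error messages. Zero-variance voxels are carried as zeros and excluded
from correlation/z-score denominators. Dice of two empty masks is defined
as 0. Top-fraction thresholding keeps `ceil(f·N)` voxels with a stable
sort, so ties resolve by voxel index deterministically. The FastICA
backend is seeded; the Lomb-Scargle reconstruction is deterministic; CLI
runs are byte-reproducible from their manifest.

## Known limitations

- The shipped motion-classifier thresholds and hyperplane are untrained
  placeholders; real deployments should retrain on labelled components.
- tDOF uses a stated accounting convention, not an effective-dof estimate
  (filtering-induced autocorrelation is ignored).
- Lowpass filtering is supported mechanically but the QC thresholds were
  not designed for it (lowpass inflates temporal autocorrelation and the
  scan-level correlation metric).
- The scan-category thresholds (0.4, 0.25, 0.38, 8 scans) are presets that
  should be re-derived per study; they do not blindly generalise.
- Group ICA through the FastICA backend is adequate for phantoms but not a
  substitute for a dedicated decomposition on real data; the interface is
  pluggable for that reason.
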