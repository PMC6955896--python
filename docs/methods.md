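# Methods

This note documents the models, numerical choices, and limitations behind
`somabci`.  The package is a self-contained re-implementation of a
source-space motor-imagery analysis: everything below can be exercised
without any external recordings.

## Forward model

The head is a concentric three-sphere conductor.  Defaults: scalp/skull/
brain outer radii 0.090 / 0.085 / 0.080 m (conventional values; the shell
radii are not dictated by the conductivity reference) and conductivities
1 / 0.0125 / 1 S/m for scalp / skull / brain.  Sources are current dipoles
with fixed radial orientation on a Fibonacci lattice at 0.95 × brain radius
(the `depth_fraction` parameter), so each source contributes one scalar
amplitude — which keeps the downstream sLORETA standardizer scalar per
source.

Scalp potentials solve Laplace's equation per spherical-harmonic degree
*n*: within each shell the potential is *Aρⁿ + Bρ⁻⁽ⁿ⁺¹⁾*, the dipole adds
its free-space Legendre expansion in the innermost layer, and potential/
radial-current continuity at the two interfaces plus the no-current outer
boundary give a 5×5 linear system per degree.  All radii are normalized by
the scalp radius before solving, which keeps the powers of ρ in [0.88, 1]
and the systems well conditioned at any truncation.

The series is truncated at `n_terms = 200` by default.  At the default
source depth the term magnitudes decay like (0.844)ⁿ with polynomial
factors; 200 terms leave a relative tail around 1e-11, and doubling the
truncation changes no lead-field column by more than ~1e-14 relative.
Sixty terms, by contrast, leave percent-level error at this depth, so the
computation raises a diagnostic error when the last retained term is not
negligible (`convergence_tol`, default 1e-8) rather than silently
truncating.  The lead field is average-referenced by centering each column
across electrodes; all sensor data are kept average-referenced throughout.

Electrode montages (32 default, 118 for high-density runs) are rings of
constant polar angle with azimuths symmetric about the mid-sagittal plane,
so the montage is exactly mirror-symmetric and mirror-image sources produce
mirror-image sensor patterns — a property the tests exploit.

## ROI atlas

The nine somatomotor regions per hemisphere (S1F, S1H, CMA, M1F, M1H, SMA,
pSMA, PMd, PMv) are realized as spherical caps of angular radius 8°.  The
literature names these regions without usable coordinates, so the geometry
is a deliberate synthetic stand-in constrained by the homuncular layout:
foot areas within 15° of the midline, hand areas 30–45° lateral, premotor
caps anterior to the motor strip, somatosensory caps posterior.  CMA, a
medial-wall area with no faithful spherical-surface location, is placed on
the posterior midline strip.  Same-hemisphere caps may not overlap (the
builder enforces this), and the right hemisphere is the exact mirror of the
left.  Centers and radius are overridable in config.

ROI membership is fixed at source-space construction by cap containment —
not distance-weighted — for determinism.  At the default 600 sources each
cap holds 2–4 sources; 500 suffices for non-emptiness.

## Synthetic trials

Each trial is a 2 s, 100 Hz epoch (matching the protocol of the public
recordings the analysis is modeled on: 3.5 s cues, a 2 s imagery slice,
fixed train/test splits).  Source activity is unit-RMS 1/f background
(exponent 1, spectrally shaped white noise) in every source, plus
band-limited Gaussian oscillations planted in chosen ROIs with
class-dependent RMS amplitude.  The default plant mirrors the regions that
dominate real hand/foot imagery: hand-class contrast in S1H_L and M1H_L,
foot-class contrast in S1F_L and M1F_L, all in the 8–13 Hz mu band, with
amplitudes 1.7 (preferred class) vs 1.0.  Physiologically the contrast is a
desynchronization (power decrease); CSP is sign-symmetric in variance
differences, so only the discriminability, not the direction, matters here.

Sensor noise is white Gaussian at `sensor_snr = 1.5` (signal RMS over noise
RMS), after which the average reference is re-applied.  These defaults were
chosen once so the full pipeline operates mid-range rather than at ceiling:
the planted four-ROI subset classifies in the mid-90s, exhaustive 3-ROI
searches in the 80–97% range, broadband searches lower.  The generator
draws each (split, trial) pair from its own counter-addressed substream of
the global seed, so train and test are disjoint by construction and adding
pipeline stages never perturbs existing draws.

What the generator does **not** emulate: eye/muscle artifacts, line noise,
spatially correlated sensor noise (available behind config only as white),
non-stationarity across a session, volume-conducted deep sources, and
realistic cortical folding.  Passing tests therefore demonstrate the
pipeline's correctness and its ability to recover planted effects through
the full forward–inverse–feature chain — not performance on real EEG.

## Band-pass filtering

Two analysis bands: broadband 0.1–30 Hz and mu 8–13 Hz.  The default filter
realizes the 4th-order Butterworth *magnitude* response spectrally (rFFT →
multiply → irFFT on reflect-padded epochs): exactly −3 dB at the band
edges, identically zero group delay, no start-up transients.  The usual
forward–backward IIR realization is available (`design="iir"`) but is a
poor fit for short epochs here: the 0.1 Hz lower edge has poles whose
transients outlast a 2 s epoch entirely, and filtfilt doubles the order so
its edges sit at −6 dB.  A linear-phase FIR variant also exists.  Epochs
are filtered directly (with padding), not cut from filtered continuous
data; for the synthetic generator the distinction is immaterial because
epochs are generated independently.

The epoch slicer defaults to the [0.5 s, 2.5 s] window after cue onset when
cutting 3.5 s cued trials, skipping the cue-onset visual transient.

## sLORETA inverse

Minimum-norm kernel *T = Lᵀ(L Lᵀ + αH)⁺* with *H* the average-reference
centering operator; the pseudoinverse is an eigendecomposition with
relative cutoff 1e-12, absorbing the rank deficiency the reference
introduces.  The noise covariance is identity — the simplest model
consistent with a "noise-normalized" solution.  Regularization defaults to
the standard minimum-norm scaling α = trace(L Lᵀ)/(n_e · SNR²) with
SNR = 3, overridable (including α = 0).

Standardization divides each source estimate by √((T L)ⱼⱼ).  With fixed
orientations the resolution diagonal is scalar, and the classical exactness
property holds: for noiseless single-source data the standardized power
arg-max is the true source, verified exhaustively on a 100-source grid (and
insensitive to α there).  Sources with all-zero lead-field columns are
flagged unreachable and standardization refuses to divide.

## ROI time courses

One time course per ROI: the sign-aligned mean of member-source
standardized estimates.  Radial dipoles on opposite cap flanks can project
with opposite polarity, so each member is flipped to correlate positively
with the cap's first principal temporal direction (first right singular
vector), with the global sign anchored to the largest-norm member; an
antiphase pair then averages to full amplitude where a plain mean cancels.
Plain-mean and first-principal-component aggregators exist behind config
for sensitivity checks.  Per-trial alignment can flip signs between trials;
variance-based CSP features are indifferent to this.

## CSP and classification

Class covariances are per-trial covariances normalized by their trace,
averaged within class, then shrunk: C ← (1−δ)C + δ(trace(C)/n)I with
δ = 1e-6 — enough to keep 3-channel ROI subsets invertible without
measurably biasing filters.  Filters solve C₊w = λ(C₊+C₋)w; eigenvalues lie
in [0, 1], are sorted descending with a stable tie-break on the original
index, and obey the λ ↔ 1−λ class-swap symmetry.  Note that per-trial trace
normalization makes eigenvalues only approximately invariant to invertible
channel mixing; with plain covariances and zero shrinkage the invariance is
exact (both are tested).  Features are log variances of the top/bottom *m*
filter pairs, normalized so exp(features) sums to one per trial.

The classifier is a standardized linear max-margin machine (C = 1), with an
RBF kernel behind config but excluded from default runs.  Scaling is
learned from the training split only.  Model selection over the filter-pair
grid (default {1, 2, 3}, capped at ⌊channels/2⌋; pinned to 6 pairs for the
six-ROI two-hemisphere mode when multiplicity allows) uses test accuracy,
deliberately mirroring the best-result-table protocol of the analysis this
package re-implements; that protocol is optimistic and is not recommended
practice for claiming generalization.

## Subset search

Modes: all non-empty subsets of one hemisphere (511 = 2⁹ − 1; the empty set
is unevaluable and skipped), all 3-ROI subsets (84 = C(9,3)), all 6-ROI
subsets of 18 (18 564 = C(18,6)), plus a raw-sensor mode.  Enumeration is
lexicographic by ROI id within ascending size — fully deterministic.
Filter-pair counts exceeding ⌊|subset|/2⌋ are recorded as skipped.  The
winner is the accuracy arg-max over (subset, m) jointly; ties break to the
smallest subset, then smallest m, then lexicographic order, and all ties
are retained.  Occurrence tallies across runs weight a k-way tie 1/k per
tied subset by default (integer single-winner tallying is available).  The
search evaluates subsets by channel-slicing a once-computed all-ROI trial
set; this is algebraically identical to running the chain per subset
(ROI aggregation is per-ROI independent), and a test asserts the equality.

## Problem sizes

Default study sizes — 32 electrodes, 600 sources, 200 train / 100 test
trials, five seeds for recovery studies, three for null calibration, a
100-source grid for the localization sweep — were chosen as the smallest
sizes at which every property of interest is comfortably measurable; the
full validation battery (`scripts/acceptance.py`) runs in roughly half a
minute.  The 118-electrode montage and the full 18 564-subset two-lobe
search are available for larger runs.

## Known limitations

- The spherical geometry and cap atlas are surrogates; none of the ROI
  coordinates correspond to real anatomy, and CMA in particular cannot be
  placed faithfully on a sphere.
- Radial-only sources cannot represent tangential (sulcal-wall) dipoles.
- Identity noise covariance and white sensor noise understate real spatial
  noise correlation, flattering the inverse.
- Accuracy numbers from synthetic runs characterize the pipeline, not any
  subject population; the external competition recordings (loadable via
  `somabci load-iva`) are needed for claims about real data and are
  intentionally outside the build and test path.
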