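# Methods

This note documents the models, parameters and design choices behind
`shapenum`, and what its simulation-based validation does and does not
establish.

## Stimulus model

Stimuli are truncated Gaussian luminance blobs (σ = 0.08 deg of visual
angle, contrast 0.90 against a 65.5 cd/m² mid-gray background, viewing
distance 100 cm) placed inside a circular area of 8 deg diameter. The
element *size* is taken as the truncation extent, 5σ = 0.4 deg, so the
minimum-spacing rule "twice the element size" becomes a 0.8 deg centre
distance; this reading makes the truncated disks non-overlapping with zero
margin, which is the most literal interpretation of an overlap-avoidance
rule. Virtual shapes are regular polygons on the circle of radius 4 deg
(the 8 deg area read as the circumscribed circle, which keeps vertex and
random conditions size-matched); the first vertex sits at the top for zero
orientation and each trial draws an orientation uniformly in [0, 2π).

Three placement rules cover the three experiment families:

- *vertex*: elements exactly on the polygon vertices;
- *contour*: elements uniform on the polygon's boundary path, excluding a
  keep-out radius of 0.8 deg around each vertex ("not on the vertices"
  needs a finite zone; we reuse the spacing constant so contour elements
  can never be confused with vertex elements perceptually);
- *interior*: elements uniform over the closed triangle (area plus
  boundary), used by the triangle-sampling experiments, with the same
  keep-out zones when the condition forbids vertex placement.

All random placement is rejection sampling (bounded at 10,000 attempts per
element, then an infeasible-geometry error), which is exactly uniform
conditional on the constraints. Mixed luminance polarity draws fair coins
per element and resamples degenerate all-equal vectors; "same polarity"
conditions resolve to all-white or all-black by a per-trial fair coin (the
white/black mixing ratio is not otherwise constrained). Schedules present
each of the 8 conditions `reps` times (default 100 → 800 trials) in a
seeded random permutation; per-trial layout seeds are split from the master
seed so any trial is independently reproducible.

## Synthetic recording model

The simulated montage holds 64 extended 10–20 electrodes (positions from
the standard 10-05 description, normalized to the unit sphere) referenced
to CZ, plus one VEOG channel. Evoked activity is a sum of three fixed
generators:

- N1: midline occipital negativity, Gaussian time course inside
  160–220 ms;
- N2: lateral posterior negativity with right-hemisphere dominance,
  Gaussian time course inside 250–400 ms;
- LMF: left fronto-central positivity, raised-cosine plateau spanning
  400–650 ms.

Templates are average-referenced and unit-GFP; the N2–LMF spatial
correlation is 0.35, low enough for segmentation to separate the
generators. Planted per-condition amplitudes are *defined* as the mean
amplitude over the component's analysis window and electrode set: a small
linear system over the three generators (and the topographic admixture
below) is solved per condition so that the extracted window means equal the
amplitude table exactly in the noise-free case. The default table encodes
the qualitative effect structure of the paradigm: the N2 negativity is
~1.5 µV deeper for shape than random configurations (and ~1 µV deeper for
different- than same-polarity stimuli in the polarity experiment); LMF
amplitude orders 3 (3.0 µV) > 4 (2.2) > 5 (1.5) ≈ 6 (1.45) and ignores
polarity; accuracy falls and RT rises with numerosity, with a
shape advantage (+3 points accuracy, −40 ms RT).

Strength differences alone are invisible to topographic tests, so the
configuration effect also has a map-shape component: in shape conditions
the N2 window carries a 1.2 µV admixture of the N1-map generator. This is
the simulation's analogue of the empirical observation that an early map
re-expresses itself during the N2 period preferentially for shape
configurations, and it is what the TANOVA detects (the numerosity contrast
is deliberately amplitude-only, so its TANOVA stays null in simulation).

Background noise is AR(1) in time (coefficient 0.97) with spatial
covariance decaying exponentially with inter-electrode great-circle
distance (scale 1 rad) and stationary SD 8 µV — a minimal model that
produces realistic GFP fluctuations. Blinks are a fixed 400 ms biphasic
waveform on VEOG (~250 µV, Poisson rate 0.15 Hz) propagated to each
channel with coefficients 0.03 + 0.35·exp(−d/0.8) of the angular distance
from the frontal pole. Gross artifacts are 120 µV, 50 ms pulses on a
random channel in a configurable fraction (default 5%) of trials. Trials
are spaced 1,100 ms (100 ms stimulus + 1,000 ms blank) plus 0–100 ms
jitter. Behaviour is Bernoulli accuracy and shifted-lognormal RT
(shift 180 ms, σ 0.22) per condition.

What this generator does *not* emulate: 1/f spectra beyond AR(1), muscle
and line noise, channel drop-out, latency jitter of components across
trials and subjects, and any nonlinear interaction between configuration
and numerosity. Passing recovery tests therefore shows the analysis chain
is correct and well-calibrated, not that it would be similarly powerful on
arbitrary real data.

### Subject-level simulation mode

Group-level power and recovery studies use a subject-ERP route that skips
the continuous recording: a subject's per-condition average ERP is the
calibrated evoked response with a subject gain (SD 0.15), a per-component
amplitude shift shared across conditions (SD 0.8 µV), an independent
per-condition amplitude jitter (SD 0.4 µV — the window-mean sampling noise
that a 100-trial average of AR(1) noise carries, which white residual
noise alone would underestimate), plus white residual noise of
8/√(trials) µV. The continuous route (filter → blink correction → epoch →
reject → average) is exercised end-to-end by the preprocessing fidelity
tests; the subject-ERP route keeps 50-replicate group studies tractable at
the 19-subject scale the design calls for.

## Preprocessing

The band-pass is a Butterworth cascade — order 2 high-pass at 0.1 Hz
(12 dB/oct) and order 8 low-pass at 30 Hz (48 dB/oct) — applied
forward-backward (`sosfiltfilt`, odd reflection padding), hence zero-phase.
Blink correction is regression of each channel on VEOG over detected blink
segments (|VEOG| > 50 µV, 50 ms padding) after removing the average
stimulus-locked activity from both, then subtracting b·VEOG everywhere;
with no detectable blinks it warns and returns the input. Epochs span
−100…1000 ms (1,101 samples at 1 kHz) and are baseline-corrected on
−100…0 ms; baseline correction is applied even though not every
description of this chain states it, because an absolute ±75 µV threshold
is only meaningful on baselined data. Rejection flags any epoch whose
absolute value exceeds 75 µV on any EEG channel (VEOG excluded, so
corrected blinks cannot trigger rejection). Grand averages re-reference
each subject ERP to the common average first; re-referencing is idempotent
and preserves GFP.

## Statistics

`rm_anova` implements fully-within repeated-measures ANOVA (1–3 factors)
via orthonormal contrast projections: for effect A, the per-subject cell
array is projected with the Kronecker product of orthonormal contrast
bases (factors in A) and orthonormal averaging vectors (factors not in A),
giving SS_effect = S‖z̄‖², SS_error = Σ‖z_s − z̄‖², identical to the
classical partitioning (verified against a cell-means oracle and against
pingouin). The Greenhouse–Geisser ε of each effect is tr(Σ)²/(df·tr(Σ²))
on the projected covariance, clipped to [1/df, 1], and multiplies both df
whenever df > 1 ("where applicable" read as: any effect with more than one
numerator df). Partial η² = SS_effect/(SS_effect + SS_error). Post-hocs
are all pairwise paired t-tests with Bonferroni multiplication clipped at
1. Window endpoints are inclusive on both sides (a fixed convention; at
1 kHz the 400 ms sample belongs to both the N2 and LMF windows). RTs
aggregate per cell by the mean, all trials retained.

The TANOVA compares two within-subject condition groups: the observed
statistic at each time point is the DISS between the two grand-average
maps (each GFP-normalized); the null swaps the two labels within each
subject with a fair coin, M = 5,000 by default, p = (1 + #{null ≥
obs})/(M + 1). When 2^S ≤ M + 1 the full sign-flip set is enumerated and
the p-value is exact. Runs of consecutive significant samples shorter than
10 ms (10 samples at 1 kHz) are discarded. Multi-condition contrasts (e.g.
low {3,4} vs high {5,6}) are averaged within group per subject before the
test.

## Microstates

Segmentation is polarity-sensitive AAHC (a map and its inverse are
distinct — the evoked-potential convention): every time-point map starts
as a singleton cluster; the cluster contributing least GEV is dissolved
and its members reassigned to the best-correlated remaining template
(templates are normalized means of members). For each candidate q the
recorded templates are then back-fitted winner-take-all to the series —
this competitive relabeling sharpens the agglomerative partition and is
what the selection criterion is computed on. σ̂² is the label-conditional
residual variance with unit-norm templates; CV(q) = σ̂²((K−1)/(K−1−q))²;
q* minimizes CV over q = 1…12. Segmentation input is the 0–1000 ms
post-stimulus window of all conditions' grand averages, concatenated
(baseline excluded — it contains no evoked structure and would only add a
noise state); the pipeline segments every 4th sample to keep the
atomization affordable. Segments shorter than 10 ms are dissolved into the
better-correlated neighbour, shortest first, within each condition.
Back-fitting ties break toward the lowest template index
(deterministic). GEV sums (GFP_t·r_t)²/Σ GFP_t² over the window per
winning template; zero-GFP points are skipped (they contribute zero
anyway).

The synthetic validation series uses 3 orthonormal random templates in
round-robin 30-sample segments, each segment with its own smooth amplitude
envelope (peak uniform in 0.6–1.4, independent of state identity) and
channel noise at amplitude SNR 10. The envelope independence matters: if
one state systematically carried low GFP, the GEV-based atomization would
dissolve it first — a property of the algorithm, not a bug.

## Numerical and degenerate-input conventions

DISS and spatial correlation raise on zero-GFP maps; the TANOVA propagates
NaN for zero-GFP grand-average time points. ANOVA effects with exactly
zero projected variance (flat data) report F = 0 rather than 0/0. The
permutation +1 correction keeps p strictly positive. All randomness flows
from explicit seeds (numpy `SeedSequence` spawning per subject/trial), so
identical configurations are bit-identical, and the pipeline report
round-trips through JSON.

## Problem sizes used in validation

The acceptance checks run at deliberately chosen scales: 24,000 layouts
for the spacing constraint; 10,000 map pairs for the DISS identity; 2,000
null datasets (10 subjects, M = 500) for TANOVA calibration; 100
replicates for microstate selection; 2,000 null simulations for the ANOVA
type-I rate; 50 replicates of 19-subject samples for planted-effect
recovery — sizes at which Monte-Carlo error is small relative to the
tolerances being asserted.

## Known limitations

- The paradigm's published group statistics derive from human recordings;
  this package validates the *machinery* on simulations with planted
  truth, and its planted effect sizes are calibrated qualitatively, not
  fitted to human data.
- The CV criterion is the only map-count selector implemented; meta-criteria
  that combine several indices would change q* on real, noisier data.
- No EDF export: recordings serialize to .npz + JSON and convert to
  `mne.io.RawArray` for interoperability with the wider MNE ecosystem.
- Blink-coefficient recovery at the 1% level needs blink-dominated
  regression segments; under heavy autocorrelated background noise the
  regression is unbiased but slower to converge, as for any
  regression-based ocular correction.
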