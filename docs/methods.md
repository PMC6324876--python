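# Methods

## Signal model and extraction

The analysis unit is a field of view (FOV): every frame of a T×H×W movie is
collapsed to its mean pixel intensity. Baseline fluorescence is modelled as
a straight line fitted by ordinary least squares to the 500 ms of data
immediately before stimulus onset (5 samples at the default 10 Hz frame
rate) and extrapolated over the whole recording:

    %ΔF/F(t) = 100 · (F(t) − B(t)) / B(t),   B(t) = a·t + b.

Dividing by the per-frame fitted value B(t) — rather than the window mean —
cancels a linear photobleaching drift exactly: an input of the form
B(t)·(1 + s) maps to the constant s. The trace is therefore invariant to
rescaling the raw fluorescence.

Transient size is the composite trapezoidal integral of %ΔF/F over a time
window. Samples with start ≤ t ≤ end form the integration nodes, so two
adjacent windows that share a boundary sample add exactly
(auc(a,b) + auc(b,c) = auc(a,c)). The abscissa is seconds by default; a
frame-index dialect is provided because integrals "over frames" appear in
the literature with either convention and replaying published tables may
require one or the other.

Precision note: extrapolating a line fitted to 5 noisy samples dominates
the error budget of everything downstream. The OLS prediction SD at the
first post-stimulus frames is ≈1.2× the trace noise SD (the lever term
(t−t̄)²/Sxx is large because Sxx = 0.1 s² for a 0.5 s window at 10 Hz) and
grows linearly beyond. Whole-field means over 64×64 px at realistic photon
counts put the trace noise at a fraction of a percent of F0, where this is
negligible; at trace SNR ≲ 20 it is not, which is why the recovery studies
below are run at shot-noise-realistic SNR (see "Validation studies").

## Kinetics

The pulse-resolved view is the first difference of the %ΔF/F trace, one bin
per frame interval (100 ms at 10 Hz). Its cumulative sum reconstructs the
trace exactly. Landmark values are read from the bins starting 100 ms
before stimulation, at the first pulse, and at the second pulse; when
stimulation is faster than the frame rate (50 Hz), several pulses share a
bin by construction.

Decay is summarized by a log-linear fit. The peak is the maximum %ΔF/F
between onset and half a second after the last pulse (earliest frame wins
ties). The fit covers the contiguous run of samples from the peak until the
trace first drops to `floor_fraction` (default 0.10) of the peak;
restricting to this run keeps noise-floor samples — and non-positive
values, which have no logarithm — out of the fit. The reported decay time
is the time for the fitted exponential to fall from peak to floor,
ln(1/floor)/|slope| (τ·ln 10 for the default floor), together with the fit
r². The floor is configurable (0.5 gives a half-decay time). The metric
depends only on trace shape, not amplitude. An unweighted log-linear fit
weights the faint tail heavily, giving relative τ precision ≈ 2.5/SNR at
10 Hz sampling of a 1 s decay; its mean is mildly biased (≈ +3 % at SNR
20).

## Puncta quantification

The baseline image is the pixelwise mean of pre-stimulus frames. A Canny
filter (scikit-image) reduces it to a binary high-contrast mask; the
fractional thresholds (defaults 0.08 and 0.2, Gaussian smoothing σ = 1.4 px)
are applied to the gradient magnitude normalized to a maximum of 1, the
convention of MATLAB-style analysis environments, by rescaling absolute
thresholds with the image's measured maximum smoothed-Sobel gradient. The
mask is invariant to adding or multiplying the image by a positive constant;
a constant image gives an empty mask. The edge-pixel count ("Canny edge
sum") is the punctate-structure proxy; no connected-component segmentation
is attempted because edge-pixel counts, not punctum counts, are the
measurement. Exact counts are implementation-sensitive (non-maximum
suppression and hysteresis details differ between libraries), so tests
assert invariances and orderings rather than counts.

## Spatial hotspot analysis

FOV positions are 2-D coordinates (µm) in the slice plane; depth is ignored
(one imaging plane per FOV). FOVs are ranked by AUC into four near-equal
groups (stable input order breaks ties; when n is not divisible by 4 the
larger groups are the lower quartiles). Pairs whose members share the top
quartile form the "top pairs". The clustering question — are high-releasing
fields near each other? — is answered by a permutation test: the statistic
is the median top-pair distance, and the null redraws the top-quartile set
uniformly at random (equivalent to permuting AUC values across positions).
The add-one p-value makes the test valid at any permutation count. Note
that pair distances share FOVs, so naive i.i.d. two-sample tests between
pair-distance sets over-reject (measured 12–19 % at nominal 5 %); the
permutation null is the correct exchangeable reference and calibrates to
5 % ± 2 % in simulation.

## Statistics

Paired and pooled-variance unpaired two-tailed t-tests (Welch by flag),
with t-based CI95 on the mean difference; degenerate inputs (zero variance)
raise instead of returning infinities. CI95 on a mean is mean ± t₀.₉₇₅·SEM.
The one-way repeated-measures ANOVA partitions a complete subjects ×
conditions table into condition, subject and residual sums of squares (with
two conditions, F equals the squared paired-t statistic); Greenhouse–
Geisser correction is available by flag but off by default. The mixed
(split-plot) ANOVA crosses a between-subject group with a within-subject
condition, testing the group effect against subjects-within-groups and the
condition and interaction effects against the condition × subject residual;
unequal group sizes use weighted (observed-frequency) sums of squares. No
multiple-testing correction is applied anywhere. scipy provides
distributions and quantiles; the partitions themselves are computed
directly and are cross-checked against pingouin in the test suite.

## Synthetic-data generator

The generator emulates the structure of the slice experiments, not their
biophysics. A raw trace is

    raw(t) = B(t) · (1 + Σₚ Aₚ·h(t − tₚ)/100) + ε(t)

with B(t) = F0·(1 − bleach·t) and h a difference-of-exponentials kernel
normalized to unit peak (rise τ = 0 degenerates to a step-and-decay). The
evoked term is proportional to the local baseline so that noiseless %ΔF/F
equals Σ Aₚ·h exactly. Per-pulse amplitudes combine:

- a Hill calcium dependence c^h/(c^h + EC50^h), defaults EC50 = 1 mM,
  h = 2 — chosen so release rises steeply from 0.5 to 2 mM and saturates
  above 2 mM;
- short-term facilitation with an exponential memory,
  Aₚ ∝ 1 + f·Σ_{q<p} exp(−(tₚ−t_q)/τ_f). Because every pairwise term grows
  as pulse intervals shrink, train amplitude strictly increases with
  frequency whenever f > 0, while f = 0 makes total release exactly
  frequency-independent;
- first-order recovery 1 − exp(−Δt/τ_rec) of releasable amplitude since the
  previous train.

Movies are a static punctate baseline image (2-D Gaussian puncta on a flat
background, frame mean normalized to F0) bleaching linearly, plus a
spatially uniform evoked flash scaled so the frame mean reproduces the
simulated trace exactly at zero noise, plus per-pixel Gaussian or Poisson
noise. Slice sessions scatter FOVs in a 1000 × 600 µm extent; a configurable
fraction are "hotspots" drawing AUC from a high distribution (defaults:
low N(1.5, 0.6²), high N(8, 2²), clipped at 0), placed uniformly or
co-located within 10 % of the extent. Canny sums and initial fluorescence
are drawn independently of AUC, encoding the observed decoupling between
transient size and punctate structure.

Region presets (defaults, arbitrary-unit F0; chosen once from the printed
values of the slice study the generator emulates):

| parameter | striatum | GPe |
|---|---|---|
| F0 | 1000 | 600 |
| bleach (1/s) | 0.005 | 0.005 |
| amplitude/pulse (%ΔF/F, saturating Ca) | 1.0 | 0.24 |
| rise τ (s) | 0.01 | 0.01 |
| decay τ (s) | 4.0 | 0.95 |
| facilitation f / memory τ_f (s) | 0 / 0.04 | 0.8 / 0.04 |
| recovery τ (s) | 60 | 10 |

These give, at standard 2.4 mM calcium: first-pulse 100-ms derivatives of
~0.85 % (striatum) and ~0.20 % (GPe); a noiseless GPe decay-to-10 % time of
~2.19 s versus ~9.2 s for striatum; a GPe 50 Hz / 10 Hz whole-train AUC
ratio of ~1.64 with the striatal ratio equal to 1 by construction; and
first-pulse-dominant derivative traces (rise and facilitation memory are
fast relative to the 100 ms frame). Noise amplitude and bleach rate are not
constrained by published values; defaults were set so recovery tests are
meaningful. All generators are pure functions of their parameters and a
seed (identical seeds give bit-identical output); multi-FOV generators
spawn per-FOV substreams from the master seed.

What the generator does not emulate: optics (no PSF, no depth attenuation),
axon morphology, vesicle-pool biophysics beyond the
amplitude/facilitation/recovery phenomenology, slice movement, and
correlated (non-white) noise. Passing tests therefore demonstrate that the
analysis recovers what this model puts in — not that the model captures
every property of real recordings.

## Validation studies

`ffnquant.validation` (used by the test suite and `scripts/acceptance.py`)
runs the pipeline at fixed study sizes chosen to finish in seconds on one
CPU:

- peak recovery: 200 single-pulse simulations through the full pipeline at
  trace SNR 50 (the shot-noise level of a 4096-pixel frame mean at typical
  photon counts; at much lower SNR the 500 ms baseline extrapolation
  dominates, see above), scoring the fraction within 10 % of ground truth;
- decay-τ recovery: noisy exponentials handed directly to the decay fit —
  mean recovered τ at SNR 20, within-5 % rate at SNR 100, matching the
  estimator's 2.5/SNR precision;
- t-test type-I error and CI95 coverage over 10,000 null replicates;
- permutation-test calibration over 500 uniform sessions (16 FOVs, 200
  permutations) and power over 200 clustered sessions (40 FOVs, hotspot
  fraction 0.25, co-location radius 10 % of extent);
- the preset contrasts (decay times, frequency ratios, landmark
  derivatives) on noiseless simulations, and the AUC-vs-Canny correlation
  across 494 simulated FOVs.

## Numerical conventions and edge cases

Time comparisons use a 1 ns tolerance. Baseline windows use samples in
[onset − w, onset); AUC windows use samples in [start, end] (additive over
adjacent windows). Traces must be uniformly sampled (1 µs tolerance);
trace CSVs with non-monotone or irregular time columns are rejected. A
constant image yields an empty edge mask, not an error. Quartile ties are
resolved by stable input order for determinism. A non-decaying log fit
(slope ≥ 0) reports an infinite decay time rather than raising. Degenerate
statistical inputs (zero variance, missing cells, single-subject groups)
raise. The pipeline's default AUC window is the stimulus period with a
300 ms floor so that 50 Hz trains remain integrable at 10 Hz sampling;
reruns with the same config and seed are byte-identical, and every output
directory carries a manifest naming the config hash that produced it.

## Known limitations

- The %ΔF/F baseline is linear; slow nonlinear drifts (wash-out, focus
  drift) alias into the transient estimate.
- Decay times assume a single-exponential tail; diffusion-shaped decays are
  summarized, not modelled.
- The Canny edge sum depends on the edge-detector implementation at the
  pixel level; cross-library comparisons should use orderings, not counts.
- The mixed ANOVA uses weighted sums of squares under unbalanced group
  sizes (Type-I-style); strongly unbalanced designs with correlated
  predictors would warrant a mixed-effects model, which is out of scope.
- The permutation test conditions on the observed positions; it tests label
  exchangeability, not any parametric spatial process.
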