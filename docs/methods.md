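# Methods

This note describes the models and procedures implemented in `toposep`,
the choices made where the design was genuinely open, and what the
synthetic-data benchmarks do and do not establish.

## Scope and data model

`toposep` analyzes stimulus-locked multichannel EEG — sensory evoked
potentials (SEPs) — with *reference-independent* topographic methods. The
canonical study layout it targets is repeated electrical stimulation of
the lower urinary tract: three stimulation frequencies (0.5 / 1.1 /
1.6 Hz) as a within-subject factor and five stimulation locations as a
between-subject factor, recorded with a 64-channel extended 10-20 cap.
Nothing in the code is specific to that paradigm; the design
specification accepts any within-factor level set and any subject
grouping.

Voltages are microvolts throughout, times are milliseconds relative to
stimulus onset, and channel order always follows an explicit `Montage`.

## Montage geometry

Spherical coordinates use polar angle `theta` from the vertex and azimuth
`phi` with **+90° anterior** (nose) and **−90° posterior**:
`x = sinθ cosφ` (right), `y = sinθ sinφ` (nose), `z = cosθ` (vertex).
EEG software disagrees on this convention; it is fixed here so that the
two standard virtual midline channels land where they belong: FzFCz at
(34°, +90°) anteriorly, CzCPz at (11°, −90°) posteriorly.

The built-in 64-channel montage resolves standard 10-10 labels against
the idealized electrode table shipped with MNE-Python, fits a sphere to
the chosen channel subset by least squares, and projects every electrode
onto the unit sphere. On this sphere the site (11°, −90°) falls between
Cz and CPz, as it should. Any montage can be supplied as a TSV of
`(label, theta, phi)` instead.

## Preprocessing

* **Filtering** — 0.5–70 Hz Butterworth band-pass, analog order 4
  (24 dB/oct per edge), applied forward-backward (`sosfiltfilt`) for zero
  phase; the two passes double the effective attenuation, matching common
  analyzer behaviour. Reflect padding of length `3·fs / f_low` tames the
  slow high-pass edge transient. The mains notch is a 2nd-order
  Butterworth band-stop at 48–52 Hz. Filtering is applied to continuous
  data before segmentation (the usual order; epoch-wise filtering of
  700 ms segments with a 0.5 Hz high-pass would be dominated by edge
  effects).
* **Average reference** subtracts the per-sample channel mean.
* **Spherical spline interpolation** (order m = 4, Legendre degree
  N = 10) implements the classical thin-plate spline on the sphere: the
  kernel `g(cosγ) = (1/4π) Σ (2n+1)/[n(n+1)]^m Pn(cosγ)` with the
  constrained linear system that reproduces constants exactly. An
  optional ridge term λ (default 0 in the low-level API, 1e-8 where the
  pipeline interpolates many samples) guards against numerically singular
  electrode layouts. Virtual channels CzCPz and FzFCz are spline values
  at their standard positions.
* **Epoching** cuts −100…+600 ms around stimulus markers; windows that
  would leave the recording are dropped and counted. **Artifact
  rejection** flags any trial exceeding ±100 µV on any channel; explicit
  keep/reject overrides provide the "semiautomatic" half without a GUI.
  **Baseline correction** subtracts the −53…−3 ms mean per channel.
* **Averaging** is the arithmetic mean over kept trials; split-half
  averages take odd/even kept trials in acquisition order (1-based
  ordinals over *kept* trials; whether parity is counted before or after
  rejection is a convention, fixed here as post-rejection).

All of these operators are linear, so they commute with trial averaging;
the test suite asserts this.

## Component markers and time windows

Markers are set automatically as windowed extrema on a single derivation
(default Cz against average reference, or any `A-B` bipolar pair):
P1 = maximum in 40–90 ms, N1 = minimum in 80–170 ms, P2 = maximum in
185–380 ms, ties resolved to the earlier sample. A recording is a
*responder* when its split-half averages correlate at r ≥ 0.5 over the
analysis window (the numeric stand-in for the visual "overlapping
waveforms" criterion; the threshold is a package default, exposed in the
config) and all components are marked. The responder rate is the
percentage of such recordings.

Component time windows come three ways:

1. **mean ± 2 SD** of individual peak latencies (sample SD, n−1),
   snapped outward to the sample grid; degenerate windows widen by one
   sample with a warning.
2. **GFP minima**: local minima of the smoothed GFP curve bracketing each
   post-stimulus GFP peak (first peak after 50 ms = N1, next = P2; no
   separate GFP peak is assumed for P1).
3. **GFP inflection points**: zero crossings of the second derivative
   flanking each peak, linearly interpolated between samples — always
   nested inside the minima windows for a unimodal bump.

The GFP curve is smoothed with a 5 ms moving average before the minima /
second-derivative search; the raw curve's derivative is noise-dominated.

## Randomization statistics

All tests share the permutation convention
`p = (#{null ≥ observed} + 1) / (n_perm + 1)` (the observed labeling
counts as one permutation, so p is never 0), and all are reproducible
bit-for-bit from `(seed, n_perm)`. An exhaustive mode enumerates every
within-subject label permutation on small designs; the suite verifies it
against an independent brute-force enumeration.

* **GFP** of a map is its spatial standard deviation (population
  divisor) — the RMS about the channel mean, independent of the
  reference.
* **TANOVA** normalizes each map to unit GFP and uses the *generalized
  dissimilarity*: Σ over factor levels of GFP(level mean map − grand mean
  map). Within-subject factors permute condition labels independently
  within each subject; between-subject factors permute subjects across
  groups; the interaction statistic is the dissimilarity of
  double-centered cell means, with labels permuted after residualizing
  out subject and level means (a stated convention — only *that* an
  interaction was tested is documented in the source literature, not
  how).
* **GFP test** applies the same permutation schemes to per-map GFP values
  with the absolute-deviation statistic, *without* normalization: it sees
  map strength and is blind to topography. Together with TANOVA this
  dissociates strength from topography.
* **TCT** (topographic consistency test): observed statistic is the GFP
  of the mean of GFP-normalized subject maps; the null shuffles channel
  values within each subject's map. One channel permutation is drawn per
  (permutation, subject) and shared across time points — each time
  point's marginal null is exact; only the across-time dependence of
  p-values differs from fully independent shuffles.
* **t-maps** are descriptive channel-wise paired or Welch t statistics on
  window-mean maps, with no multiplicity correction.

Maps with GFP below 1e-12 are excluded from normalization-based tests
(with a logged count) rather than producing infinities. No cluster- or
duration-based correction over time is applied; significance periods are
reported raw, as an extension point.

## Microstates

**AAHC** (atomize and agglomerate hierarchical clustering) starts with
every map as a singleton cluster and repeatedly dissolves the cluster
contributing least to the global explained variance
(GEV = Σ (GFP_t · corr_t)² / Σ GFP_t²), reassigning freed maps to the
best-correlating surviving cluster. Polarity-**sensitive** mode (default
for evoked data, where the N1 negativity and P2 positivity are distinct
states) uses signed spatial correlation and mean prototypes;
polarity-**ignorant** mode uses |correlation| and first-principal-
direction prototypes. One descent yields models for every intermediate
class count.

**Model selection** runs repeated split-half cross-validation over
subjects (default 50 repeats; odd subject counts drop one random subject
per repeat, mirroring an 83 → 41 + 41 split): AAHC fits the training
half's grand average for each k in 3…20, and the score for k is the mean
correlation between the halves *under the training segmentation* — each
test-half time point is correlated with the prototype that the training
labels assign at that time point. This detail matters: freely
re-assigning test maps to their best-fitting prototype yields a score
that never decreases with k (the maximum over more prototypes gains a
selection bonus), so it cannot peak at the true class count. Evaluating
the training segmentation penalizes prototypes fitted to training noise,
and the curve peaks at the programmed k in the recovery benchmark. Ties
break toward fewer classes.

**Assignment** labels each time point of a condition's series with its
best-correlating prototype (maps with near-zero GFP stay unassigned) and
derives per-class parameters inside the 20–600 ms analysis window: total
duration, mean GFP, and GFP-weighted occurrence (the class's share of the
summed GFP). Condition differences in these parameters are tested with
the within-subject permutation scheme on per-subject parameter values;
onsets/offsets are reported descriptively only, since they are undefined
for subjects in whom a class never wins.

## Synthetic data generator

The generator produces stimulus-locked epochs with the statistical
structure the analyses assume, plus a ground-truth record, so every
downstream benchmark is self-contained.

* **Spatial patterns** are sums of von-Mises-like lobes
  `exp(κ(cosγ − 1))` centered on montage labels (κ set by angular FWHM),
  mean-centered (average-reference compatible) and scaled to unit peak.
  Defaults: P1 — weak central positivity (1.2 µV, 60 ms); N1 —
  centro-parietal negativity with frontal counter-positivity (5 µV,
  115 ms); P2 — central positivity inside a negative surround (4 µV,
  255 ms); CNV — broad central negativity ramping linearly over the
  pre-stimulus span and decaying exponentially (τ = 200 ms) after
  stimulus.
* **Condition structure**: per-component frequency multipliers, default
  1.0 / 0.8 / 0.6 for P1/N1/P2 (map strength decreases with stimulation
  frequency) and 1.0 / 0.4 / 0.15 for the CNV (slow-frequency
  anticipation effect). Locations are a between-subject grouping with no
  programmed effect by default.
* **Subject variability**: lognormal amplitude factors (σ = 0.3) and
  Gaussian latency jitter (3–8 ms SD per component), drawn once per
  subject and shared across that subject's conditions.
* **Noise**: white Gaussian per trial, smoothed across channels with a
  ~60° FWHM spherical kernel and across time with a 20 ms Gaussian
  kernel; both kernels are L2-normalized so the per-sample SD equals the
  configured value (default 1 µV). This gives realistic spatial and
  temporal correlation without a volume-conduction forward model.

What the generator does *not* emulate: real head geometry and volume
conduction, eye/muscle artifacts, non-stationary background rhythms, and
latency drift within a session. Benchmarks passing on this generator
therefore establish the correctness and calibration of the *algorithms*,
not performance guarantees on any particular real recording.

## Benchmark problem sizes and numerical choices

The validation suite and `scripts/acceptance.py` run everything on one
CPU in a few minutes by scaling the study down, not by weakening checks:

* **Calibration** (type-I error at α = 0.05): 500 simulations × 999
  permutations, 12 subjects × 2 conditions, 20 channels × 50 time points
  (70 Hz sampling), rejections pooled over time points. TANOVA and the
  GFP test are calibrated on null datasets that keep the full evoked
  signal but make it identical under both condition labels (their
  exchangeable unit is the within-subject label). TCT is calibrated on
  signal-free, channel-uncorrelated noise, because its null shuffles
  channels within a map: spatially smoothed noise violates that
  exchangeability by construction, and a consistent evoked signal is
  exactly what the test is supposed to detect.
* **Frequency effect**: 50 runs, 20 subjects × 3 frequencies,
  100 trials/average, noise 1 µV, 125 Hz, 20 channels; the GFP test and
  TANOVA run on N1-window (87–147 ms) mean maps. The trial count keeps
  evoked noise in the regime of real recordings (several hundred trials
  per average); with far fewer trials the GFP-normalization of noisier
  weak-condition maps leaks a small strength signature into TANOVA.
* **Marker recovery**: 200 runs on the noise-free Cz–Fz trace plus
  temporally smoothed noise scaled so the weaker component's peak/noise
  ratio is 5, at 125 Hz. A detection counts as recovered within one
  sample interval *after grid quantization* (|error| ≤ 1.5 samples): the
  programmed latencies (115, 255 ms) cannot fall on any admissible
  sample grid that also contains stimulus onset, so half a sample of
  quantization error is unavoidable.
* **Microstate recovery**: 25 dataset seeds, 20 subjects, 4 orthonormal
  smooth templates × 24 samples each, per-subject channel noise SD 1.0
  relative to unit-GFP templates; CV with 50 repeats over k = 3…20.
* **Spline accuracy**: constant-field and electrode-site reproduction,
  plus recovery of a random degree-≤3 spherical-harmonic field at
  between-electrode midpoint targets on the 64-channel montage. Accuracy
  is weakest for targets near the rim of the electrode-covered cap,
  where the problem shades into extrapolation.

Numerical conventions: population divisor in GFP; `argmax`/`argmin` ties
resolve to the earliest index; CV ties to the smallest k; permutation
comparisons use a 1e-12 slack so exact ties count as ≥; all randomness
flows through `numpy.random.default_rng` with explicit seeds, and the
pipeline writes a manifest (config hash, seed, versions) with every run.

## Known limitations

* The BrainVision reader covers multiplexed float32/int16 files with
  `Stimulus` markers — the common recorder output — and rejects
  vectorized or EDF-style inputs explicitly.
* Ocular correction is a no-op hook: the upstream algorithm is
  analyzer-specific, and synthetic benchmarks contain no ocular
  artifacts. Real pipelines should clean eye artifacts before `toposep`.
* TCT's channel-shuffle null is anti-conservative when map noise is
  spatially correlated; on real data its significant periods should be
  read as "consistent topography relative to channel-exchangeable
  noise".
* No duration/count statistics over significance periods and no
  cluster-based multiplicity control are implemented.
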