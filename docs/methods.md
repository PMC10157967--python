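# Methods

This note documents the models, conventions and numerical choices behind
`planeeg`, in the order the pipeline applies them, followed by an account
of what the synthetic-data generator does and does not emulate.

## Signal model

A recording is a continuous voltage trace (µV) sampled at `fs` (default
500 Hz) for ~10 minutes per dataset, one or more channels, labelled by
experimental condition.  The working model of the signal is

    power-law background  +  band-limited oscillations  +  artifacts

where the background power spectral density follows S(f) ∝ f^(−x).  The
exponent x is the quantity of scientific interest: x ≈ 0 is white noise,
x near 1 is typical of neural field potentials, and values near 3
indicate low-frequency instrumentation noise.  Artifacts are brief
large-amplitude myogenic-like transients and power-line contamination at
50 Hz and its (sub)harmonics (25, 100 Hz).

## Preprocessing

**Filter design.**  Linear-phase FIR filters from the window method with a
Hamming window.  The order follows the classic Hamming rule

    order = ceil(3.3 · fs / Δf),  rounded up to even,

where Δf is the transition bandwidth, and the cutoff sits at the −6 dB
(half-amplitude) point.  Defaults: high-pass cutoff 0.1 Hz with Δf =
0.2 Hz (order 8250 at 500 Hz; passband edge 0.2 Hz) and low-pass cutoff
23 Hz with Δf = 0.25 × cutoff = 5.75 Hz (order 288; passband edge
≈ 20.1 Hz).  The 0.25 × cutoff convention is the only transition rule
consistent with both of those orders, which is why it is the default for
low-pass and notch designs.  Notch filters (used for the wide-band 0.5–80
Hz variant) are band-stops with stop edges at the center ± 2 Hz.

**Two-pass filtering.**  Each filter is applied forward and then to the
time-reversed signal, so phase responses cancel exactly and stop-band
attenuation doubles in dB.  Before each pass the signal is reflect-padded
by one filter length to bound startup transients; the symmetric taps are
applied as a centered convolution (FFT-based), so no group delay is
introduced at any stage.  Inputs no longer than the filter order are
rejected.

**Trimming and epoching.**  The first and last 0.5 s are discarded, then
the trace is tiled from the start into non-overlapping 6 s epochs
(indices 0-based, intervals half-open); a trailing remainder shorter than
one epoch is dropped.  A 600 s recording yields floor(599/6) = 99 epochs.

## Automatic artifact rejection

For every (channel, epoch) cell four metrics are computed:

- **peak** — max |sample| (µV);
- **variance** — within-epoch sample variance, ddof = 1 (µV²);
- **z-value** — mean over time of |sample − channel mean| / channel SD,
  with the channel mean and SD pooled over *all* epochs of that channel;
- **kurtosis** — within-epoch standardized fourth moment m₄/m₂²
  (Pearson convention, Gaussian → 3; an excess-kurtosis switch subtracts
  3, which shifts the metric by a constant and cannot change removals).

Thresholds are computed **once** from the full metric table (single pass,
no iterative re-thresholding): a cell is flagged when its peak lies
strictly more than 5 SD from the mean peak (both tails) or when variance,
z-value, or kurtosis lies strictly more than 2.5 SD *above* its mean
(upper tail only).  A flagged cell removes its epoch; channels are judged
by the same thresholds applied to their epoch-averaged metrics.  Strict
inequalities make the degenerate zero-spread table a well-defined
no-removal case.  A dataset is retained when ≥ 1 channel and > 5 epochs
survive.  Zero-variance epochs/channels report kurtosis/z-value 0 with a
warning rather than an error.

**A structural property worth knowing:** k equal-magnitude outlier epochs
among N can reach at most ≈ √((N−k)(N−1)/(kN)) SDs in the single-pass
metric table.  Contamination denser than roughly 10% of epochs therefore
saturates the 2.5 SD threshold and nothing is flagged; likewise a single
outlier among fewer than ~9 epochs cannot be flagged at all.  The
procedure is designed for long recordings with sparse artifacts (a 50-SD
spike epoch among 99 clean ones stands ~4.4 SD out and is removed
reliably); it is not a dense-noise cleaner.  On clean Gaussian data the
empirical false-removal rate is ~1% of epochs (bounded below 5% by a
seeded 1,000-dataset test at 20 epochs × 500 samples per dataset — epoch
length does not enter the metric distributions under the null).

## Spectral estimation

**Frequency grid.**  23 logarithmically spaced targets between 0.5 and
20 Hz, each snapped to the nearest DFT bin after zero-padding the 3000
sample epoch to 4096 (bin width 500/4096 = 0.1220703125 Hz).  The snapped
grid runs 0.488–20.019 Hz; duplicate snapped targets (which occur on the
44-step 0.5–80 Hz wide-band grid) are collapsed with a warning.

**Multitaper PSD.**  Per epoch and channel the demeaned signal is
multiplied by K discrete prolate spheroidal (Slepian) tapers with
time-half-bandwidth NW = T·W (T = 6 s, W = ±1 Hz smoothing), K = 2TW − 1
= 11; one-sided density (µV²/Hz) is averaged over tapers, then over
epochs and surviving channels.  The estimate integrates to the signal
variance (Parseval check within 10% on white noise).

**Aperiodic fit.**  Ordinary least squares of log₁₀ power on log₁₀
frequency over a configurable range; exponent = −slope, with the OLS
standard error and R² reported (`AperiodicSpectrumModel.fit()` returns a
results object with `summary()`).  On a noiseless power law the estimator
is exact for any x.  **Default fit range: 2–20 Hz.**  Grid centers below
about twice the smoothing half-bandwidth carry substantial bandwidth
leakage — at 0.488 Hz the ±1 Hz taper band reaches across 0 Hz, and for
steep spectra the leaked low-frequency power inflates the estimate there,
biasing a full-grid fit by up to ≈ +0.45 at x = 2.7 while the 2–20 Hz fit
recovers x ∈ {0.5, 1, 1.5, 2.7} with mean absolute error < 0.1 on
10-minute recordings.  The full-grid fit remains available by passing an
explicit range and is what the white-noise reference computation uses
(where the leakage bias is negligible because the spectrum is flat).

## Group statistics

**Per-frequency permutation test.**  The observed statistic at each grid
frequency is the pooled-variance independent-samples t on log₁₀ power
(spectra span orders of magnitude; a linear-power switch exists).  Group
labels are randomly reassigned 10,000 times — the *same* reassignment
across frequencies, preserving cross-frequency dependence; reassignments
are drawn with replacement — and the two-tailed p is the fraction of
permutations with |t_perm| ≥ |t_obs|, floored at 1/10,000 = 0.0001.

**FDR correction.**  Benjamini–Yekutieli step-up at q = 0.01: sorted p(i)
compared against (i/m)·q / Σ_{j≤m}(1/j), flags returned in input order.
The BY variant is valid under the arbitrary positive dependence of
neighboring spectral estimates; the plain Benjamini–Hochberg step-up is
deliberately not used (on the reference per-frequency p-values it flags
additional mid-range frequencies and fails the reproduction check in the
test suite).  The critical alpha for the exponent contrasts is 0.01,
adjusted for three pairwise group comparisons.

**Exponent contrasts.**  Welch's unequal-variance t-test with
Welch–Satterthwaite fractional degrees of freedom and a 95% CI for the
mean difference.

## Synthetic data

`generate_colored_noise` shapes white Gaussian noise in the frequency
domain — DFT amplitudes scaled by f^(−x/2), DC zeroed, inverse transform,
standardized to zero mean and unit sample variance — giving an exact
expected spectrum and a trivial periodogram oracle, unlike AR
approximations.  Oscillations are Gaussian-envelope narrow-band noise
(center, bandwidth, amplitude relative to the background SD).  Spikes are
raised-cosine transients of 40 ms half-width (shorter than an epoch, long
enough to move epoch variance and kurtosis), peak amplitude in background
SD units, polarity random, count Poisson at the configured rate; line
noise is a random-phase sinusoid per component.  Default study
conditions: 500 Hz, 600 s, one channel, group exponents {darkness 1.23,
light 1.31, control 2.72, decapitated darkness 1.32, decapitated light
1.48}, line noise (25 Hz, 0.5), (50 Hz, 1.0), (100 Hz, 0.5), spikes at
0.5/min with 20 SD peaks.  The spike rate is set so that contamination
stays sparse (~5 of 99 epochs), the regime the single-pass rejection
procedure is built for (see the saturation property above).  All
randomness derives from one study seed via per-dataset child seeds;
identical configurations are bit-identical.

Amplitudes are deliberately dimensionless (background-SD units): the
absolute µV scale of planarian surface recordings is not a settled
quantity, and every pipeline stage is scale-invariant.  What the
generator does **not** emulate: biophysics of the cephalic ganglia,
electrode/volume conduction, nonstationarity (drift, state changes within
a recording), movement artifacts other than discrete spikes, and
non-Gaussian background statistics.  Passing tests therefore demonstrate
the correctness and calibration of the *analysis* under the stated signal
model, not the physiological validity of any particular recording setup.

## Problem sizes and seeds in the test suite

The suite validates exponent recovery at the production scale (20 seeded
10-minute recordings per exponent level).  The permutation-test null
calibration uses 500 replicate two-group studies of ten 60-s datasets per
group at 1,000 permutations, checking the pooled per-frequency rejection
rate at p < 0.05 against [0.03, 0.07]; the p-value floor check uses two
fully separated groups of 12 at 10,000 permutations.  All seeds are fixed
in the tests; changing them moves Monte-Carlo quantities by at most
binomial sampling error.

## Known limitations

- The rejection procedure's saturation property (above): dense
  contamination or very short recordings pass through unflagged.
- The aperiodic model has no peak component; a spectrum with strong
  narrow-band oscillations inside the fit range biases the exponent
  toward shallower slopes.  A peak-aware parameterization is out of
  scope.
- The EDF writer uses 1 s records and therefore requires whole-second
  recordings and an integer sampling rate; arbitrary lengths round-trip
  through delimited text instead.
- Channel-level rejection aggregates metrics as the mean over epochs
  before thresholding; with a single channel the channel criterion is
  vacuous (one value has zero spread against its own mean).
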