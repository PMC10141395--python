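# Methods

## The estimator

MFDFA assumes an equidistantly sampled, finite-variance series whose
fluctuations scale as a power law over an intermediate range of scales. It
is robust to slow additive trends (they are removed segment-wise by the
polynomial detrending) but not to nonstationarities faster than the
smallest scale — which is why protocol recordings are windowed to a single
constant-voltage stretch before analysis.

Implementation choices, in the order the algorithm runs:

* **Profile.** Cumulative sum of mean-subtracted samples. The last profile
  value is zero up to rounding; inputs with non-finite samples are rejected
  with the offending index named.
* **Scale grid.** The scaling region is a user choice; defaults are
  `n_min = 16`, `n_max = ⌊N/4⌋`, 30 log-spaced unique integers. The upper
  bound keeps at least four forward segments per scale so the segment
  average at extreme `q` is not dominated by one or two segments. `n_min`
  must exceed `l + 1` (the detrending fit must be over-determined).
* **Segmentation.** `M_n = ⌊N/n⌋` forward segments from the start plus
  `M_n` backward segments tiled from the end. There is no third "centred"
  pass. Reversal symmetry holds exactly at the level of the *profile*
  (forward segments of the reversed profile are the reversed backward
  segments); reversing the *series* shifts the segment boundaries by one
  sample because the profile is a cumulative sum, so series reversal changes
  `F_q(n)` by a small finite-size amount, not exactly zero. The tests assert
  the exact profile-level identity and bound the series-level effect.
* **Detrending.** Least squares polynomial, order `l = 1` by default
  (linear detrending is the standard practical choice; the order is
  configurable). The fit uses a segment-local abscissa mapped to [−1, 1]
  for conditioning; only residuals are consumed, so the abscissa scaling is
  observationally irrelevant. `F²(ν,n)` is the mean squared residual
  (division by `n`).
* **Fluctuation function.** Generalised mean of order `q/2` over the `2M_n`
  segment variances, evaluated in log space (`logsumexp`) so that extreme
  `q` neither overflows nor underflows for currents in amperes (variances
  ~10⁻²⁴ A²). At `q = 0` the logarithmic average
  `exp{(1/4M_n) Σ ln F²}` is used — the continuous limit of the generalised
  mean. Zero-variance segments make negative moments infinite; they are
  excluded from the `q ≤ 0` averages (for `q > 0` they contribute zero and
  the full `2M_n` denominator is kept), and their count is recorded per
  scale rather than silently dropped. A series whose every segment is
  exactly detrended at some scale ("locally deterministic") is a degenerate
  input and raises an error naming that condition.
* **Scaling fit.** Ordinary least squares of `ln F_q(n)` on `ln n` per `q`,
  optionally restricted to a scale sub-range; R² is reported per `q` so a
  user can inspect linearity and restrict the range. At least three scales
  are required.

## Singularity spectrum

`dH/dq` is computed by central finite differences on the `q` grid
(one-sided at the two ends); no smoothing is applied — splines would add a
hidden bandwidth parameter. By construction `f(α(0)) = 1` exactly. Two
width conventions are reported side by side because both are in use:
`width_alpha = max α − min α` (the spectrum's support) and
`width_hurst = max H(q) − min H(q)` (the convention used when widths are
tabulated directly from the generalised Hurst exponent). The spectrum's
"left-hand endpoint" is the small-α end, i.e. the point at the largest `q`
(most active segments); it lies below the apex `α(0)` whenever `α` is
decreasing in `q`.

The default `q` grid is −6..6 in steps of 0.25. Beyond |q| ≈ 6 the moments
of a ~60,000-sample series are dominated by a handful of segments and the
estimates are no longer reliable, which is why the grid stops there.

## Protocol pipeline

The voltage-step protocol holds −40 mV for 0.5 s, then a test potential
(±60, ±80, ±100 mV) for 3.5 s at dt = 5×10⁻⁵ s — 80,000 samples per
recording, five replicates per condition. Analysis must avoid the
capacitive/gating transient at the voltage step, so a window of the test
phase is extracted. The default window is defined *by sample count*: start
at the first sample at or after 0.501 s and take exactly 59,600 samples
(ending at 3.481 s). A time-bounded window [0.501 s, 3.49 s) would contain
59,780 samples; the count-based definition is the package default because
the analysis length, not the end time, is what downstream statistics depend
on. Both bounds and the count are configurable.

Replicates are treated as exchangeable: per-`q` mean and *sample* standard
deviation (ddof = 1, the natural choice at n = 5) are aggregated only over
replicates whose analysis completed; failures are logged and counted, and a
single-replicate condition reports σ as missing (NaN), never 0. No
inferential statistics across conditions are computed — the output is
descriptive tables (width mean/σ and endpoint coordinates per condition),
matching how such experiments are normally summarised.

## Synthetic generators

* **Fractional Gaussian noise** (`simulate_fgn`) uses exact circulant
  (Davies–Harte) embedding: the sample's second-order structure equals the
  target autocovariance `γ(k) = (σ²/2)(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})`
  exactly, which is what oracle tests need. If the embedding ever fails
  (H → 1 at unfavourable lengths) the error names the opt-in fallback
  (eigenvalue clipping, approximate spectral synthesis).
* **Binomial cascade** (`simulate_cascade`) recursively splits mass `a` /
  `1 − a`; the series of length `2^k` is positive and sums to 1. Its
  generalised Hurst exponent is known in closed form,
  `H(q) = 1/q − log₂(a^q + (1−a)^q)/q`, giving an analytic oracle for the
  whole pipeline. The canonical branch order is deterministic; seeded
  branch shuffling generates "replicates" that share `H(q)` in theory.
* **Channel gating** (`simulate_channel_current`) is a two-state
  (closed/open) Markov chain per channel with per-sample switch probability
  `1 − exp(−rate·dt)`, realised by sampling geometric dwell lengths (the
  identical law, drawn dwell-by-dwell); `n_channels` independent channels
  superpose, plus Gaussian instrumentation noise. Defaults (1 pA unitary
  current, 0.2 pA noise, opening rate scaling with |U|, closing rate
  150 s⁻¹, 3 channels) are order-of-magnitude plausible for single-channel
  vacuolar patches — they are *not* calibrated to any real dataset, and a
  warning is raised when `dt·rate > 0.1` (discretisation bias).

What the simulator does **not** emulate: correlated (non-Markov) gating,
voltage-dependent unitary conductance changes, seal drift, 1/f amplifier
noise, or any treatment mechanism. A two-state Markov chain has
exponentially decaying memory, so simulated recordings are *not* expected
to show the wide multifractal spectra of real channel data; passing tests
demonstrate that the analysis machinery is correct and reproducible, not
that the biology is reproduced. Where a test needs conditions with known,
graded multifractality (effect-recovery), cascade-based series stand in for
treatment recordings (`simulate_graded_multifractal_arm`).

## Validation design and problem sizes

* Monofractal recovery: fGn at H ∈ {0.3, 0.5, 0.7}, N = 2¹⁶, 20 seeds;
  mean `Ĥ(2)` lands within 0.05 of H (measured ≈0.005 off) and the `H(q)`
  spread over q ∈ [−6, 6] stays below 0.15 (measured ≈0.02–0.03).
* Multifractal recovery: cascade a = 0.75, k = 16; `Ĥ(q)` within 0.10
  (q ≥ 0) / 0.15 (q < 0) of the closed form; estimated α-width within 20%
  of the analytic width on the same q grid (≈1.58).
* Brute-force equivalence: an explicit-loop reference implementation
  (`tests/_naive.py`, np.polyfit per segment, direct power means) agrees
  with the vectorised estimator to ≤10⁻¹⁰ relative on 50 random series of
  N ≤ 2,000.
* Shuffle surrogate: randomly permuting a series destroys temporal ordering
  but preserves the value distribution. Multifractality has two sources —
  long-range correlation and a broad value distribution — and only the
  first collapses under shuffling. For strongly asymmetric cascades
  (a ≥ 0.7) the distributional part alone sustains ~58% of the width at any
  length, so the shuffle test uses a mildly asymmetric cascade (a = 0.6,
  ordering-dominated), where permutation removes ≥50% of the width
  (measured ≈66–69%).
* Effect recovery: eight conditions graded by cascade `a` from 0.55 to
  0.90, five shuffled-branch replicates each, k = 14; the rank correlation
  between recovered width and `a` is 1.0 in practice (threshold 0.8 over
  10 master seeds). k = 14 keeps the 400-fit sweep fast; oracle-accuracy
  tests use k = 16.
* Pipeline determinism: one master seed (via `numpy.random.SeedSequence`)
  fixes every simulated recording and therefore every downstream byte of
  the result bundle; reruns are compared byte-for-byte.

## Known limitations

* `H(q)` estimates at |q| ≳ 6 and spectrum endpoints inherit the usual
  small-sample bias of extreme moments; no bias correction or confidence
  intervals beyond per-fit R² are provided.
* The scaling region is chosen by the user (defaults above); no automatic
  crossover detection is attempted.
* No wavelet-based (WTMM) alternative, no partition-function formalism, and
  no binary (amplifier-native) file formats — recordings are plain text.
* Negative-moment averages depend on the zero-variance exclusion rule when
  a series is locally deterministic; the exclusion count is reported so
  such cases are visible.
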