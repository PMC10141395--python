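# mfpatch

Multifractal analysis of single-channel patch-clamp current time series.

Ion-channel gating is not memoryless: the sequence of open and closed states
of a channel can carry long-range correlations, and the strength of those
correlations can depend on the fluctuation scale — the current trace is then
*multifractal*. `mfpatch` implements the standard tool for detecting this,
multifractal detrended fluctuation analysis (MFDFA), together with the
protocol-aware machinery needed to apply it to voltage-step patch-clamp
experiments (such as recordings from fast-activating vacuolar K⁺ channels of
plant tonoplasts): analysis-window extraction, per-replicate analysis,
mean/σ aggregation across replicates, and per-condition summary tables.

It is aimed at electrophysiologists and biophysicists who have (or simulate)
single-channel current recordings and want scale-resolved correlation
measures rather than open-probability statistics alone.

## Method

For samples `x_1..x_N`:

1. **Profile** — `Y_j = Σ_{i≤j} (x_i − ⟨x⟩)`.
2. **Segmentation** — at each scale `n`, split the profile into
   `M_n = ⌊N/n⌋` disjoint segments of length `n`, once from the start and
   once from the end (`2M_n` segments, so an incomplete tail is still used).
3. **Detrending** — fit a polynomial of order `l` (linear by default) in each
   segment ν and keep the residual variance
   `F²(ν,n) = (1/n) Σ_j (Y_seg(j) − P_ν(j))²`.
4. **Fluctuation function** —
   `F_q(n) = { (1/2M_n) Σ_ν [F²(ν,n)]^{q/2} }^{1/q}`, with the logarithmic
   average at `q = 0`. Negative `q` weight the quietest segments, positive
   `q` the most active ones.
5. **Scaling** — `F_q(n) ~ n^{H(q)}`; the generalised Hurst exponent `H(q)`
   is the slope of `ln F_q` vs `ln n` (per-`q` R² is reported).

A Legendre transform converts `H(q)` into the singularity spectrum:
`α(q) = H(q) + q·dH/dq`, `f(α) = q[α − H(q)] + 1`. A monofractal collapses
to the point `(H, 1)`; the spectrum width (either the α span or
`max H(q) − min H(q)`) quantifies multifractal strength.

Synthetic references with known answers are built in: exact fractional
Gaussian noise (circulant embedding), the binomial multiplicative cascade
(closed-form `H(q)`), and a two-state Markov gating simulator that produces
protocol-shaped recordings (0.5 s holding at −40 mV, 3.5 s test potential,
dt = 5×10⁻⁵ s → 80,000 samples, five replicates per condition).

## Worked example

```python
import numpy as np
from mfpatch import (MFDFA, CascadeSpec, simulate_cascade,
                     cascade_hurst_theory, spectrum_summary)

x = simulate_cascade(CascadeSpec(a=0.75, k_levels=16))   # 65,536 samples
est = MFDFA().fit(x)                                     # q = -6..6, 30 scales
q = est.q_values_
for qi in (-6.0, -2.0, 0.0, 2.0, 6.0):
    i = int(np.flatnonzero(q == qi)[0])
    print(f"q={qi:+.0f}  H(q)={est.hurst_[i]:.3f}  "
          f"theory={cascade_hurst_theory(0.75, qi):.3f}  R^2={est.r_squared_[i]:.4f}")
summ = spectrum_summary(est.singularity_spectrum(), est.hurst_function())
print(f"spectrum width (alpha span): {summ.width_alpha:.3f}")
print(f"spectrum width (H span):     {summ.width_hurst:.3f}")
```

prints

```
q=-6  H(q)=1.810  theory=1.834  R^2=0.9983
q=-2  H(q)=1.550  theory=1.576  R^2=0.9990
q=+0  H(q)=1.182  theory=1.208  R^2=0.9984
q=+2  H(q)=0.796  theory=0.839  R^2=0.9970
q=+6  H(q)=0.577  theory=0.581  R^2=0.9986
spectrum width (alpha span): 1.535
spectrum width (H span):     1.233
```

`H(q)` falls from ≈1.8 to ≈0.58 as `q` sweeps the quiet-to-active segment
range — the strongly `q`-dependent exponent of a genuine multifractal — and
tracks the cascade's closed form at every `q` (R² ≈ 0.998 confirms clean
power-law scaling). The spectrum width ≈1.5 is far from the near-zero width
of noise; fitting white noise instead gives a flat `H(q) ≈ 0.5` and width
below 0.1.

The same analysis is available from the shell:

```bash
mfpatch simulate protocol --test-voltage -100 --seed 1 --out rec.txt
mfpatch analyze --input rec.txt --t-start 0.501 --window-samples 59600 --out rec
mfpatch spectrum --hurst-file rec_hurst.tsv --out rec
mfpatch pipeline --out study/ --master-seed 1    # full simulated study
```

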