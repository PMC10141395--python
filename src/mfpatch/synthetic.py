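"""Synthetic signals with known fractal structure and protocol-shaped recordings.

Three generators cover the reference cases needed to validate a multifractal
analysis of patch-clamp currents:

* exact fractional Gaussian noise (fGn) — the canonical *monofractal*, whose
  generalised Hurst exponent is constant, ``H(q) = H``;
* the binomial multiplicative cascade — the canonical *multifractal*, with a
  closed-form generalised Hurst exponent and singularity spectrum;
* a two-state (closed/open) Markov gating model producing stepwise
  single-channel current traces, which can be assembled into full
  voltage-step protocol recordings (holding phase followed by a test phase).

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .recording import Recording

__all__ = [
    "FgnSpec",
    "CascadeSpec",
    "GatingSpec",
    "ProtocolSpec",
    "simulate_fgn",
    "fgn_autocovariance",
    "simulate_cascade",
    "cascade_hurst_theory",
    "cascade_alpha_theory",
    "simulate_channel_current",
    "binary_dwells",
    "assemble_protocol_recording",
]


# ---------------------------------------------------------------------------
# fractional Gaussian noise
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FgnSpec:
    """Specification of a fractional Gaussian noise sample path.

    ``hurst`` must lie strictly in (0, 1); ``H = 0.5`` is i.i.d. Gaussian
    noise, ``H > 0.5`` persistent, ``H < 0.5`` anti-persistent.
    """

    hurst: float
    n_samples: int
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.hurst < 1.0):
            raise ParameterError(f"hurst must be in (0, 1), got {self.hurst}")
        if self.n_samples < 2:
            raise ParameterError("n_samples must be at least 2")
        if not (self.sigma > 0):
            raise ParameterError("sigma must be positive")


def fgn_autocovariance(hurst: float, lags, sigma: float = 1.0) -> np.ndarray:
    """Theoretical fGn autocovariance.

    gamma(k) = (sigma^2 / 2) (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H})
    """
    k = np.abs(np.asarray(lags, dtype=float))
    two_h = 2.0 * hurst
    return 0.5 * sigma**2 * (
        np.abs(k + 1) ** two_h - 2 * k**two_h + np.abs(k - 1) ** two_h
    )


def simulate_fgn(spec: FgnSpec, allow_approximate: bool = False) -> np.ndarray:
    """Generate exact fractional Gaussian noise by circulant embedding.

    The Davies–Harte construction embeds the n-point covariance in a 2n
    circulant matrix whose eigenvalues are the FFT of the covariance ring.
    When every eigenvalue is non-negative the sample is *exact*: its
    covariance equals :func:`fgn_autocovariance` in distribution.

    Parameters
    ----------
    spec
        Generator specification.
    allow_approximate
        If the embedding has negative eigenvalues (possible for H very close
        to 1 at some lengths), clip them to zero — an approximate spectral
        synthesis — instead of raising.
    """
    n = spec.n_samples
    gamma = fgn_autocovariance(spec.hurst, np.arange(n + 1), spec.sigma)
    # circulant first row: gamma_0..gamma_n, gamma_{n-1}..gamma_1
    ring = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(ring).real
    tol = -1e-9 * max(1.0, float(lam.max()))
    if lam.min() < tol:
        if not allow_approximate:
            raise ParameterError(
                "circulant embedding is not non-negative definite for "
                f"H={spec.hurst}, n={n}; pass allow_approximate=True to fall "
                "back to approximate spectral synthesis (clipped eigenvalues)"
            )
    lam = np.clip(lam, 0.0, None)
    rng = np.random.default_rng(spec.seed)
    m = ring.size  # 2n
    xi = (rng.standard_normal(m) + 1j * rng.standard_normal(m)) / np.sqrt(2.0)
    z = np.fft.fft(np.sqrt(lam) * xi) / np.sqrt(m)
    # real part carries covariance gamma/2 -> rescale by sqrt(2)
    return np.sqrt(2.0) * z.real[:n]


# ---------------------------------------------------------------------------
# binomial multiplicative cascade
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CascadeSpec:
    """Binomial multiplicative cascade of length ``2**k_levels``.

    Each interval recursively splits its mass into a fraction ``a`` (left
    half) and ``1 - a`` (right half).  ``a != 0.5`` yields a multifractal
    measure with the closed-form exponent of :func:`cascade_hurst_theory`.
    With ``shuffle=True`` the left/right assignment is randomised per branch
    (seeded); branch order does not change H(q).
    """

    a: float
    k_levels: int
    seed: int = 0
    shuffle: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.a < 1.0):
            raise ParameterError(f"a must be in (0, 1), got {self.a}")
        if self.k_levels < 1:
            raise ParameterError("k_levels must be positive")


def simulate_cascade(spec: CascadeSpec) -> np.ndarray:
    """Generate the cascade measure; values are positive and sum to 1."""
    rng = np.random.default_rng(spec.seed) if spec.shuffle else None
    mass = np.array([1.0])
    for _ in range(spec.k_levels):
        left = spec.a * mass
        right = (1.0 - spec.a) * mass
        if rng is not None:
            swap = rng.random(mass.size) < 0.5
            left, right = (
                np.where(swap, right, left),
                np.where(swap, left, right),
            )
        out = np.empty(2 * mass.size)
        out[0::2] = left
        out[1::2] = right
        mass = out
    return mass


def cascade_hurst_theory(a: float, q) -> np.ndarray:
    """Closed-form generalised Hurst exponent of the binomial cascade.

    H(q) = 1/q - log2(a^q + (1-a)^q) / q for q != 0, with the continuous
    limit H(0) = -(log2 a + log2(1-a)) / 2.
    """
    q = np.asarray(q, dtype=float)
    b = 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        h = 1.0 / q - np.log2(a**q + b**q) / q
    h0 = -(np.log2(a) + np.log2(b)) / 2.0
    return np.where(q == 0.0, h0, h)


def cascade_alpha_theory(a: float, q) -> np.ndarray:
    """Closed-form Hölder exponent alpha(q) = d(qH)/dq of the cascade."""
    q = np.asarray(q, dtype=float)
    b = 1.0 - a
    return -(a**q * np.log(a) + b**q * np.log(b)) / ((a**q + b**q) * np.log(2.0))


# ---------------------------------------------------------------------------
# two-state Markov channel gating
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GatingSpec:
    """Two-state (closed <-> open) Markov gating sampled at interval ``dt``.

    Rates are in 1/s; currents in amperes.  The per-sample switch
    probability is ``1 - exp(-rate * dt)``, so the stationary open
    probability is ``open_rate / (open_rate + close_rate)`` and dwell times
    are geometric (exponential in the continuum limit).  Defaults give a
    1 pA unitary current with 0.2 pA Gaussian instrumentation noise,
    order-of-magnitude plausible for single-channel patches.
    """

    open_rate: float
    close_rate: float
    unitary_current: float = 1e-12
    baseline_current: float = 0.0
    noise_sd: float = 0.2e-12
    n_channels: int = 1
    dt: float = 5e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.open_rate < 0:
            raise ParameterError("open_rate must be >= 0")
        if not (self.close_rate > 0):
            raise ParameterError("close_rate must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.n_channels < 1:
            raise ParameterError("n_channels must be >= 1")
        if not (self.dt > 0):
            raise ParameterError("dt must be > 0")

    @property
    def p_open(self) -> float:
        """Stationary open probability, open_rate / (open_rate + close_rate)."""
        return self.open_rate / (self.open_rate + self.close_rate)


def _simulate_states(g: GatingSpec, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Number of open channels per sample, shape (n_samples,)."""
    p_co = -np.expm1(-g.open_rate * g.dt)   # closed -> open per step
    p_oc = -np.expm1(-g.close_rate * g.dt)  # open -> closed per step
    n_open = np.zeros(n_samples, dtype=np.int64)
    for _ in range(g.n_channels):
        state = 1 if rng.random() < g.p_open else 0
        pos = 0
        while pos < n_samples:
            p_switch = p_oc if state else p_co
            if p_switch <= 0.0:
                dwell = n_samples - pos
            else:
                dwell = int(rng.geometric(p_switch))
            stop = min(pos + dwell, n_samples)
            if state:
                n_open[pos:stop] += 1
            pos = stop
            state = 1 - state
    return n_open


def simulate_channel_current(
    g: GatingSpec, n_samples: int, return_states: bool = False
):
    """Simulate a patch current: baseline + open-channel steps + noise.

    Each of ``n_channels`` independent channels follows the two-state chain;
    the sample current is ``baseline + n_open * unitary_current`` plus
    Gaussian noise of standard deviation ``noise_sd``.  A warning is issued
    when ``dt * rate > 0.1`` (per-sample discretisation bias).
    """
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    if g.dt * max(g.open_rate, g.close_rate) > 0.1:
        warnings.warn(
            "dt * rate exceeds 0.1; per-sample gating discretisation is biased",
            stacklevel=2,
        )
    rng = np.random.default_rng(g.seed)
    n_open = _simulate_states(g, n_samples, rng)
    current = g.baseline_current + n_open * g.unitary_current
    if g.noise_sd > 0:
        current = current + g.noise_sd * rng.standard_normal(n_samples)
    if return_states:
        return current, n_open
    return current


def binary_dwells(states: np.ndarray):
    """Run lengths of a binary state sequence, censored runs at the edges dropped.

    Returns ``(closed_dwells, open_dwells)`` in samples.
    """
    s = np.asarray(states).astype(bool).astype(np.int8)
    change = np.flatnonzero(np.diff(s)) + 1
    if change.size < 2:
        return np.array([], dtype=int), np.array([], dtype=int)
    lengths = np.diff(change)
    values = s[change[:-1]]
    return lengths[values == 0], lengths[values == 1]


# ---------------------------------------------------------------------------
# voltage-step protocol assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProtocolSpec:
    """Voltage-step protocol: a holding phase followed by a test phase.

    Defaults reproduce the standard FV-channel protocol: 0.5 s holding at
    -40 mV, then 3.5 s at the test potential, sampled at 5e-5 s — exactly
    80,000 samples per recording, five replicates per condition.
    """

    test_voltage: float
    holding_voltage: float = -40.0
    holding_duration: float = 0.5
    test_duration: float = 3.5
    dt: float = 5e-5
    n_replicates: int = 5

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ParameterError("dt must be > 0")
        if self.holding_duration < 0 or self.test_duration <= 0:
            raise ParameterError("durations must be non-negative (test > 0)")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")

    @property
    def n_holding(self) -> int:
        return round(self.holding_duration / self.dt)

    @property
    def n_test(self) -> int:
        return round(self.test_duration / self.dt)

    @property
    def n_samples(self) -> int:
        """Total samples; defaults yield 80,000."""
        return round((self.holding_duration + self.test_duration) / self.dt)


def assemble_protocol_recording(
    p: ProtocolSpec,
    g_holding: GatingSpec,
    g_test: GatingSpec,
    replicate: int = 1,
    condition: str = "control",
    incubation_min: float | None = None,
) -> Recording:
    """Concatenate holding- and test-phase gating currents into one Recording."""
    if not (g_holding.dt == g_test.dt == p.dt):
        raise ParameterError(
            f"sampling intervals disagree: protocol dt={p.dt}, "
            f"holding dt={g_holding.dt}, test dt={g_test.dt}"
        )
    parts = []
    if p.n_holding > 0:
        parts.append(simulate_channel_current(g_holding, p.n_holding))
    parts.append(simulate_channel_current(g_test, p.n_test))
    values = np.concatenate(parts)
    return Recording(
        values=values,
        dt=p.dt,
        voltage_mV=p.test_voltage,
        replicate=replicate,
        condition=condition,
        incubation_min=incubation_min,
    )
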