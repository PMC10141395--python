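"""Singularity spectrum: Legendre transform of the generalised Hurst exponent.

With ``tau(q) = q H(q) - 1`` the Hölder exponent and spectrum follow as

    alpha(q) = H(q) + q dH/dq,        f(alpha) = q [alpha(q) - H(q)] + 1.

``alpha`` measures local signal regularity (smaller alpha = rougher);
``f(alpha)`` is the fractal dimension of the set of points with that
regularity.  A monofractal collapses to the single point ``(H, 1)``; the
width of the alpha support quantifies the strength of multifractality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .mfdfa import HurstFunction

__all__ = ["SingularitySpectrum", "SpectrumSummary", "legendre_transform", "spectrum_summary"]


@dataclass
class SingularitySpectrum:
    """Paired (alpha(q), f(alpha(q))) curve on the q grid of its Hurst function."""

    q_values: np.ndarray
    alpha: np.ndarray
    f_alpha: np.ndarray


@dataclass
class SpectrumSummary:
    """Scalar descriptors of one spectrum.

    ``width_alpha`` is the span of the Hölder exponents, max alpha - min
    alpha.  ``width_hurst`` is max H(q) - min H(q) over the q grid — the
    convention used when the spectrum width is tabulated directly from the
    generalised Hurst exponent.  The left-hand endpoint is the small-alpha
    end of the curve, i.e. the point at the largest q.
    """

    width_alpha: float
    width_hurst: float
    endpoint_alpha: float
    endpoint_f: float
    q_min: float
    q_max: float


def _as_q_h(h) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(h, HurstFunction):
        return np.asarray(h.q_values, float), np.asarray(h.hurst, float)
    q, hurst = h
    return np.asarray(q, float), np.asarray(hurst, float)


def legendre_transform(h) -> SingularitySpectrum:
    """Compute (alpha, f) from H(q) by finite-difference Legendre transform.

    ``dH/dq`` uses central differences on the q grid (one-sided at the two
    endpoints).  Accepts a :class:`~mfpatch.mfdfa.HurstFunction` or a
    ``(q_values, hurst)`` pair.  By construction ``f(alpha(0)) = 1`` exactly.
    """
    q, hurst = _as_q_h(h)
    if q.size < 3:
        raise ParameterError("need H(q) on at least 3 grid points")
    if np.any(np.diff(q) <= 0):
        raise ParameterError("q grid must be strictly increasing")
    dh = np.gradient(hurst, q)
    alpha = hurst + q * dh
    f_alpha = q * (alpha - hurst) + 1.0
    return SingularitySpectrum(q_values=q, alpha=alpha, f_alpha=f_alpha)


def spectrum_summary(s: SingularitySpectrum, h=None) -> SpectrumSummary:
    """Width and endpoint descriptors of a singularity spectrum.

    Both width conventions are reported: the alpha span of the spectrum and
    the H(q) span (max - min over the q grid).  If ``h`` is omitted the H
    span is recovered from the spectrum via ``H = [q alpha - f + 1]/q``.
    """
    if s.alpha.size == 0:
        raise ParameterError("empty spectrum")
    if h is not None:
        _, hurst = _as_q_h(h)
    else:
        q = s.q_values
        with np.errstate(divide="ignore", invalid="ignore"):
            hurst = np.where(q != 0, (q * s.alpha - s.f_alpha + 1.0) / np.where(q != 0, q, 1.0), np.nan)
        hurst = hurst[np.isfinite(hurst)]
    return SpectrumSummary(
        width_alpha=float(s.alpha.max() - s.alpha.min()),
        width_hurst=float(hurst.max() - hurst.min()),
        endpoint_alpha=float(s.alpha[-1]),
        endpoint_f=float(s.f_alpha[-1]),
        q_min=float(s.q_values[0]),
        q_max=float(s.q_values[-1]),
    )
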