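"""Multifractal detrended fluctuation analysis (MFDFA).

Given equidistant samples ``x_1..x_N`` the method proceeds in five steps:

1. integrate the mean-subtracted signal into the profile
   ``Y_j = sum_{i<=j} (x_i - <x>)``;
2. at each scale ``n`` divide the profile into ``M_n = floor(N/n)`` disjoint
   segments of length ``n``, once from the start and once from the end of the
   series (``2 M_n`` segments in total, so an incomplete tail is still used);
3. detrend each segment with a least-squares polynomial of order ``l``
   (linear by default) and record the residual variance ``F^2(nu, n)``;
4. form the q-th-order fluctuation function
   ``F_q(n) = {(1/2M_n) sum_nu [F^2(nu, n)]^{q/2}}^{1/q}``
   (logarithmic average at ``q = 0``);
5. estimate the generalised Hurst exponent ``H(q)`` as the slope of
   ``ln F_q(n)`` against ``ln n``.

For a monofractal series ``H(q)`` is constant; a ``q``-dependent ``H``
signals multifractality — negative ``q`` magnifies the small-fluctuation
segments (short-range structure), positive ``q`` the large ones.

The :class:`MFDFA` estimator is the main entry point; the module-level
functions expose the individual steps and are what the estimator runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegenerateSeriesError, FitError, InputError, ParameterError

__all__ = [
    "MFDFA",
    "MultifractalFeatures",
    "HurstFunction",
    "FluctuationSurface",
    "default_q_grid",
    "compute_profile",
    "build_scale_grid",
    "segment_slices",
    "segment_variances",
    "segment_fluctuation",
    "fluctuation_function",
    "estimate_hurst",
    "mfdfa",
]

#: Zero-variance threshold: residual variances at or below this are treated
#: as exactly detrended segments and excluded from q <= 0 averages.
_ZERO_TOL = np.finfo(float).tiny


def default_q_grid(q_min: float = -6.0, q_max: float = 6.0, q_step: float = 0.25) -> np.ndarray:
    """Moment orders from -6 to +6 in steps of 0.25 (q = 0 included)."""
    n = int(round((q_max - q_min) / q_step))
    return q_min + q_step * np.arange(n + 1)


def _validate_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise InputError("expected a one-dimensional series")
    if x.size < 2:
        raise InputError("series must contain at least two samples")
    bad = ~np.isfinite(x)
    if bad.any():
        raise InputError(f"non-finite sample at index {int(np.flatnonzero(bad)[0])}")
    return x


def compute_profile(x) -> np.ndarray:
    """Integrated mean-subtracted profile Y_j = sum_{i<=j} (x_i - <x>)."""
    x = _validate_series(x)
    return np.cumsum(x - x.mean())


def build_scale_grid(
    n_samples: int,
    n_min: int = 16,
    n_max: int | None = None,
    n_scales: int = 30,
    detrend_order: int = 1,
) -> np.ndarray:
    """Logarithmically spaced integer scales.

    ``n_max`` defaults to ``floor(N/4)`` so the largest scale still yields at
    least four forward segments; ``n_min`` must exceed ``detrend_order + 1``
    so the polynomial fit is over-determined.
    """
    if n_max is None:
        n_max = n_samples // 4
    if n_max > n_samples:
        raise ParameterError(f"n_max={n_max} exceeds series length {n_samples}")
    if n_min < detrend_order + 2:
        raise ParameterError(
            f"n_min={n_min} too small for detrend order {detrend_order} "
            f"(need at least {detrend_order + 2})"
        )
    if not (n_min < n_max):
        raise ParameterError(f"need n_min < n_max, got {n_min} >= {n_max}")
    grid = np.unique(
        np.round(np.exp(np.linspace(np.log(n_min), np.log(n_max), n_scales))).astype(int)
    )
    return grid


def segment_slices(n_samples: int, scale: int) -> list[tuple[int, int]]:
    """0-based (start, stop) bounds of the 2*M_n segments at one scale.

    Forward segments nu = 1..M_n tile from the start; backward segments
    nu = M_n+1..2M_n tile symmetrically from the end (the segment for
    nu = M_n + k covers the k-th length-n block counted from the tail).
    """
    m = n_samples // scale
    forward = [(i * scale, (i + 1) * scale) for i in range(m)]
    backward = [(n_samples - (k + 1) * scale, n_samples - k * scale) for k in range(m)]
    return forward + backward


def _design_matrix(scale: int, order: int) -> np.ndarray:
    # segment-local abscissa mapped to [-1, 1] for conditioning; residuals
    # are invariant to the abscissa affine scaling
    t = np.linspace(-1.0, 1.0, scale) if scale > 1 else np.zeros(1)
    return np.vander(t, order + 1, increasing=True)


def segment_variances(profile: np.ndarray, scale: int, detrend_order: int = 1) -> np.ndarray:
    """Residual variances F^2(nu, n) of all 2*M_n segments at one scale.

    Each segment is detrended with a least-squares polynomial of the given
    order; the returned value is the mean squared residual (division by n).
    """
    n_samples = profile.size
    if scale <= detrend_order + 1:
        raise ParameterError(
            f"scale {scale} too small to detrend with order {detrend_order}"
        )
    m = n_samples // scale
    if m < 1:
        raise ParameterError(f"scale {scale} exceeds series length {n_samples}")
    fwd = profile[: m * scale].reshape(m, scale)
    bwd = profile[n_samples - m * scale :].reshape(m, scale)[::-1]
    segs = np.vstack([fwd, bwd])  # (2m, scale)
    design = _design_matrix(scale, detrend_order)
    coef, *_ = np.linalg.lstsq(design, segs.T)
    resid = segs.T - design @ coef
    return np.mean(resid**2, axis=0)


def segment_fluctuation(
    profile: np.ndarray, scale: int, nu: int, detrend_order: int = 1
) -> float:
    """F^2(nu, n) for one 1-based segment index nu in 1..2*M_n."""
    profile = np.asarray(profile, dtype=float)
    bounds = segment_slices(profile.size, scale)
    if not (1 <= nu <= len(bounds)):
        raise ParameterError(f"segment index {nu} outside 1..{len(bounds)}")
    if scale <= detrend_order + 1:
        raise ParameterError(
            f"scale {scale} too small to detrend with order {detrend_order}"
        )
    start, stop = bounds[nu - 1]
    seg = profile[start:stop]
    design = _design_matrix(scale, detrend_order)
    coef, *_ = np.linalg.lstsq(design, seg)
    resid = seg - design @ coef
    return float(np.mean(resid**2))


def _fq_from_variances(f2: np.ndarray, q: float) -> tuple[float, int]:
    """(F_q(n), number of zero-variance segments excluded)."""
    f2 = np.asarray(f2, dtype=float)
    positive = f2 > _ZERO_TOL
    n_zero = int(f2.size - positive.sum())
    if not positive.any():
        raise DegenerateSeriesError(
            "all segment variances vanish: series is locally deterministic at this scale"
        )
    log_f2 = np.log(f2[positive])
    if q == 0.0:
        # logarithmic average, the q -> 0 limit of the generalised mean
        return float(np.exp(0.5 * np.mean(log_f2))), n_zero
    # q > 0: zero-variance segments contribute 0 to the sum, keep full count;
    # q < 0: they would be infinite, exclude them (count reported)
    denom = f2.size if q > 0 else int(positive.sum())
    log_mean = logsumexp(0.5 * q * log_f2) - np.log(denom)
    return float(np.exp(log_mean / q)), n_zero


def fluctuation_function(f2, q: float) -> float:
    """q-th-order fluctuation F_q(n) from the segment variances at one scale."""
    value, _ = _fq_from_variances(np.asarray(f2, dtype=float), float(q))
    return value


@dataclass
class FluctuationSurface:
    """F^2(nu, n) per scale and the fluctuation matrix F_q(n)."""

    scales: np.ndarray                      # (n_scales,)
    q_values: np.ndarray                    # (n_q,)
    fq: np.ndarray                          # (n_q, n_scales)
    segment_variances: dict = field(repr=False, default_factory=dict)
    n_zero_segments: np.ndarray | None = None  # per scale


@dataclass
class HurstFunction:
    """Generalised Hurst exponent H(q) with per-q fit diagnostics."""

    q_values: np.ndarray
    hurst: np.ndarray
    intercept: np.ndarray
    r_squared: np.ndarray
    scales: np.ndarray          # scales used in the fit
    fit_range: tuple | None = None


def estimate_hurst(
    scales,
    fq,
    q_values=None,
    fit_range: tuple[float, float] | None = None,
) -> HurstFunction:
    """Per-q OLS of ln F_q(n) on ln n; the slope is H(q).

    ``fit_range=(n_lo, n_hi)`` restricts the fit to scales inside the
    inclusive bounds (the scaling region); the coefficient of determination
    is reported per q so users can judge and restrict the linear region.
    """
    scales = np.asarray(scales, dtype=float)
    fq = np.atleast_2d(np.asarray(fq, dtype=float))
    if q_values is None:
        q_values = np.arange(fq.shape[0], dtype=float)
    q_values = np.asarray(q_values, dtype=float)
    mask = np.ones(scales.size, dtype=bool)
    if fit_range is not None:
        lo, hi = fit_range
        mask = (scales >= lo) & (scales <= hi)
    if mask.sum() < 3:
        raise FitError(f"need at least 3 scales in the fit range, have {int(mask.sum())}")
    sub = fq[:, mask]
    if not np.all(np.isfinite(sub)) or np.any(sub <= 0):
        raise FitError("F_q(n) must be positive and finite over the fit range")
    ln_n = np.log(scales[mask])
    ln_f = np.log(sub)
    # closed-form OLS, vectorised over q
    x = ln_n - ln_n.mean()
    slope = (ln_f @ x) / (x @ x)
    intercept = ln_f.mean(axis=1) - slope * ln_n.mean()
    pred = intercept[:, None] + slope[:, None] * ln_n
    ss_res = np.sum((ln_f - pred) ** 2, axis=1)
    ss_tot = np.sum((ln_f - ln_f.mean(axis=1, keepdims=True)) ** 2, axis=1)
    tiny = 1e-300
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > tiny, 1.0 - ss_res / np.maximum(ss_tot, tiny), 1.0)
    return HurstFunction(
        q_values=q_values,
        hurst=slope,
        intercept=intercept,
        r_squared=r2,
        scales=scales[mask].astype(int),
        fit_range=fit_range,
    )


class MFDFA(BaseEstimator):
    """Multifractal detrended fluctuation analysis of one time series.

    Parameters
    ----------
    q_values : array-like or None
        Moment orders; default -6..6 in steps of 0.25 (q = 0 handled by the
        logarithmic average).
    n_min, n_max, n_scales : int
        Scale grid: ~``n_scales`` log-spaced integers between ``n_min`` and
        ``n_max`` (default ``floor(N/4)``).
    detrend_order : int
        Polynomial order of the segment detrending (1 = linear, the usual
        choice).
    fit_range : (float, float) or None
        Inclusive scale bounds for the H(q) fit; default uses every scale.

    Attributes
    ----------
    scales_, q_values_ : the grids actually used.
    fluctuation_ : ndarray (n_q, n_scales), F_q(n).
    hurst_, intercept_, r_squared_ : per-q scaling fit results.
    n_zero_segments_ : per-scale count of zero-variance segments excluded
        from q <= 0 averages.

    Examples
    --------
    >>> from mfpatch import MFDFA, simulate_cascade, CascadeSpec
    >>> x = simulate_cascade(CascadeSpec(a=0.75, k_levels=14))
    >>> est = MFDFA().fit(x)
    >>> est.hurst_[est.q_values_ == 2.0]  # doctest: +SKIP
    array([0.84...])
    """

    def __init__(
        self,
        q_values=None,
        n_min: int = 16,
        n_max: int | None = None,
        n_scales: int = 30,
        detrend_order: int = 1,
        fit_range: tuple[float, float] | None = None,
    ):
        self.q_values = q_values
        self.n_min = n_min
        self.n_max = n_max
        self.n_scales = n_scales
        self.detrend_order = detrend_order
        self.fit_range = fit_range

    def fit(self, X, y=None) -> "MFDFA":
        """Run the full analysis on one series and store the results."""
        x = _validate_series(X)
        q = (
            default_q_grid()
            if self.q_values is None
            else np.asarray(self.q_values, dtype=float)
        )
        if q.size == 0:
            raise ParameterError("q grid must be non-empty")
        if np.any(np.diff(q) <= 0):
            raise ParameterError("q grid must be strictly increasing")
        profile = np.cumsum(x - x.mean())
        scales = build_scale_grid(
            x.size, self.n_min, self.n_max, self.n_scales, self.detrend_order
        )
        fq = np.empty((q.size, scales.size))
        n_zero = np.zeros(scales.size, dtype=int)
        variances = {}
        for j, n in enumerate(scales):
            f2 = segment_variances(profile, int(n), self.detrend_order)
            variances[int(n)] = f2
            for i, qi in enumerate(q):
                fq[i, j], nz = _fq_from_variances(f2, float(qi))
            n_zero[j] = nz
        hf = estimate_hurst(scales, fq, q, self.fit_range)
        self.n_samples_ = x.size
        self.profile_last_ = float(profile[-1])
        self.scales_ = scales
        self.q_values_ = q
        self.fluctuation_ = fq
        self.segment_variances_ = variances
        self.n_zero_segments_ = n_zero
        self.hurst_ = hf.hurst
        self.intercept_ = hf.intercept
        self.r_squared_ = hf.r_squared
        self.fit_scales_ = hf.scales
        return self

    def hurst_function(self) -> HurstFunction:
        self._check_fitted()
        return HurstFunction(
            q_values=self.q_values_,
            hurst=self.hurst_,
            intercept=self.intercept_,
            r_squared=self.r_squared_,
            scales=self.fit_scales_,
            fit_range=self.fit_range,
        )

    def fluctuation_surface(self) -> FluctuationSurface:
        self._check_fitted()
        return FluctuationSurface(
            scales=self.scales_,
            q_values=self.q_values_,
            fq=self.fluctuation_,
            segment_variances=self.segment_variances_,
            n_zero_segments=self.n_zero_segments_,
        )

    def singularity_spectrum(self):
        """Singularity spectrum (alpha, f(alpha)) of the fitted H(q)."""
        from .spectrum import legendre_transform

        return legendre_transform(self.hurst_function())

    def _check_fitted(self) -> None:
        if not hasattr(self, "hurst_"):
            raise FitError("this MFDFA instance is not fitted yet; call fit first")


class MultifractalFeatures(BaseEstimator, TransformerMixin):
    """Extract multifractal summary features from a batch of series.

    ``transform`` maps each row of ``X`` (or each element of a list of 1-d
    arrays) to ``[H(2), width_H, width_alpha, endpoint_alpha, endpoint_f]``,
    making the analysis usable inside sklearn pipelines.
    """

    _feature_names = (
        "hurst_q2",
        "width_hurst",
        "width_alpha",
        "endpoint_alpha",
        "endpoint_f",
    )

    def __init__(
        self,
        q_values=None,
        n_min: int = 16,
        n_max: int | None = None,
        n_scales: int = 30,
        detrend_order: int = 1,
        fit_range: tuple[float, float] | None = None,
    ):
        self.q_values = q_values
        self.n_min = n_min
        self.n_max = n_max
        self.n_scales = n_scales
        self.detrend_order = detrend_order
        self.fit_range = fit_range

    def fit(self, X, y=None) -> "MultifractalFeatures":
        self.n_features_out_ = len(self._feature_names)
        return self

    def transform(self, X) -> np.ndarray:
        from .spectrum import spectrum_summary

        rows = []
        for series in X:
            est = MFDFA(**self.get_params()).fit(series)
            hf = est.hurst_function()
            summ = spectrum_summary(est.singularity_spectrum(), hf)
            q = est.q_values_
            idx = int(np.argmin(np.abs(q - 2.0)))
            rows.append(
                [
                    est.hurst_[idx],
                    summ.width_hurst,
                    summ.width_alpha,
                    summ.endpoint_alpha,
                    summ.endpoint_f,
                ]
            )
        return np.asarray(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self._feature_names, dtype=object)


def mfdfa(
    x,
    q_values=None,
    n_min: int = 16,
    n_max: int | None = None,
    n_scales: int = 30,
    detrend_order: int = 1,
    fit_range: tuple[float, float] | None = None,
) -> tuple[FluctuationSurface, HurstFunction]:
    """Functional one-shot MFDFA; thin wrapper over the :class:`MFDFA` estimator."""
    est = MFDFA(
        q_values=q_values,
        n_min=n_min,
        n_max=n_max,
        n_scales=n_scales,
        detrend_order=detrend_order,
        fit_range=fit_range,
    ).fit(x)
    return est.fluctuation_surface(), est.hurst_function()
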