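"""Signal-to-concentration conversion and gamma-variate bolus characterization.

The tracer concentration is obtained from the T2/T2* signal drop as

    C(t) = -(K / TE) * ln(S(t) / S0)

with S0 the mean pre-contrast baseline signal.  K is the (tissue- and
field-dependent) relaxivity constant; because any global scale on C cancels
in the AIF/tissue ratio that yields CBF, K and TE are applied literally in
whatever consistent unit the caller supplies.

Candidate arterial input functions are characterized by fitting the
first-pass portion of the curve with a gamma-variate

    y(t) = A * (t - t_arrival)^alpha * exp(-(t - t_arrival)/beta)

and reading off time-to-peak (TTP = t_arrival + alpha*beta), peak height,
full width at half maximum, and the onset time (the first raw time point
above the mean of the whole curve).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq, curve_fit

from .series import ConcentrationSeries, DynamicSeries

__all__ = [
    "ConversionParams",
    "GammaFit",
    "AIFFeatures",
    "GammaFitError",
    "signal_to_concentration",
    "gamma_variate",
    "fit_gamma_variate",
    "aif_features",
]

log = logging.getLogger(__name__)

#: default gamma-variate fit window, 1-based inclusive time points
DEFAULT_FIT_WINDOW = (7, 25)


class GammaFitError(RuntimeError):
    """Raised when the gamma-variate fit cannot converge.

    Carries ``best_rss`` (the best residual sum of squares reached, or inf).
    """

    def __init__(self, msg: str, best_rss: float = math.inf):
        super().__init__(msg)
        self.best_rss = best_rss


@dataclass(frozen=True)
class ConversionParams:
    """Constants of the log-ratio concentration conversion.

    ``k`` and ``te`` must share a time unit (e.g. K = 7.62 with TE = 60 if
    TE is entered in ms); ``baseline_window`` is 1-based inclusive.
    """

    k: float = 7.62
    te: float = 0.06
    baseline_window: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.k <= 0 or self.te <= 0:
            raise ValueError("k and te must be positive")


@dataclass(frozen=True)
class GammaFit:
    amplitude: float
    t_arrival: float
    alpha: float
    beta: float
    rss: float
    fit_window: Tuple[int, int]

    @property
    def ttp(self) -> float:
        """Time of the fitted peak, t_arrival + alpha*beta."""
        return self.t_arrival + self.alpha * self.beta

    @property
    def peak_value(self) -> float:
        """Analytic mode value A * (alpha*beta)^alpha * e^(-alpha)."""
        return self.amplitude * (self.alpha * self.beta) ** self.alpha * math.exp(-self.alpha)

    def __call__(self, t) -> np.ndarray:
        return gamma_variate(t, self.amplitude, self.t_arrival, self.alpha, self.beta)


@dataclass(frozen=True)
class AIFFeatures:
    """Bolus-shape indicators of a candidate AIF (all times in seconds)."""

    ttp: float
    onset_time: float
    fwhm: float
    peak_height: float


# ---------------------------------------------------------------------------
# concentration conversion
# ---------------------------------------------------------------------------

def signal_to_concentration(series: DynamicSeries, p: ConversionParams) -> ConcentrationSeries:
    """Convert a signal series to concentration via C = -(K/TE) ln(S/S0).

    S0 is the per-voxel mean over the baseline window.  Voxels with
    non-positive signal samples yield NaN at those samples (logged); a
    voxel with non-positive S0 is NaN throughout.
    """
    window = p.baseline_window or series.baseline_window
    lo, hi = window
    if not (1 <= lo <= hi <= series.n_timepoints):
        raise ValueError(f"invalid baseline window {window}")
    s = series.data
    s0 = s[lo - 1:hi].mean(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = s / s0
        conc = -(p.k / p.te) * np.log(ratio)
    bad = ~np.isfinite(conc) | (ratio <= 0)
    if bad.any():
        log.warning("signal_to_concentration: %d non-positive samples flagged NaN", int(bad.sum()))
        conc = np.where(bad, np.nan, conc)

    return ConcentrationSeries(
        data=conc,
        dt=series.dt,
        te=series.te,
        injection_tp=series.injection_tp,
        baseline_window=window,
        meta={**series.meta, "conversion_k": p.k, "conversion_te": p.te,
              "baseline_window": window},
    )


# ---------------------------------------------------------------------------
# gamma-variate fitting
# ---------------------------------------------------------------------------

def gamma_variate(t, amplitude: float, t_arrival: float, alpha: float, beta: float) -> np.ndarray:
    """Evaluate A (t-t0)^alpha e^{-(t-t0)/beta}, zero for t <= t0."""
    t = np.asarray(t, dtype=float)
    shifted = t - t_arrival
    out = np.zeros_like(shifted)
    pos = shifted > 0
    out[pos] = amplitude * shifted[pos] ** alpha * np.exp(-shifted[pos] / beta)
    return out


def fit_gamma_variate(
    curve: Sequence[float],
    dt: float,
    fit_window: Tuple[int, int] = DEFAULT_FIT_WINDOW,
    starts: Optional[Sequence[Tuple[int, float]]] = None,
    maxfev: int = 20000,
) -> GammaFit:
    """Least-squares gamma-variate fit of the first-pass bolus.

    ``fit_window`` is 1-based inclusive over time points.  Deterministic
    multi-start: t_arrival seeded at the last pre-peak sample minus
    {0, 1, 2} sampling intervals, crossed with alpha in {2, 3}; the start
    with the lowest residual sum of squares wins (ties by start order).
    A fit whose TTP falls outside the window is rejected.
    """
    y = np.asarray(curve, dtype=float)
    lo, hi = fit_window
    if not (1 <= lo <= hi <= y.size):
        raise ValueError(f"fit window {fit_window} outside curve of length {y.size}")
    idx = np.arange(lo - 1, hi)
    if idx.size < 6:
        raise ValueError("fit window must contain at least 6 points")
    yw = y[idx]
    if not np.isfinite(yw).all():
        finite = np.isfinite(yw)
        if finite.sum() < 6:
            raise GammaFitError("too few finite samples in fit window")
        idx, yw = idx[finite], yw[finite]
    if np.ptp(yw) == 0:
        raise GammaFitError("flat curve: gamma-variate fit undefined")
    k_peak_global = int(np.nanargmax(y))
    if not (idx[0] <= k_peak_global <= idx[-1]):
        raise ValueError("fit window must contain the curve maximum")

    t = idx * dt
    k_peak = idx[int(np.argmax(yw))]
    y_peak = float(np.max(yw))
    t_lo, t_hi = t[0], t[-1]

    if starts is None:
        starts = [(m, a) for m in (0, 1, 2) for a in (2.0, 3.0)]
    best: Optional[Tuple[float, np.ndarray]] = None
    for m, a_start in starts:
        t0_start = (k_peak - 1 - m) * dt
        b_start = max((k_peak * dt - t0_start) / a_start, dt / 10)
        amp_start = y_peak / ((a_start * b_start) ** a_start * math.exp(-a_start))
        p0 = [amp_start, t0_start, a_start, b_start]
        try:
            popt, _ = curve_fit(
                gamma_variate, t, yw, p0=p0,
                bounds=([0.0, t_lo - 20 * dt, 0.2, dt / 50],
                        [np.inf, k_peak * dt - dt / 4, 20.0, 1e3]),
                maxfev=maxfev,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((gamma_variate(t, *popt) - yw) ** 2))
        ttp = popt[1] + popt[2] * popt[3]
        if not (t_lo <= ttp <= t_hi):
            continue
        if best is None or rss < best[0] - 1e-15:
            best = (rss, popt)
    if best is None:
        raise GammaFitError("gamma-variate fit failed to converge from all starts")
    rss, popt = best
    return GammaFit(
        amplitude=float(popt[0]), t_arrival=float(popt[1]),
        alpha=float(popt[2]), beta=float(popt[3]),
        rss=rss, fit_window=fit_window,
    )


def aif_features(curve: Sequence[float], fit: GammaFit, dt: float) -> AIFFeatures:
    """Bolus indicators: TTP and FWHM/peak from the fit, onset from the raw curve.

    Onset is ``dt`` times the first (0-based) index whose raw value strictly
    exceeds the mean of the whole curve.  FWHM is found by root bisection of
    the fitted curve on both sides of the peak.
    """
    y = np.asarray(curve, dtype=float)
    mean = float(np.nanmean(y))
    above = np.nonzero(y > mean)[0]
    if above.size == 0:
        raise ValueError("onset undefined: no sample above the curve mean")
    onset = float(above[0]) * dt

    peak = fit.peak_value
    if peak <= 0:
        raise ValueError("non-positive fitted peak")
    half = peak / 2.0
    ttp = fit.ttp
    span_end = (y.size - 1) * dt

    def g(t):
        return float(fit(np.array([t]))[0] - half)

    left = brentq(g, fit.t_arrival + 1e-9, ttp)
    if g(span_end) >= 0:
        raise ValueError("right half-maximum not bracketed inside the sampled span")
    right = brentq(g, ttp, span_end)
    return AIFFeatures(ttp=ttp, onset_time=onset, fwhm=right - left, peak_height=peak)
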