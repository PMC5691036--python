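"""Oxic/anoxic horizon estimation from dissolved-oxygen depth profiles.

Dissolved oxygen in these soils decays roughly exponentially with depth.
Fitting DO(z) = a * exp(-b z) to all measurements for one ecosite and
month gives a smooth curve whose crossing of a DO threshold (default
20 umol O2 per kg H2O) defines the oxic horizon.  Confidence bounds are
the 2.5th and 97.5th percentiles of the crossing depth under a parametric
bootstrap of the fitted parameters, and horizons are interpolated linearly
in time between monthly estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_DO_THRESHOLD",
    "DOMeasurementSet",
    "OxicHorizonEstimate",
    "HorizonSeries",
    "DOProfileModel",
    "fit_reverse_exponential",
    "horizon_from_fit",
    "interpolate_horizon",
]

DEFAULT_DO_THRESHOLD = 20.0  # umol O2 per kg H2O

_B_MIN = 1e-6  # cm^-1, lower bound on the decay rate (flat-profile guard)


@dataclass
class DOMeasurementSet:
    """Dissolved-oxygen measurements vs depth for one ecosite and month.

    Depths are cm below the soil surface (positive downward); DO readings
    above the soil surface are excluded before constructing the set.
    """

    depth_cm: np.ndarray
    do_umol_per_kg: np.ndarray
    ecosite: str = ""
    month: str | float = ""

    def __post_init__(self) -> None:
        self.depth_cm = np.asarray(self.depth_cm, dtype=float)
        self.do_umol_per_kg = np.asarray(self.do_umol_per_kg, dtype=float)
        if self.depth_cm.shape != self.do_umol_per_kg.shape:
            raise ValueError("depth and DO arrays must have equal length")
        if self.depth_cm.size < 4:
            raise ValueError("need at least 4 DO measurements")
        if (self.do_umol_per_kg < 0).any():
            raise ValueError("DO must be non-negative")


@dataclass
class OxicHorizonEstimate:
    """Threshold-crossing depth of the fitted DO curve, with bounds."""

    horizon_cm: float
    lower_cm: float
    upper_cm: float
    threshold: float = DEFAULT_DO_THRESHOLD
    fit_params: tuple[float, float] = (np.nan, np.nan)  # (a: surface DO, b: cm^-1)
    ecosite: str = ""
    time: float = np.nan
    all_anoxic: bool = False

    def __post_init__(self) -> None:
        if not (self.lower_cm <= self.horizon_cm + 1e-12 and self.horizon_cm <= self.upper_cm + 1e-12):
            raise ValueError("bounds must bracket the horizon (lower <= point <= upper)")


def _reverse_exponential(z: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * np.exp(-b * z)


def fit_reverse_exponential(data: DOMeasurementSet) -> tuple[tuple[float, float], np.ndarray]:
    """Bounded nonlinear least-squares fit of DO(z) = a exp(-b z).

    Returns the fitted ``(a, b)`` and their 2x2 covariance.  ``a`` is the
    extrapolated surface DO (umol kg^-1) and ``b`` the decay rate (cm^-1);
    both are constrained positive.  A flat profile drives ``b`` to its
    tiny lower bound, which is reported with a warning rather than failing.
    """
    z = data.depth_cm
    do = data.do_umol_per_kg
    if z.max() - z.min() < 10.0:
        raise ValueError("DO measurements must span at least 10 cm of depth")
    # Log-linear starting point from the strictly positive readings.
    pos = do > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(z[pos], np.log(do[pos]), 1)
        p0 = (float(np.exp(intercept)), float(max(-slope, _B_MIN * 10)))
    else:
        p0 = (max(do.max(), 1.0), 0.1)
    try:
        popt, pcov = curve_fit(
            _reverse_exponential,
            z,
            do,
            p0=p0,
            bounds=([1e-9, _B_MIN], [np.inf, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"reverse-exponential fit did not converge for "
            f"{data.ecosite!r}/{data.month!r}: {exc}"
        ) from exc
    a, b = float(popt[0]), float(popt[1])
    if b <= _B_MIN * 1.01:
        logger.warning(
            "DO profile %r/%r is essentially flat; decay rate pinned at its lower bound",
            data.ecosite, data.month,
        )
    return (a, b), pcov


def _crossing_depth(a: np.ndarray, b: np.ndarray, threshold: float) -> np.ndarray:
    """Depth where a*exp(-b z) = threshold; 0 where the curve starts below."""
    a = np.maximum(np.asarray(a, dtype=float), 1e-12)
    b = np.maximum(np.asarray(b, dtype=float), _B_MIN)
    with np.errstate(divide="ignore"):
        depth = np.log(a / threshold) / b
    return np.maximum(depth, 0.0)


def horizon_from_fit(
    a: float,
    b: float,
    covariance: np.ndarray | None,
    threshold: float = DEFAULT_DO_THRESHOLD,
    n_boot: int = 1000,
    seed: int = 0,
    data: DOMeasurementSet | None = None,
    ecosite: str = "",
    time: float = np.nan,
    dof: int | None = None,
) -> OxicHorizonEstimate:
    """Convert a fitted DO curve into an oxic-horizon estimate with bounds.

    The point estimate is the closed-form crossing ``ln(a/threshold)/b``.
    Bounds come from ``n_boot`` parametric-bootstrap draws of (a, b) from
    the fit covariance: the 2.5th/97.5th percentiles of the draw-wise
    crossing depths.  When ``dof`` (residual degrees of freedom, n - 2) is
    given, draws are multivariate-t rather than normal — the covariance's
    residual-variance estimate is itself uncertain at small n, and normal
    draws understate the envelope.  If the covariance is unusable and the
    raw data are available, a fit-residual bootstrap is used instead
    (refitting on resampled residuals); otherwise independent per-parameter
    normals from the covariance diagonal serve as a last resort.
    """
    if a <= threshold:
        # Soil surface already below the DO threshold: the column is
        # effectively anoxic throughout.
        return OxicHorizonEstimate(
            0.0, 0.0, 0.0, threshold, (a, b), ecosite, time, all_anoxic=True
        )
    point = float(_crossing_depth(a, b, threshold))
    rng = np.random.default_rng(seed)
    draws = None
    if covariance is not None:
        cov = np.asarray(covariance, dtype=float)
        if cov.shape == (2, 2) and np.isfinite(cov).all():
            sym = 0.5 * (cov + cov.T)
            eigvals = np.linalg.eigvalsh(sym)
            if (eigvals >= -1e-12 * max(eigvals.max(), 1.0)).all():
                draws = rng.multivariate_normal(
                    [a, b], sym, size=n_boot, method="svd"
                )
                if dof is not None and dof > 2:
                    # Student-t scale mixture: widen normal draws by the
                    # chi-square uncertainty of the residual variance.
                    scale = np.sqrt(dof / rng.chisquare(dof, size=n_boot))
                    draws = np.array([a, b]) + (draws - np.array([a, b])) * scale[:, None]
    if draws is None:
        if data is not None:
            logger.warning("covariance not usable; falling back to residual bootstrap")
            draws = _residual_bootstrap_draws(data, a, b, n_boot, rng)
        else:
            logger.warning(
                "covariance not usable and no data supplied; using diagonal-only draws"
            )
            sd = np.sqrt(np.abs(np.diag(np.asarray(covariance, dtype=float)))) if covariance is not None else np.zeros(2)
            draws = np.column_stack(
                [rng.normal(a, sd[0], n_boot), rng.normal(b, sd[1], n_boot)]
            )
    depths = _crossing_depth(draws[:, 0], draws[:, 1], threshold)
    lower = float(np.percentile(depths, 2.5))
    upper = float(np.percentile(depths, 97.5))
    # The percentile band is centred on the bootstrap distribution, not the
    # point estimate; enforce the bracketing invariant explicitly.
    lower = min(lower, point)
    upper = max(upper, point)
    return OxicHorizonEstimate(point, lower, upper, threshold, (a, b), ecosite, time)


def _residual_bootstrap_draws(
    data: DOMeasurementSet, a: float, b: float, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    fitted = _reverse_exponential(data.depth_cm, a, b)
    residuals = data.do_umol_per_kg - fitted
    draws = np.empty((n_boot, 2))
    for i in range(n_boot):
        resampled = fitted + rng.choice(residuals, size=residuals.size, replace=True)
        resampled = np.maximum(resampled, 0.0)
        try:
            popt, _ = curve_fit(
                _reverse_exponential,
                data.depth_cm,
                resampled,
                p0=(a, b),
                bounds=([1e-9, _B_MIN], [np.inf, np.inf]),
                maxfev=2_000,
            )
            draws[i] = popt
        except RuntimeError:
            draws[i] = (a, b)
    return draws


@dataclass
class HorizonSeries:
    """Piecewise-linear oxic horizon (and bounds) vs time."""

    times: np.ndarray
    horizon: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def at(self, t: np.ndarray | float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Interpolated (horizon, lower, upper) at time(s) ``t``, cm.

        Constant extrapolation outside the measured span, with a warning.
        """
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if (t_arr < self.times[0] - 1e-9).any() or (t_arr > self.times[-1] + 1e-9).any():
            logger.warning(
                "horizon queried outside measurement span [%.1f, %.1f] d; "
                "holding end values constant",
                self.times[0], self.times[-1],
            )
        h = np.interp(t_arr, self.times, self.horizon)
        lo = np.interp(t_arr, self.times, self.lower)
        up = np.interp(t_arr, self.times, self.upper)
        if np.isscalar(t):
            return float(h[0]), float(lo[0]), float(up[0])
        return h, lo, up


def interpolate_horizon(estimates: list[OxicHorizonEstimate]) -> HorizonSeries:
    """Linear-in-time interpolation of monthly horizon estimates.

    A single month yields a constant function (logged).  Horizon, lower
    and upper bounds are interpolated independently.
    """
    if not estimates:
        raise ValueError("no horizon estimates supplied")
    est = sorted(estimates, key=lambda e: e.time)
    times = np.array([e.time for e in est], dtype=float)
    if np.isnan(times).any():
        raise ValueError("every estimate needs a numeric time for interpolation")
    if len(est) == 1:
        logger.warning("single monthly estimate; horizon treated as constant in time")
        times = np.array([times[0], times[0] + 1.0])
        est = [est[0], est[0]]
    return HorizonSeries(
        times=times,
        horizon=np.array([e.horizon_cm for e in est]),
        lower=np.array([e.lower_cm for e in est]),
        upper=np.array([e.upper_cm for e in est]),
    )


class DOProfileModel:
    """Reverse-exponential model of one month's dissolved-oxygen profile.

    Thin model/fit wrapper: ``DOProfileModel(data).fit()`` returns the
    :class:`OxicHorizonEstimate` for the configured threshold.
    """

    def __init__(
        self,
        data: DOMeasurementSet,
        threshold: float = DEFAULT_DO_THRESHOLD,
        n_boot: int = 1000,
    ) -> None:
        self.data = data
        self.threshold = threshold
        self.n_boot = n_boot

    def fit(self, seed: int = 0, time: float = np.nan) -> OxicHorizonEstimate:
        (a, b), cov = fit_reverse_exponential(self.data)
        if self.data.do_umol_per_kg.max() < self.threshold:
            logger.warning(
                "all DO readings below threshold for %r/%r; column flagged anoxic",
                self.data.ecosite, self.data.month,
            )
            return OxicHorizonEstimate(
                0.0, 0.0, 0.0, self.threshold, (a, b),
                self.data.ecosite, time, all_anoxic=True,
            )
        return horizon_from_fit(
            a, b, cov,
            threshold=self.threshold,
            n_boot=self.n_boot,
            seed=seed,
            data=self.data,
            ecosite=self.data.ecosite,
            time=time,
            dof=self.data.depth_cm.size - 2,
        )
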