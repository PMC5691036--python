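"""Forward model of dissolved CH4 transport in a 1D soil column.

The column is discretized with a cell-centered finite volume scheme on a
uniform depth grid (positive downward, cm).  Dissolved methane obeys a
diffusion equation with a depth-resolved net source/sink term::

    dC/dt = d/dz( D(t,z) dC/dz ) + R(z)

with a Neumann no-flux condition at the bottom face and a prescribed flux
(positive = emission out of the column) at the top face.  Time stepping is
implicit backward Euler, which is unconditionally stable and keeps the
scheme exactly mass conservative at cell interfaces.

Canonical units throughout: depth cm, time days, concentration nmol cm^-3
(numerically identical to umol L^-1), fluxes nmol cm^-2 d^-1, rates
nmol cm^-3 d^-1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import solve_banded

logger = logging.getLogger(__name__)

__all__ = [
    "DepthGrid",
    "ConcentrationProfile",
    "DiffusivityModel",
    "TemperatureField",
    "SourceProfile",
    "BoundaryFluxSeries",
    "ForwardContext",
    "ForwardSolution",
    "diffusivity_profile",
    "step_implicit",
    "solve_forward",
    "column_mass_balance",
    "ignorant_guess",
    "affine_propagator",
]


@dataclass(frozen=True)
class DepthGrid:
    """Uniform vertical grid of soil layers, depths in cm positive downward.

    The default mirrors a porewater dialysis sampler (peeper) with 20
    stacked windows at 2.8 cm vertical resolution spanning the upper
    56 cm of soil.
    """

    n_layers: int = 20
    layer_thickness: float = 2.8

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if not self.layer_thickness > 0:
            raise ValueError("layer_thickness must be > 0")

    @property
    def layer_centers(self) -> np.ndarray:
        dz = self.layer_thickness
        return dz * (np.arange(self.n_layers) + 0.5)

    @property
    def layer_edges(self) -> np.ndarray:
        return self.layer_thickness * np.arange(self.n_layers + 1)

    @property
    def depth(self) -> float:
        """Total column depth (cm)."""
        return self.n_layers * self.layer_thickness


@dataclass
class ConcentrationProfile:
    """Per-layer porewater CH4 concentration (nmol cm^-3) at one instant."""

    grid: DepthGrid
    values: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_layers,):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.n_layers} layers)"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite < 0).any():
            raise ValueError("concentrations must be non-negative")

    @property
    def mass(self) -> float:
        """Column inventory, nmol cm^-2 (NaN-layers excluded)."""
        return float(np.nansum(self.values) * self.grid.layer_thickness)


# Dissolved CH4 diffusivity in water, quadratic in temperature.  The default
# coefficients are normalized so the polynomial evaluates to 1 at 15 degC;
# reference_diffusivity then carries the magnitude (cm^2 d^-1 at 15 degC).
_DEFAULT_T_COEFFS = (0.641946, 0.0195632, 0.000287078)


@dataclass
class DiffusivityModel:
    """Temperature-dependent effective diffusivity D(T) for porewater CH4.

    ``D(T) = tortuosity * reference_diffusivity * poly(T)`` with ``poly``
    a polynomial in temperature (degC, ascending coefficients).  The
    multiplicative tortuosity/porosity factor defaults to 1 (free water);
    set it below 1 for sediment-corrected diffusivities.  A fixed per-layer
    profile override bypasses the temperature dependence entirely.
    """

    reference_diffusivity: float = 1.319  # cm^2 d^-1, CH4 in water at 15 degC
    temperature_coefficients: Sequence[float] = _DEFAULT_T_COEFFS
    tortuosity: float = 1.0
    fixed_profile: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.fixed_profile is not None:
            self.fixed_profile = np.asarray(self.fixed_profile, dtype=float)
            if (self.fixed_profile <= 0).any():
                raise ValueError("fixed diffusivity profile must be positive")
            return
        t_check = np.linspace(-5.0, 40.0, 46)
        d_check = self._evaluate(t_check)
        if (d_check <= 0).any():
            bad = t_check[np.argmin(d_check)]
            raise ValueError(
                f"diffusivity non-positive at T={bad:.1f} degC; check coefficients"
            )

    def _evaluate(self, temperature: np.ndarray) -> np.ndarray:
        poly = np.polynomial.polynomial.polyval(
            np.asarray(temperature, dtype=float),
            np.asarray(self.temperature_coefficients, dtype=float),
        )
        return self.tortuosity * self.reference_diffusivity * poly

    def at_temperature(self, temperature: np.ndarray) -> np.ndarray:
        if self.fixed_profile is not None:
            return self.fixed_profile.copy()
        return self._evaluate(temperature)


@dataclass
class TemperatureField:
    """Soil temperature (degC) on (time, layer); linear interpolation in time."""

    times: np.ndarray
    grid: DepthGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (self.times.size, self.grid.n_layers):
            raise ValueError(
                f"temperature values must be (n_times, n_layers)="
                f"({self.times.size}, {self.grid.n_layers}), got {self.values.shape}"
            )
        if self.times.size > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("temperature times must be strictly increasing")

    @classmethod
    def constant(cls, grid: DepthGrid, temperature: float) -> "TemperatureField":
        return cls(np.array([0.0]), grid, np.full((1, grid.n_layers), temperature))

    def at(self, time: float) -> np.ndarray:
        if self.times.size == 1:
            return self.values[0].copy()
        if time < self.times[0] or time > self.times[-1]:
            logger.warning(
                "temperature queried at t=%.3f d outside span [%.3f, %.3f]; clamping",
                time, self.times[0], self.times[-1],
            )
        out = np.empty(self.grid.n_layers)
        for j in range(self.grid.n_layers):
            out[j] = np.interp(time, self.times, self.values[:, j])
        return out


@dataclass
class SourceProfile:
    """Net volumetric CH4 production rate per layer, nmol cm^-3 d^-1.

    Positive values are methanogenesis (production); negative values are
    oxidation/consumption.
    """

    grid: DepthGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_layers,):
            raise ValueError("source profile length must equal n_layers")
        if not np.isfinite(self.values).all():
            raise ValueError("source profile must be finite")

    @classmethod
    def zeros(cls, grid: DepthGrid) -> "SourceProfile":
        return cls(grid, np.zeros(grid.n_layers))

    def column_integral(self) -> float:
        """Depth-integrated net production, nmol cm^-2 d^-1."""
        return float(self.values.sum() * self.grid.layer_thickness)


@dataclass
class BoundaryFluxSeries:
    """Surface CH4 flux vs time; positive = emission out of the column."""

    times: np.ndarray
    flux: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.flux = np.atleast_1d(np.asarray(self.flux, dtype=float))
        if self.times.shape != self.flux.shape:
            raise ValueError("times and flux must have equal length")
        if self.times.size > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("boundary times must be strictly increasing")

    @classmethod
    def constant(cls, flux: float, t0: float = 0.0, t1: float = 1e9) -> "BoundaryFluxSeries":
        return cls(np.array([t0, t1]), np.array([flux, flux]))

    def at(self, time: float) -> float:
        if time < self.times[0] or time > self.times[-1]:
            logger.warning(
                "boundary flux queried at t=%.3f d outside span [%.3f, %.3f]; clamping",
                time, self.times[0], self.times[-1],
            )
        return float(np.interp(time, self.times, self.flux))


def diffusivity_profile(
    model: DiffusivityModel, temperature: TemperatureField, time: float
) -> np.ndarray:
    """Per-layer diffusivity (cm^2 d^-1) at one instant.

    Evaluates the temperature polynomial on the interpolated temperature
    profile, or returns the fixed override when set.
    """
    if model.fixed_profile is not None:
        prof = model.fixed_profile
        if prof.shape != (temperature.grid.n_layers,):
            raise ValueError("fixed diffusivity profile length must equal n_layers")
        return prof.copy()
    temps = temperature.at(time)
    d = model.at_temperature(temps)
    if (d <= 0).any() or not np.isfinite(d).all():
        k = int(np.argmin(d))
        raise ValueError(
            f"non-positive diffusivity {d[k]:.4g} in layer {k} (T={temps[k]:.2f} degC)"
        )
    return d


def _interface_diffusivity(d_profile: np.ndarray) -> np.ndarray:
    """Harmonic-mean diffusivity at interior cell faces (length n-1)."""
    a, b = d_profile[:-1], d_profile[1:]
    return 2.0 * a * b / (a + b)


def _banded_system(d_profile: np.ndarray, dz: float, dt: float) -> np.ndarray:
    """Banded form (3, n) of I - dt*L for scipy.linalg.solve_banded.

    L is the finite-volume diffusion operator with closed top and bottom
    faces (the prescribed top flux enters the right-hand side instead).
    """
    n = d_profile.size
    d_face = _interface_diffusivity(d_profile) * dt / dz**2
    ab = np.zeros((3, n))
    # upper diagonal: coupling to layer below-to-above (ab[0, j] = A[j-1, j])
    ab[0, 1:] = -d_face
    ab[2, :-1] = -d_face
    ab[1, :] = 1.0
    ab[1, :-1] += d_face
    ab[1, 1:] += d_face
    return ab


def _rhs_boundary(top_flux: float, n: int, dz: float) -> np.ndarray:
    """Boundary source vector b: the surface flux removed from layer 1."""
    b = np.zeros(n)
    b[0] = -top_flux / dz
    return b


def step_implicit(
    c: ConcentrationProfile,
    d_profile: np.ndarray,
    r: SourceProfile,
    top_flux: float,
    dt: float,
) -> ConcentrationProfile:
    """One backward-Euler step of the diffusion-reaction system.

    Solves the tridiagonal system ``(I - dt*L) c_new = c_old + dt*(r + b)``
    where ``b`` carries the prescribed surface flux (finite-volume form of
    Fick's 1st law at the top face: a positive flux is a sink in layer 1)
    and the bottom face flux is identically zero.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    grid = c.grid
    d_profile = np.asarray(d_profile, dtype=float)
    if d_profile.shape != (grid.n_layers,):
        raise ValueError("diffusivity profile length must equal n_layers")
    if r.grid.n_layers != grid.n_layers or r.grid.layer_thickness != grid.layer_thickness:
        raise ValueError("source profile grid does not match concentration grid")
    dz = grid.layer_thickness
    rhs = c.values + dt * (r.values + _rhs_boundary(top_flux, grid.n_layers, dz))
    ab = _banded_system(d_profile, dz, dt)
    try:
        new = solve_banded((1, 1), ab, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
        raise ValueError(f"singular implicit system (dt={dt}): {exc}") from exc
    if not np.isfinite(new).all():
        raise ValueError("implicit step produced non-finite concentrations")
    # Clip tiny negative round-off; genuine negatives (strong sinks) pass
    # through so callers can see them.
    new[(new < 0) & (new > -1e-12)] = 0.0
    return _unchecked_profile(grid, new, c.time + dt)


def _unchecked_profile(grid: DepthGrid, values: np.ndarray, time: float) -> ConcentrationProfile:
    """Build a ConcentrationProfile without the non-negativity check.

    The implicit scheme can transiently produce negative values when the
    source term consumes more methane than a layer holds; the inversion
    relies on seeing those values rather than a masked error.
    """
    prof = ConcentrationProfile.__new__(ConcentrationProfile)
    prof.grid = grid
    prof.values = np.asarray(values, dtype=float)
    prof.time = time
    return prof


@dataclass
class ForwardContext:
    """Everything the forward model needs for one simulation interval."""

    grid: DepthGrid
    dmodel: DiffusivityModel
    temperature: TemperatureField
    boundary: BoundaryFluxSeries
    t_start: float = 0.0
    t_end: float = 30.0

    @property
    def interval(self) -> float:
        return self.t_end - self.t_start


@dataclass
class ForwardSolution:
    """Time series of concentration profiles from :func:`solve_forward`."""

    grid: DepthGrid
    times: np.ndarray
    values: np.ndarray  # (n_times, n_layers)
    boundary_integral: float  # sum of dt*flux over the discrete steps
    source: SourceProfile

    @property
    def initial(self) -> ConcentrationProfile:
        return _unchecked_profile(self.grid, self.values[0].copy(), self.times[0])

    @property
    def final(self) -> ConcentrationProfile:
        return _unchecked_profile(self.grid, self.values[-1].copy(), self.times[-1])

    def mass(self) -> np.ndarray:
        return self.values.sum(axis=1) * self.grid.layer_thickness


def _step_times(t_start: float, t_end: float, dt: float) -> np.ndarray:
    n_full = int(np.floor((t_end - t_start) / dt + 1e-9))
    times = t_start + dt * np.arange(n_full + 1)
    if times[-1] < t_end - 1e-9 * max(1.0, abs(t_end)):
        times = np.append(times, t_end)
    else:
        times[-1] = t_end
    return times


def solve_forward(
    c0: ConcentrationProfile,
    dmodel: DiffusivityModel,
    temperature: TemperatureField,
    r: SourceProfile,
    boundary: BoundaryFluxSeries,
    t_end: float,
    dt: float = 0.1,
    t_start: float | None = None,
) -> ForwardSolution:
    """Integrate the column forward from ``c0`` to ``t_end``.

    Repeated backward-Euler steps with the diffusivity and surface flux
    evaluated at each step's end time (consistent with the implicit
    discretization).  The final partial step is shortened to land exactly
    on ``t_end``.
    """
    if t_start is None:
        t_start = c0.time
    if not t_end > t_start:
        raise ValueError("t_end must exceed the start time")
    times = _step_times(t_start, t_end, dt)
    grid = c0.grid
    values = np.empty((times.size, grid.n_layers))
    values[0] = c0.values
    profile = c0
    boundary_integral = 0.0
    for k in range(1, times.size):
        step = times[k] - times[k - 1]
        flux_k = boundary.at(times[k])
        d_k = diffusivity_profile(dmodel, temperature, times[k])
        try:
            profile = step_implicit(profile, d_k, r, flux_k, step)
        except ValueError as exc:
            raise ValueError(f"forward solve failed at t={times[k]:.3f} d: {exc}") from exc
        values[k] = profile.values
        boundary_integral += step * flux_k
    return ForwardSolution(grid, times, values, boundary_integral, r)


def column_mass_balance(
    series: ForwardSolution,
    r: SourceProfile | None = None,
    boundary: BoundaryFluxSeries | None = None,
) -> float:
    """Mass-balance closure residual of a forward solution, nmol cm^-2.

    Returns ``dM - integral(R dz dt) + integral(top_flux dt)``; for output
    of :func:`solve_forward` this is pure round-off because the implicit
    scheme conserves mass exactly at the discrete level.
    """
    if r is None:
        r = series.source
    if r.grid.n_layers != series.grid.n_layers or (
        r.grid.layer_thickness != series.grid.layer_thickness
    ):
        raise ValueError("source grid does not match series grid")
    dz = series.grid.layer_thickness
    delta_m = float((series.values[-1] - series.values[0]).sum() * dz)
    duration = float(series.times[-1] - series.times[0])
    source_integral = r.values.sum() * dz * duration
    if boundary is None:
        flux_integral = series.boundary_integral
    else:
        # Recompute with the discrete quadrature the solver used (flux at
        # step end times).
        flux_integral = 0.0
        for k in range(1, series.times.size):
            flux_integral += (series.times[k] - series.times[k - 1]) * boundary.at(
                series.times[k]
            )
    return delta_m - source_integral + flux_integral


def ignorant_guess(
    c_start: ConcentrationProfile,
    c_end: ConcentrationProfile,
    dmodel: DiffusivityModel,
    temperature: TemperatureField,
    boundary: BoundaryFluxSeries,
    interval: float,
) -> SourceProfile:
    """First-pass source estimate from one month-long backward-Euler step.

    Inverting a single implicit step of length ``interval`` for R gives
    ``R = (c_end - c_start)/dt - L c_end + flux_term`` exactly.  The
    diffusion operator uses the interval-midpoint diffusivity and the
    boundary term uses the interval-mean surface flux, so the guess closes
    the column mass budget of the coarse step.
    """
    if not interval > 0:
        raise ValueError("interval must be positive")
    grid = c_start.grid
    if c_end.grid.n_layers != grid.n_layers:
        raise ValueError("start and end profiles must share the grid")
    t_mid = c_start.time + interval / 2.0
    d_mid = diffusivity_profile(dmodel, temperature, t_mid)
    dz = grid.layer_thickness
    d_face = _interface_diffusivity(d_mid) / dz**2
    c = c_end.values
    lc = np.zeros(grid.n_layers)
    lc[:-1] += d_face * (c[1:] - c[:-1])
    lc[1:] += d_face * (c[:-1] - c[1:])
    t_probe = np.linspace(c_start.time, c_start.time + interval, 31)
    mean_flux = float(np.mean([boundary.at(t) for t in t_probe]))
    rvals = (c - c_start.values) / interval - lc + mean_flux / dz * _e1(grid.n_layers)
    return SourceProfile(grid, rvals)


def _e1(n: int) -> np.ndarray:
    e = np.zeros(n)
    e[0] = 1.0
    return e


def affine_propagator(
    c0: ConcentrationProfile,
    ctx: ForwardContext,
    dt: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact affine map of the discrete forward model over an interval.

    Because backward Euler is linear, the end-of-interval concentration for
    a source profile held constant over the interval is ``c_end = v0 + M r``
    with ``v0`` the zero-source solution and ``M`` the accumulated response
    matrix.  Both are computed by propagating the identity through the same
    tridiagonal solves :func:`solve_forward` performs, so ``v0 + M r``
    reproduces the stepped solution to round-off.  One precomputation makes
    each subsequent source evaluation a single (n x n) mat-vec, which is
    what makes a 40,000-iteration Markov chain affordable.
    """
    grid = c0.grid
    n = grid.n_layers
    dz = grid.layer_thickness
    times = _step_times(ctx.t_start, ctx.t_end, dt)
    v = c0.values.astype(float).copy()
    m = np.zeros((n, n))
    eye = np.eye(n)
    for k in range(1, times.size):
        step = times[k] - times[k - 1]
        flux_k = ctx.boundary.at(times[k])
        d_k = diffusivity_profile(ctx.dmodel, ctx.temperature, times[k])
        ab = _banded_system(d_k, dz, step)
        rhs_v = v + step * _rhs_boundary(flux_k, n, dz)
        v = solve_banded((1, 1), ab, rhs_v)
        m = solve_banded((1, 1), ab, m + step * eye)
    if not (np.isfinite(v).all() and np.isfinite(m).all()):
        raise ValueError("affine propagator produced non-finite entries")
    return v, m
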