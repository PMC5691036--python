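"""Synthetic wetland methane campaigns with known ground truth.

Emulates one growing season of the measurement set the pipeline consumes:
four monthly peeper porewater CH4 profiles (20 windows at 2.8 cm), duplicate
chamber fluxes per ecosite per campaign, dissolved-oxygen depth profiles,
soil temperature, and daily tower flux + footprint fractions for four
ecosites.  Every quantity any pipeline stage estimates (R, oxic horizon,
F', p, f_oxic) has a stored or closed-form true value on the Scenario, so
each stage has a recovery test with no external data.

Noise is independent Gaussian per instrument (no autocorrelation), which is
deliberately simpler than field data: real peepers smear concentrations over
the equilibration time, chambers disturb the surface, and footprints carry
model error.  Passing recovery tests therefore demonstrate correctness of
the estimators under their own assumptions, not field accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .budget import SiteAreaConfig, _fraction_above
from .oxic_horizon import DEFAULT_DO_THRESHOLD, HorizonSeries
from .transport import (
    BoundaryFluxSeries,
    ConcentrationProfile,
    DepthGrid,
    DiffusivityModel,
    ForwardContext,
    SourceProfile,
    TemperatureField,
    solve_forward,
)

__all__ = ["Scenario", "make_scenario", "simulate_measurements", "PRESETS"]

PRESETS = ("null", "surface_source", "deep_source")

START_DATE = "2015-06-15"  # day 0 of the synthetic season

MODELED_ECOSITES = ("open", "mud")
ALL_ECOSITES = ("open", "typha", "nelumbo", "mud")


@dataclass
class Scenario:
    """Complete synthetic campaign: forcing, truth, and noise levels."""

    preset: str
    seed: int
    grid: DepthGrid
    month_days: np.ndarray  # campaign days, e.g. [0, 30, 60, 90]
    true_r: dict[str, np.ndarray]  # ecosite -> (n_intervals, n_layers)
    c0: dict[str, np.ndarray]  # initial CH4 profile per modeled ecosite
    dmodel: DiffusivityModel
    temperature: TemperatureField
    top_flux: dict[str, BoundaryFluxSeries]  # true surface flux, modeled ecosites
    chamber_flux_true: dict[str, np.ndarray]  # all four ecosites, at month_days
    do_params_true: dict[str, list[tuple[float, float]]]  # (a, b) per month
    fprime_op: np.ndarray  # daily true open-water flux strength
    footprint: dict[str, np.ndarray]  # daily e per ecosite
    areas: SiteAreaConfig
    noise: dict[str, float]
    do_threshold: float = DEFAULT_DO_THRESHOLD

    # ------------------------------------------------------------------ truth
    @property
    def days(self) -> np.ndarray:
        return np.arange(self.month_days[0], self.month_days[-1] + 1.0)

    @property
    def n_intervals(self) -> int:
        return len(self.month_days) - 1

    def forward_context(self, ecosite: str, interval: int) -> ForwardContext:
        return ForwardContext(
            grid=self.grid,
            dmodel=self.dmodel,
            temperature=self.temperature,
            boundary=self.top_flux[ecosite],
            t_start=float(self.month_days[interval]),
            t_end=float(self.month_days[interval + 1]),
        )

    def true_peeper_profiles(self, ecosite: str, dt: float = 0.1) -> list[ConcentrationProfile]:
        """Noise-free monthly profiles from the forward model under true R."""
        profile = ConcentrationProfile(self.grid, self.c0[ecosite], float(self.month_days[0]))
        out = [profile]
        for k in range(self.n_intervals):
            ctx = self.forward_context(ecosite, k)
            sol = solve_forward(
                profile,
                self.dmodel,
                self.temperature,
                SourceProfile(self.grid, self.true_r[ecosite][k]),
                ctx.boundary,
                t_end=ctx.t_end,
                dt=dt,
                t_start=ctx.t_start,
            )
            profile = sol.final
            out.append(profile)
        return out

    def true_horizon_cm(self, ecosite: str) -> np.ndarray:
        """Closed-form DO threshold crossings, one per campaign month."""
        out = []
        for a, b in self.do_params_true[ecosite]:
            out.append(max(np.log(a / self.do_threshold) / b, 0.0) if a > self.do_threshold else 0.0)
        return np.array(out)

    def true_horizon_series(self, ecosite: str) -> HorizonSeries:
        h = self.true_horizon_cm(ecosite)
        return HorizonSeries(self.month_days.astype(float), h, h.copy(), h.copy())

    def true_p_daily(self, ecosite: str) -> np.ndarray:
        """Daily oxic-production fraction from true R and true horizon.

        NaN where the column-total production is zero (the null preset).
        """
        series = self.true_horizon_series(ecosite)
        days = self.days
        h_daily, _, _ = series.at(days)
        p = np.empty(days.size)
        for i, (d, h) in enumerate(zip(days, h_daily)):
            k = min(int(np.searchsorted(self.month_days, d, side="right") - 1), self.n_intervals - 1)
            p[i], ok = _fraction_above(self.true_r[ecosite][k], self.grid, h, 1e-9)
            if not ok:
                p[i] = np.nan
        return p

    def true_m_ratios(self) -> dict[str, np.ndarray]:
        """Daily chamber-flux ratios interpolated from the campaign truths."""
        days = self.days
        md = self.month_days.astype(float)
        op = self.chamber_flux_true["open"]
        if np.all(op == 0):  # null preset: no emissions anywhere
            zero = np.zeros(days.size)
            return {"m1": zero, "m2": zero.copy(), "m3": zero.copy()}
        return {
            "m1": np.interp(days, md, self.chamber_flux_true["typha"] / op),
            "m2": np.interp(days, md, self.chamber_flux_true["nelumbo"] / op),
            "m3": np.interp(days, md, self.chamber_flux_true["mud"] / op),
        }

    def true_fprime(self) -> dict[str, np.ndarray]:
        m = self.true_m_ratios()
        return {
            "open": self.fprime_op,
            "typha": m["m1"] * self.fprime_op,
            "nelumbo": m["m2"] * self.fprime_op,
            "mud": m["m3"] * self.fprime_op,
        }

    def true_tower_flux(self) -> np.ndarray:
        fp = self.true_fprime()
        return (
            fp["open"] * self.footprint["open"]
            + fp["typha"] * self.footprint["typha"]
            + fp["nelumbo"] * self.footprint["nelumbo"]
            + fp["mud"] * self.footprint["mud"]
        )

    def true_site_oxic_fraction(self) -> float:
        """Flux-weighted area/time average of the true oxic fractions.

        Raises for the null preset, where column production is zero and
        the fraction is undefined.
        """
        p_op = self.true_p_daily("open")
        p_mu = self.true_p_daily("mud")
        if np.isnan(p_op).all() or np.isnan(p_mu).all():
            raise ValueError(
                "true oxic fraction undefined: column-total production is zero "
                f"(preset {self.preset!r})"
            )
        fp = self.true_fprime()
        w_op = self.areas.f_op * fp["open"]
        w_mu = self.areas.f_mu * fp["mud"]
        num = w_op * p_op + w_mu * p_mu
        den = w_op + w_mu
        return float(np.nansum(num) / den.sum())

    # ------------------------------------------------------------ serialization
    def to_dict(self) -> dict:
        def arr(x):
            return np.asarray(x).tolist()

        return {
            "preset": self.preset,
            "seed": self.seed,
            "grid": {"n_layers": self.grid.n_layers, "layer_thickness": self.grid.layer_thickness},
            "month_days": arr(self.month_days),
            "true_r": {k: arr(v) for k, v in self.true_r.items()},
            "c0": {k: arr(v) for k, v in self.c0.items()},
            "top_flux": {
                k: {"times": arr(v.times), "flux": arr(v.flux)} for k, v in self.top_flux.items()
            },
            "chamber_flux_true": {k: arr(v) for k, v in self.chamber_flux_true.items()},
            "do_params_true": {k: [list(t) for t in v] for k, v in self.do_params_true.items()},
            "fprime_op": arr(self.fprime_op),
            "footprint": {k: arr(v) for k, v in self.footprint.items()},
            "areas": {"f_op": self.areas.f_op, "f_mu": self.areas.f_mu},
            "noise": dict(self.noise),
            "do_threshold": self.do_threshold,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def _layer_rates(grid: DepthGrid, fn) -> np.ndarray:
    return np.array([fn(z) for z in grid.layer_centers], dtype=float)


def _surface_source_rate(z: float) -> float:
    """Shallow production peak, mid-depth oxidation band, weak deep production."""
    production = 4.0 * np.exp(-(((z - 4.0) / 4.0) ** 2))
    oxidation = -1.5 * np.exp(-(((z - 15.0) / 5.0) ** 2))
    deep = 0.6 if z > 25.0 else 0.0
    return production + oxidation + deep


def _deep_source_rate(z: float) -> float:
    """Classic anoxic-only methanogenesis at depth with shallow oxidation."""
    production = 3.0 * np.exp(-(((z - 40.0) / 6.0) ** 2))
    oxidation = -0.5 * np.exp(-(((z - 6.0) / 4.0) ** 2))
    return production + oxidation


def make_scenario(preset: str = "surface_source", overrides: dict | None = None,
                  seed: int = 0) -> Scenario:
    """Build a fully specified synthetic season; deterministic per seed.

    Presets
    -------
    null
        Zero net activity everywhere, zero surface flux, uniform initial
        profiles (static columns); the oxic fraction is undefined.
    surface_source
        Methanogenesis peaking in the upper 10 cm, an oxidation band at
        10-20 cm and weak deep production; most production sits above the
        oxic horizon (true oxic fraction > 0.5 by construction).
    deep_source
        Production confined below ~30 cm with mild near-surface oxidation;
        the oxic layers contribute almost nothing.

    ``overrides`` patches Scenario attributes after construction (e.g.
    ``{"noise": {"peeper_sigma": 0.0, ...}}``).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    grid = DepthGrid()
    month_days = np.array([0.0, 30.0, 60.0, 90.0])
    n_intervals = len(month_days) - 1
    days = np.arange(0.0, 91.0)

    # Season-long warming, damped with depth.
    t_surface = 15.0 + 7.0 * month_days / 90.0
    t_field = 12.0 + (t_surface[:, None] - 12.0) * np.exp(-grid.layer_centers[None, :] / 25.0)
    temperature = TemperatureField(month_days, grid, t_field)
    dmodel = DiffusivityModel(tortuosity=0.6)

    # Interval-constant true rates with mild month-to-month modulation.
    if preset == "null":
        base = np.zeros(grid.n_layers)
        modulation = np.ones(n_intervals)
    elif preset == "surface_source":
        base = _layer_rates(grid, _surface_source_rate)
        modulation = np.array([1.0, 1.2, 0.9])
    else:
        base = _layer_rates(grid, _deep_source_rate)
        modulation = np.array([1.0, 1.1, 0.95])
    true_r = {
        "open": np.outer(modulation, base),
        "mud": np.outer(modulation * np.array([0.9, 1.0, 1.1]), 0.8 * base),
    }

    if preset == "null":
        c0 = {e: np.full(grid.n_layers, 100.0) for e in MODELED_ECOSITES}
        flux_open = np.zeros(len(month_days))
        flux_mud = np.zeros(len(month_days))
    else:
        c0 = {
            "open": 60.0 + 5.0 * grid.layer_centers,
            "mud": 80.0 + 6.0 * grid.layer_centers,
        }
        # Surface emission removes most (not all) of the column production,
        # so profiles drift month to month without running negative.
        budget_open = np.array(
            [float(true_r["open"][min(k, n_intervals - 1)].sum() * grid.layer_thickness)
             for k in range(len(month_days))]
        )
        budget_mud = np.array(
            [float(true_r["mud"][min(k, n_intervals - 1)].sum() * grid.layer_thickness)
             for k in range(len(month_days))]
        )
        flux_open = 0.85 * budget_open
        flux_mud = 0.85 * budget_mud
    top_flux = {
        "open": BoundaryFluxSeries(month_days.copy(), flux_open),
        "mud": BoundaryFluxSeries(month_days.copy(), flux_mud),
    }

    # Chamber truths: modeled ecosites emit their boundary flux; vegetated
    # ecosites emit fixed multiples of open water (plant transport).
    if preset == "null":
        chamber = {e: np.zeros(len(month_days)) for e in ALL_ECOSITES}
    else:
        chamber = {
            "open": flux_open.copy(),
            "mud": flux_mud.copy(),
            "typha": 2.5 * flux_open,
            "nelumbo": 1.2 * flux_open,
        }

    # True DO curves per month: oxic horizon shoaling then deepening over
    # the season, shallower in mud than open water.
    do_params = {
        "open": [(250.0, 0.16), (230.0, 0.20), (210.0, 0.22), (240.0, 0.17)],
        "mud": [(160.0, 0.24), (150.0, 0.28), (140.0, 0.30), (155.0, 0.25)],
    }

    if preset == "null":
        fprime_op = np.zeros(days.size)
    else:
        fprime_op = 20.0 + 3.0 * np.sin(2 * np.pi * days / 60.0)
    footprint = {
        "open": 0.74 + 0.05 * np.sin(2 * np.pi * days / 90.0),
        "typha": 0.12 + 0.02 * np.sin(2 * np.pi * days / 45.0 + 1.0),
        "nelumbo": np.full(days.size, 0.04),
        "mud": 0.05 + 0.01 * np.cos(2 * np.pi * days / 30.0),
    }

    scenario = Scenario(
        preset=preset,
        seed=seed,
        grid=grid,
        month_days=month_days,
        true_r=true_r,
        c0=c0,
        dmodel=dmodel,
        temperature=temperature,
        top_flux=top_flux,
        chamber_flux_true=chamber,
        do_params_true=do_params,
        fprime_op=fprime_op,
        footprint=footprint,
        areas=SiteAreaConfig(f_op=0.9, f_mu=0.1),
        noise={"peeper_sigma": 5.0, "do_sigma": 8.0, "flux_sigma": 1.0, "tower_sigma": 1.0},
        do_threshold=DEFAULT_DO_THRESHOLD,
    )
    for key, value in (overrides or {}).items():
        if not hasattr(scenario, key):
            raise ValueError(f"unknown Scenario field {key!r}")
        if key == "noise":
            scenario.noise.update(value)
        else:
            setattr(scenario, key, value)
    return scenario


def _dates(day_values: np.ndarray) -> pd.Series:
    return pd.Timestamp(START_DATE) + pd.to_timedelta(np.asarray(day_values, float), unit="D")


def simulate_measurements(scenario: Scenario) -> dict[str, pd.DataFrame]:
    """Generate the six observation tables (tidy DataFrames) for a scenario.

    Noise draws come from a generator seeded with ``scenario.seed``; with
    all sigmas zero the peeper values equal the forward-model output
    exactly and every other table equals its truth.
    """
    rng = np.random.default_rng(scenario.seed)
    grid = scenario.grid
    noise = scenario.noise
    month_dates = _dates(scenario.month_days).strftime("%Y-%m-%d")

    # Peeper CH4 profiles: forward-model truth + noise, floored at 0.
    peeper_rows = []
    for eco in MODELED_ECOSITES:
        truths = scenario.true_peeper_profiles(eco)
        for date, prof in zip(month_dates, truths):
            vals = prof.values + rng.normal(0.0, noise["peeper_sigma"], grid.n_layers)
            vals = np.maximum(vals, 0.0)
            for z, v in zip(grid.layer_centers, vals):
                peeper_rows.append((date, eco, z, v))
    peeper = pd.DataFrame(peeper_rows, columns=["date", "ecosite", "depth_cm", "ch4_umol_per_L"])

    # Chamber fluxes measured in duplicate per ecosite per campaign.
    chamber_rows = []
    for eco in ALL_ECOSITES:
        for date, truth in zip(month_dates, scenario.chamber_flux_true[eco]):
            for _ in range(2):
                chamber_rows.append((date, eco, truth + rng.normal(0.0, noise["flux_sigma"])))
    chamber = pd.DataFrame(chamber_rows, columns=["date", "ecosite", "flux_nmol_cm2_d"])

    # Dissolved oxygen: reverse-exponential truth + noise, floored at 0.
    do_depths = np.arange(1.0, 30.0, 2.0)
    do_rows = []
    for eco in MODELED_ECOSITES:
        for date, (a, b) in zip(month_dates, scenario.do_params_true[eco]):
            vals = a * np.exp(-b * do_depths) + rng.normal(0.0, noise["do_sigma"], do_depths.size)
            vals = np.maximum(vals, 0.0)
            for z, v in zip(do_depths, vals):
                do_rows.append((date, eco, z, v))
    do = pd.DataFrame(do_rows, columns=["date", "ecosite", "depth_cm", "do_umol_per_kg"])

    # Soil temperature probes: campaign-day profiles at layer centers.
    temp_rows = []
    for i, date in enumerate(month_dates):
        for z, t in zip(grid.layer_centers, scenario.temperature.values[i]):
            temp_rows.append((date, z, t))
    temperature = pd.DataFrame(temp_rows, columns=["date", "depth_cm", "temp_c"])

    # Tower flux composed from the true F' and footprints, plus noise.
    tower_truth = scenario.true_tower_flux()
    tower = pd.DataFrame(
        {
            "date": _dates(scenario.days).strftime("%Y-%m-%d"),
            "flux_nmol_cm2_d": tower_truth + rng.normal(0.0, noise["tower_sigma"], tower_truth.size),
        }
    )

    footprint = pd.DataFrame(
        {
            "date": _dates(scenario.days).strftime("%Y-%m-%d"),
            "e_op": scenario.footprint["open"],
            "e_ty": scenario.footprint["typha"],
            "e_ne": scenario.footprint["nelumbo"],
            "e_mu": scenario.footprint["mud"],
        }
    )

    return {
        "peeper": peeper,
        "chamber": chamber,
        "do": do,
        "temperature": temperature,
        "tower": tower,
        "footprint": footprint,
    }
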