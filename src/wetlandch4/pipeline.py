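"""Stage orchestration: from validated tables to the site-level oxic fraction.

The stages mirror the field workflow.  Monthly peeper CH4 profiles bracket
each inversion interval; chamber fluxes set the surface boundary condition;
temperature probes drive the diffusivity; dissolved-oxygen profiles give
the oxic horizon; tower flux and footprints scale the per-ecosite oxic
production shares to the site level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .budget import (
    BudgetResult,
    EcositeFluxStrengths,
    FootprintSeries,
    OxicFractionSeries,
    SiteAreaConfig,
    TowerFluxSeries,
    decompose_tower_flux,
    oxic_production_fraction,
    ratios_from_chambers,
    site_oxic_fraction,
)
from .inversion import InversionConfig, InversionResult, invert_series
from .io import Tables
from .oxic_horizon import (
    DOMeasurementSet,
    DOProfileModel,
    HorizonSeries,
    OxicHorizonEstimate,
    interpolate_horizon,
)
from .transport import (
    BoundaryFluxSeries,
    ConcentrationProfile,
    DepthGrid,
    DiffusivityModel,
    ForwardContext,
    TemperatureField,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MODELED_ECOSITES",
    "PipelineReport",
    "peeper_profiles",
    "temperature_field",
    "boundary_series",
    "run_inversion",
    "run_horizon",
    "run_budget",
    "run_all",
]

MODELED_ECOSITES = ("open", "mud")


def peeper_profiles(
    tables: Tables, ecosite: str, grid: DepthGrid
) -> tuple[list[ConcentrationProfile], np.ndarray]:
    """Monthly concentration profiles for one ecosite on the model grid.

    Peeper depths must match the grid's layer centers; windows absent from
    a month's table become NaN (masked in the inversion misfit).
    """
    sub = tables.peeper[tables.peeper["ecosite"] == ecosite]
    if sub.empty:
        raise ValueError(f"no peeper data for ecosite {ecosite!r}")
    centers = grid.layer_centers
    days = np.sort(sub["day"].unique())
    profiles = []
    for d in days:
        month = sub[sub["day"] == d]
        values = np.full(grid.n_layers, np.nan)
        for _, row in month.iterrows():
            idx = int(np.argmin(np.abs(centers - row["depth_cm"])))
            if abs(centers[idx] - row["depth_cm"]) > grid.layer_thickness / 2:
                raise ValueError(
                    f"peeper depth {row['depth_cm']} cm does not sit on the "
                    f"{grid.n_layers}x{grid.layer_thickness} cm grid"
                )
            values[idx] = row["ch4_nmol_cm3"]
        profiles.append(ConcentrationProfile(grid, np.where(np.isnan(values), np.nan, np.maximum(values, 0.0)), float(d)))
    return profiles, days


def temperature_field(tables: Tables, grid: DepthGrid) -> TemperatureField:
    """Interpolate probe temperatures onto the model grid's layer centers."""
    temp = tables.temperature
    days = np.sort(temp["day"].unique())
    values = np.empty((days.size, grid.n_layers))
    for i, d in enumerate(days):
        snap = temp[temp["day"] == d].sort_values("depth_cm")
        values[i] = np.interp(grid.layer_centers, snap["depth_cm"], snap["temp_c"])
    return TemperatureField(days, grid, values)


def boundary_series(tables: Tables, ecosite: str) -> BoundaryFluxSeries:
    """Chamber-based surface flux series (replicates averaged per campaign)."""
    sub = tables.chamber[tables.chamber["ecosite"] == ecosite]
    if sub.empty:
        raise ValueError(f"no chamber data for ecosite {ecosite!r}")
    by_day = sub.groupby("day")["flux_nmol_cm2_d"].mean()
    return BoundaryFluxSeries(by_day.index.to_numpy(float), by_day.to_numpy())


def run_inversion(
    tables: Tables,
    cfg: InversionConfig,
    grid: DepthGrid | None = None,
    dmodel: DiffusivityModel | None = None,
    ecosites: tuple[str, ...] = MODELED_ECOSITES,
) -> dict[str, list[InversionResult]]:
    """Invert the source term for every month interval of each ecosite."""
    grid = grid or DepthGrid()
    dmodel = dmodel or DiffusivityModel()
    temp = temperature_field(tables, grid)
    out: dict[str, list[InversionResult]] = {}
    for j, eco in enumerate(ecosites):
        profiles, days = peeper_profiles(tables, eco, grid)
        boundary = boundary_series(tables, eco)
        contexts = [
            ForwardContext(grid, dmodel, temp, boundary, float(days[k]), float(days[k + 1]))
            for k in range(len(days) - 1)
        ]
        eco_cfg = InversionConfig(
            **{**cfg.__dict__, "rng_seed": (cfg.rng_seed + 7919 * j) % 2**31}
        )
        out[eco] = invert_series(profiles, contexts, eco_cfg, ecosite=eco)
    return out


def run_horizon(
    tables: Tables,
    threshold: float,
    seed: int = 0,
    n_boot: int = 1000,
    ecosites: tuple[str, ...] = MODELED_ECOSITES,
) -> dict[str, list[OxicHorizonEstimate]]:
    """Fit monthly DO profiles and extract oxic horizons per ecosite."""
    out: dict[str, list[OxicHorizonEstimate]] = {}
    for j, eco in enumerate(ecosites):
        sub = tables.do[tables.do["ecosite"] == eco]
        if sub.empty:
            raise ValueError(f"no dissolved-oxygen data for ecosite {eco!r}")
        estimates = []
        for i, d in enumerate(np.sort(sub["day"].unique())):
            month = sub[sub["day"] == d]
            data = DOMeasurementSet(
                month["depth_cm"].to_numpy(),
                month["do_umol_per_kg"].to_numpy(),
                ecosite=eco,
                month=str(d),
            )
            est = DOProfileModel(data, threshold=threshold, n_boot=n_boot).fit(
                seed=(seed + 104729 * j + i) % 2**31, time=float(d)
            )
            estimates.append(est)
        out[eco] = estimates
    return out


def daily_oxic_fractions(
    inversions: dict[str, list[InversionResult]],
    horizons: dict[str, list[OxicHorizonEstimate]],
    seed: int = 0,
    n_draws: int = 200,
) -> OxicFractionSeries:
    """Daily per-ecosite oxic production shares over the peeper window.

    The horizon is interpolated linearly to each day; the source profile
    is the interval's posterior summary (R held constant within its month
    interval).  Posterior spread is propagated into a daily s.d. of p.
    """
    res_any = next(iter(inversions.values()))
    t0 = min(r.t_start for r in res_any)
    t1 = max(r.t_end for r in res_any)
    days = np.arange(t0, t1 + 1.0)
    series = {}
    for j, (eco, results) in enumerate(inversions.items()):
        hseries = interpolate_horizon(horizons[eco])
        starts = np.array([r.t_start for r in results])
        p = np.full(days.size, np.nan)
        sd = np.zeros(days.size)
        for i, d in enumerate(days):
            k = int(np.clip(np.searchsorted(starts, d, side="right") - 1, 0, len(results) - 1))
            res = results[k]
            h_pt, _, h_up = hseries.at(float(d))
            est = oxic_production_fraction(
                res,
                _pointwise_horizon(h_pt, h_up),
                n_draws=n_draws,
                seed=(seed + 31 * j + i) % 2**31,
            )
            if est.defined:
                p[i] = est.p
                sd[i] = est.sd if np.isfinite(est.sd) else 0.0
        series[eco] = (p, sd)
    return OxicFractionSeries(
        day=days,
        p_op=series["open"][0],
        p_mu=series["mud"][0],
        p_op_sd=series["open"][1],
        p_mu_sd=series["mud"][1],
    )


def _pointwise_horizon(h: float, upper: float) -> OxicHorizonEstimate:
    return OxicHorizonEstimate(h, min(h, upper), max(h, upper))


def run_budget(
    tables: Tables,
    inversions: dict[str, list[InversionResult]],
    horizons: dict[str, list[OxicHorizonEstimate]],
    areas: SiteAreaConfig,
    seed: int = 0,
) -> tuple[BudgetResult, OxicFractionSeries, EcositeFluxStrengths]:
    """Decompose the tower flux and scale oxic shares to the site level."""
    tower = TowerFluxSeries(tables.tower["day"].to_numpy(), tables.tower["flux_nmol_cm2_d"].to_numpy())
    fp = FootprintSeries(
        tables.footprint["day"].to_numpy(),
        tables.footprint["e_op"].to_numpy(),
        tables.footprint["e_ty"].to_numpy(),
        tables.footprint["e_ne"].to_numpy(),
        tables.footprint["e_mu"].to_numpy(),
    )
    chambers = tables.chamber.rename(columns={"day": "day"})
    ratios = ratios_from_chambers(chambers[["day", "ecosite", "flux_nmol_cm2_d"]])
    strengths = decompose_tower_flux(tower, fp, ratios)
    p_series = daily_oxic_fractions(inversions, horizons, seed=seed)
    res_any = next(iter(inversions.values()))
    window = (min(r.t_start for r in res_any), max(r.t_end for r in res_any))
    result = site_oxic_fraction(strengths, p_series, areas, window, seed=seed)
    return result, p_series, strengths


@dataclass
class PipelineReport:
    """Bundle of all stage outputs from one full run."""

    inversions: dict[str, list[InversionResult]]
    horizons: dict[str, list[OxicHorizonEstimate]]
    budget: BudgetResult
    p_series: OxicFractionSeries
    strengths: EcositeFluxStrengths

    def r_table(self) -> pd.DataFrame:
        rows = []
        for eco, results in self.inversions.items():
            for res in results:
                for z, r, s in zip(res.grid.layer_centers, res.mean_r.values, res.sd_r):
                    rows.append((eco, res.t_start, res.t_end, z, r, s))
        return pd.DataFrame(
            rows,
            columns=["ecosite", "t_start_day", "t_end_day", "depth_cm", "mean_r", "sd_r"],
        )

    def horizon_table(self) -> pd.DataFrame:
        rows = []
        for eco, ests in self.horizons.items():
            for e in ests:
                rows.append(
                    (eco, e.time, e.horizon_cm, e.lower_cm, e.upper_cm,
                     e.fit_params[0], e.fit_params[1], e.all_anoxic)
                )
        return pd.DataFrame(
            rows,
            columns=["ecosite", "day", "horizon_cm", "lower_cm", "upper_cm",
                     "fit_a", "fit_b", "all_anoxic"],
        )


def run_all(
    tables: Tables,
    inversion_cfg: InversionConfig,
    do_threshold: float,
    areas: SiteAreaConfig,
    grid: DepthGrid | None = None,
    dmodel: DiffusivityModel | None = None,
    seed: int = 0,
) -> PipelineReport:
    """Execute the full pipeline on validated tables."""
    inversions = run_inversion(tables, inversion_cfg, grid=grid, dmodel=dmodel)
    horizons = run_horizon(tables, do_threshold, seed=seed)
    budget, p_series, strengths = run_budget(tables, inversions, horizons, areas, seed=seed)
    return PipelineReport(inversions, horizons, budget, p_series, strengths)
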