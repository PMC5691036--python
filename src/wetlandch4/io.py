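"""CSV readers/writers and run configuration.

All tables are tidy long-format CSV with exact headers and ISO dates.
Depths are cm below the soil surface, positive downward, at layer centers.
Readers convert to the package's canonical units on ingest; CH4 arrives in
umol L^-1, which is numerically identical to the internal nmol cm^-3.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .budget import SiteAreaConfig
from .inversion import InversionConfig
from .oxic_horizon import DEFAULT_DO_THRESHOLD
from .transport import DepthGrid

logger = logging.getLogger(__name__)

__all__ = ["ValidationError", "Tables", "RunConfig", "read_tables", "load_config"]


class ValidationError(Exception):
    """Raised when an input table or config fails validation."""


SCHEMAS = {
    "peeper": ["date", "ecosite", "depth_cm", "ch4_umol_per_L"],
    "chamber": ["date", "ecosite", "flux_nmol_cm2_d"],
    "do": ["date", "ecosite", "depth_cm", "do_umol_per_kg"],
    "temperature": ["date", "depth_cm", "temp_c"],
    "tower": ["date", "flux_nmol_cm2_d"],
    "footprint": ["date", "e_op", "e_ty", "e_ne", "e_mu"],
}

_NONNEG = {
    "peeper": "ch4_umol_per_L",
    "do": "do_umol_per_kg",
}

_DUPLICATE_KEYS = {
    "peeper": ["date", "ecosite", "depth_cm"],
    "do": None,  # replicate DO readings at one depth are legitimate
    "temperature": ["date", "depth_cm"],
    "tower": ["date"],
    "footprint": ["date"],
    "chamber": None,  # duplicate chamber measurements are the norm
}


@dataclass
class Tables:
    """Validated in-memory observation tables, canonical units, day column added."""

    peeper: pd.DataFrame
    chamber: pd.DataFrame
    do: pd.DataFrame
    temperature: pd.DataFrame
    tower: pd.DataFrame
    footprint: pd.DataFrame
    day_zero: pd.Timestamp

    def __getitem__(self, name: str) -> pd.DataFrame:
        return getattr(self, name)


def _read_one(name: str, path: Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{name} table not found: {path}")
    df = pd.read_csv(path)
    expected = SCHEMAS[name]
    if list(df.columns) != expected:
        raise ValidationError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    try:
        parsed = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError):
        good = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
        bad_row = int(np.argmax(good.isna().to_numpy())) + 2  # header is line 1
        raise ValidationError(
            f"{path}:{bad_row}: unparsable ISO date {df['date'].iloc[bad_row - 2]!r}"
        ) from None
    df = df.assign(date=parsed)
    for col in expected[1:]:
        if col == "ecosite":
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().to_numpy().any() and not df[col].isna().all():
            bad_row = int(np.argmax(vals.isna().to_numpy())) + 2
            raise ValidationError(f"{path}:{bad_row}: non-numeric value in column {col!r}")
        df[col] = vals
    nonneg_col = _NONNEG.get(name)
    if nonneg_col is not None and (df[nonneg_col] < 0).any():
        bad_row = int(np.argmax((df[nonneg_col] < 0).to_numpy())) + 2
        raise ValidationError(
            f"{path}:{bad_row}: negative {nonneg_col} ({df[nonneg_col].iloc[bad_row - 2]})"
        )
    keys = _DUPLICATE_KEYS.get(name)
    if keys and df.duplicated(subset=keys).any():
        bad_row = int(np.argmax(df.duplicated(subset=keys).to_numpy())) + 2
        raise ValidationError(f"{path}:{bad_row}: duplicate {tuple(keys)} row")
    return df


def read_tables(paths: dict[str, Path | str]) -> Tables:
    """Read and validate the six observation CSVs.

    ``paths`` maps table names (peeper, chamber, do, temperature, tower,
    footprint) to file paths.  A ``day`` column (float days since the
    earliest peeper date) is added to every table; CH4 concentrations are
    stored as nmol cm^-3 (1:1 with the umol L^-1 input).
    """
    missing = [k for k in SCHEMAS if k not in paths]
    if missing:
        raise ValidationError(f"missing table paths: {missing}")
    frames = {name: _read_one(name, Path(paths[name])) for name in SCHEMAS}
    day_zero = frames["peeper"]["date"].min()
    for name, df in frames.items():
        df["day"] = (df["date"] - day_zero) / pd.Timedelta(days=1)
    frames["peeper"] = frames["peeper"].rename(columns={"ch4_umol_per_L": "ch4_nmol_cm3"})
    return Tables(day_zero=day_zero, **frames)


@dataclass
class RunConfig:
    """Configuration for a pipeline run (TOML-loadable)."""

    paths: dict[str, str] = field(default_factory=dict)
    grid: DepthGrid = field(default_factory=DepthGrid)
    inversion: InversionConfig = field(default_factory=InversionConfig)
    do_threshold: float = DEFAULT_DO_THRESHOLD
    areas: SiteAreaConfig = field(default_factory=SiteAreaConfig)
    diffusivity_tortuosity: float = 1.0
    outdir: str = "wetlandch4_out"
    seed: int = 0
    log_level: str = "INFO"


def load_config(path: Path | str) -> RunConfig:
    """Load a TOML run configuration with field-level validation."""
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ValidationError(f"{path}: invalid TOML: {exc}") from exc
    cfg = RunConfig()
    try:
        if "paths" in raw:
            cfg.paths = {str(k): str(v) for k, v in raw["paths"].items()}
        if "grid" in raw:
            cfg.grid = DepthGrid(**raw["grid"])
        if "inversion" in raw:
            cfg.inversion = InversionConfig(**raw["inversion"])
        if "budget" in raw:
            b = raw["budget"]
            if "do_threshold" in b:
                cfg.do_threshold = float(b["do_threshold"])
            if "f_op" in b or "f_mu" in b:
                cfg.areas = SiteAreaConfig(f_op=b.get("f_op", 0.9), f_mu=b.get("f_mu", 0.1))
        for key in ("outdir", "seed", "log_level", "diffusivity_tortuosity"):
            if key in raw:
                setattr(cfg, key, raw[key])
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    return cfg
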