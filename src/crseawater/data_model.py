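"""Domain types, unit conversions and station-table I/O.

Station tables are comma-separated text with a header row, one row per
bottle replicate (columns: station, lat, depth_m, time_local,
cr_total_nmolkg, cr_total_sd, d53cr_permil, d53cr_2se, cr3_nmolkg,
cr3_sd, replicate, day). Missing optional cells are left absent rather
than imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .constants import DEFAULT_CONSTANTS, Constants

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("station", "depth_m", "cr_total_nmolkg")
OPTIONAL_COLUMNS = (
    "lat", "time_local", "cr_total_sd", "d53cr_permil", "d53cr_2se",
    "cr3_nmolkg", "cr3_sd", "replicate", "day",
)


class StationTableFormatError(ValueError):
    """Input file does not satisfy the station-table contract."""


class ValidationError(ValueError):
    """A field value violates a physical invariant."""


@dataclass
class SeawaterSample:
    """One bottle measurement of the dissolved chromium system.

    Concentrations in nmol/kg with 1σ; d53cr in permil vs NIST SRM 979
    with 2 SE; ``cr3`` may be absent (None). ``flags`` holds QC markers
    such as ``outlier``, ``above_winter_ml``, ``in_euphotic_zone``,
    ``diel_replicated``.
    """

    station_id: str
    depth: float
    cr_total: float
    latitude: float | None = None
    time_local: float | None = None     # decimal hours, local
    cr_total_sd: float | None = None
    d53cr: float | None = None
    d53cr_2se: float | None = None
    cr3: float | None = None
    cr3_sd: float | None = None
    replicate_tag: int | None = None
    day: int | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValidationError(f"depth must be >= 0, got {self.depth}")
        if self.cr_total < 0:
            raise ValidationError(
                f"negative total Cr {self.cr_total} at station "
                f"{self.station_id}, depth {self.depth}")
        if self.cr3 is not None:
            if self.cr3 < 0:
                raise ValidationError(
                    f"negative Cr(III) {self.cr3} at station "
                    f"{self.station_id}, depth {self.depth}")
            s_tot = self.cr_total_sd or 0.0
            s_cr3 = self.cr3_sd or 0.0
            slack = 2.0 * math.hypot(s_tot, s_cr3)
            if self.cr3 > self.cr_total + slack:
                raise ValidationError(
                    f"Cr(III) {self.cr3} exceeds total Cr {self.cr_total} "
                    f"beyond 2σ at station {self.station_id}, depth {self.depth}")
        if self.d53cr is not None and not math.isfinite(self.d53cr):
            raise ValidationError("d53cr must be finite when present")


@dataclass
class StationContext:
    """Per-station hydrographic and productivity metadata.

    ``winter_ml_depth`` is the deep winter mixed layer that bounds the
    deficit integration (default 100 m); ``obs_ml_depth`` the mixed
    layer while on station; ``euphotic_depth`` the 1% isolume. NCP in
    mmol C m-3 day-1, ANCP in mol C m-2 yr-1.
    """

    station_id: str
    winter_ml_depth: float = 100.0
    obs_ml_depth: float | None = None
    euphotic_depth: float | None = None
    ncp_vol: float | None = None
    ancp: float | None = None

    def __post_init__(self) -> None:
        if self.euphotic_depth is not None and self.euphotic_depth <= 0:
            raise ValidationError("euphotic_depth must be positive")
        if self.obs_ml_depth is not None:
            if self.obs_ml_depth <= 0:
                raise ValidationError("obs_ml_depth must be positive")
            if self.obs_ml_depth > self.winter_ml_depth:
                logger.warning(
                    "station %s: observed ML (%.1f m) deeper than winter ML "
                    "(%.1f m)", self.station_id, self.obs_ml_depth,
                    self.winter_ml_depth)


def _get(row: pd.Series, col: str) -> float | None:
    if col not in row.index:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    try:
        return float(v)
    except (TypeError, ValueError):
        logger.warning("unparseable cell %r in column %s; treated as absent",
                       v, col)
        return None


def read_station_table(path: str | Path) -> list[SeawaterSample]:
    """Read a station-table CSV into typed :class:`SeawaterSample` records.

    Row order is preserved; optional columns that are absent yield absent
    fields. Raises :class:`StationTableFormatError` for missing required
    columns and :class:`ValidationError` (naming the row) for negative
    concentrations.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise StationTableFormatError(
            f"{path}: missing required column(s) {missing}")
    samples = []
    for i, row in df.iterrows():
        try:
            rep = _get(row, "replicate")
            day = _get(row, "day")
            samples.append(SeawaterSample(
                station_id=str(row["station"]),
                depth=float(row["depth_m"]),
                cr_total=float(row["cr_total_nmolkg"]),
                latitude=_get(row, "lat"),
                time_local=_get(row, "time_local"),
                cr_total_sd=_get(row, "cr_total_sd"),
                d53cr=_get(row, "d53cr_permil"),
                d53cr_2se=_get(row, "d53cr_2se"),
                cr3=_get(row, "cr3_nmolkg"),
                cr3_sd=_get(row, "cr3_sd"),
                replicate_tag=int(rep) if rep is not None else None,
                day=int(day) if day is not None else None,
            ))
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {i}: {exc}") from exc
    return samples


def write_station_table(samples: list[SeawaterSample], path: str | Path) -> None:
    """Write samples back to the station-table CSV schema (lossless)."""
    rows = []
    for s in samples:
        rows.append({
            "station": s.station_id, "lat": s.latitude, "depth_m": s.depth,
            "time_local": s.time_local, "cr_total_nmolkg": s.cr_total,
            "cr_total_sd": s.cr_total_sd, "d53cr_permil": s.d53cr,
            "d53cr_2se": s.d53cr_2se, "cr3_nmolkg": s.cr3,
            "cr3_sd": s.cr3_sd, "replicate": s.replicate_tag, "day": s.day,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_contexts(path: str | Path) -> list[StationContext]:
    """Read per-station context CSV (station, winter_ml_depth, obs_ml_depth,
    euphotic_depth, ncp_vol, ancp)."""
    df = pd.read_csv(path)
    if "station" not in df.columns:
        raise StationTableFormatError(f"{path}: missing 'station' column")
    out = []
    for _, row in df.iterrows():
        out.append(StationContext(
            station_id=str(row["station"]),
            winter_ml_depth=_get(row, "winter_ml_depth") or 100.0,
            obs_ml_depth=_get(row, "obs_ml_depth"),
            euphotic_depth=_get(row, "euphotic_depth"),
            ncp_vol=_get(row, "ncp_vol"),
            ancp=_get(row, "ancp"),
        ))
    return out


def write_contexts(contexts: list[StationContext], path: str | Path) -> None:
    pd.DataFrame([{
        "station": c.station_id, "winter_ml_depth": c.winter_ml_depth,
        "obs_ml_depth": c.obs_ml_depth, "euphotic_depth": c.euphotic_depth,
        "ncp_vol": c.ncp_vol, "ancp": c.ancp,
    } for c in contexts]).to_csv(path, index=False)


def convert_conc_to_areal(conc: float, thickness: float,
                          density: float = DEFAULT_CONSTANTS.density_sw) -> float:
    """Convert a concentration anomaly (nmol/kg) over a layer to an areal
    inventory (µmol/m2).

    nmol/kg × kg/m3 × m × 1e-3 = µmol/m2.
    """
    if thickness <= 0:
        raise ValueError(f"layer thickness must be positive, got {thickness}")
    return conc * density * thickness * 1e-3


def gigatons_c_to_mol_cr(c_export: float, crc: float,
                         constants: Constants = DEFAULT_CONSTANTS) -> float:
    """Scale a carbon export flux (Gt C/yr) to a chromium flux (mol Cr/yr)
    at a given Cr:C ratio (µmol Cr / mol C)."""
    if c_export < 0 or crc < 0:
        raise ValueError("carbon export and Cr:C must be non-negative")
    mol_c = c_export * 1e15 / constants.molar_mass_c
    return mol_c * crc * 1e-6


def crc_from_dry_weight(cr_ug_per_g: float, c_weight_frac: float,
                        constants: Constants = DEFAULT_CONSTANTS) -> float:
    """Cr:C ratio (µmol Cr / mol C) from a cellular Cr content (µg Cr per g
    dry weight) and a carbon mass fraction of dry weight."""
    if cr_ug_per_g < 0 or not 0 < c_weight_frac <= 1:
        raise ValueError("need cr_ug_per_g >= 0 and 0 < c_weight_frac <= 1")
    mol_cr_per_g = cr_ug_per_g * 1e-6 / constants.molar_mass_cr
    mol_c_per_g = c_weight_frac / constants.molar_mass_c
    return mol_cr_per_g / mol_c_per_g * 1e6
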