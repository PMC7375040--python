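"""Mixed-layer chromium inventory deficits and export budgets.

The upper-ocean Cr deficit is the difference between the mean [Cr] of a
subsurface reference layer (150-200 m) and the trapezoid-integrated
mean of the layer above the winter mixed layer (0-100 m). A deficit is
called significant only when it exceeds the combined analytical
precision of the two layer means. Deficits are compared with the Cr
export expected from annual net community production scaled by
phytoplankton/particulate Cr:C ratios, and the same scaling extrapolates
global carbon export to a global biological Cr flux for comparison with
the riverine source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_CONSTANTS, Constants
from .data_model import convert_conc_to_areal, gigatons_c_to_mol_cr


@dataclass
class BudgetResult:
    """Per-station deficit and export comparison (Table-style row)."""

    station_id: str
    mean_upper: float               # nmol/kg, 0-100 m
    mean_ref: float                 # nmol/kg, 150-200 m
    deficit_conc: float             # nmol/kg
    significant: bool
    areal_deficit_ml: float | None          # µmol/m2, deficit_conc x ML x rho
    areal_deficit_ml_profile: float | None  # µmol/m2, trapezoid of (ref - c)
    inferred_export_low: float | None       # µmol m-2 yr-1
    inferred_export_high: float | None


def trapezoid_layer_mean(depths, concs, z_top: float, z_bottom: float,
                         min_samples: int = 2) -> float:
    """Thickness-normalised trapezoidal integral of a profile over
    [z_top, z_bottom].

    The shallowest sample is extended uniformly up to z_top and the
    deepest extended to z_bottom (linear interpolation applies between
    samples). Requires at least two samples intersecting the layer.
    """
    z = np.asarray(depths, dtype=float)
    c = np.asarray(concs, dtype=float)
    if z_bottom <= z_top:
        raise ValueError("z_bottom must exceed z_top")
    order = np.argsort(z)
    z, c = z[order], c[order]
    in_range = (z >= z_top) & (z <= z_bottom)
    if in_range.sum() < min_samples:
        raise ValueError(
            f"need >= {min_samples} samples inside [{z_top}, {z_bottom}] m, "
            f"have {int(in_range.sum())}")
    grid = np.unique(np.concatenate([[z_top, z_bottom],
                                     z[(z > z_top) & (z < z_bottom)]]))
    vals = np.interp(grid, z, c)   # np.interp clamps at the ends
    integral = np.trapezoid(vals, grid)
    return float(integral / (z_bottom - z_top))


def deficit(depths, concs, upper: tuple[float, float] = (0.0, 100.0),
            ref: tuple[float, float] = (150.0, 200.0),
            rsd: float = DEFAULT_CONSTANTS.rsd_cr,
            rule: str = "combined") -> tuple[float, bool]:
    """Concentration deficit (ref-layer mean minus upper-layer mean) and
    its significance against analytical precision.

    ``rule='combined'`` (default) requires the deficit to exceed
    √2 × RSD × ref mean — both layer means carry the measurement RSD;
    ``rule='single'`` uses one RSD.
    """
    mean_upper = trapezoid_layer_mean(depths, concs, *upper)
    mean_ref = trapezoid_layer_mean(depths, concs, *ref)
    d = mean_ref - mean_upper
    threshold = rsd * mean_ref * (math.sqrt(2.0) if rule == "combined" else 1.0)
    return d, bool(d > threshold)


def inferred_export(ancp: float,
                    crc_low: float = DEFAULT_CONSTANTS.crc_low,
                    crc_high: float = DEFAULT_CONSTANTS.crc_high,
                    ) -> tuple[float, float]:
    """Annual Cr export range (µmol Cr m-2 yr-1) from ANCP
    (mol C m-2 yr-1) times bracketing Cr:C ratios (µmol/mol)."""
    if ancp < 0:
        raise ValueError("ANCP must be non-negative")
    return ancp * crc_low, ancp * crc_high


def round_sig(value: float, sig: int = 1) -> float:
    """Round to ``sig`` significant figures (presentation only)."""
    if value == 0:
        return 0.0
    k = sig - 1 - math.floor(math.log10(abs(value)))
    return round(value, k)


def station_budget(station_id: str, depths, concs,
                   obs_ml_depth: float | None, ancp: float | None,
                   constants: Constants = DEFAULT_CONSTANTS,
                   upper: tuple[float, float] = (0.0, 100.0),
                   ref: tuple[float, float] = (150.0, 200.0),
                   rule: str = "combined") -> BudgetResult:
    """Assemble the per-station deficit/export comparison.

    The areal deficit inside the on-station mixed layer is reported two
    ways: the concentration deficit scaled by ML thickness and density,
    and the trapezoid of (ref mean − c(z)) over the ML, which weights
    the near-surface part of the depletion profile. Areal deficits are
    reported only for positive concentration deficits.
    """
    d, sig = deficit(depths, concs, upper=upper, ref=ref,
                     rsd=constants.rsd_cr, rule=rule)
    mean_upper = trapezoid_layer_mean(depths, concs, *upper)
    mean_ref = trapezoid_layer_mean(depths, concs, *ref)
    areal = areal_profile = None
    if obs_ml_depth is not None and d > 0:
        areal = convert_conc_to_areal(d, obs_ml_depth, constants.density_sw)
        # thin on-station MLs may contain a single bottle; interpolation
        # from the full profile still defines the integral
        ml_mean = trapezoid_layer_mean(depths, concs, 0.0, obs_ml_depth,
                                       min_samples=1)
        areal_profile = convert_conc_to_areal(
            mean_ref - ml_mean, obs_ml_depth, constants.density_sw)
    lo = hi = None
    if ancp is not None:
        lo, hi = inferred_export(ancp, constants.crc_low, constants.crc_high)
    return BudgetResult(
        station_id=station_id, mean_upper=mean_upper, mean_ref=mean_ref,
        deficit_conc=d, significant=sig, areal_deficit_ml=areal,
        areal_deficit_ml_profile=areal_profile,
        inferred_export_low=lo, inferred_export_high=hi)


@dataclass
class GlobalExport:
    """Global biological Cr export vs the external source flux."""

    cr_export_low: float        # mol Cr / yr
    cr_export_high: float
    source_low: float
    source_high: float
    overlaps_sources: bool


def global_export(c_exports_gt, crc_low: float = DEFAULT_CONSTANTS.crc_low,
                  crc_high: float = DEFAULT_CONSTANTS.crc_high,
                  source_range: tuple[float, float] = (0.5e8, 5.6e8),
                  constants: Constants = DEFAULT_CONSTANTS) -> GlobalExport:
    """Range of global Cr export (mol/yr) over carbon-export estimates
    (Gt C/yr) × Cr:C bounds, compared with the total external Cr source
    flux (default: the riverine range 0.5-5.6 × 1e8 mol/yr)."""
    c_exports_gt = list(c_exports_gt)
    if not c_exports_gt or any(c <= 0 for c in c_exports_gt):
        raise ValueError("carbon export estimates must be positive")
    fluxes = [gigatons_c_to_mol_cr(c, crc, constants)
              for c in c_exports_gt for crc in (crc_low, crc_high)]
    lo, hi = min(fluxes), max(fluxes)
    s_lo, s_hi = source_range
    return GlobalExport(cr_export_low=lo, cr_export_high=hi,
                        source_low=s_lo, source_high=s_hi,
                        overlaps_sources=bool(lo <= s_hi and s_lo <= hi))
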