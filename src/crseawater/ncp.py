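"""Net community production from O2/Ar supersaturation.

Argon has nearly identical solubility physics to oxygen but no
biological sources or sinks, so the measured O2/Ar ratio relative to
its air-equilibrium value isolates the biologically produced oxygen
excess Δ(O2/Ar). At steady state, and neglecting vertical mixing, the
air-sea flux of that biological oxygen equals net community production:

    NCP_O2 = k · [O2]_sat · Δ(O2/Ar)      (mmol O2 m-2 day-1)

with k the gas transfer velocity. k is computed from the quadratic
wind-speed relation k660 = a·u10² scaled by (Sc/660)^-1/2 and, because
the surface ocean integrates over the residence time of oxygen in the
mixed layer, is weighted over a 60-day wind history: each interval's
weight is the fraction of the mixed layer it ventilated times the
fraction left un-ventilated by all later intervals. Division by a
photosynthetic quotient O2:C = 1.4 converts to carbon units.

Solubility and Schmidt-number parameterisations are fixed published
coefficient sets (Garcia & Gordon 1992 combined fit for O2; Hamme &
Emerson 2004 for Ar; Wanninkhof 2014 Schmidt polynomial and transfer
coefficient a = 0.251 cm/hr per (m/s)²).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_CONSTANTS, Constants

logger = logging.getLogger(__name__)

# O2 solubility, Garcia & Gordon (1992) combined fit, µmol/kg.
_O2_A = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)
_O2_B = (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3)
_O2_C0 = -2.75915e-7

# Ar solubility, Hamme & Emerson (2004), µmol/kg.
_AR_A = (2.79150, 3.17609, 4.13116, 4.90379)
_AR_B = (-6.96233e-3, -7.66670e-3, -1.16888e-2)

# Schmidt number of O2 in seawater (S=35), Wanninkhof (2014).
_SC_O2 = (1920.4, -135.6, 5.2122, -0.10939, 9.3777e-4)
# Schmidt number of Ar in seawater (S=35), Wanninkhof (2014).
_SC_AR = (2078.1, -146.74, 5.6403, -0.11838, 1.0148e-3)

WANNINKHOF_A = 0.251     # cm/hr per (m/s)^2, quadratic transfer relation


def _scaled_temp(t_c: float) -> float:
    return math.log((298.15 - t_c) / (273.15 + t_c))


def _check_ts(t_c: float, s: float) -> None:
    if not -2.0 <= t_c <= 40.0 or not 0.0 <= s <= 42.0:
        raise ValueError(f"T={t_c} degC, S={s} outside physical range")


def o2_solubility(t_c: float, s: float) -> float:
    """Air-equilibrium O2 concentration, µmol/kg."""
    _check_ts(t_c, s)
    ts = _scaled_temp(t_c)
    ln_c = sum(a * ts ** i for i, a in enumerate(_O2_A))
    ln_c += s * sum(b * ts ** i for i, b in enumerate(_O2_B))
    ln_c += _O2_C0 * s * s
    return math.exp(ln_c)


def ar_solubility(t_c: float, s: float) -> float:
    """Air-equilibrium Ar concentration, µmol/kg."""
    _check_ts(t_c, s)
    ts = _scaled_temp(t_c)
    ln_c = sum(a * ts ** i for i, a in enumerate(_AR_A))
    ln_c += s * sum(b * ts ** i for i, b in enumerate(_AR_B))
    return math.exp(ln_c)


def schmidt_o2(t_c: float) -> float:
    """Schmidt number of O2 in seawater (valid −2 to 40 degC)."""
    return sum(c * t_c ** i for i, c in enumerate(_SC_O2))


@dataclass
class NcpInputs:
    """Inputs for one station's O2/Ar NCP estimate.

    ``o2ar_meas`` is the measured dissolved O2/Ar mole ratio;
    ``wind_times_days`` / ``wind_u10`` a 10-m wind-speed history
    covering at least the weighting window before sampling (times in
    days, increasing, sampling at the last time).
    """

    o2ar_meas: float
    temperature: float          # degC
    salinity: float             # PSU
    mld: float                  # m
    wind_times_days: np.ndarray | list
    wind_u10: np.ndarray | list
    o2_conc: float | None = None    # Winkler O2, µmol/kg (diagnostic)

    def __post_init__(self) -> None:
        if self.o2ar_meas <= 0:
            raise ValueError("measured O2/Ar must be positive")
        if self.mld <= 0:
            raise ValueError("mixed-layer depth must be positive")
        t = np.asarray(self.wind_times_days, dtype=float)
        u = np.asarray(self.wind_u10, dtype=float)
        if t.size != u.size or t.size == 0:
            raise ValueError("wind series empty or mismatched")
        if np.any(u < 0):
            raise ValueError("wind speeds must be non-negative")


def equilibrium_o2ar(t_c: float, s: float) -> float:
    """Air-equilibrium O2/Ar mole ratio."""
    return o2_solubility(t_c, s) / ar_solubility(t_c, s)


def bio_supersaturation(inputs: NcpInputs) -> float:
    """Biological O2 supersaturation Δ(O2/Ar) =
    (O2/Ar)_measured / (O2/Ar)_equilibrium − 1."""
    return inputs.o2ar_meas / equilibrium_o2ar(
        inputs.temperature, inputs.salinity) - 1.0


def instantaneous_k(u10, t_c: float, a: float = WANNINKHOF_A) -> np.ndarray:
    """Gas transfer velocity for O2, m/day, from 10-m wind speed (m/s):
    k = a·u10²·(Sc/660)^−1/2, a in cm/hr."""
    u10 = np.asarray(u10, dtype=float)
    k_cm_hr = a * u10 ** 2 * (schmidt_o2(t_c) / 660.0) ** -0.5
    return k_cm_hr * 24.0 / 100.0


def weighted_gas_transfer(wind_times_days, wind_u10, t_c: float, s: float,
                          mld: float, window_days: float = 60.0,
                          a: float = WANNINKHOF_A) -> float:
    """Mixed-layer-ventilation-weighted gas transfer velocity, m/day.

    Working backward in time from the sampling date over ``window_days``,
    each interval i ventilates the fraction f_i = k_i·Δt_i / mld of the
    mixed layer (capped at 1); its weight is f_i times the product of
    (1 − f_j) over all intervals j closer to sampling, i.e. the share of
    present mixed-layer gas it last equilibrated. Weights are
    normalised to sum to 1.
    """
    t = np.asarray(wind_times_days, dtype=float)
    u = np.asarray(wind_u10, dtype=float)
    if t.size == 0:
        raise ValueError("empty wind series")
    order = np.argsort(t)
    t, u = t[order], u[order]
    t_end = t[-1]
    sel = t >= t_end - window_days
    if (t_end - t[0]) < window_days:
        logger.warning("wind series spans %.1f days, shorter than the "
                       "%.0f-day window", t_end - t[0], window_days)
    t, u = t[sel], u[sel]
    if t.size < 2:
        raise ValueError("need >= 2 wind observations inside the window")
    dt = np.diff(t)
    if np.any(dt > 1.0 + 1e-9):
        logger.warning("gap > 1 day in wind series (max %.2f days)", dt.max())
    k = instantaneous_k(u, t_c, a)
    # interval k as mean of endpoints; intervals ordered old -> recent
    k_int = 0.5 * (k[:-1] + k[1:])
    f = np.minimum(k_int * dt / mld, 1.0)
    # survival of interval i's signature through later ventilation
    surv = np.append(np.cumprod((1.0 - f)[::-1])[-2::-1], 1.0)
    w = f * surv
    if w.sum() == 0:
        return float(k_int[-1])
    w = w / w.sum()
    return float(np.sum(w * k_int))


@dataclass
class NcpResult:
    """NCP in the three unit conventions used downstream."""

    areal: float         # mmol C m-2 day-1
    volumetric: float    # mmol C m-3 day-1
    annual: float        # mol C m-2 yr-1
    k: float             # m/day
    delta_o2ar: float
    o2_sat_mmol_m3: float
    net_heterotrophy: bool


def ncp(inputs: NcpInputs, constants: Constants = DEFAULT_CONSTANTS,
        window_days: float = 60.0, a: float = WANNINKHOF_A) -> NcpResult:
    """Net community production from one station's O2/Ar inputs.

    areal = k·[O2]_sat·Δ(O2/Ar) / (O2:C); volumetric divides by the
    mixed-layer depth; annual scales by 365.25/1000. Negative Δ gives
    negative NCP (net heterotrophy), flagged but allowed.
    """
    delta = bio_supersaturation(inputs)
    k = weighted_gas_transfer(inputs.wind_times_days, inputs.wind_u10,
                              inputs.temperature, inputs.salinity,
                              inputs.mld, window_days, a)
    o2_sat = o2_solubility(inputs.temperature, inputs.salinity)
    o2_sat_vol = o2_sat * constants.density_sw / 1000.0    # mmol/m3
    areal = k * o2_sat_vol * delta / constants.o2c_ratio
    return NcpResult(
        areal=areal, volumetric=areal / inputs.mld,
        annual=areal * 365.25 / 1000.0, k=k, delta_o2ar=delta,
        o2_sat_mmol_m3=o2_sat_vol, net_heterotrophy=bool(delta < 0))
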