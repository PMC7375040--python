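"""Physical constants and study-wide parameters.

All concentration work is done in nmol/kg; depths are metres, positive
downward, 0 at the sea surface; delta values are permil vs NIST SRM 979.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class Constants:
    """Fixed parameters of the chromium budget and measurement model.

    Attributes
    ----------
    cr6nr_const : float
        Assumed constant [Cr(VI) + Cr(III)_NR] pool, nmol/kg. The inert
        (non-particle-reactive) chromium background against which the
        reactive Cr(III) mass balance is evaluated.
    o2c_ratio : float
        Photosynthetic quotient, mol O2 per mol C, used to convert
        O2-based net community production to carbon units.
    crc_low, crc_high : float
        Bracketing phytoplankton/particulate Cr:C ratios, µmol Cr per
        mol C (sediment-trap and surface-assemblage end members).
    density_sw : float
        Nominal seawater density for kg <-> m3 conversions, kg/m3.
    rsd_cr : float
        External reproducibility of [Cr] measurements, relative 1 SD.
    cr3_default_unc : float
        Conservative relative uncertainty applied to non-replicated
        Cr(III) measurements.
    ext_2sd_d53cr : float
        External reproducibility of seawater δ53Cr, permil (2 SD).
    """

    cr6nr_const: float = 2.9          # nmol/kg
    o2c_ratio: float = 1.4            # mol O2 / mol C
    crc_low: float = 0.555            # µmol Cr / mol C
    crc_high: float = 2.7             # µmol Cr / mol C
    molar_mass_c: float = 12.011      # g/mol
    molar_mass_cr: float = 51.996     # g/mol
    density_sw: float = 1025.0        # kg/m3
    rsd_cr: float = 0.0082            # relative 1 SD
    cr3_default_unc: float = 0.10     # relative
    ext_2sd_d53cr: float = 0.033      # permil, 2 SD

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"constant {f.name} must be positive, got {v}")
        if not self.crc_low < self.crc_high:
            raise ValueError("crc_low must be below crc_high")


DEFAULT_CONSTANTS = Constants()


def load_constants(path: str | Path) -> Constants:
    """Constants with overrides from a YAML mapping (unknown keys are an
    error so typos do not silently keep defaults)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(Constants)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown constant override(s): {sorted(unknown)}")
    return replace(DEFAULT_CONSTANTS, **data)
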