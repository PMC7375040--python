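"""Chromium redox speciation arithmetic.

The reactive Cr(III) fraction recovered by Mg(OH)2 coprecipitation is
differenced from total dissolved Cr to give the residual pool, nominally
Cr(VI) plus any non-reactive Cr(III) ("Cr(VI)+Cr(III)_NR"; whether a
non-recovered Cr(III) fraction exists is left open, hence the compound
name). Uncertainties combine in quadrature, treating the two
measurements as independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import DEFAULT_CONSTANTS, Constants
from .data_model import ValidationError


@dataclass
class SpeciationRecord:
    """Speciated chromium concentrations with propagated 1σ."""

    cr_total: float
    cr_total_sd: float
    cr3: float
    cr3_sd: float
    cr6_nr: float
    cr6_nr_sd: float
    pct_cr3: float
    pct_cr3_sd: float


def speciate(cr_total: float, cr_total_sd: float,
             cr3: float, cr3_sd: float) -> SpeciationRecord:
    """Difference total Cr and Cr(III) into a :class:`SpeciationRecord`.

    cr6_nr = cr_total − cr3 with quadrature σ; pct_cr3 = 100·cr3/cr_total
    with relative errors combined in quadrature. A deficit beyond 2σ
    combined (cr3 > cr_total) raises :class:`ValidationError`.
    """
    diff = cr_total - cr3
    sd = math.hypot(cr_total_sd, cr3_sd)
    if diff < -2.0 * sd:
        raise ValidationError(
            f"Cr(III) {cr3} exceeds total Cr {cr_total} beyond 2σ ({sd:.3g})")
    pct = 100.0 * cr3 / cr_total
    if cr3 > 0:
        pct_sd = pct * math.hypot(cr3_sd / cr3, cr_total_sd / cr_total)
    else:
        pct_sd = 100.0 * cr3_sd / cr_total
    return SpeciationRecord(
        cr_total=cr_total, cr_total_sd=cr_total_sd, cr3=cr3, cr3_sd=cr3_sd,
        cr6_nr=diff, cr6_nr_sd=sd, pct_cr3=pct, pct_cr3_sd=pct_sd)


@dataclass
class BlankCorrected:
    """Blank-corrected Cr(III) concentration with QC flag."""

    conc: float                 # nmol/kg
    flag: str | None            # None | "at-blank" | "below-blank"


def blank_correct(raw_pg: float, blanks_pg: tuple[float, ...] | list[float],
                  volume_l: float,
                  constants: Constants = DEFAULT_CONSTANTS) -> BlankCorrected:
    """Correct a raw Cr mass (pg in the processed aliquot) for procedural
    blanks and convert to nmol/kg.

    Subtracts the summed blanks (chromatography plus reagent, pg Cr),
    converts pg -> pmol via the Cr molar mass, and divides by the sample
    mass (volume × nominal density). Corrected masses at or below the
    blank clip to zero with a flag rather than going negative.
    """
    if volume_l <= 0:
        raise ValueError("sample volume must be positive")
    if any(b < 0 for b in blanks_pg):
        raise ValueError("blanks must be non-negative")
    net_pg = raw_pg - sum(blanks_pg)
    flag = None
    if net_pg < 0:
        net_pg, flag = 0.0, "below-blank"
    elif net_pg == 0:
        flag = "at-blank"
    pmol = net_pg / constants.molar_mass_cr
    mass_kg = volume_l * constants.density_sw / 1000.0
    return BlankCorrected(conc=pmol / mass_kg / 1000.0, flag=flag)
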