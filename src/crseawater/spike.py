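"""Double-spike MC-ICP-MS data reduction for chromium.

A 50Cr-54Cr double spike is mixed with the sample before chemistry, so
that natural mass-dependent fractionation (α), instrumental mass bias
(β) and the spike proportion (λ) can be solved simultaneously from
three measured isotope ratios (50/52, 53/52, 54/52). Both fractionation
laws are exponential: a ratio of isotopes with masses m_i, m_j scales
as (m_i/m_j)^φ per unit φ (per-amu to first order).

The measurement model, with ratios to 52Cr and λ the fraction of the
52Cr in the mixture contributed by the spike, is

    measured_i = (λ·S_i + (1−λ)·R_i·(m_i/m_52)^α) · (m_i/m_52)^β

(mixing of ratios sharing a denominator is exact in λ). The system is
solved by Newton iteration with an analytic Jacobian. δ53Cr follows
from α: δ53Cr = 1000·((m_53/m_52)^α − 1).

Isobaric interferences of Ti, V and Fe on masses 50 and 54 are stripped
beforehand using the monitor masses 49, 51 and 56 and natural abundance
ratios; the largest such interference is 54Fe on 54Cr.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

# Atomic masses (u) of the chromium isotopes.
CR_MASSES = {50: 49.9460442, 52: 51.9405075, 53: 52.9406494, 54: 53.9388804}

# NIST SRM 979 certificate isotope-amount ratios (external constants;
# the reference against which delta values are expressed).
SRM979_RATIOS = {50: 0.051859, 53: 0.113386, 54: 0.028222}

# Natural isotope-abundance ratios used for interference stripping.
NATURAL_50TI_49TI = 5.18 / 5.41
NATURAL_50V_51V = 0.250 / 99.750
NATURAL_54FE_56FE = 5.845 / 91.754


def _default_spike() -> dict[int, float]:
    # Plausible 50Cr-54Cr double spike (~48% 50Cr, ~48% 54Cr by moles),
    # expressed as ratios to 52Cr; a config input, not a measured value.
    return {50: 13.7, 53: 0.143, 54: 13.7}


@dataclass
class IsotopeSystem:
    """Reference and spike compositions plus interference systematics."""

    reference_ratios: dict[int, float] = field(
        default_factory=lambda: dict(SRM979_RATIOS))
    spike_ratios: dict[int, float] = field(default_factory=_default_spike)
    masses: dict[int, float] = field(default_factory=lambda: dict(CR_MASSES))
    ti_ratio: float = NATURAL_50TI_49TI     # 50Ti/49Ti
    v_ratio: float = NATURAL_50V_51V        # 50V/51V
    fe_ratio: float = NATURAL_54FE_56FE     # 54Fe/56Fe

    def __post_init__(self) -> None:
        for d in (self.reference_ratios, self.spike_ratios):
            if any(v <= 0 for v in d.values()):
                raise ValueError("isotope ratios must be positive")

    def mass_ratio(self, i: int, j: int = 52) -> float:
        return self.masses[i] / self.masses[j]

    def spike_52_abundance(self) -> float:
        """Fractional abundance of 52Cr in the spike."""
        return 1.0 / (1.0 + sum(self.spike_ratios.values()))

    def reference_52_abundance(self) -> float:
        return 1.0 / (1.0 + sum(self.reference_ratios.values()))


DEFAULT_SYSTEM = IsotopeSystem()


@dataclass
class InversionResult:
    """Products of the three-ratio double-spike inversion.

    ``lambda_52`` is the spike's share of the 52Cr beam (the variable
    the inversion is linear in); ``lambda_molar`` the spike's share of
    total Cr moles, used for isotope dilution. α and β are the natural
    and instrumental exponential-law fractionation exponents, and
    ``d53cr`` the permil deviation of the sample 53Cr/52Cr from the
    reference implied by α.
    """

    lambda_52: float
    alpha: float
    beta: float
    d53cr: float
    lambda_molar: float
    converged: bool
    iterations: int
    residual_norm: float


class ContaminationError(ValueError):
    """Interference-corrected beam is significantly negative."""


def interference_correct(beams: dict[int, float],
                         system: IsotopeSystem = DEFAULT_SYSTEM,
                         noise_sd: float = 0.0) -> dict[int, float]:
    """Strip Ti, V and Fe isobars from the Cr beams.

    ``beams`` maps mass -> intensity for 49-56. Ti (via 49) and V (via
    51) contribute at mass 50; Fe (via 56) at mass 54. Corrected beams
    below −3·``noise_sd`` raise :class:`ContaminationError`; small
    negative excursions clip to zero.
    """
    if any(beams.get(m, 0.0) < 0 for m in (49, 51, 56)):
        raise ValueError("monitor intensities must be non-negative")
    out = {m: float(beams[m]) for m in (50, 52, 53, 54)}
    out[50] -= beams.get(49, 0.0) * system.ti_ratio
    out[50] -= beams.get(51, 0.0) * system.v_ratio
    out[54] -= beams.get(56, 0.0) * system.fe_ratio
    for m in (50, 54):
        if out[m] < -3.0 * noise_sd:
            raise ContaminationError(
                f"corrected mass-{m} beam {out[m]:.3g} below -3 sigma")
        out[m] = max(out[m], 0.0)
    return out


def _forward(lam: float, alpha: float, beta: float,
             system: IsotopeSystem) -> np.ndarray:
    """Measured (50/52, 53/52, 54/52) for parameters (λ, α, β)."""
    out = np.empty(3)
    for k, i in enumerate((50, 53, 54)):
        p = system.mass_ratio(i)
        nat = system.reference_ratios[i] * p ** alpha
        mix = lam * system.spike_ratios[i] + (1.0 - lam) * nat
        out[k] = mix * p ** beta
    return out


def forward_model(lam: float, alpha: float, beta: float,
                  system: IsotopeSystem = DEFAULT_SYSTEM) -> dict[int, float]:
    """Public forward model: synthetic measured ratios to 52Cr."""
    r = _forward(lam, alpha, beta, system)
    return {50: r[0], 53: r[1], 54: r[2]}


def alpha_for_d53(d53: float, system: IsotopeSystem = DEFAULT_SYSTEM) -> float:
    """Exponential-law α equivalent to a given δ53Cr (‰)."""
    return math.log(1.0 + d53 / 1000.0) / math.log(system.mass_ratio(53))


def double_spike_invert(measured: dict[int, float],
                        system: IsotopeSystem = DEFAULT_SYSTEM,
                        tol: float = 1e-12, max_iter: int = 100,
                        x0: tuple[float, float, float] = (0.5, 0.0, 0.0),
                        ) -> InversionResult:
    """Solve (λ, α, β) from measured (50/52, 53/52, 54/52) ratios by
    Newton-Raphson with an analytic Jacobian.

    Raises on non-convergence or λ outside (0, 1).
    """
    y = np.array([measured[50], measured[53], measured[54]], dtype=float)
    if np.any(y <= 0):
        raise ValueError("measured ratios must be positive")
    x = np.array(x0, dtype=float)
    converged = False
    it = 0
    res_norm = math.inf
    for it in range(1, max_iter + 1):
        lam, alpha, beta = x
        f = np.empty(3)
        J = np.empty((3, 3))
        for k, i in enumerate((50, 53, 54)):
            p = system.mass_ratio(i)
            lnp = math.log(p)
            nat = system.reference_ratios[i] * p ** alpha
            mix = lam * system.spike_ratios[i] + (1.0 - lam) * nat
            pb = p ** beta
            f[k] = mix * pb - y[k]
            J[k, 0] = (system.spike_ratios[i] - nat) * pb
            J[k, 1] = (1.0 - lam) * nat * lnp * pb
            J[k, 2] = mix * pb * lnp
        res_norm = float(np.linalg.norm(f))
        if res_norm < tol:
            converged = True
            break
        x = x - np.linalg.solve(J, f)
    lam, alpha, beta = (float(v) for v in x)
    if not converged:
        raise RuntimeError(
            f"double-spike inversion did not converge ({it} iterations, "
            f"residual {res_norm:.3g})")
    if not 0.0 < lam < 1.0:
        raise RuntimeError(f"spike fraction lambda={lam:.3g} outside (0,1)")
    d53 = 1000.0 * (system.mass_ratio(53) ** alpha - 1.0)
    # spike share of total moles from its share of the 52Cr beam
    x52_s = system.spike_52_abundance()
    x52_n = system.reference_52_abundance()
    moles_ratio = (lam / x52_s) / (lam / x52_s + (1.0 - lam) / x52_n)
    return InversionResult(
        lambda_52=lam, alpha=alpha, beta=beta, d53cr=d53,
        lambda_molar=moles_ratio, converged=converged, iterations=it,
        residual_norm=res_norm)


def isotope_dilution_conc(spike_pmol: float, lambda_molar: float,
                          sample_mass_kg: float) -> float:
    """Sample [Cr] (nmol/kg) from the spike addition and the molar spike
    fraction: [Cr] = spike·(1−λ)/λ / mass."""
    if spike_pmol <= 0 or sample_mass_kg <= 0:
        raise ValueError("spike amount and sample mass must be positive")
    if not 0.0 < lambda_molar < 1.0:
        raise ValueError("lambda_molar must lie strictly inside (0, 1)")
    sample_pmol = spike_pmol * (1.0 - lambda_molar) / lambda_molar
    return sample_pmol / sample_mass_kg * 1e-3   # pmol/kg -> nmol/kg


@dataclass
class ReducedAnalysis:
    """Cycle-averaged products of one mass-spectrometer analysis."""

    d53cr: float
    d53cr_2sem: float
    lambda_52: float
    lambda_molar: float
    beta: float
    n_cycles: int
    conc_nmolkg: float | None = None


def reduce_analysis(cycles: dict[int, np.ndarray],
                    system: IsotopeSystem = DEFAULT_SYSTEM,
                    spike_pmol: float | None = None,
                    sample_mass_kg: float | None = None,
                    noise_sd: float = 0.0) -> ReducedAnalysis:
    """Reduce a block of beam cycles to δ53Cr (± 2 SEM) and, when the
    spike addition is known, [Cr] by isotope dilution.

    Each cycle is interference-corrected, converted to ratios to 52Cr
    and inverted independently; cycle statistics give the internal
    error. The concentration uses the mean molar spike fraction.
    """
    n = len(np.asarray(cycles[52]))
    d53s = np.empty(n)
    lams = np.empty(n)
    lams_mol = np.empty(n)
    betas = np.empty(n)
    for c in range(n):
        beams = {m: float(np.asarray(v)[c]) for m, v in cycles.items()}
        corr = interference_correct(beams, system, noise_sd=noise_sd)
        meas = {m: corr[m] / corr[52] for m in (50, 53, 54)}
        inv = double_spike_invert(meas, system)
        d53s[c], lams[c] = inv.d53cr, inv.lambda_52
        lams_mol[c], betas[c] = inv.lambda_molar, inv.beta
    two_sem = 2.0 * d53s.std(ddof=1) / math.sqrt(n) if n > 1 else math.nan
    conc = None
    if spike_pmol is not None and sample_mass_kg is not None:
        conc = isotope_dilution_conc(spike_pmol, float(lams_mol.mean()),
                                     sample_mass_kg)
    return ReducedAnalysis(
        d53cr=float(d53s.mean()), d53cr_2sem=float(two_sem),
        lambda_52=float(lams.mean()), lambda_molar=float(lams_mol.mean()),
        beta=float(betas.mean()), n_cycles=n, conc_nmolkg=conc)


def daily_normalize(sample_d53: float, standards: list[float] | np.ndarray,
                    ) -> tuple[float, float]:
    """Adjust a sample δ53Cr to the daily mean of bracketing double-spiked
    reference-material analyses; returns (adjusted δ, 2 SEM of the
    standard replicates)."""
    std = np.asarray(standards, dtype=float)
    if std.size < 2:
        raise ValueError("need at least 2 bracketing standards")
    two_sem = 2.0 * std.std(ddof=1) / math.sqrt(std.size)
    return sample_d53 - float(std.mean()), float(two_sem)
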