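"""Isotope mass balance and fractionation fitting.

Two complementary views of chromium isotope fractionation in the upper
ocean:

* **Cr(III) mass balance.** With a constant inert background pool
  C = [Cr(VI)+Cr(III)_NR] and a linear trend of total dissolved δ53Cr
  against [Cr(III)], the two-pool mass balance

      [Cr] = C + [Cr(III)]
      δ_total·[Cr] = δ_VI+NR·C + δ_III·[Cr(III)]

  identifies the intercept of the trend with δ_VI+NR (the [Cr(III)] → 0
  limit) and the isotopic offset of the Cr(III) pool being added or
  removed as Δ53Cr = slope × C, constant along the trend.

* **Rayleigh systematics.** Net removal of Cr at a constant enrichment
  factor ε produces δ53Cr linear in ln[Cr] with slope ε; the global
  open-ocean compilation follows a single such trend.

The headline fits are ordinary least squares ("simple linear fit"); an
errors-in-variables (York) fit is available when both axes carry known
measurement errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import DEFAULT_CONSTANTS


@dataclass
class FractionationFit:
    """Linear-fit products plus derived isotope-systematics quantities.

    ``slope``/``intercept`` describe δ53Cr against the chosen abscissa
    ([Cr(III)] in nmol/kg, or ln[Cr]); 95% CIs are half-widths from the
    Student t distribution with n−2 df. Derived fields are populated by
    :func:`mass_balance_delta_iii` (``delta_vi_nr``, ``delta_cap``) or
    :func:`fit_global_epsilon` (``epsilon``).
    """

    slope: float
    intercept: float
    ci95_slope: float
    ci95_intercept: float
    r2: float
    n: int
    method: str = "OLS"
    slope_se: float = math.nan
    intercept_se: float = math.nan
    delta_vi_nr: float | None = None
    delta_cap: float | None = None
    delta_cap_ci95: float | None = None
    epsilon: float | None = None
    epsilon_ci95: float | None = None


def fit_line(x, y, sy=None, sx=None, max_iter: int = 100,
             tol: float = 1e-12) -> FractionationFit:
    """Fit y = a + b·x.

    Default is unweighted ordinary least squares. When per-point 1σ on
    both axes are supplied (``sx`` and ``sy``), a York-type
    errors-in-variables fit is used instead. 95% confidence half-widths
    use t(n−2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points to fit a line")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    tcrit = stats.t.ppf(0.975, n - 2)

    if sx is not None and sy is not None:
        sx = np.asarray(sx, dtype=float)
        sy = np.asarray(sy, dtype=float)
        wx = 1.0 / sx**2
        wy = 1.0 / sy**2
        b = np.polyfit(x, y, 1)[0]
        for _ in range(max_iter):
            W = wx * wy / (wx + b * b * wy)
            xbar = np.sum(W * x) / np.sum(W)
            ybar = np.sum(W * y) / np.sum(W)
            U, V = x - xbar, y - ybar
            beta = W * (U / wy + b * V / wx)
            b_new = np.sum(W * beta * V) / np.sum(W * beta * U)
            if abs(b_new - b) < tol * max(abs(b), 1.0):
                b = b_new
                break
            b = b_new
        a = ybar - b * xbar
        xadj = xbar + np.sum(W * beta) / np.sum(W)  # adjusted points
        u = (xbar + beta) - xadj
        sb = math.sqrt(1.0 / np.sum(W * u * u))
        sa = math.sqrt(1.0 / np.sum(W) + xadj * xadj * sb * sb)
        method = "york"
    else:
        res = stats.linregress(x, y)
        a, b = res.intercept, res.slope
        sa, sb = res.intercept_stderr, res.stderr
        method = "OLS"
    yhat = a + b * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FractionationFit(
        slope=float(b), intercept=float(a), slope_se=float(sb),
        intercept_se=float(sa), ci95_slope=float(tcrit * sb),
        ci95_intercept=float(tcrit * sa), r2=min(max(r2, 0.0), 1.0),
        n=int(n), method=method)


def mass_balance_delta_iii(fit: FractionationFit,
                           cr6nr_const: float = DEFAULT_CONSTANTS.cr6nr_const,
                           ) -> FractionationFit:
    """Derive δ53Cr(VI+NR) and Δ53Cr from a δ53Cr-vs-[Cr(III)] fit.

    Under the two-pool mass balance with constant background C, the
    trend intercept is δ_VI+NR and Δ53Cr = slope × C (exact closed
    form: substituting δ_total = a + b·x gives
    δ_III = a + b·(C + x), so δ_III − δ_total = b·C for every x).
    The Δ CI scales the slope CI by C.
    """
    if cr6nr_const is None or not cr6nr_const > 0:
        raise ValueError("cr6nr_const must be a positive concentration")
    fit.delta_vi_nr = fit.intercept
    fit.delta_cap = fit.slope * cr6nr_const
    fit.delta_cap_ci95 = fit.ci95_slope * cr6nr_const
    return fit


def delta_iii_pointwise(d53_total: float, cr_total: float, cr3: float,
                        delta_vi_nr: float,
                        cr6nr: float | None = None) -> float:
    """Back-compute δ53Cr of the Cr(III) pool for one sample from the
    exact mass balance (no linearisation). ``cr6nr`` defaults to
    cr_total − cr3."""
    if cr3 <= 0:
        raise ValueError("cr3 must be positive to carry an isotope ratio")
    if cr6nr is None:
        cr6nr = cr_total - cr3
    return (d53_total * cr_total - delta_vi_nr * cr6nr) / cr3


def fit_global_epsilon(cr, d53, sy=None, cr_rel_err: float | None = None,
                       ) -> FractionationFit:
    """Fit δ53Cr against ln[Cr]; the slope is the isotope enrichment
    factor ε of net Cr addition/removal.

    Unweighted OLS by default. With per-point δ uncertainties (``sy``,
    1σ) and a relative concentration error (``cr_rel_err``, e.g. 0.01),
    an errors-in-variables fit propagates both (σ_ln[Cr] ≈ relative
    error).
    """
    cr = np.asarray(cr, dtype=float)
    if np.any(cr <= 0):
        raise ValueError("concentrations must be positive for ln[Cr]")
    x = np.log(cr)
    if sy is not None and cr_rel_err is not None:
        sx = np.full_like(x, cr_rel_err)
        fit = fit_line(x, np.asarray(d53, float), sy=sy, sx=sx)
    else:
        fit = fit_line(x, d53)
    fit.epsilon = fit.slope
    fit.epsilon_ci95 = fit.ci95_slope
    return fit


def rayleigh_predict(cr0: float, d0: float, epsilon: float,
                     f) -> tuple[np.ndarray, np.ndarray]:
    """Evolve a reservoir (cr0 nmol/kg, d0 ‰) under Rayleigh removal at
    enrichment factor ε to remaining fraction(s) f ∈ (0, 1]:
    cr = f·cr0, δ = d0 + ε·ln f."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0) or np.any(f > 1):
        raise ValueError("remaining fraction must lie in (0, 1]")
    return f * cr0, d0 + epsilon * np.log(f)


def mixing_delta_total(x, delta_vi: float, delta_cap: float,
                       cr6nr_const: float = DEFAULT_CONSTANTS.cr6nr_const,
                       reference: str = "total") -> np.ndarray:
    """Exact forward model of δ_total(x) under the two-pool mass balance
    δ_total·(C+x) = δ_VI·C + δ_III·x, used as an oracle for the
    linear-fit recovery of Δ53Cr over a restricted [Cr(III)] range.

    ``reference`` fixes what the Cr(III) offset Δ* is anchored to:

    * ``"total"`` — δ_III = δ_total(x) + Δ* (offset to the evolving
      dissolved pool, the convention of the Δ53Cr estimate itself).
      Solving the self-consistent balance gives the exactly linear
      δ_total = δ_VI + (Δ*/C)·x.
    * ``"background"`` — δ_III = δ_VI + Δ* (a fixed Cr(III)
      end-member), the genuinely hyperbolic curve
      δ_total = δ_VI + Δ*·x/(C + x); fitting a line to it quantifies
      the curvature bias of the quasi-linear approximation.
    """
    x = np.asarray(x, dtype=float)
    if reference == "total":
        return delta_vi + delta_cap * x / cr6nr_const
    if reference == "background":
        return delta_vi + delta_cap * x / (cr6nr_const + x)
    raise ValueError("reference must be 'total' or 'background'")
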