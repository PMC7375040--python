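"""Diel replicate QC: outlier rejection and aggregation.

Replicate Cr(III) samples collected every few hours over one or two diel
cycles are screened with a modified Thompson τ test (the occasional
anomalously high value is attributed to incompletely decanted seawater
supernatant during shipboard Mg(OH)2 coprecipitation), then averaged to a
station/depth mean with 1 SD. Non-replicated depths carry a conservative
10% relative uncertainty instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import DEFAULT_CONSTANTS, Constants
from .data_model import SeawaterSample

logger = logging.getLogger(__name__)


@dataclass
class DielGroup:
    """Replicate set at one station/depth with its robust summary."""

    station_id: str
    depth: float
    values: list[float]
    times: list[float | None] = field(default_factory=list)
    outlier_mask: list[bool] = field(default_factory=list)
    mean: float = math.nan
    sd: float = math.nan

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def n_kept(self) -> int:
        return int(np.sum(~np.asarray(self.outlier_mask)))


def thompson_tau_critical(n: int, alpha: float = 0.05,
                          bonferroni: bool = True) -> float:
    """Critical τ for the modified Thompson test at sample size ``n``:
    τ = t·(n−1) / (√n · √(n−2+t²)) with t the two-sided Student critical
    value and n−2 degrees of freedom.

    Because the test screens the *largest* of n deviations, the critical
    value is taken at the Bonferroni-adjusted level alpha/n by default,
    which keeps the clean-data rejection rate per group near ``alpha``;
    ``bonferroni=False`` gives the textbook per-observation level, which
    over-flags noticeably for n ≳ 5.
    """
    level = alpha / n if bonferroni else alpha
    t = stats.t.ppf(1.0 - level / 2.0, n - 2)
    return t * (n - 1) / (math.sqrt(n) * math.sqrt(n - 2 + t * t))


def modified_thompson_tau(values, alpha: float = 0.05) -> np.ndarray:
    """Iterative modified Thompson τ outlier mask.

    At each step the single point with the largest absolute deviation
    from the current mean is flagged if that deviation exceeds τ·SD of
    the remaining points; the statistic is then recomputed without it.
    Symmetric: low outliers are eligible too. With fewer than 3 points
    the test is not applicable and nothing is rejected. At most half of
    the points (rounded up) may be rejected.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    mask = np.zeros(n, dtype=bool)
    if n < 3:
        return mask
    max_reject = math.ceil(n / 2)

    # Robust initialisation: provisionally set aside points far from the
    # median (5 normalised MADs). Without this, two or more coincident
    # contaminated values inflate the naive SD enough to mask each other
    # (the well-known masking weakness of one-at-a-time rejection); every
    # provisional call is then confirmed or reversed by the tau criterion
    # itself below.
    med = float(np.median(x))
    mad = 1.4826 * float(np.median(np.abs(x - med)))
    if mad > 0:
        robust_dev = np.abs(x - med)
        candidates = np.argsort(robust_dev)[::-1]
        for i in candidates[:max_reject]:
            if robust_dev[i] > 5.0 * mad:
                mask[i] = True

    for _ in range(2 * n + 2):
        keep = ~mask
        m = int(keep.sum())
        if m < 3:
            break
        mu = x[keep].mean()
        sd = x[keep].std(ddof=1)
        if sd == 0:
            break
        tau_sd = thompson_tau_critical(m, alpha) * sd
        dev = np.abs(x - mu)
        # re-admit the provisionally flagged point closest to the mean
        if mask.any():
            dev_in = np.where(mask, dev, np.inf)
            i = int(np.argmin(dev_in))
            if dev_in[i] <= tau_sd:
                mask[i] = False
                continue
        # flag the worst kept point
        if mask.sum() < max_reject:
            dev_out = np.where(keep, dev, -np.inf)
            j = int(np.argmax(dev_out))
            if dev_out[j] > tau_sd:
                mask[j] = True
                continue
        break
    return mask


def aggregate_diel(samples: list[SeawaterSample], alpha: float = 0.05,
                   by_day: bool = False,
                   constants: Constants = DEFAULT_CONSTANTS,
                   value: str = "cr3") -> list[DielGroup]:
    """Group samples by station × depth (× day if ``by_day``), reject
    outliers, and summarise.

    Means and 1 SD are computed over survivors; single-value groups get
    the conservative default relative uncertainty. Samples in groups of
    n ≥ 2 are flagged ``diel_replicated``; rejected samples are flagged
    ``outlier``.
    """
    keyed: dict[tuple, list[SeawaterSample]] = {}
    for s in samples:
        v = getattr(s, value)
        if v is None:
            continue
        key = (s.station_id, s.depth) + ((s.day,) if by_day else ())
        keyed.setdefault(key, []).append(s)

    groups = []
    for key, members in keyed.items():
        vals = [getattr(s, value) for s in members]
        if not vals:
            raise ValueError(f"empty replicate group {key}")
        mask = modified_thompson_tau(vals, alpha)
        kept = np.asarray(vals)[~mask]
        g = DielGroup(
            station_id=key[0], depth=key[1], values=list(vals),
            times=[s.time_local for s in members],
            outlier_mask=list(mask),
        )
        g.mean = float(kept.mean())
        if kept.size >= 2:
            g.sd = float(kept.std(ddof=1))
        else:
            g.sd = constants.cr3_default_unc * g.mean
        for s, flagged in zip(members, mask):
            if flagged:
                s.flags.add("outlier")
            if len(members) >= 2:
                s.flags.add("diel_replicated")
        groups.append(g)
    return groups


@dataclass
class DielCycleFit:
    """Fixed-period sinusoid fit to a replicate time series.

    ``significant`` applies the simple 2×SE amplitude screen;
    ``p_value`` is the F-test of the sine/cosine pair against the flat
    model (the calibrated criterion).
    """

    amplitude: float
    amplitude_se: float
    phase_hours: float
    mean_level: float
    significant: bool
    p_value: float = math.nan


def detect_diel_cycle(group: DielGroup, period_hours: float = 24.0,
                      exclude_outliers: bool = True) -> DielCycleFit:
    """Least-squares fit of a fixed-period (default 24 h) sinusoid.

    Fits mean + a·cos(ωt) + b·sin(ωt); the amplitude √(a²+b²) is deemed
    significant when it exceeds twice its standard error (delta-method).
    Requires at least 4 timestamped points spanning one full period.
    """
    t = np.asarray([ti for ti in group.times if ti is not None], dtype=float)
    x = np.asarray([v for v, ti in zip(group.values, group.times)
                    if ti is not None], dtype=float)
    if exclude_outliers and group.outlier_mask:
        keep = ~np.asarray([m for m, ti in zip(group.outlier_mask, group.times)
                            if ti is not None])
        t, x = t[keep], x[keep]
    if t.size < 4 or (t.max() - t.min()) < period_hours:
        raise ValueError(
            "diel fit needs >= 4 timed points spanning a full period")
    w = 2 * math.pi / period_hours
    A = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    coef, res, rank, _ = np.linalg.lstsq(A, x, rcond=None)
    dof = t.size - 3
    if dof > 0 and res.size:
        s2 = float(res[0]) / dof
    else:
        r = x - A @ coef
        s2 = float(r @ r) / max(dof, 1)
    cov = s2 * np.linalg.inv(A.T @ A)
    a, b = coef[1], coef[2]
    amp = math.hypot(a, b)
    if amp > 0:
        grad = np.array([a / amp, b / amp])
        amp_se = math.sqrt(grad @ cov[1:, 1:] @ grad)
    else:
        amp_se = math.sqrt(max(cov[1, 1], cov[2, 2]))
    phase = math.atan2(-b, a) / w % period_hours
    # F-test of the harmonic pair vs the flat model
    ss_res = float(np.sum((x - A @ coef) ** 2))
    ss_null = float(np.sum((x - x.mean()) ** 2))
    if dof > 0 and ss_res > 0:
        fstat = ((ss_null - ss_res) / 2.0) / (ss_res / dof)
        p = float(stats.f.sf(fstat, 2, dof))
    else:
        p = math.nan
    return DielCycleFit(amplitude=amp, amplitude_se=amp_se,
                        phase_hours=phase, mean_level=float(coef[0]),
                        significant=bool(amp > 2 * amp_se), p_value=p)
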