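"""End-to-end analysis pipeline.

Runs diel QC -> speciation -> isotope fits -> mixed-layer budgets
(-> NCP when forcing is supplied) on a station table, producing a
machine-readable report. All stage outputs are pure functions of their
inputs; re-running with the same inputs reproduces the report
byte-for-byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constants import DEFAULT_CONSTANTS, Constants
from .budgets import BudgetResult, station_budget
from .data_model import SeawaterSample, StationContext
from .isotopes import (FractionationFit, fit_global_epsilon, fit_line,
                       mass_balance_delta_iii)
from .qc import DielGroup, aggregate_diel
from .speciation import speciate


@dataclass
class RunReport:
    """Everything one pipeline run computed, with its audit trail."""

    version: str
    constants: dict
    qc_alpha: float
    diel_groups: list[DielGroup]
    speciation_table: pd.DataFrame
    delta_fit: FractionationFit | None
    epsilon_fit: FractionationFit | None
    budgets: list[BudgetResult]
    selection_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def fit_d(f):
            return None if f is None else asdict(f)
        return {
            "version": self.version,
            "constants": self.constants,
            "qc_alpha": self.qc_alpha,
            "diel_groups": [
                {"station": g.station_id, "depth": g.depth, "n": g.n,
                 "n_kept": g.n_kept, "mean": g.mean, "sd": g.sd,
                 "n_outliers": int(sum(g.outlier_mask))}
                for g in self.diel_groups],
            "delta_fit": fit_d(self.delta_fit),
            "epsilon_fit": fit_d(self.epsilon_fit),
            "budgets": [asdict(b) for b in self.budgets],
            "selection_ids": self.selection_ids,
        }

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True,
                          allow_nan=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _weighted_mean_2sem(values, two_ses):
    """Inverse-variance weighted mean of replicate δ analyses with 2 SEM."""
    v = np.asarray(values, dtype=float)
    w = 1.0 / np.maximum(np.asarray(two_ses, dtype=float), 1e-9) ** 2
    mean = float(np.sum(w * v) / np.sum(w))
    if v.size > 1:
        sem2 = 2.0 * float(v.std(ddof=1)) / math.sqrt(v.size)
    else:
        sem2 = float(two_ses[0])
    return mean, sem2


def select_fit_samples(samples: list[SeawaterSample],
                       contexts: dict[str, StationContext],
                       groups: list[DielGroup],
                       restrict_station_day: dict[str, int] | None = None,
                       ) -> pd.DataFrame:
    """Declarative selection for the δ53Cr-vs-[Cr(III)] fit: diel-replicated
    station/depths above the winter mixed layer, outliers removed, with
    δ as the weighted mean across repeats (2 SEM) and Cr(III) as the
    robust group mean.

    ``restrict_station_day`` maps station -> the single sampling day to
    keep there (used where the replicate sets differ between days).
    """
    restrict_station_day = restrict_station_day or {}
    bygroup = {(g.station_id, g.depth): g for g in groups}
    rows = []
    for (sid, depth), g in bygroup.items():
        ctx = contexts.get(sid)
        winter_ml = ctx.winter_ml_depth if ctx else 100.0
        if depth >= winter_ml or g.n < 2:
            continue
        members = [s for s in samples
                   if s.station_id == sid and s.depth == depth
                   and "outlier" not in s.flags]
        day = restrict_station_day.get(sid)
        if day is not None:
            members = [s for s in members if s.day == day]
            vals = [s.cr3 for s in members if s.cr3 is not None]
            cr3_mean = float(np.mean(vals)) if vals else g.mean
        else:
            cr3_mean = g.mean
        d_vals = [(s.d53cr, s.d53cr_2se or 0.033) for s in members
                  if s.d53cr is not None]
        if not d_vals or not members:
            continue
        d53, d53_2sem = _weighted_mean_2sem([d for d, _ in d_vals],
                                            [e for _, e in d_vals])
        rows.append({"station": sid, "depth": depth, "cr3": cr3_mean,
                     "cr3_sd": g.sd, "d53": d53, "d53_2sem": d53_2sem,
                     "n_rep": len(members)})
    return pd.DataFrame(rows)


def run_all(samples: list[SeawaterSample],
            contexts: list[StationContext],
            constants: Constants = DEFAULT_CONSTANTS,
            qc_alpha: float = 0.05,
            restrict_station_day: dict[str, int] | None = None,
            deficit_rule: str = "combined") -> RunReport:
    """Execute the full chain and assemble a :class:`RunReport`."""
    ctx_map = {c.station_id: c for c in contexts}

    groups = aggregate_diel(samples, alpha=qc_alpha, constants=constants)

    spec_rows = []
    for s in samples:
        if s.cr3 is None or "outlier" in s.flags:
            continue
        rec = speciate(s.cr_total, s.cr_total_sd or constants.rsd_cr * s.cr_total,
                       s.cr3, s.cr3_sd or constants.cr3_default_unc * s.cr3)
        spec_rows.append({"station": s.station_id, "depth": s.depth,
                          "cr_total": rec.cr_total, "cr3": rec.cr3,
                          "cr6nr_nmolkg": rec.cr6_nr,
                          "cr6nr_sd": rec.cr6_nr_sd,
                          "pct_cr3": rec.pct_cr3})
    spec_table = pd.DataFrame(spec_rows)

    fit_df = select_fit_samples(samples, ctx_map, groups,
                                restrict_station_day)
    delta_fit = None
    if len(fit_df) >= 3 and fit_df["cr3"].nunique() >= 3:
        delta_fit = fit_line(fit_df["cr3"], fit_df["d53"])
        delta_fit = mass_balance_delta_iii(delta_fit, constants.cr6nr_const)

    eps_fit = None
    ok = [(s.cr_total, s.d53cr) for s in samples
          if s.d53cr is not None and s.cr_total > 0]
    if len(ok) >= 3:
        cr, d53 = zip(*ok)
        if len(set(cr)) >= 3:
            eps_fit = fit_global_epsilon(cr, d53)

    budgets = []
    for sid, ctx in ctx_map.items():
        prof = {}
        for s in samples:
            if s.station_id == sid:
                prof.setdefault(s.depth, []).append(s.cr_total)
        depths = sorted(prof)
        concs = [float(np.mean(prof[d])) for d in depths]
        if len(depths) < 4 or max(depths) < 150.0:
            continue
        budgets.append(station_budget(
            sid, depths, concs, ctx.obs_ml_depth, ctx.ancp,
            constants=constants, rule=deficit_rule))

    return RunReport(
        version=__version__, constants=asdict(constants), qc_alpha=qc_alpha,
        diel_groups=groups, speciation_table=spec_table,
        delta_fit=delta_fit, epsilon_fit=eps_fit, budgets=budgets,
        selection_ids=[f"{r.station}:{r.depth:g}"
                       for r in fit_df.itertuples()])
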