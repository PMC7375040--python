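# crseawater

Tools for the marine chromium cycle: redox speciation, stable-isotope
mass balance, and productivity-linked export budgets for upper-ocean
seawater surveys.

Dissolved chromium exists in seawater as largely inert Cr(VI) and
particle-reactive Cr(III). Biological activity reduces Cr to Cr(III) in
productive surface waters; that Cr(III) adsorbs to sinking particles and
is exported, preferentially removing light isotopes and leaving surface
waters depleted in Cr and enriched in heavy δ53Cr (the permil deviation
of 53Cr/52Cr from NIST SRM 979). `crseawater` implements the full chain
a survey of this system needs:

* **diel QC** — replicate aggregation with masking-resistant modified
  Thompson τ outlier rejection and a fixed-period diel screen;
* **speciation** — [Cr(VI)+Cr(III)_NR] = [Cr] − [Cr(III)] with
  quadrature error propagation and blank correction;
* **isotope systematics** — the two-pool mass balance
  δ·[Cr] = δ_VI+NR·C + δ_III·[Cr(III)] giving δ_VI+NR (trend intercept)
  and the removal offset **Δ53Cr = slope × C**; and the Rayleigh fit of
  δ53Cr on ln[Cr] giving the enrichment factor **ε**;
* **double-spike reduction** — 50Cr–54Cr inversion (exponential law,
  Newton–Raphson), isobar stripping, isotope dilution, daily
  standard normalisation;
* **budgets** — trapezoidal mixed-layer Cr deficits, significance
  against the 0.82% analytical RSD, Cr:C-scaled export comparison and
  global extrapolation;
* **NCP** — net community production from O2/Ar supersaturation with
  60-day ventilation-weighted gas exchange and O2:C = 1.4;
* **synthetic ocean** — a seeded generator of station tables, diel
  replicate sets, mass-spectrometer beams and wind forcing with the
  survey's statistical structure, so every stage is testable offline.

## Worked example

```python
from crseawater import GeneratorConfig, generate_survey, run_all

samples, contexts, truth = generate_survey(GeneratorConfig(seed=1))
report = run_all(samples, contexts)

f = report.delta_fit
print(f"delta53Cr(VI+NR) = {f.delta_vi_nr:.3f} +/- {f.ci95_intercept:.3f} permil")
print(f"Delta53Cr        = {f.delta_cap:.2f} +/- {f.delta_cap_ci95:.2f} permil")
print(f"r2 = {f.r2:.2f}, n = {f.n}")
for b in report.budgets[:2]:
    print(b.station_id, f"deficit {b.deficit_conc:.2f} nmol/kg",
          f"significant={b.significant}",
          f"export {b.inferred_export_low:.1f}-{b.inferred_export_high:.1f} umol/m2/yr")
```

prints

```
delta53Cr(VI+NR) = 1.163 +/- 0.015 permil
Delta53Cr        = -0.92 +/- 0.20 permil
r2 = 0.91, n = 12
S1 deficit 0.06 nmol/kg significant=True export 1.7-8.2 umol/m2/yr
S2 deficit 0.04 nmol/kg significant=True export 1.2-6.0 umol/m2/yr
```

The fit uses the twelve diel-replicated station/depths above the winter
mixed layer. The intercept estimates the δ53Cr of the inert background
pool; Δ53Cr is the isotopic offset of the Cr(III) being removed relative
to the total dissolved pool, obtained by scaling the trend slope by the
2.9 nmol/kg background concentration — here recovering the generator's
configured 1.178‰ and −1.08‰ within the fit CIs. Station deficits are
the 150–200 m reference mean minus the 0–100 m mean; the export range
multiplies each station's annual NCP by the bracketing particulate
Cr:C ratios (0.555–2.7 µmol Cr per mol C).

The same stages are scriptable from a shell:

```sh
crseawater simulate --seed 42 --out sim/
crseawater qc sim/stations.csv qc.csv
crseawater run-all sim/stations.csv sim/contexts.csv --out report.json
```

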