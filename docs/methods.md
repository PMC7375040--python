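# Methods

`crseawater` implements the inference chain that links dissolved chromium
concentration, its redox speciation, its stable-isotope composition
(δ53Cr, the permil deviation of 53Cr/52Cr from NIST SRM 979), and
upper-ocean biological productivity. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
tests do and do not demonstrate.

## Two-pool isotope mass balance

Total dissolved Cr is treated as two pools: the particle-reactive,
biologically cycled Cr(III), and an operationally inert background of
Cr(VI) plus any non-reactive Cr(III) that Mg(OH)2 coprecipitation does
not recover ("Cr(VI)+Cr(III)_NR" — the compound name deliberately leaves
open whether a non-reactive fraction exists). With a constant background
pool C (default 2.9 nmol/kg) the balance reads

    [Cr]          = C + [Cr(III)]
    δ_total·[Cr]  = δ_VI+NR·C + δ_III·[Cr(III)]

If total δ53Cr is linear in [Cr(III)] — a good approximation over a
restricted [Cr(III)] range near zero with C roughly constant — then the
intercept of that trend is δ_VI+NR (the [Cr(III)] → 0 limit) and the
isotopic offset of the Cr(III) pool being added or removed is

    Δ53Cr = δ_III − δ_total = slope × C,

a closed-form identity that holds at every point on the line (substitute
δ_total = a + b·x into the balance). The 95% CI on Δ is the slope CI
scaled by C; a Monte-Carlo alternative over both fit parameters exists
but the slope-CI scaling is the default, since the intercept enters Δ
only through the linearisation. Note Δ measures the net effect of
Cr(III) production, complexation and removal together; it is not the
offset between redox-specific pools.

The forward oracle `mixing_delta_total` quantifies the linearisation
two ways. Anchoring the Cr(III) offset to the evolving total pool
(`reference="total"`, the same convention as the estimate) the balance
solves to an exactly linear δ_total(x), so the fit recovers Δ with zero
bias. Anchoring it to a fixed Cr(III) end-member
(`reference="background"`) gives a genuine hyperbola,
δ_total = δ_VI + Δ·x/(C+x), and the linear fit then under-reports the
offset by ≈ 0.12‰ over x ∈ [0.05, 0.35] nmol/kg — the honest size of
the approximation error if the end-member, not the offset, is constant.

## Rayleigh systematics

Net removal of Cr at a constant enrichment factor ε leaves the residual
pool on δ = δ0 + ε·ln([Cr]/[Cr]0). `fit_global_epsilon` estimates ε as
the OLS slope of δ53Cr on ln[Cr] (errors-in-variables optional, see
below); `rayleigh_predict` is its exact inverse on noise-free data and
satisfies the semigroup property f1·f2 ≡ two successive removals. The
global open-ocean compilation this emulates spans a much wider [Cr]
range than any single station; the generator therefore provides a
separate compilation-style dataset for ε work, distinct from the
station profiles used for Δ.

## Regression machinery

The headline fits are deliberately plain OLS ("simple linear fit"), so
r² is comparable with the study-scale statistic; 95% CIs use Student t
with n−2 df. When both axes carry known measurement error a York-type
errors-in-variables fit is available (`fit_line(x, y, sy=..., sx=...)`,
iterated to |Δb| < 1e−12, CIs from the standard York variance
formulae). Samples entering the Δ fit are selected declaratively:
diel-replicated station/depths above the winter mixed layer, outliers
removed, δ as the inverse-variance weighted mean across repeats with
2 SEM, Cr(III) as the robust replicate mean; the report records the
exact station:depth list used.

## Diel QC: modified Thompson τ with robust initialisation

Replicate Cr(III) sets (5–21 members per chosen depth) are screened
with the modified Thompson τ criterion: a point is an outlier when its
absolute deviation from the group mean exceeds τ·SD, with
τ = t·(n−1)/(√n·√(n−2+t²)). Two numerical choices matter:

* **Calibration.** Because the criterion is applied to the *largest* of
  n deviations, t is taken at the Bonferroni-adjusted two-sided level
  α/n (α = 0.05 default). The textbook per-observation level flags
  something in roughly half of clean n = 10 groups; the adjusted level
  keeps the clean-data rejection rate per group near α (measured ≈ 0.07
  per group, ≈ 0.01 per point).
* **Masking resistance.** One-at-a-time rejection cannot start when two
  or more contaminated values jointly inflate the SD (they shield each
  other). The iteration is therefore initialised from a median ± 5
  normalised-MAD provisional screen; every provisional exclusion is
  then confirmed or re-admitted by the τ criterion on the kept subset,
  so the final mask is still τ-defined. On the generator's default 10%
  one-sided contamination this raises detection from ≈ 54% to ≈ 86%.

The test is symmetric (low outliers are eligible) even though the
physical artifact — retained seawater supernatant in the Mg(OH)2 pellet,
which roughly doubles an affected value — is one-sided high. At most
⌈n/2⌉ points can be rejected. Groups of one get a conservative 10%
relative uncertainty; groups of n ≥ 2 get mean ± 1 SD over survivors.
A fixed-24-h sinusoid fit (`detect_diel_cycle`) screens for diel
periodicity; its calibrated criterion is the F-test of the harmonic
pair against a flat model (the simple amplitude > 2·SE screen has an
inherent ≈ 13% null rate and is reported alongside).

## Budgets

Layer means are trapezoidal integrals divided by layer thickness, with
the shallowest bottle extended uniformly to the surface and linear
interpolation elsewhere (exact for piecewise-linear profiles between
bottles). The deficit is the 150–200 m reference mean minus the
0–100 m (winter mixed layer) mean; it is significant when it exceeds
√2 × 0.82% × reference mean — both layer means carry the analytical
RSD, combined in quadrature (a single-RSD rule is available). Areal
deficits inside the thinner on-station mixed layer are reported two
ways — concentration deficit × ML × ρ, and the trapezoid of
(reference − c(z)) over the ML — because the two differ whenever the
depletion is surface-concentrated, and published tabulations are
consistent with the profile-weighted form at some stations. Export
comparisons multiply annual NCP by the bracketing particulate Cr:C
ratios 0.555 and 2.7 µmol/mol (the latter from 3.9 µg Cr/g dry weight
at 33 wt% C); presentation rounds to 1 significant figure only at
render time. Global extrapolation scales carbon-export estimates
(5–8 Gt C/yr surface, 0.43 Gt C/yr at 2,000 m) through the same Cr:C
bounds and compares with the riverine source flux (0.5–5.6 × 10⁸
mol/yr). Seawater mass↔volume conversions use a fixed ρ = 1025 kg/m³
(configurable); C = 12.011 g/mol.

## Net community production from O2/Ar

Argon shares oxygen's solubility physics but has no biology, so
Δ(O2/Ar) = (O2/Ar)_meas/(O2/Ar)_eq − 1 isolates biologically produced
oxygen. At steady state with negligible vertical mixing,

    NCP = k · [O2]_sat · Δ(O2/Ar) / 1.4      (carbon units)

with the photosynthetic quotient 1.4 mol O2 per mol C dividing the
oxygen flux. Equilibrium concentrations use the Garcia & Gordon (1992)
combined fit for O2 and Hamme & Emerson (2004) for Ar; the gas transfer
velocity uses the quadratic wind-speed relation k660 = 0.251·u10²
(cm/hr) scaled by (Sc/660)^−1/2 with the Wanninkhof (2014) Schmidt
polynomial. Because surface oxygen integrates over its mixed-layer
residence time, k is weighted over a 60-day wind history: interval i
ventilates the fraction f_i = k_i·Δt_i/mld (capped at 1) of the mixed
layer and receives weight f_i·∏_{later j}(1−f_j), normalised — the
share of today's mixed layer it last equilibrated. Weights are
non-negative and sum to one; constant wind reduces exactly to the
instantaneous k. Negative Δ yields negative NCP (net heterotrophy),
flagged but not suppressed. Volumetric NCP divides by the mixed-layer
depth; annual NCP scales by 365.25/1000.

## Double-spike reduction

A 50Cr–54Cr double spike lets the natural fractionation α, instrumental
mass bias β and spike fraction λ be solved simultaneously from the
three measured ratios (50/52, 53/52, 54/52). Both fractionations follow
the exponential law r = R·(m_i/m_j)^φ. With ratios to 52Cr and λ the
spike's share of the 52Cr beam, mixing is exactly linear:

    measured_i = (λ·S_i + (1−λ)·R_i·(m_i/m_52)^α) · (m_i/m_52)^β

solved by Newton–Raphson with an analytic Jacobian (tolerance 1e−12 on
the residual norm, max 100 iterations, start (0.5, 0, 0)). δ53Cr
follows from α; the molar spike fraction for isotope dilution
([Cr] = spike·(1−λ_molar)/λ_molar / mass) converts from λ via the 52Cr
abundances of spike and sample (the sample's taken as the reference
abundance — the α-dependence of that abundance is a < 1e−5 relative
effect at permil-level α). SRM 979 certificate ratios and a plausible
spike composition (~48% 50Cr, ~48% 54Cr) are external config constants;
the study's actual spike stoichiometry is unpublished, so correctness
is established by forward/inverse round trip (1e−6‰ over 1,000 random
draws) and Jacobian-vs-finite-difference checks, not by reproducing
instrumental values. Ti, V and Fe isobars are stripped at masses 50 and
54 using the 49/51/56 monitors and natural abundance ratios before
inversion; per-cycle inversion of a block yields the internal 2 SEM,
and bracketing-standard daily normalisation subtracts the session mean.

## The synthetic ocean

The generator emulates the statistical structure the analysis assumes —
it is the package's test bed, not a circulation model. Six stations
span the observed productivity range (ANCP 0.29–3.79 mol C m⁻² yr⁻¹,
with the study's on-station mixed-layer and euphotic depths) on the
bottle grid {10, 25, 50, 75, 100, 150, 200} m. Defaults, chosen once to
match the conditions the analysis reports:

| parameter | default | meaning |
|---|---|---|
| `cr6nr_const` | 2.9 nmol/kg | inert background pool |
| `delta_vi_nr` | 1.178 ‰ | background δ53Cr |
| `delta_cap` | −1.08 ‰ | Cr(III) offset vs total |
| `epsilon_true` | −0.82 ‰ | global ln[Cr] slope |
| `cr3_base`, `cr3_ncp_slope` | 0.16, 0.5 | Cr(III) = base + slope·NCP_vol·e^(−z/60 m) |
| `export_crc`, `export_years` | 2 µmol/mol, 1 yr | total-Cr surface deficit = ANCP·Cr:C·yr, e-folding 30 m |
| `contamination_rate` | 0.10 | one-sided high diel artifacts, roughly doubling |
| noise | 0.82% [Cr], 0.033‰ 2SD δ, 10% Cr(III) | stated analytical levels |

δ53Cr_total is generated from the exact mass balance at the nominal
constant background C (so the configured δ_VI+NR and Δ are recoverable
and the balance holds identically pre-noise), while measured total Cr
carries the NCP-scaled export deficit. The ≈ 0.2 nmol/kg bookkeeping
difference between C + Cr(III) and the deficit-bearing total mirrors
the constant-background approximation the analysis itself makes. Beam
noise is Gaussian per cycle with shot-noise-like intensity scaling; its
single scale constant is set so the reduced internal error falls in the
stated 0.02–0.03‰ window, which also reproduces the ≈ 0.021‰ external
2 SD across analyses. Wind forcing inverts the steady-state flux
balance so an imposed ANCP round-trips exactly through the NCP stage.

What the generator does *not* emulate: lateral advection and
entrainment, seasonality beyond a single snapshot, depth-varying
hydrography (T/S), correlated errors between [Cr] and [Cr(III)]
measured on shared aliquots, and any genuine diel periodicity. Passing
recovery tests therefore show the estimators are consistent and
correctly calibrated under the stated error model — not that the
physical assumptions (steady state, constant background pool) hold in
the real ocean.

## Problem sizes and determinism

Distributional checks use 25–100 seeded replicate surveys (a full
survey is ~190 bottle records; the whole chain runs in ~10 ms), 100
Rayleigh datasets of n = 100, 1,000 spike round-trip draws, and 77
simulated standard analyses — sizes at which the sampling error of each
check is several times smaller than its tolerance. One seeded generator
stream per run makes every output reproducible; property tests are
derandomised. Single-survey caveat: with twelve replicate groups per
survey, an individual seed occasionally concentrates > 30% contamination
in one high-leverage group, which any τ-type screen can mask — recovery
statements are therefore made on medians and CI-coverage rates over
seeds, not on a single draw.

## Known limitations

* The Δ53Cr estimate inherits the constant-background linearisation;
  with a genuinely fixed Cr(III) end-member it would be biased by
  ≈ 0.1‰ (quantified by the mixing oracle).
* The deficit significance rule treats the two layer means as
  independent with equal relative error; bottle-to-bottle correlation
  within a cast is ignored.
* The NCP budget omits entrainment, vertical mixing and bubble
  injection; ε and Δ are compared only in magnitude, as the two
  estimators act on different spatial scales.
* Published areal-deficit tabulations cannot be reproduced exactly
  without the underlying bottle data; both candidate areal definitions
  are reported instead.
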