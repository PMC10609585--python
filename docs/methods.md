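# Methods

This note documents the models implemented in `prokrates`, the defaults and
why they were chosen, what the synthetic-experiment generator does and does
not emulate, and the numerical choices that matter.

## Populations and rate definitions

The heterotrophic prokaryote (HProk) assemblage in a closed incubation is
modelled as a single exponentially growing and dying population,

    N(t) = N0 · exp((SGR − MR) · t),

with three per-day rates:

* **SGR** (specific instantaneous growth rate): estimated from biomass B
  (µgC L⁻¹) and daily carbon production P (µgC L⁻¹ d⁻¹) as
  `SGR = ln(1 + P/B)`.  This is the gross per-capita growth rate under the
  exponential assumption — production adds P to a standing stock B over one
  day, so the stock multiplies by (1 + P/B).
* **NGR** (net growth rate): `(ln N_t − ln N0)/t`, the realised change in
  abundance over the incubation of length t (default 2 days).
* **MR** (mortality rate): `SGR − NGR`, the lumped loss rate.  Grazing and
  viral lysis are not separated; MR is an indirect estimate and inherits the
  biases of both inputs.  The MR:SGR ratio is reported as an index of
  top-down control (1 = losses exactly balance gross growth).

Rates are computed **per replicate**, and treatment summaries are means of
per-replicate rates with standard errors `sd/√n`.  This order of operations
keeps the identity `MR = SGR − NGR` exact for summaries too, which the test
suite asserts at 1e−12.  SGR pairs end-of-incubation production with
end-of-incubation biomass (production is only assayed at the end of these
experiments); pairing against start biomass is a config choice away but not
the default.

## Observation models

**Microscopy.** Abundance = mean cells per visual field × (filtration area /
field area) / volume filtered.  The counting protocol targets ≥ 50 fields
and ≥ 400 cells per slide; sparser slides produce a `LowCountWarning` rather
than an error, because protocol targets are not data-validity rules.

**Cell carbon.** The allometric conversion is CC = a·CV^0.72 with CV in µm³.
`CellCarbonModel()` carries the conventional picogram-units coefficient
a = 0.12; the package's working default for biomass bookkeeping is the same
allometry in femtograms, `FG_CELL_CARBON` (a = 120), which gives ~23 fgC for
a typical 0.1 µm³ coastal bacterioplankton cell and keeps abundance
(cells L⁻¹) × cell carbon (fgC) × 10⁻⁹ = biomass (µgC L⁻¹) on the scale
coastal studies report (tens of µgC L⁻¹ at ~10⁹ cells L⁻¹).  Mean cell
carbon is computed by converting the mean biovolume (mean-then-convert);
converting each cell and averaging is available via
`volume_averaging: convert-then-mean` and yields smaller values on skewed
volume distributions (the power law is concave) — the choice is documented
because field practice is ambiguous.

**Leucine assay.** Net DPM = mean(live aliquots) − mean(killed blanks),
floored at zero with a warning (blanks can exceed samples by counting
noise).  Rate conversion: net DPM / 2.22×10⁶ DPM µCi⁻¹ / specific activity
(304 µCi µmol⁻¹ for the stock modelled here) / incubation (2 h) / aliquot
volume, reported as nmol Leu L⁻¹ h⁻¹.  Daily carbon production extrapolates
the 2-h rate linearly (×24) and applies the theoretical 1.5 kgC mol⁻¹
leucine-to-carbon factor (1 nmol ≡ 1.5 µgC); isotope dilution is ignored
(the 60 nM addition is treated as saturating).  Cell-specific activity is
the daily leucine rate divided by abundance, reported ×10⁹ to match the
conventional 10⁻⁹ nmol cell⁻¹ d⁻¹ table units.

## Carbonate system

`speciate_from_ta_ph` solves the total-scale alkalinity balance

    TA = [HCO3⁻] + 2[CO3²⁻] + [B(OH)4⁻] + [OH⁻] − [H⁺]

by subtracting the borate/water terms from TA at the given [H⁺] to get
carbonate alkalinity, then splitting it with K1/K2 and converting CO2* to
pCO₂ with K0.  Constants: K1/K2 from Lueker et al. (2000, total scale),
K0 from Weiss (1974), K_B from Dickson (1990), K_W from the DOE handbook,
total boron proportional to salinity (Uppström).  Nutrient alkalinity terms
are omitted (< 1 µmol kg⁻¹ at coastal phosphate/silicate levels) and pCO₂
is reported without a fugacity correction (~0.4% at these temperatures).
`solve_ph_from_ta_pco2` inverts the balance by bracketed root-finding
(Brent, pH ∈ [6, 9], xtol 1e−12).  Inputs are validated against named
bounds (S ∈ (0, 45], T ∈ [−2, 40] °C, pH ∈ [6, 9]).

The implementation is cross-checked in the tests against
`tests/data/carbonate_reference.csv`, a frozen grid (TA 2000–2500, pH
7.7–8.3, T 8–20 °C, S 30–38) produced by `scripts/carbonate_reference.R` —
an independently written base-R solver that parameterises the system by DIC
(TA is linear in DIC at fixed [H⁺]) rather than by carbonate-alkalinity
subtraction — with agreement required to 1% in pCO₂ and 0.005 pH units,
plus published check values for the constants at S = 35, T = 25 °C
(pK1 5.8472, pK2 8.9660, K0 2.839×10⁻²).

The glass-electrode pH of field datasets is assumed to be on (or close to)
the total scale; NBS-calibrated electrodes read ~0.1 higher, which alone
moves pCO₂ by tens of percent.  Treatment pCO₂ values reported alongside
unprinted alkalinities therefore cannot be reproduced exactly; the tests
assert plausibility (ambient winter pH ~8.1 at 13 °C sits in the
few-hundred-µatm range) rather than digits.

## Factorial ANOVA and effect sizes

Each response (abundance, biomass, production, cellular activity, SGR, NGR,
MR) is analysed with a balanced two-way factorial ANOVA including the
interaction, by the cell-mean decomposition (in a balanced design the
Type I/II/III distinctions coincide; unbalanced input is rejected).  F uses
df = 1 and N − 4; the decomposition is tested to 1e−10 against a
linear-model projection oracle and against `statsmodels.anova_lm`.

Effect sizes are **generalized ω²** for the case where every non-error
factor is manipulated (true for CO₂/UV/temperature treatments):

    ω²_G = (SS_eff − df_eff·MS_err) / (SS_total + MS_err),

with partial ω² also computed.  Null effects give slightly negative
estimates at small n; these are kept as computed in the report and clamped
to 0 only in the display table, which also suppresses ω² for
non-significant effects (the usual reporting convention) and flags
ω²_G > 0.70 as a large effect.  Normality is checked with Shapiro–Wilk on
the pooled residuals (n = 3 per cell is too small for per-cell testing) and
homoscedasticity with mean-centred Levene (median-centring available);
failures annotate the report with a warning and never abort the analysis.
α = 0.05 by default; no multiple-testing correction is applied across the
seven responses, matching standard practice for these designs.

## Synthetic experiments

The generator is built as the exact inverse of the estimator chain so that
round-trip identities are meaningful:

1. true abundance follows the exponential model above;
2. microscopy counts are independent Poisson draws per field around
   N × volume filtered / area ratio (expected total cells per slide below
   the 400-cell protocol floor is a configuration error, reported loudly);
3. cell volumes are lognormal around the true mean (biovolumes are positive
   and right-skewed) with the mean matched exactly;
4. the true end biomass and SGR imply a true production
   P = B·(e^SGR − 1), which is converted backwards through the assay
   arithmetic to an expected net DPM; live aliquots get blank + signal and
   blanks the blank mean, each with multiplicative Gaussian noise.

Defaults: 60 fields per slide, filtration/field area ratio 10⁵, 2 mL
filtered (≈ 50–70 cells per field at ~3×10⁹ cells L⁻¹, comfortably above
the counting floor), 100 cells sized per unit with 35% biovolume CV, 5 mL
assay aliquots, 50 DPM blanks, 10% DPM noise CV.  With those defaults the
synthetic net DPM is ~10⁴ against tens-of-DPM blanks — the signal-to-blank
regime of real winter coastal incubations — and per-replicate SGR scatter
is ~0.02–0.04 d⁻¹.  The default scenario (`experiment2_scenario`) encodes a
winter CO₂ × warming incubation: ambient SGR 0.5 / MR 0.3 d⁻¹, warming
doubling gross growth (1.0) and roughly quadrupling mortality (1.1), CO₂
truly neutral, N₀ = 2.43×10⁹ cells L⁻¹, 3 replicates, 2 days.

Randomness: one master seed is expanded with numpy `SeedSequence.spawn`
into one child stream per (treatment, replicate, timepoint), in design
order; regeneration is bit-identical.  Poisson counting and volume scatter
are treated as switchable noise terms (`ObservationNoiseModel.noiseless()`),
because the noiseless round-trip contract — pipeline estimates equal ground
truth to 1e−6 — is only meaningful when the intrinsic counting noise can be
turned off.

**What passing tests do and do not show.**  The generator emulates
observation noise around a known truth; it does not emulate bottle-to-bottle
biological variability (true rate differences between replicate units),
time-varying rates within the incubation, grazer/virus dynamics as explicit
populations, or assay-level systematic errors (isotope dilution,
conversion-factor bias).  Replicate scatter in real tables is therefore
larger than the generator's default observation noise, and recovery/power
results here bound only the observation-noise contribution.  ω²_G values on
the default scenario run higher (~0.98 for warming on SGR) than typical
field tables (~0.77) for the same reason.

## Problem sizes and calibration checks

The simulation studies in the tests and in `scripts/acceptance.py` use
200 seeds for ground-truth recovery (asserted within 2 Monte-Carlo standard
errors), 200 seeds for warming-effect detection (≥ 90% required; observed
≈ 100%), and 1000–2000 null experiments for the type-I error of the
pipeline ANOVA (required within [0.03, 0.08] at nominal 0.05; observed
≈ 0.05).  A full simulate→reduce→rates→ANOVA cycle runs in ~10 ms, so the
complete suite stays within a few tens of seconds.

## Known limitations

* MR is an indirect difference estimate; negative point estimates can occur
  under noise and are reported as computed.
* The exponential model treats rates as constant over the 2-day incubation.
* The leucine→carbon conversion uses the fixed theoretical factor; no
  empirical calibration is attempted.
* Carbonate speciation assumes total-scale pH and unpolluted nutrient
  levels; no free/seawater scale conversions are provided.
* The two published-table inconsistencies the worked examples avoid (rows
  whose printed MR differs from SGR − NGR on printed means, and a narrative
  MR:SGR ratio that disagrees with its own table row) are documented in the
  acceptance tests rather than reproduced.
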