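# Methods

`coralvar` re-implements, as a tested library, the computational chain that
links raw field measurements on cold-water corals in a stratified fjord to
the inference that calcification tracks mean temperature and short-term
temperature variability rather than aragonite saturation. This note
documents the models, the numerical choices, the synthetic-data generator
and the limits of what the test suite demonstrates.

## Carbonate chemistry (`coralvar.carbonate`)

The CO2 system is resolved from the measured pair (TA, DIC) at in-situ
temperature, salinity and pressure, on the total hydrogen-ion scale.
`total_alkalinity_from_ph_dic` implements the explicit alkalinity balance

    TA = [HCO3-] + 2[CO3 2-] + [B(OH)4-] + [OH-]
         + ([HPO4 2-] + 2[PO4 3-] - [H3PO4]) + [SiO(OH)3-]
         - [H+]free - [HSO4-] - [HF],

and `solve_ph_from_ta_dic` finds the total-scale pH as the Brent root of
`TA_model(pH) - TA_measured` on pH in [2, 12] (xtol 1e-10; the balance is
monotone in pH so the bracket is safe; a residual above 1e-4 umol kg-1
raises). Speciation, pCO2 = [CO2*]/K0 (ideal-gas approximation; fugacity
correction deliberately omitted — immaterial at the accuracy relevant
here) and Omega_arag = [Ca2+][CO3 2-]/Ksp follow from the solved pH.

Constant choices: carbonic acid after Lueker et al. (2000), bisulfate
after Dickson (1990a), total boron after Uppstroem (1974). The remaining
constants required by the alkalinity balance use the conventional defaults
of the standard CO2-system programmes: boric acid Dickson (1990b), water
Millero (1995), fluoride Perez & Fraga (1987), phosphoric and silicic
acids Millero (1995), CO2 solubility Weiss (1974), aragonite solubility
Mucci (1983), calcium Riley & Tongudai (1967). Pressure corrections use
the Millero (1995) molal-volume/compressibility polynomials applied on the
seawater scale, with the total-scale conversion recomputed from the
pressure-corrected KS and KF; the correction factor is exactly 1 at 0 dbar.

Verification is dual-route: the constants are pinned to printed literature
check values at S = 35, 25 degC (pK1 = 5.8472, pK2 = 8.9660, pKB = 8.5975,
ln K0 = -3.5617, Ksp_arag = 6.48e-7 mol2 kg-2), and the solver is checked
against an independently coded zooming grid scan of the same alkalinity
balance plus forward-inverse round trips (recovery within 1e-6 pH). No
third-party CO2-system package is used anywhere in the computation.

Seawater density is EOS-80 (UNESCO 1983), validated against the published
check-value table to 1e-3 kg m-3. Depth converts to pressure with the
Saunders (1981) approximation at a configurable latitude (default 42 S,
the fjord's latitude).

## Physiology rates (`coralvar.rates`)

Skeletal dry mass follows from buoyant mass by Archimedes' principle,
`M_dry = M_buoyant / (1 - rho_sw/rho_skeleton)`, with seawater density at
the weighing-bath temperature and salinity and the species' skeletal
aragonite density 2.793 g cm-3 as default. `skeletal_density` is the exact
algebraic inverse and the pair is property-tested as such.

Net calcification over a growth period is `G = dM * 1000 / (A * t)` in
mg CaCO3 cm-2 d-1 (negative G = net dissolution); the mass-normalised
alternative is `100 * dM / (M_start * t)` in % d-1. The normalising area
is the tissue-covered calyx area from calliper geometry under a cup
approximation: a truncated cone whose inner face is congruent to the outer
lateral face (wall thickness, basal disc, rim annulus and septa ignored),
`A = f_tissue * 2 pi (r_oral + r_basal) * slant`. This is the simplest
reading of the cup geometry; a wall-thickness or rim term would change
areas by a few percent and rates by the inverse factor.

Respiration from closed-chamber incubations subtracts the mean seawater
control (background plankton) drawdown, scales by vial volume, normalises
to calyx area and converts to daily rates. Negative net consumption is
returned and flagged rather than dropped. The vial volume is not corrected
for the coral's displacement volume (typically <1% of an 800 ml vial).

Area policy: shallow corals change area little within the year, so the
final (most accurate, end-of-study) geometry record is used for every
period; deep corals expand their calyx substantially, so each period uses
the most recent geometry record at or before the period start. The policy
is a per-station switch keyed on the deep-station set.

## Temperature variability (`coralvar.env_variability` -> `variability`)

A 15-min logger series is decomposed into diurnal anomalies, a(t) = T(t)
minus the mean of T over the calendar day containing t. Days with fewer
than 80% of the expected 96 samples are excluded. Timestamps are treated
as local time (an optional UTC offset shifts them first): "diurnal" is a
local solar day.

The canonical variability statistic is the mean over days of the
within-day population standard deviation of the anomalies (population SD,
so a full-period sampled sinusoid of amplitude A gives exactly A/sqrt(2)).
Two alternatives are selectable and propagated through the pipeline by
name: the mean daily range (sinusoid: 2A) and the pooled SD of all
anomalies in the window. Which of the three aggregations a given analysis
should use is genuinely open; the choice is therefore isolated behind
`metric_name` so the headline analysis can be rerun under each.

The season calendar defaults to the field year's growth periods —
austral summer 2016-09-15..2017-01-15, autumn ..2017-05-15, winter
..2017-08-15 — and is configurable.

## Inference (`coralvar.inference`)

**Repeated-measures mixed models.** Calcification or respiration is
modelled with season, station and optionally station x transplant as fixed
factors and a specimen random intercept (the same corals are measured
every season). Fitting is REML via statsmodels' MixedLM. Term tests are
Wald F statistics with containment-style denominator degrees of freedom:
a term whose columns are constant within specimens is tested against the
specimen stratum (n_specimens - rank of the between design), all others
against the residual stratum. For balanced random-intercept designs this
reproduces the classical ANOVA F tests exactly, which is what makes the
type-I-error calibration test sharp; Satterthwaite approximation was
considered and rejected as unnecessary for the balanced designs this
package targets. Post-hoc pairwise least-squares means (marginal
predictions averaged over a balanced grid of the other factors) use the
Tukey studentized-range adjustment by default, Holm as alternative.

Two model presets mirror the field analysis: the shallow-native model
(season + station on native corals of the six shallow stations) and the
four-station transplant model (season + station + station:transplant on
native and novel corals at A, F, Es, Ed).

**All-subsets selection.** The response is the station x season mean
calcification (native and novel corals pooled; per-coral analysis is
available by passing the unaggregated table). All 2^6 - 1 = 63 non-empty
main-effects subsets of {mean T, T variability, pH_T, Omega_arag,
salinity, oxygen} are fitted by OLS and ranked by AICc (k counts the
intercept, slopes and the residual variance, the convention of the R AICc
tooling; plain AIC selectable), with delta values, Akaike weights,
adjusted R^2 and the design condition number per model. Collinear fits
proceed (lstsq); undersized subsets are skipped with a warning.

A small-sample property worth stating explicitly: with a true two-
predictor model and four additional null predictors at n = 21, the
probability that the exact true subset is AICc-best is bounded near
(1 - P(F(1,17) > 3.5))^4, about 0.72, independent of effect sizes and
noise levels, because each null predictor's partial F is central under
the true model. Exact-subset recovery rates around 70% (with the true
pair *contained* in the winner about 90% of the time, and its coefficient
signs and magnitudes recovered essentially always) are therefore the
expected behaviour of the procedure itself, not an implementation defect.

**Diagnostics.** Normality of standardized residuals via the
Kolmogorov-Smirnov statistic with the Lilliefors correction for estimated
moments (plain KS against a fixed N(0,1) would be conservative);
Shapiro-Wilk on the raw response as the pre-modelling screen; Breusch-
Pagan as the homoscedasticity score. Degenerate (zero-variance) residuals
raise.

## Synthetic data (`coralvar.synthetic`)

The generator emulates the study system from explicit ground truth:

* **Stations.** Six shallow stations (head A to mouth F, 20 m) with mean
  annual temperature near 12.5 degC, an annual harmonic of amplitude
  1.8 degC peaking in late January, and a tidal (12.42 h) + diurnal (24 h)
  harmonic mixture plus AR(1) noise whose scale declines from head
  (1.10 degC) to mouth (0.55 degC) and is modulated seasonally (larger in
  summer/autumn). Summer daily swings at the head reach ~3.5-4 degC and
  maxima exceed 16 degC. One deep station (Ed, 300 m) at 11.4 degC with
  amplitude 0.12 degC and anomaly scale 0.04 degC, more variable in winter
  (inverted modulation); in winter the deep station is warmer than the
  shallow ones (convective cooling of the upper column).
* **Bottle samples** are built backwards: a target (pH_T, DIC) per
  station-season is combined with the realized seasonal mean temperature,
  salinity and depth-derived pressure, and TA is computed forward with the
  same constant set the solver uses — so inverse solving is an exact
  recovery test. Deep targets give Omega_arag < 1 in all seasons; shallow
  water is supersaturated except for the head-of-fjord summer excursion,
  which is comparable to depth. Salinity and oxygen are affine in the
  seasonal mean temperature (the water-mass axis along which all
  conservative properties co-vary) plus small sampling noise; pH and
  Omega are chemically coupled through the carbonate system. The four
  non-temperature predictors influence nothing in the response model —
  they exist to make the selection problem realistic.
* **Corals.** The roster mirrors the field design: 10 native corals per
  shallow station, 8 at depth, and reciprocal novel cohorts between A-F
  and Es-Ed (68 native + 38 novel). True seasonal calcification follows
  G = 1.12 + 0.15 (meanT - 12) - 1.5 V + u + eps (mg CaCO3 cm-2 d-1,
  specimen SD 0.10, residual SD 0.15), a deliberate echo of the selected
  model: variability spans ~0.03-0.7 degC across stations, so the deep
  station's stability roughly doubles its calcification relative to the
  fjord head despite being ~1.2 degC colder. G depends on the deployment
  station only, so the true transplantation effect is zero unless
  configured. True respiration is 2.0 (deep) vs 1.2 (shallow)
  umol O2 cm-2 d-1 with a summer bonus. Dry-mass trajectories integrate G
  over the area the rate pipeline will use; buoyant weights are emitted
  through the inverse Archimedes relation at the recorded bath conditions
  plus balance noise (SD 1 mg); O2 endpoints come from true respiration,
  vial geometry and a control-vial blank drift plus probe noise (SD
  1 umol L-1); calyx geometry from the sampled size distribution (oral
  diameter 18.10 +/- 4.47 mm) with calliper noise (SD 0.05 mm).

Randomness uses one root seed with per-stream derivation from stable label
hashes (station, specimen), so adding a station or specimen does not
perturb existing streams, and identical configurations write byte-
identical files.

Replicated simulation studies (selection recovery, mixed-model
calibration) use `gen_rate_table`, a response-level draw over the same
roster and response model that skips the instrument chain. The chain
itself is shown separately to be exact at zero instrument noise and adds
only ~1 mg / 1 umol L-1 scale perturbations otherwise, so response-level
draws are statistically equivalent for those studies and keep 200-500
replicates within interactive runtimes (problem sizes used: 21
station-season cells for selection; 76 corals x 3 seasons for the
transplant model).

What the generator does **not** emulate: salinity/oxygen/pH time series
(only discrete seasonal values, as sampled in the field), tidal
constituent structure beyond two harmonics, logger gaps and drift, coral
mortality and tissue loss, bioerosion, feeding and energetics, and any
origin-dependence of physiology. Passing tests therefore demonstrate that
the pipeline recovers known parameters under an idealised but
structurally faithful data-generating process; they cannot certify
behaviour under field pathologies the generator omits.

## Pipeline and reproducibility (`coralvar.pipeline`, `coralvar.cli`)

The pipeline reads six plain CSV tables, runs carbonate -> variability ->
rates -> mixed models -> selection -> diagnostics, and writes every
artifact with fixed float formatting plus a manifest of SHA-256 content
hashes, package version and seed; reruns on unchanged inputs are
byte-identical (no timestamps enter any artifact). Input validation
reports schema, range and referential-integrity violations without
aborting unless strict. The `coralvar` console script is a thin click
front end over these library calls; the library API is the primary
interface.

## Known limitations

* The carbonate module supports only the TA+DIC input pair and the total
  pH scale — exactly what the analysis chain needs, nothing more.
* Containment degrees of freedom are exact for balanced designs but
  approximate under strong imbalance; for heavily unbalanced field data a
  Satterthwaite or parametric-bootstrap alternative would be preferable.
* The cup surface-area formula ignores wall thickness; absolute rates
  scale inversely with any systematic area bias, though station and
  season contrasts are unaffected.
* AICc exact-subset recovery saturates near 70% at n = 21 with four null
  candidates (see above); conclusions should rest on the coefficient
  estimates and the containment of the true pair, which are robust.
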