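# Methods

## Scope and data model

The package analyses natal dispersal — the straight-line km distance from
the natal nest box to the box of the first local breeding attempt — in a
population breeding in a finite nest-box network, with a binary heritable
color morph (gray/brown, one locus, two alleles, brown dominant) and
year-level environmental covariates. Four tables drive everything:

* **registry**: box id, planar coordinates (km) or lat/lon, first year of
  availability;
* **recruits**: natal and breeding box, hatch year, sex, morph, fledging
  body mass, age at recruitment (1 / 2 / 3+), brood id;
* **climate**: a station temperature series, daily or monthly;
* **prey**: annual snap-trapping captures and trap nights.

Coordinates given as lat/lon are projected once at ingest to a local
azimuthal-equidistant plane centred on the registry centroid (spherical
Earth, R = 6371.0088 km). Over a study area of a few hundred km² the
planar-Euclidean error is metres — far below box spacing — so no geodesic
machinery is carried further.

## Covariates

**Winter anomaly.** A winter is labelled by the calendar year of its
December and spans Dec 1 – Feb 28; Feb 29 is always excluded. Daily series
require full coverage of the 90-day window (a configurable number of
missing days can be tolerated); monthly series are averaged with weights
31/31/28. The anomaly is the winter mean minus the mean of winter means
over a fixed baseline (default winters 1981–2010), so colder-than-baseline
winters are negative. A cohort hatched in year *Y* experiences winter *Y*
(its first winter after fledging). Whether the baseline window is read as
winter labels or winter-end years is a convention; the label convention is
used and configurable via `baseline_start`/`baseline_end`.

**Prey index.** 100 × captures / trap-nights. The emulated trapping design
is 2 sites × 16 spots × 3 traps × 2 nights = 384 trap nights.

**Standardization.** Body mass is z-scored (sample SD) over the rows that
actually enter each model, so the two analysis sets are standardized
separately. Prey abundance is entered raw.

## Randomization null for median dispersal

For recruit *i*, the candidate set is the distance from its natal box to
every box available in its hatch year. Availability: hatch in or after the
enlargement year (default 1987) → the full network; earlier → only boxes
with `first_year` before that cutoff. The natal box (self-distance 0) is
excluded by default — settling in the natal box is not a dispersal event —
and can be included by flag.

One repetition draws one candidate per recruit uniformly and records the
median across recruits; m repetitions (default 999) give the null. With
tail = `lower` (default), P = (#{null ≤ observed} + 1)/(m + 1). Ties count
toward rejection, which is conservative and makes the test deterministic
given a seed. The literal `upper` count and a `two-sided` doubling are
options, as is a pooled-urn variant in which all recruits' candidates are
merged before drawing. Draws are independent across recruits and
repetitions; no box-occupancy exclusivity is imposed. Morph-stratified
tests rerun the identical procedure on one morph's recruits; smaller
strata mechanically yield wider null distributions.

Verified properties (see the test suite): exact agreement with exhaustive
enumeration on small candidate sets; type-I error at the nominal 5% under
simulated random settlement (measured 0.050 over 300 study-scale
replicates during development; the acceptance suite re-checks the
[0.03, 0.08] band over 200); monotone power against philopatric kernels.

## Mixed model and Satterthwaite degrees of freedom

The dispersal LMM has treatment-coded fixed effects (reference levels
gray, female, age 1): morph, winter anomaly, morph × anomaly, prey index,
sex, standardized mass, and — in the all-ages analysis set only — the
two-df age factor. Random intercepts for hatch year, brood and natal box
are **crossed**, not nested (brood ids are already unique per year).

Estimation is REML with the residual variance profiled out; the optimizer
(L-BFGS-B, two starts, ftol 1e-10) works on the non-negative variance
ratios, and ratios below 1e-10 are snapped to an exact zero boundary.
Dense n × n linear algebra is used throughout — with n in the hundreds
this is exact and fast, and it gives direct access to the likelihood
surface in the variance components, which the inference needs. The
implementation reproduces statsmodels MixedLM (variance-component
formulation) to ~5 significant figures on crossed test problems; that
cross-check is kept as a permanent test.

For a contrast c, the Satterthwaite denominator df is
2·f²/ Var(f̂), f(θ) = cᵀ(XᵀV(θ)⁻¹X)⁻¹c, with Var(f̂) = gᵀA g from the
gradient g of f in the variance components θ and the asymptotic covariance
A = H⁻¹, H the observed REML information (central-difference Hessian,
relative step 1e-4). Components estimated exactly at the zero boundary are
excluded from θ (the information matrix is singular there); if the reduced
information is still not positive definite the residual df n − p is used
with a warning. With no random effects at all the fit collapses to OLS and
df = n − p exactly. The two-group heteroscedastic construction reproduces
the Welch–Satterthwaite closed form to < 0.01% — note that for a balanced
one-way intercept the df is g − 1 for *any* positive group variance and
jumps to n − p only at the boundary; this discontinuity is inherent to the
method, not an artefact.

Multi-df terms (age) are tested as a joint marginal (Type III) F; the
denominator df follows the eigen-contrast recipe: decompose the term's
covariance block, compute a Satterthwaite df νᵢ per eigen-contrast, then
E = Σ νᵢ/(νᵢ−2) and df = 2E/(E−q) (falling back to min νᵢ when any νᵢ ≤ 2
or E ≤ q). Two-sided p-values throughout; no multiplicity adjustment.

Marginal effects per morph over an anomaly grid hold all non-focal design
columns at their sample means; the 95% band uses the fixed-effect
covariance only (population-level prediction), and grid points outside the
fitted anomaly range are flagged as extrapolated.

The yearly brown-proportion model is a statsmodels binomial GLM
(logit link) with successes/failures supplied as counts, i.e. weighted by
yearly totals; a separation flag is raised when |slope| or its SE explodes.

## Synthetic populations

The generator is the package's testbed: it draws data from exactly the
process the models assume, so estimation bias is attributable to the two
deliberate discretization steps (distance floor, nearest-box settlement).

Defaults (one set of study conditions, chosen once):

| parameter | default | why |
|---|---|---|
| n_years / n_boxes | 40 / 360 | four decades, ~360-box network |
| area | 50 × 10 km (500 km²) | elongated: the network diameter must exceed the longest plausible dispersal (~40+ km); modal pairwise distances land near 10–15 km |
| enlargement | half the boxes from 1987 | mid-study second locality |
| broods/yr, brood size | 25, 2–4 | ~3 000 ringed offspring over the study |
| recruitment_prob | 0.06 | ~6% local recruitment → ~180 recruits |
| brown_allele_freq | 0.16 | Hardy–Weinberg with dominance → ~29% brown |
| morph_unscored_frac | 0.01 | a few recruits never color-scored |
| β: intercept, morph, anomaly, interaction, mass | 10.4, 0.3, −0.85, 2.37, −0.8 | study-scale effect sizes (km, km/°C, km/SD) |
| σ: year, brood, box, resid | 0.1, 0.1, 1.84, 6.5 km | year/brood variance near zero, box SD ~1.8, total dispersal SD ~6.9 |
| anomaly_sd_c | 2.0 °C | interannual winter variability at a boreal station |
| prey cycle | period 3, base 8, amplitude 5 | vole cycle per 100 trap nights |
| mass | 340 ± 30 g | fledging mass scale |

Mechanics per year: parent pairs drawn from Hardy–Weinberg allele
frequencies breed in distinct available boxes; offspring genotypes follow
Mendelian segregation; each offspring recruits independently with
`recruitment_prob`. A recruit's latent distance is
max(0.1 km, linear predictor + u_year + u_brood + u_box + ε), and its
breeding box is the available box (hatch-year rule, natal box excluded)
whose distance from the natal box is closest to the latent value, ties to
the lowest box id. The emitted monthly climate series is constructed so
that re-deriving anomalies through the covariate module returns the
generator's values exactly; prey indices are discretized to integer
captures out of 384 trap nights. `simulate_random_settlement` replaces the
kernel step with a uniform draw over the candidate boxes — exactly the
randomization test's null — for calibration. A replicate with zero
recruits regenerates with seed + 1 and a warning. Bundles are bit-identical
under identical parameters.

**What the generator does not emulate:** territory vacancy and
competition, morph-specific survival of non-recruits, spatially structured
habitat or climate, observation error in coordinates or mass, immigration.
Passing recovery/calibration tests therefore demonstrates correctness of
the *estimators* under the assumed process, not robustness of the
scientific conclusions to these real-world features.

**Known distortion:** with study-scale moments (latent mean ~10.4 km,
residual SD ~6.5 km) about 6% of latent draws hit the 0.1 km floor, which
attenuates the morph × anomaly interaction by roughly 7% (median over 200
replicates: −6.7%); the nearest-box mapping adds ~1%. Recovery tests
budget for this.

## Pipeline

`run_pipeline` executes ingest → covariates → descriptives → GLM → LMM
(both analysis sets) → randomization (all, gray, brown) → report. Ingest
validates schema and cross-references (unknown boxes, duplicate recruit
ids, unparseable factor levels are itemized); complete-case counts are
recorded and reported at every stage, and descriptive partitions are
checked to sum to the ingested total. Percentages are rounded half-up to
one decimal. The report JSON embeds the config hash and SHA-256 input
checksums; seeds are mandatory (no clock seeding), and reruns with the
same config are byte-identical. A stage failure raises an error naming the
stage and moves partial outputs to `failed/`.

## Problem sizes in the test and acceptance runs

The statistical suites run at the study scale they validate: 200
replicates for randomization calibration (m = 999) and for interaction
recovery (generating value +2.4 km/°C), 100 paired replicates for the
power ordering, 10⁵ draws for enumeration equivalence, 10⁴ draws for the
Mendelian checks. The acceptance script uses one study-scale pipeline run
plus 100 calibration replicates. These sizes keep Monte-Carlo error
comfortably inside each test's tolerance.

## Limitations

* Dispersal out of the network is structurally unobservable; the
  randomization test quantifies, but cannot remove, that censoring.
* The LMM treats box-to-box distance as continuous and Gaussian; strongly
  skewed kernels would call for a transformed or non-Gaussian response.
* Satterthwaite df relies on the asymptotic normality of
  variance-component estimates; with very few levels (< ~5) of a grouping
  factor the approximation is rough, as it is in any mixed-model software.
* The CLI is a thin veneer; programmatic use through the library is the
  primary interface.
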