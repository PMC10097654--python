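# Methods

## Scientific problem

Reef corals facing recurrent marine heatwaves would benefit from heat-tolerant
genotypes — but only if tolerance is not bought at the expense of other
fitness components such as growth or fecundity. This package implements a
complete trade-off analysis for a single-population colony study of a
corymbose *Acropora*: replicate fragments of each tagged colony are exposed
to a tank-based heatwave emulation while the donor colonies' growth,
fecundity and Symbiodiniaceae community are measured on the reef, and the
association between heat tolerance and each trait is inferred with Bayesian
linear regression.

## Heat stress: degree heating weeks

Tank temperature loggers (10-min cadence) are aggregated to calendar-day
means (partial first/last days dropped). The daily hotspot is the anomaly
above the adjusted climatological baseline `MMM_adj`, retained only when it
exceeds 1 °C; DHW on day *t* is the sum of hotspots over the trailing
84 days divided by 7 (°C-weeks). Two deliberate choices:

* **Strict `> 1 °C` hotspot rule.** The experiment's definition accumulates
  anomalies strictly greater than 1 °C; the operational `>= 1` variant used
  by some monitoring products is available as `hotspot_rule=">=1"`. At the
  boundary (anomaly exactly 1.0 °C) the two differ, so the rule is explicit.
* **`MMM_adj` by daily OLS calibration.** Satellite-derived MMM is mapped to
  in-tank conditions by regressing daily in-situ temperature on daily
  satellite SST over at least 30 overlapping days:
  `MMM_adj = intercept + slope × MMM`.

## Bleaching survival index and the DHW grid

Fragment health is scored into five ordinal categories (healthy, half
bleached, bleached, partial mortality, dead). For a colony with category
proportions `c1..c5` over its replicate heat-tank fragments,

    BMI = (0·c1 + 1·c2 + 2·c3 + 3·c4 + 4·c5) / (N − 1),  N = 5
    BSI = 1 − BMI.

Colonies that lose a fragment in an unheated procedural-control tank are
removed entirely (handling artefact) and never scored.

Because tanks accumulate DHW at slightly different rates, colonies are
compared on a fixed grid of 21 evenly spaced DHW levels from 0 to the
minimum final DHW across heat tanks, not on calendar dates. For each tank
the first instant it reaches a grid level is found by linear interpolation
of the daily DHW curve (values stamped at day end), and each fragment
carries its most recent surveyed category forward to that instant (step
interpolation). Whether the original alignment scheme interpolated ordinal
categories or a numeric score is not documented for this protocol family;
the step-on-categories form is the default and a linear-on-score variant
(`interpolation="linear"`) is provided without asserting which is original.
Death is absorbing: fragment states are made non-improving before colony
proportions are formed.

Colony tolerance summaries: `average_bsi` is the unweighted mean of BSI over
grid levels (the grid, not survey dates, is the unbiased comparison axis; a
survey-axis average is available via `tolerance_average_axis="surveys"`);
`critical_dhw` is the smallest grid level with BSI ≤ 0.75, a tie at exactly
0.75 counting as onset (the operational reading of "declines below" — an
all-half-bleached colony is already responding); categories are
high (≥ 0.8) > medium (≥ 0.7) > low on average BSI.

## Size-corrected growth

Annual growth is the size change between successive 3D-model surveys divided
by the interval in years (365.25 d); with two usable intervals the
arithmetic mean is taken; shrinkage is preserved; intervals ≤ 30 days are
rejected. Raw areal/volumetric growth scales with colony size, so rates are
multiplied by dimensionless adjustment factors one dimension below the
metric: `areal_AF = mean(D)/D_i` and `volumetric_AF = mean(A)/A_i` with
`A_i = D_i·(D_i/2)` (height assumed half the diameter). Colonies lacking a
taped diameter get one from the printed log–log calibration
`log(D) = −0.738 + 0.537·log(SA)`; natural logarithms are assumed (the
source convention is not stated; `log_base="10"` is provided). The
correction is exact for idealized hemispherical growth at equal linear
extension, which the test suite verifies by simulation.

## Fecundity scaling

Per colony (nominally 20 dissected polyps from 2 fragments): `EC` is the
mean egg count per polyp (mean, not median — the whole-colony products read
as expectations); each egg's `GMD` is the geometric mean of its two measured
perpendicular axis diameters (`√(d1·d2)`; the exact image-analysis formula
is not reprinted in the protocol, so the two-axis geometric mean is the
package's choice); `EV = 4/3·π·(GMD/2)³` in mm³; `TEP = EC × PD × LiveSA`
(eggs per colony) with `PD` the polyp density per cm²;
`TEV = EV × TEP / 1000` in cm³, the mm³→cm³ conversion applied exactly once.
Polyp density measurement is undocumented in the protocol and is a required
input column here.

## Bayesian trade-off regressions

Each trait is regressed against colony tolerance,
`tolerance ~ β0 + β1·trait + ε`, and the quantity of interest is
`P(β1 > 0)`: the posterior probability that no trade-off exists. The
original analysis used integrated nested Laplace approximation; for a
two-coefficient Gaussian linear model the exact conjugate
normal–inverse-gamma posterior is available in closed form, so this package
uses it directly — an approximation-free substitute, not an approximation.
Default prior: `β | σ² ~ N(0, 10⁶·σ²·I)`, `σ² ~ InvGamma(0.01, 0.01)`
(diffuse; with it the posterior slope mean coincides with least squares).
The marginal of `β1` is a location-scale Student-t, from which medians,
central 50/75/95% credible intervals and `P(β1 > 0)` follow analytically.
Predictors are standardized internally and slopes back-transformed to trait
units (raw slopes are ~10⁻⁵ only because growth is ~10³ cm²/yr while BSI is
~10⁻¹; standardization stabilizes the prior without changing `P(β1 > 0)`).
A dense-grid numerical-integration oracle in the test suite confirms the
closed-form quantiles to 10⁻³.

The slope progression fits the same model independently at each of the 21
DHW levels with instantaneous colony BSI as the response. Levels where
every colony shares one BSI value (all healthy pre-stress, or all dead) are
degenerate: the slope posterior is exactly centered at zero
(`P(β1 > 0) = 0.5`) and flagged.

Sensitivity refits: growth regressions excluding shrinkage colonies
(negative growth), fecundity regressions excluding the single most fecund
colony.

## Symbiont and confounder tests

Colonies are assigned their highest-abundance ITS2 type profile (only a
couple of colonies are mixed). The profile effect on the BSI–DHW response is
a binomial GLM of colony BSI (as a proportion, weighted by
`(N−1) × n_fragments` Bernoulli-equivalent units) on DHW level and profile
group. Because a colony's grid levels are repeated measures, covariance is
cluster-robust by colony — without this the test is badly anti-conservative,
which the null-calibration test demonstrates. Pairwise group contrasts are
family-wise adjusted via the studentized-range (Tukey) distribution; groups
with a single colony are reported but flagged as having insufficient power,
not tested. Partial-mortality confounding of each trait uses one-way ANOVA
with Tukey HSD when Shapiro normality of residuals holds (p ≥ 0.05), else
Kruskal–Wallis with Bonferroni-adjusted pairwise Wilcoxon rank-sum tests; the
branch taken is reported. A centered PCA of the colony × profile abundance
matrix, labeled by tolerance category, supports visual overlap inspection.

## Synthetic-data generator

The generator produces a full study (all six input tables plus latent
ground truth) under the energetic-continuum hypothesis: a latent
standard-normal energy score `z` per colony drives its critical DHW exactly
(`critical = 6.7 + 1.1·z` °C-weeks, the study's observed tolerance
distribution) and its growth/fecundity with configurable correlations
(`trait = μ + σ·(r·z + √(1−r²)·ε)`), so sample correlations between truth
columns recover `r` and downstream inference can be validated against known
couplings.

Key defaults and their provenance:

| parameter | default | basis |
|---|---|---|
| colonies / heat / control fragments | 66 / 4 / 2 | study design |
| initial diameter | N(24, 8) cm, > 5 | study population |
| eggs per polyp | N(4.9, 1.4) within colony | study mean ± SD |
| mean egg volume | 0.11 mm³ (lognormal GMD calibrated) | study mean |
| LiveSA / volumetric growth | N(216, 722) / N(404, 647) | study mean ± SD |
| ramp / peak anomaly / assay | 0.8 °C wk⁻¹ / +3.5 °C / 35 d | tank profile |
| baseline `MMM_adj` | 29.5 °C | plausible warm-pool value; profile is defined by the anomaly, any baseline is accepted |
| tolerance–growth coupling | 0.35 | reproduces the reported ~90%/94% P(β1>0) regime at n ≈ 45 |
| tolerance–fecundity coupling | 0.0 | reported ~50:50 odds |
| polyp density | N(60, 8) cm⁻² | chosen so TEP ≈ 2.7×10⁵ eggs at the study's colony sizes |
| handling-death probability | 2/66 | exercises the exclusion rule at the observed rate |
| fragment threshold SD | 0.4 °C-weeks | undocumented in the protocol; exposed as a parameter |
| category spacing δ | 1.0 °C-weeks | produces the observed onset-to-death span |

Bleaching is modeled as DHW-threshold crossings, the simplest mechanism
giving sigmoidal BSI trajectories without inventing unpublished
dose–response parameters: a fragment enters ordinal state `k+1` when its
tank DHW crosses `h_f + (k − ½)·δ`, where `h_f` is the colony's critical
DHW plus fragment noise. Centering the first transition half a spacing
early makes the colony's *expected* BSI equal exactly 0.75 when tank DHW
equals its latent critical DHW (for symmetric fragment noise,
`Φ(c/σ) + Φ((c−δ)/σ) = 1` at `c = δ/2`), so the estimated critical DHW is
approximately unbiased by construction; residual bias from grid rounding
(+half a grid step) and first-crossing noise largely cancels, and the
end-to-end recovery is verified to within 0.6 °C-weeks.

Randomness flows through named substreams (temperature, calibration,
population, health) spawned from one seed, so regenerating a single table
is reproducible and the whole dataset is byte-identical under a fixed seed.

**What the generator does not emulate:** tank micro-position effects and
light gradients, fragment acclimatisation drift, measurement error in 3D
model sizes, seasonal gametogenic timing, symbiont shuffling under stress,
and any spatial reef structure. Passing tests therefore demonstrate that
the estimators recover known parameters under the stated mechanism — not
that the mechanism is the true generative process of the deposited data.

## Problem sizes and numerical choices

The test suite and acceptance script run the full pipeline at the study's
own scale (66 colonies, 6 tanks, 42 logger days at 10-min cadence, 16
surveys) — a couple of seconds end to end. Calibration checks use 600
zero-coupling replicates and 200 positive-coupling replicates of the
population generator at n = 55 colonies; coupling recovery uses n = 500.
The posterior oracle integrates over a 1601 × 301 × 301 grid in
(slope, intercept, log σ²). Tie-breaks and degenerate inputs: BSI exactly
0.75 counts as onset; zero-variance predictors raise; zero-variance
responses yield the flagged, zero-centered slope posterior; colonies with
fewer than two usable size surveys are omitted with a warning; polyps with
no eggs leave EV undefined and TEP = 0.

Stage outputs are written unconditionally on each run (no content-hash
caching): the full pipeline is fast enough that caching would add state and
failure modes without benefit.

## Known limitations

* The binomial GLM response encoding (colony-level weighted proportion) is
  one of two defensible readings; a fragment-level Bernoulli encoding would
  weight colonies differently. No random effect is fitted.
* The critical-DHW estimator inherits a half-grid-step discretization; finer
  grids reduce it at the cost of extrapolating less-covered tanks.
* `average_bsi` over the grid differs slightly from a survey-date average
  when tanks lag each other; both are available but only the grid axis is
  default.
* Real deposited tables may use different column names; a per-schema
  column-mapping block in the run config handles renames, but unit
  mismatches are the user's responsibility.
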