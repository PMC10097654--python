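# coraltrade

Does coral heat tolerance come at the cost of growth or fecundity?
`coraltrade` is an analysis pipeline for colony-level trade-off studies in
reef corals: it turns tank temperature logs, ordinal fragment bleaching
surveys, repeated 3D-model colony sizes, polyp dissections and ITS2
symbiont profiles into per-colony heat-tolerance scores and trait
estimates, then infers — by exact conjugate Bayesian linear regression —
the posterior probability that no trade-off exists between tolerance and
each trait. It is aimed at coral ecophysiologists running marine-heatwave
emulation assays and at anyone who needs the underlying primitives
(degree-heating-week accumulation, bleaching-survival scoring, size-bias
correction, whole-colony fecundity scaling).

## The model in brief

* **Heat dose.** Degree heating weeks per tank:
  `DHW(t) = Σ_{s∈(t−84d, t]} hotspot(s) / 7`, where the daily hotspot is the
  anomaly above the adjusted climatological baseline `MMM_adj` when it
  exceeds 1 °C. `MMM_adj = a + b·MMM` from an OLS fit of daily in-situ on
  satellite temperature.
* **Tolerance.** Fragments are scored into five ordinal categories; with
  colony category proportions `c1..c5`,
  `BSI = 1 − (0c1 + 1c2 + 2c3 + 3c4 + 4c5)/(N−1)`, `N = 5`. Colonies are
  compared at 21 fixed DHW levels shared across tanks; tolerance is the
  average BSI over the grid, and the critical DHW is the first level with
  `BSI ≤ 0.75`. Colonies losing a fragment in a procedural-control tank are
  excluded outright.
* **Traits.** Annual growth from repeated 3D models, de-biased by
  adjustment factors `AF_areal = D̄/D_i`, `AF_vol = Ā/A_i` with
  `A_i = D_i²/2`; whole-colony fecundity `TEP = EC·PD·LiveSA` and
  `TEV = EV·TEP` with `EV = 4/3·π·(GMD/2)³`.
* **Inference.** `tolerance ~ β0 + β1·trait + ε` under a conjugate
  normal–inverse-gamma prior; the marginal of `β1` is Student-t, so
  credible intervals and `P(β1 > 0)` — the probability of *no* trade-off —
  are exact. The same regression is repeated independently at every DHW
  level (the slope progression).

A built-in synthetic-data generator emulates the whole study under an
energetic-continuum model (a latent energy budget couples tolerance to
growth/fecundity with configurable correlations), providing ground truth
for every estimator. See `docs/methods.md` for the full account.

## Worked example

The numbered scripts under `analysis/` run the study end to end on
synthetic data (seed 1):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_heat_stress.py
python analysis/03_bleaching_response.py
python analysis/04_colony_traits.py
python analysis/05_tradeoff_inference.py
```

Selected output:

```
baseline: MMM 28.80 -> MMM_adj 29.50 degC (slope 0.994, intercept 0.880)
final DHW per tank (degC-weeks):
  T2 (heat): 9.17
  ...
grid: 21 levels from 0 to 8.92 degC-weeks
procedural-control exclusion: 1 colony(ies) removed ['A28']
scored 65 colonies
  average BSI: 0.85 (range 0.56-1.00)
  critical DHW: 6.7 +/- 1.3 degC-weeks (range 4.0-8.0; ...)
...
overall trade-off regressions (tolerance ~ trait):
   corrected_livesa_growth [             all]  slope +4.85e-05  P(slope>0) = 0.99 (n = 45)
      corrected_vol_growth [             all]  slope +4.41e-05  P(slope>0) = 1.00 (n = 45)
                       tep [             all]  slope -1.23e-07  P(slope>0) = 0.10 (n = 33)
                       tev [             all]  slope -1.04e-03  P(slope>0) = 0.10 (n = 33)
```

Reading this: the satellite baseline is calibrated up by the in-situ
offset; heat tanks accumulate ~9 °C-weeks over the 35-day assay; one colony
is excluded by the control rule; bleaching onset occurs at 6.7 ± 1.3
°C-weeks across colonies. The growth regressions give high posterior odds
(0.99/1.00) that the tolerance–growth slope is positive — growth and
tolerance acting in concert, no trade-off — while the fecundity traits are
generated uncoupled from tolerance, so their `P(slope>0)` scatters around
0.5 from run to run (here 0.10). The tiny slope magnitudes (~10⁻⁵) only
reflect the unit disparity between growth (~10³ cm²/yr) and BSI (~10⁻¹).
Script 05 also writes `results/slope_progression.png`, the per-DHW-level
slope with 50/75/95% credible bands, which peaks around the mean onset DHW.

The same run is available as a single call:

```python
from coraltrade import RunConfig, SyntheticConfig, run_full_analysis
res = run_full_analysis(RunConfig(output_dir="results/run",
                                  synth=SyntheticConfig(seed=1), seed=1))
print(res["summary"]["p_positive"])
```

or from a YAML config (`RunConfig.from_yaml`), with file-based inputs for
real datasets (six CSV/TSV tables; a column-mapping block handles foreign
column names).

## Repository layout

```
src/coraltrade/     library: data_io, synth, thermal, bleaching, traits,
                    tradeoff, pipeline
analysis/           numbered narrative drivers for the full study
tests/              pytest suite incl. numerical-integration oracles
scripts/            acceptance script
docs/methods.md     models, assumptions, generator calibration, limitations
```
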