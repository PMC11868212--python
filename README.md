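# mossmap

Mapping background cadmium levels from forest-moss biomonitoring surveys.

Terrestrial mosses take up atmospheric metals and are sampled by national
biomonitoring networks at far higher density than instrumented deposition
stations. `mossmap` implements a complete analysis pipeline for turning
such a survey — a few hundred forest sites with measured Cd concentrations
and environmental covariates — into national concentration maps with
uncertainty, and for judging whether covariate-driven regression actually
out-predicts a covariate-free geostatistical baseline.

## The model

Concentrations are physically bounded: a moss sample cannot hold less than
0 µg/g and background samples stay below a practical ceiling
Cd_max (1.5 µg/g by default). The response is therefore mapped to the real
line with a complementary log–log (CLL) transform and modelled linearly:

    ln( ln( Cd_max / Y_i ) ) = α + Σ_j β_j X_i^j + ε_i,   ε_i ~ N(0, σ²)

where Y_i is the Cd concentration at site i and the X^j are quantitative
covariates (buffered land-use percentages, distances to infrastructure,
modelled deposition/air concentration, soil Cd, altitude) plus dummy-coded
moss species, tree cover and biogeographical zone. Back-transforming a
linear predictor through `y = Cd_max·exp(−exp(η))` always lands strictly
inside (0, Cd_max), so extrapolated maps cannot produce impossible values;
because the transform is monotone the back-transformed prediction is the
*median* of Y given η.

Around this core the package provides:

- **Covariate screening** — drop variables with >95 % exact zeros, then a
  Spearman collinearity filter (|ρ| > 0.75): buffer families collapse onto
  their smallest radius, cross-family conflicts drop the more redundant
  member.
- **Backward–forward AIC selection** — best-first stepwise moves on whole
  variables (categorical dummy blocks move together), AIC
  = −2ℓ + 2(k+1).
- **Moran's I diagnostics** — global spatial autocorrelation of the
  transformed response and of model residuals, with a permutation test
  (k-nearest-neighbour weights).
- **Grid prediction** — median-scale concentration maps for a reference
  profile (Hc moss under deciduous cover) with delta-method standard
  deviations, per-zone models mosaicked into one national map.
- **Ordinary-kriging baseline** — Matheron variogram of log(Y), WLS model
  fit, OK system with unit-sum weights.
- **LOOCV comparison** — leave-one-out RMSE on the concentration scale for
  both predictors, nation-wide and per zone.
- **Synthetic campaign generator** — 445 sites across 4 zones, 5 moss
  species with realistic frequencies, ~52 covariates from shared latent
  Gaussian fields, responses drawn from the CLL model; every stage is
  testable without any external data.

## Worked example

```python
from mossmap import (default_study_config, StudyGenerator, screen,
                     stepwise_aic, moran_i, cll_transform)
from mossmap.evaluation import loocv_regression, loocv_kriging

cfg = default_study_config(seed=7)
gen = StudyGenerator(cfg)
sites = gen.simulate_response(gen.generate_sites())

rep = screen(sites)
fit, trace = stepwise_aic(sites,
                          ["moss_species", "tree_cover", "zone"] + rep.retained)

z = cll_transform(sites.data["cd"].to_numpy(), cfg.cd_max)
before = moran_i(z, sites.coords(), n_perm=999, seed=0)

reg = loocv_regression(sites, fit.variables)
krig = loocv_kriging(sites)
```

Printed for seed 7:

```
445 sites, 52 quantitative covariates
screening retained 15 covariates
AIC selection kept 11 variables (AIC 219.88 after 7 moves)
selected: moss_species, tree_cover, zone, Urban_1, Industrial_1,
          Agricultural_1, Water_1, Sea_1, EMEP_air, RMQS_tot, Altitude
Moran I on transformed response: 0.457 (p = 0.001)
LOOCV RMSE: regression 0.154 ug/g vs ordinary kriging 0.192 ug/g
```

Reading the numbers: the zero/collinearity screens cut 52 covariates to
15 (buffer families collapse to their 1-km member); AIC keeps the three
design factors and the covariates that actually drive the simulated
response (air concentration, soil Cd, land-use shares). The transformed
response is strongly spatially clustered (I = 0.457 against an expectation
of −1/444 ≈ −0.002) because the driving covariates are themselves spatial
fields. The regression predicts held-out sites better than ordinary
kriging (0.154 < 0.192 µg/g), the motivating comparison for
covariate-based mapping.

The same workflow is scriptable from the shell:

```sh
mossmap run-all --outdir out/            # full pipeline, default campaign
mossmap simulate --out sites.csv         # or stage by stage
mossmap screen --sites sites.csv --out screening.csv
mossmap loocv  --sites sites.csv --out loocv.csv
```

## Layout

```
src/mossmap/
  config.py      study configuration (zones, species, covariate specs)
  fields.py      latent Gaussian fields (random Fourier features)
  synthetic.py   site tables, grids, CLL responses
  screening.py   zero-proportion and Spearman filters
  cll.py         transform, OLS fit, stepwise AIC
  moran.py       Moran's I with permutation test
  prediction.py  grid extrapolation, delta-method SDs, mosaicking
  kriging.py     variogram + ordinary kriging baseline
  evaluation.py  LOOCV and scope comparison
  qa.py          batch summaries and CRM checks
  io.py          validated CSV readers/writers
  cli.py         typer CLI and the run-all orchestrator
```

See `docs/methods.md` for the statistical details and design choices.
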