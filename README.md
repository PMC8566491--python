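# oralflow

Predict the perceived "thickness" of shear-thinning liquid foods from their
rheology. The package chains three physical steps:

1. **Rheology** (`oralflow.rheology`) — fit the power law
   `sigma = kappa * rate**n` to measured flow curves (log-log least squares).
2. **Squeeze flow** (`oralflow.squeeze_flow`) — model the liquid trapped
   between the tongue and the palate as a disk squeezed under a constant
   lingual force while the tongue slides sideways. The thin-film
   (lubrication) solution gives the gap `h(t)` in closed form and the total
   shear stress on the tongue `sigma(t) = kappa * (V / h(t))**n`.
   Two published variants of the closed form (bracket constant 2 vs 3) are
   provided as `main_text` (default) and `derivation`; the latter is the one
   consistent with the load integral and is cross-checked against adaptive
   ODE integration. The parallel-plate geometry is justified by Hertz-type
   contact estimates in `oralflow.oral_geometry`.
3. **Psychophysics** (`oralflow.psychophysics`) — relate the computed
   stress to panel thickness scores (0–15 scale) by fitting the
   Weber-Fechner log law `S = a + b*log10(sigma)` and the Stevens power law
   `S = c + k*sigma**m`, and compare them on held-out samples.

`oralflow.datasets` packages the 20-product reference table (bouillons and
xanthan-gum solutions: `kappa`, `n`, panel score mean/SEM per product) and
provides deterministic synthetic generators (noisy flow curves, panel score
tables drawn from a known law) for parameter-recovery testing.

## CLI

```bash
# stress on the tongue for a fluid (kappa in Pa s^n) at t = 1.2 s
oralflow stress --kappa 0.026 --n 0.55

# fit a power law to a flow curve CSV (columns shear_rate, shear_stress)
oralflow fit-rheology curve.csv --out fit.json

# gap/stress time series
oralflow gap-trace --kappa 0.026 --n 0.55 --out trace.csv

# fit both psychophysical laws on a sample table (train sets 1&2, test set 3)
oralflow psychofit samples.csv --out report.json

# synthetic panel-score table from a known log law
oralflow simulate --seed 1 --out panel.csv

# one-shot reproduction of the reference analysis
oralflow reproduce --outdir reproduction/
```

Oral parameters (force, speed, bolus volume, contact radius, ...) default to
the reference values; override them via a flat YAML config (`--config`,
keys = field names of `OralParameters`, SI units) or per-flag. Exit codes:
0 success, 1 failed reproduction check, 2 invalid input, 3 numerical
failure.

## Library quick start

```python
import oralflow as of

params = of.default_oral_parameters()
fluid = of.PowerLawFluid(kappa=0.026, n=0.55)
sigma = of.tongue_stress(fluid, params, params.t_assess)   # Pa

train = of.table1_samples(sets=("set1", "set2"))
test = of.table1_samples(sets=("set3",))
report = of.compare_fits(train, test, params)
print(report.preferred)            # "weber_fechner"
score = of.predict_thickness(fluid, params, report.weber_fechner)
```
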