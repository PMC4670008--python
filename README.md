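# oxyscale

Quantitative analysis of how ambient oxygen and temperature jointly control
the timing of *Drosophila melanogaster* embryogenesis, built around per-embryo
morphological event-time tables from time-lapse imaging.

Temperature changes stretch the embryonic timeline almost uniformly — every
stage keeps its proportional share.  Oxygen does not: gut formation slows
disproportionately in hypoxia while syncytial development and head involution
are relatively spared, to the point that landmark *order* inverts between
hypoxic and hyperoxic embryos.  `oxyscale` packages the statistical toolkit
for this kind of data:

* **Data model** — per-embryo records of nine hand-annotated landmarks
  (pole-bud appearance through tracheal filling), with suffix right-censoring
  for arrested embryos, validated CSV I/O.
* **Heterochrony analysis** — timelines normalized between the end of
  cellularization (0) and tracheal filling (1); each landmark's normalized
  position is regressed on oxygen (% O₂); slopes are compared between events
  with a pooled-variance *t*-test and Bonferroni correction; crossing fitted
  lines give the event-order **inversion point**.
* **Rate models** — total developmental time *t* fitted per temperature with
  the Monod-style law *t = a + b/[O₂]*, per oxygen level with an Arrhenius-style
  *t = a·e^(b/T)*, and jointly with a catalogue of combined surfaces selected
  by adjusted R²; single-predictor model families (linear, exponential,
  logarithmic, quadratic, cubic, inverse-proportional) are selected by the
  Pearson correlation between fitted and observed responses.
* **Viability** — each embryo binned by its point of failure
  (pre-gastrulation, gastrulation→midgut, late pre-tracheal, hatching
  failure, hatched) and cross-tabulated by condition.
* **Synthetic generator** — a seeded, fully parameterized simulator of the
  18-condition study grid (10–29% O₂ × 17.5/22.5/27.5 °C) whose defaults are
  the fitted per-temperature Monod coefficients, event-specific heterochrony
  slopes, Gaussian annotation noise, and condition-dependent stage-binned
  mortality, so the whole pipeline is testable without any data download.

## Worked example

```python
import oxyscale as ox

dataset = ox.generate_dataset(ox.default_config(n_per_condition=20, noise_sd=0.5, seed=1))
for temp, fit in ox.fit_monod_per_temperature(dataset).items():
    a, b = fit.parameters
    print(f"{temp:g} C: a = {a:6.2f} h, b = {b:7.2f} h*%O2   (r = {fit.pearson_r:.4f}, n = {fit.n})")
```

prints

```
17.5 C: a =  30.08 h, b =  282.62 h*%O2   (r = 0.9920, n = 91)
22.5 C: a =  17.84 h, b =  164.14 h*%O2   (r = 0.9751, n = 93)
27.5 C: a =   8.90 h, b =  199.87 h*%O2   (r = 0.9774, n = 79)
```

`a` is the high-oxygen asymptote of total developmental time (hours between
the end of cellularization and tracheal filling) and `b/[O₂]` the hypoxic
slowdown — dropping from 29% to 10% O₂ costs `b·(1/10 − 1/29)` ≈ 13–18 hours
depending on temperature.  The fits recover the generator's ground truth
(30.13, 280.92), (17.58, 167.39), (8.55, 204.03) within sampling error.

The `examples/` directory has one short script per capability: simulation,
heterochrony + inversion, rate models, and viability.  A thin CLI wraps the
same pipeline:

```sh
oxyscale simulate --seed 17 --n 20 --out sim.csv
oxyscale analyze all --in sim.csv --out report/
```

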