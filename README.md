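# lakesip

Rate inference for stable-isotope tracer incubations of deep-lake water
columns: potential ammonia oxidation, dark DIC fixation and ammonia
assimilation, from bulk bottle measurements down to single cells.

## The problem

In the cold, aphotic hypolimnion of deep oligotrophic lakes, ammonia
oxidation (the first step of nitrification, dominated by ammonia-oxidizing
archaea, AOA) and dark fixation of dissolved inorganic carbon (DIC) are
assumed to be tightly linked, because AOA are chemolithoautotrophs. Testing
that link requires turning raw ¹⁵N/¹³C tracer-incubation measurements into
comparable rates at three scales:

* **Bulk slope rates.** After amending water with ¹⁵NH₄⁺ (labeling fraction
  F ≈ 0.93), produced ¹⁵N-nitrite accumulates linearly; the potential
  oxidation rate is the OLS slope divided by F, kept only when the slope is
  significantly positive (one-tailed t test, P < .05):
  `rate = slope(¹⁵NO₂⁻ vs t) / F`.
* **Bulk endpoint rates.** ¹³C-DIC and ¹⁵N-ammonium uptake into biomass over
  48 h gives `rate = (x_end − x₀)/(F − x₀) · pool / Δt`, where x are
  heavy-isotope atom fractions of particulate C or N.
* **Single-cell rates.** nanoSIMS ion counts per cell give
  `x = minor/(minor+major)`; measurements with Poisson relative error
  `√(1/minor + 1/major)` ≥ 5% are discarded; the per-cell rate is
  `(x − x_nat)/(F − x_nat) · cell content / Δt`. Distributions are
  right-skewed and summarized by median/IQR/skewness, groups compared by
  Mann–Whitney U with Benjamini–Hochberg correction, and group means
  extrapolated to volumetric rates through the cell census.
* **Partitioning.** Culture stoichiometry (AOA oxidize ~10–11 mol N per mol
  C fixed; nitrite oxidizers ~28) converts oxidation rates into an expected
  fixation share; measured single-cell shares are bounded upward for the
  16–77% isotope dilution caused by CARD-FISH staining.
* **Temperature responses.** Exponential (Q10) versus Gaussian-optimum
  models fitted per process and compared by AICc, plus the per-temperature
  assimilation:fixation ratio.

Because no raw field data are distributed, the package includes a
first-class synthetic-data generator (`lakesip.synthetic`) that emulates all
of these measurements from explicit ground truth, so every estimator is
verifiable by round trip.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data calibrated to the hypolimnion (85 m, ~5 °C) condition:

```sh
python analysis/01_simulate.py --seed 1   # writes results/data/
python analysis/02_bulk_rates.py
python analysis/03_single_cell.py
python analysis/04_partition.py
python analysis/05_temperature.py
```

`02_bulk_rates.py` prints (seed 1):

```
bulk rate recovery (mean ± sd vs truth):
  oxidation        7.31 ± 0.36 (truth 7.5) nmol N/l/d, n=3
  dic_fixation     1.31 ± 0.08 (truth 1.3) nmol/l/d, n=3
  n_assimilation   5.77 ± 0.19 (truth 5.5) nmol/l/d, n=3
```

i.e. triplicate bottles with 5% measurement noise recover the true
volumetric rates within their replicate spread. `04_partition.py` then
shows the central disconnect the pipeline is built to expose:

```
oxidation 7.31 nmol N/l/d over total fixation 1.31 nmol C/l/d
  expected AOA share (yield 10-11 N/C): 50.6-55.7%
  observed single-cell AOA share:       5.8%  -> verdict: lower
  upper bound at 77% isotope dilution:  10.4%
```

Stoichiometry predicts AOA should drive about half of dark DIC fixation,
but the single-cell measurements (25 AOA cells against 427 other
picoplankton cells) attribute only a minor share to them — even after
correcting for the strongest reported staining dilution. `05_temperature.py`
recovers the decoupled temperature responses (oxidation optimum near 10 °C,
width ~4 °C; fixation Q10 ≈ 1.9; assimilation:fixation ratio rising from
2.85 ± 0.17 at 5 °C to 6.97 ± 1.45 at 20 °C for this seed).

The same stages are available as a CLI
(`lakesip --seed 1 --out-dir out all`) or as library calls
(`lakesip.pipeline.run_pipeline`).

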