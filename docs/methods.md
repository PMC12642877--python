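# Methods

## Rate models

**Ammonia oxidation (slope method).** The tracer design adds ¹⁵NH₄Cl far in
excess of ambient ammonium and traps produced ¹⁵N-nitrite in a ¹⁴N-nitrite
carrier pool. With the substrate labeling fraction F effectively constant
over 48 h, the product pool grows linearly: d[¹⁵NO₂⁻]/dt = r·F. The
estimator is an ordinary least-squares slope per bottle divided by F, with a
one-tailed t test (H₁: slope > 0, n−2 df) at α = 0.05. Negative slopes are
never significant; non-significant estimates are retained but excluded from
summaries. Per-bottle fits are averaged (rather than pooling all bottles
into one regression) so the replicate spread carries the uncertainty.
Division by F is applied always; with F > 0.9 it changes rates by < 10% but
omitting it would bias every rate low.

**Endpoint uptake (DIC fixation, ammonia assimilation).** With x₀ the
natural-abundance atom fraction and x_end the measured endpoint fraction of
particulate C or N, the newly synthesized biomass fraction is
(x_end − x₀)/(F − x₀) and the volumetric rate is that fraction times the
particulate pool divided by the incubation time. A single interval yields no
per-sample p-value; uncertainty enters as replicate spread at the summary
level. Negative excess (x_end < x₀) is physically impossible under the
design and is reported as rate 0 with a flag, not an exception, because it
occurs legitimately through measurement noise at near-zero rates.

**Single cells.** Atom fractions come from ion counts as minor/(minor+major)
per element; the relative standard error of the underlying isotope ratio
under independent Poisson counting is √(1/minor + 1/major), and cells at or
above the 5% threshold are excluded per element. Rates then follow the same
excess-enrichment inversion with a fixed per-cell element content.
Group differences use a two-sided Mann–Whitney U (midranks). The p-value is
exact by full enumeration of group assignments when both groups have n ≤ 8
(correct under ties), exact via the tie-free null distribution up to n = 20,
and a tie-corrected normal approximation beyond; Benjamini–Hochberg is
applied across the four comparisons (C, N × rate, enrichment) within a
sample. Population extrapolation multiplies group *means* by group cell
densities: means, not medians, because mean × density is the only statistic
that conserves mass when aggregating; for strongly right-skewed
distributions this makes the extrapolation sensitive to the sampled tail,
which is a property of the measurement design, not of the software.

**Partitioning.** Expected guild share = oxidation rate / (yield · total
fixation), with yields of 10–11 mol N per mol C (ammonia oxidizers) and 28
(nitrite oxidizers); the nitrite flux to nitrite oxidizers defaults to the
ammonia-oxidation rate (steady-state nitrite) unless supplied. The dilution
correction for CARD-FISH staining multiplies the measured share by (1 + d)
by default (d the reported fractional dilution, up to 0.77). The more
conventional reading of "signal diluted by d" would divide by (1 − d); it is
available as `convention="rescale"` and is stricter. The multiplicative form
is the default: it reads a reported "diluted by d" as a fractional loss
relative to the measured value (so an 11% share at d = 0.77 bounds the true
share at 19.5%), which is how such dilution percentages are commonly quoted;
since quoted dilution ranges rarely define the convention, both forms are
implemented and labeled.

**Temperature responses.** Exponential r(T) = r_ref·Q10^((T−T_ref)/10) is
fitted log-linearly (exact on noiseless model data; under multiplicative
noise the log transform introduces a small, quantified lognormal bias that
the Monte-Carlo tests allow for). The unimodal alternative is a Gaussian in
temperature, r(T) = r_opt·exp(−(T−T_opt)²/(2w²)) — the minimal 3-parameter
unimodal form; no mechanistic claim is attached. It is fitted by bounded
nonlinear least squares initialized at the argmax temperature with
half-range width, T_opt constrained to [min T − 5, max T + 5] so monotone
data pin it at a flagged boundary. Model choice is by AICc on rate-space
residuals (k = parameters + 1 for the variance); AICc is undefined (NaN) for
n ≤ k + 1, in which case selection raises while the fits themselves remain
usable. |ΔAICc| < 2 is reported as indistinguishable. Assimilation:fixation
ratios are computed per (temperature, replicate) pair before averaging, so
the reported ± reflects replicate-level ratio spread; zero-fixation
replicates are dropped with reduced n.

## Synthetic data: what it emulates

The generator produces every input table from explicit ground truth and a
seed; identical seeds give bit-identical outputs (per-stage streams are
spawned from one master seed).

* **Defaults are the hypolimnion (85 m) study condition**: true rates 7.5
  nmol N l⁻¹ d⁻¹ oxidized, 1.3 nmol C l⁻¹ d⁻¹ fixed, 5.5 nmol N l⁻¹ d⁻¹
  assimilated; F(¹⁵N) = 0.93 (5 µM amendment at 0.99 purity over ~0.32 µM
  ambient ammonium), F(¹³C) = 0.43 (1.3 mM tracer over 1.6 mM ambient DIC);
  48 h incubations sampled at 5 timepoints; 5% measurement CV.
* **Noise model** is multiplicative Gaussian (CV-parameterized) on
  concentrations and endpoint excess — instrument error scales with signal —
  and Poisson on ion counts. Negative draws clip to zero.
* **Single-cell truth** is lognormal per group and element, parameterized by
  (median, IQR) because those are the natural summaries of right-skewed
  rate data; the scale parameter solves IQR = 2·median·sinh(zσ) in closed
  form (σ = asinh(IQR/2·median)/z, z = Φ⁻¹(0.75)). Skewness is emergent,
  not fitted. Defaults: AOA median 2.17×10⁻¹⁸ mol C cell⁻¹ d⁻¹ (IQR
  3.8×10⁻¹⁸) and 8.14×10⁻¹⁸ mol N (IQR 23.4×10⁻¹⁸), n = 25; other
  picoplankton 0.36×10⁻¹⁸ mol C (IQR 1.51×10⁻¹⁸) and 1.67×10⁻¹⁸ mol N (IQR
  7.19×10⁻¹⁸), n = 427. The newly synthesized fraction saturates at 1: a
  cell cannot become more enriched than its substrate pool, which caps the
  extreme lognormal tail physically instead of rejecting the draw.
* **Ion counts** default to 10⁵ expected major-isotope counts per cell and
  element, chosen so typical cells pass the 5% Poisson filter while
  weakly-enriched ¹⁵N cells near natural abundance can still fail it, as in
  real data. Count depths are a declared modeling choice (config-exposed),
  not an inference of any instrument's settings.
* **Cell constants**: 1.75×10⁻¹⁵ mol C and 3.1×10⁻¹⁶ mol N per cell
  (≈ 21 fg C, C:N ≈ 5.6), config-exposed and recorded in provenance.
* **Temperature truth**: oxidation is Gaussian with T_opt = 10 °C and width
  4.25 °C (chosen so rates double from 5 to 10 °C); fixation is exponential
  with Q10 = 2.0 (a field-typical default) referenced to 1.3 nmol C l⁻¹ d⁻¹
  at 5 °C; assimilation is exponential with its reference rate and Q10 set
  so the noiseless assimilation:fixation ratio is exactly 2.9 at 5 °C and
  6.5 at 20 °C. Oxidation uses a wider grid (5–28 °C) than the other
  processes (5–20 °C), and the fitting tolerates unequal grids.
* **Substrate depletion** is off by default (the 5 µM amendment exceeds
  consumption by orders of magnitude). In depletion mode, oxidation that
  removes ¹⁵N and ¹⁴N in proportion to the current labeling fraction leaves
  that fraction constant while the pool shrinks, so the model reduces to an
  exhaustion guard: truths whose consumption would empty the pool within
  the incubation are rejected, and cumulative labeled nitrite can never
  exceed the initial labeled ammonium. No remineralization (which would
  genuinely dilute F over time) is modeled.

**What passing tests do not show.** The generator draws independent cells,
bottles and timepoints; real incubations have bottle effects, temporal
autocorrelation, community change over 48 h, nitrite consumption by nitrite
oxidizers, and staining-induced isotope dilution that differs by taxon and
element — none of which are simulated (the last is handled only as an
explicit bound at the partitioning step). Recovery of truth here therefore
validates the inference arithmetic and its statistical calibration, not the
field accuracy of any measured rate.

## Numerical choices and quantified biases

* Quartiles use linear interpolation between order statistics (the common
  "type 7" rule) everywhere, including the generator's IQR solve; skewness
  is the adjusted Fisher–Pearson coefficient (bias-corrected), reported as 0
  with a flag for zero-variance samples and omitted below n = 3.
* Internal units are nmol, liters, days; µmol pools and hour timestamps are
  converted at I/O only.
* The decoded single-cell *median* for the carbon channel sits ~4–6% above
  the lognormal truth at the default count depth: the Poisson counting noise
  on x is comparable to the small ¹³C excess, and adding roughly symmetric
  noise to a right-skewed distribution shifts the median toward the mean.
  This is a property of the emulated measurement itself and is left in the
  reported values rather than corrected away; the nitrogen channel, with a
  ~50× larger relative excess, shows no measurable bias. Where a reported
  round-trip median is itself a Monte-Carlo quantity, the acceptance script
  averages per-dataset medians over 25 independent simulated datasets of
  the same 2000-cell experiment to keep simulation error well below that
  measurement bias.
* Degenerate inputs: flat time series → rate 0, not significant; zero minor
  counts → infinite counting error (filtered); zero combined population
  rate → shares undefined with a flag; monotone temperature data → boundary
  optimum with a flag.

## Known limitations and open readings

* The package defines a group's population share as group over
  combined-including-group. Published extrapolation summaries are often
  rounded to two figures and sometimes quote the complement group as the
  denominator, so shares recomputed from quoted rate pairs may differ from
  a quoted percentage by a percentage point or more; exact reproduction of
  rounded published shares is therefore not promised.
* Which ion pairs (¹³C/¹²C vs ¹³C¹²C/¹²C₂, ¹²C¹⁵N/¹²C¹⁴N) underlie a given
  dataset is irrelevant to the arithmetic; the cells table accepts generic
  (minor, major) counts per element.
* No nitrite-sink correction, no urea/cyanate oxidation, no isotope
  fractionation, no Arrhenius/Sharpe–Schoolfield thermodynamics, and no
  extrapolation beyond the measured temperature range.
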