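# Methods

This note documents the models, defaults and numerical choices behind
`robustmatch`, and what the synthetic-data generator does and does not
emulate.

## Phenotypes

**Robustness.** Stress survival is scored as
robustness = log₁₀(N_t) − log₁₀(N₀), the log-reduction of viable counts
after t minutes of stress. Base 10 is the microbiology convention ("one log
unit" = a tenfold change). Replicates are aggregated as the arithmetic mean
of per-replicate log ratios, not the log of mean counts: plating replicates
are roughly lognormal, and averaging on the log scale keeps the estimator
unbiased for the median log reduction. t = 0 entries define N₀ and have
robustness 0 by construction. A replicate with N_t = 0 is below the plating
detection limit; it is flagged and excluded with a warning rather than
floored, because any floor value would leak into downstream correlations.

**μ_max.** The maximum specific growth rate is the steepest slope of ln(OD)
vs time over all sliding windows (default 4 points), floored at 0. A window
estimator is robust to lag and stationary phases without committing to a
parametric growth model; windows containing non-positive OD are skipped.

**Factor effects.** Each fermentation parameter is tested by a Welch
(unequal-variance) two-sample *t*-test between its levels, with every other
parameter varying in the background — exactly what a combinatorial design
supports. Welch is the safer default for the unbalanced groups this design
produces (e.g. 4 vs 5 fermentations for temperature pairs). The three
temperature levels are tested pairwise (27–30, 27–35, 30–35) and reported
separately. Significance is raw p < 0.05 throughout; no multiplicity
correction is applied to factor-effect tests, matching the reporting
convention of the study the package models.

## Microarray preprocessing

Arrays are assumed to share a common reference channel, so each array's
corrected log ratio is directly the sample's relative expression. (The
original experiment hybridized samples in interlocked loops; extracting
per-sample levels from a loop requires a design-matrix model that is not
part of this package's scope, and the common-reference layout preserves
every computation that is: lowess, scaling, median summarization, log₂
units.)

Steps, per array:

1. **MA transform** — M = log₂(sample) − log₂(reference),
   A = ½(log₂ sample + log₂ reference). Probes with a zero channel are
   flagged and excluded; an array with no usable probes is an error.
2. **Lowess normalization** — M_corrected = M − lowess(M ~ A), span 0.4,
   3 robustifying iterations (statsmodels implementation, with a small
   interpolation delta for speed). The residual-trend diagnostic refits
   lowess on the corrected values and reports the maximum |fit| on the
   central 5–95% of the A axis; the sparse extremes of any local regression
   are unstable and are excluded from the diagnostic. Well-normalized
   arrays stay below 0.05.
3. **Scaling** — corrected M is shifted to median 0 and divided by the raw
   median absolute deviation, making array distributions comparable. Zero
   MAD is an error (a degenerate array, not a quantity to guess around).
4. **Summarization** — ORF expression is the median of its probes' corrected
   M per array; ORFs lacking an unflagged probe on some array are dropped
   with a warning. The result is the log₂ expression matrix used everywhere
   downstream.

## Signature selection

Per gene and stress, expression is regressed on robustness (OLS) at 30 and
60 minutes; the slope's two-sided p-value equals the Pearson-correlation
p-value, so the selected set is orientation-invariant (asserted by a test).
Duplicated fermentation conditions enter as individual samples. A gene is
selected when p₃₀ < α, p₆₀ < α and p₃₀·p₆₀ < c with strict inequalities
(defaults α = 0.05, c = 5×10⁻⁵), and its slope signs agree at the two time
points; discordant genes are never selected, since a signature gene has one
direction. Signatures are ordered by ascending p-value product
(most significant first). For independent uniform p-value pairs and c < α²
the null pass probability is c(1 + ln(α²/c)) — the area of
{(x, y) ∈ (0, α)² : xy < c} — which the Monte-Carlo calibrator reproduces.

**Dependence caveat.** The closed form assumes independent time points. In
real (and realistically simulated) data the 30- and 60-minute robustness
vectors share a condition-level component, so a null gene whose noise
happens to correlate with that shared component tends to get small p-values
at *both* time points. The realized null selection rate is therefore higher
than the independent-pair calibration — with the default generator, roughly
0.3–0.6% of unplanted genes per stress (≈ 7–15 genes of 2369) instead of
0.025%. This is a structural property of the dual-time-point criterion, not
an implementation artifact; it is visible in the pipeline's recovery
reports, and it is why the criterion should be read as a strong enrichment
filter rather than an error-rate guarantee.

## Synthetic-data generator

The generator reproduces the statistical structure the analysis assumes, not
the chemistry that produced it.

* **Design** — the canonical 13-row combinatorial design over salt
  {0, 100 mM}, starting pH {6.0, 6.5}, temperature {27, 30, 35 °C} and
  aeration {+, −}, with row 13 duplicating row 6; other sizes are sampled
  from the full factorial under a level-coverage constraint (every level in
  ≥ 2 rows for n ≥ 12).
* **Growth** — logistic OD trajectories; intrinsic rate anchored per
  temperature (0.81/0.97/1.07 h⁻¹ at 27/30/35 °C) and carrying capacity per
  starting pH (2.06/2.96 at pH 6.0/6.5), matching the observed group means
  of the bundled growth table; multiplicative OD noise (SD 0.03).
* **Latent robustness** — for fermentation f, stress s, time t:
  R = base_s + effect_s(f) + G_f + S_{f,s} + ε_{f,s,t}, in log₁₀ units.
  Systematic effects: aeration raises heat robustness by 1.5 log, 35 °C vs
  27 °C raises oxidative robustness by 1.5 log. Condition noise is split
  into a cross-stress component G (SD 0.35) and a stress-specific component
  S (SD 0.35), both shared by the two time points — heat and oxidative
  survival co-vary across conditions, and the 30- and 60-minute assays of
  one stress correlate. Time-point noise is asymmetric: SD 0.5 at 30 min
  (duplicate conditions vary by about one log unit there) and SD 0.2 at
  60 min (duplicates are highly repeatable). Pooled across conditions,
  stresses and time points the latent surface spans ≥ 3 log units
  (up-to-1000-fold survival differences).
* **CFU counts** — N₀ lognormal around 10⁸ CFU/ml; N_t = N₀·10^R observed
  through Poisson noise at the plated-colony scale (expectation capped at
  ~300 colonies per spot, rescaled by the power-of-ten dilution), two
  replicates.
* **Probe intensities** — 2369 genes, 1–5 probes each, per-gene baseline
  ~N(10, 1.5) log₂ units, per-probe affinity ~N(0, 0.5). Ten planted genes
  per stress respond linearly to the time-point-free part of R with slopes
  drawn uniformly from ±[0.5, 1.0] (70% positive); an optional subset of
  genes carries factor main effects (off by default so recovery accounting
  is purely noise-driven). Channel noise SD 0.2 (log₂). Dye bias is a
  single smooth bow, amplitude·sin(0.5(A − 10)), applied ±half to the two
  channels so M is distorted while A is preserved — the classic two-color
  banana shape.

All stages draw from independent substreams of a single seed, so outputs are
byte-identical under a fixed configuration and insensitive to call order.

**What the generator does not emulate** — hybridization chemistry, dye-swap
loop designs, spatial array artifacts, growth in milk, survival-curve
kinetics (D-values, tailing), or biologically structured expression
covariance (gene expression noise is independent across genes given the
design). Passing recovery tests therefore demonstrate that the statistical
machinery recovers signals of the assumed form at the study's scale and
noise level, not that real arrays would behave as cleanly.

## Problem sizes and determinism

The default study is deliberately desk-scale: 13 fermentations, 2369 genes,
~7,000 probes per array. Recovery statistics in the acceptance script are
averaged over 20 independently seeded studies; the criterion calibration
uses 10⁶ Monte-Carlo pairs. Every random quantity flows from one integer
seed.

## Known limitations

* The common-reference simplification means loop-design contrasts cannot be
  ingested directly; real loop data would need external contrast extraction
  first.
* The genome-scale gene counts of the original study (per-time-point
  correlated-gene counts, the 18/54 signature sizes) depend on the original
  array data and are out of scope; the package reproduces the worked
  examples and the method's statistical behaviour instead.
* Linkage grouping uses gene features only; intervening non-gene features
  are invisible to the spacing rule, and "nearby" groups separated by a
  single wide gap are not merged.
* The null selection rate of the dual-time-point criterion depends on the
  inter-time-point correlation of the phenotype (see the dependence caveat
  above); reported false-positive rates are specific to the generator's
  default noise structure.
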