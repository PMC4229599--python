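# robustmatch

Transcriptome–phenotype matching for fermentation-induced stress robustness
in *Lactococcus lactis*.

Industrial starter cultures of *L. lactis* are usually preserved by spray
drying, which exposes the cells to lethal heat and oxidative stress. How well
a culture survives depends strongly on how it was fermented beforehand: salt,
starting pH, temperature and aeration can shift survival by three orders of
magnitude. `robustmatch` implements the full desk-side analysis of such a
combinatorial fermentation experiment, for microbiologists and
bioinformaticians who want to connect fermentation conditions, stress
survival phenotypes and genome-wide expression:

* **Growth phenotyping** — maximum specific growth rate μ_max (steepest
  sliding-window slope of ln OD₆₀₀ vs time) and final OD from growth curves.
* **Robustness scoring** — from CFU plate counts,
  robustness = log₁₀ N_t − log₁₀ N₀ per fermentation × stress × time point
  (0 = full survival, −3 = 1000-fold kill), with survival % = 100·10^robustness.
* **Factor-effect testing** — Welch *t*-tests of each fermentation parameter
  (all other parameters varying in the background, as a combinatorial design
  intends) on any phenotype.
* **Two-color microarray preprocessing** — MA transform, per-array lowess
  normalization of M on A (dye-bias removal), median/MAD scaling, and median
  summarization of probes to ORF-level log₂ expression.
* **Differential expression** — per-gene Welch *t*-tests per factor level
  pair (raw *P* < 0.05 by convention; optional Benjamini–Hochberg), and the
  pairwise DE-set overlap matrix.
* **Signature selection** — per gene, OLS regression of expression on
  robustness at 30 and 60 minutes of stress; a gene enters the stress
  signature when *P*₃₀ < 0.05, *P*₆₀ < 0.05, the product
  *P*₃₀·*P*₆₀ < 5×10⁻⁵, and the slope signs agree. Under the null with
  independent time points the pass probability is
  c(1 + ln(α²/c)) ≈ 2.456×10⁻⁴ for α = 0.05, c = 5×10⁻⁵ (closed form and
  Monte-Carlo cross-checked).
* **Genetic linkage** — operon-like groups of adjacent, same-strand genes
  with intergenic spacing < 100 bp, read from GFF3, used to annotate
  signature genes with co-regulated neighbours.
* **Synthetic data** — a seeded generator producing the full study structure
  (combinatorial design, logistic growth, latent robustness with shared
  30/60-minute components, Poisson plate counts, two-channel probe
  intensities with intensity-dependent dye bias and planted
  robustness-responsive genes), so the whole pipeline is testable without
  any external download.

The package ships the study's 13-fermentation design/growth table and the
published heat (18-gene) and oxidative (54-gene) robustness signatures as
plain-text fixtures.

## Worked example

```python
from robustmatch import (SimulationConfig, simulate_study, compute_robustness,
                         preprocess_probes, build_signature, summarize_signs,
                         test_parameter_effect, load_fermentation_table)

# published design/growth table: is growth slower at 27 than at 35 degC?
table = load_fermentation_table()
mu = table.set_index("fermentation_id")["mu_max"]
eff = test_parameter_effect(table, mu, "temperature_C", 27, 35)
print(f"mu_max 27C vs 35C: t = {eff.t_statistic:.2f}, p = {eff.p_value:.4f}")

# synthetic study: recover the planted robustness signature
study = simulate_study(SimulationConfig(seed=0))
profile = compute_robustness(study.cfu)
expr = preprocess_probes(study.probes)
for stress in ("heat", "oxidative"):
    sig = build_signature(expr, profile, stress)
    pos, neg = summarize_signs(sig)
    hits = study.truth.planted_ids(stress) & set(sig.gene_ids)
    print(f"{stress}: {len(sig)} genes ({pos}+/{neg}-), {len(hits)}/10 planted")
```

prints

```
mu_max 27C vs 35C: t = -3.69, p = 0.0102
heat: 11 genes (6+/5-), 6/10 planted
oxidative: 26 genes (16+/10-), 10/10 planted
```

The *t*-test confirms the slower growth at 27 °C (p = 0.010). On this seed
the pipeline recovers 6 of 10 planted heat genes and all 10 oxidative ones;
the extra selected genes are a mix of noise-driven selections (the 30- and
60-minute phenotypes share a latent component, so a gene that randomly
correlates with it tends to pass at both time points — see
`docs/methods.md`). Averaged over 20 seeds the sensitivity is ≈ 0.96 with a
false-positive rate below 0.5%.

The same analysis is available from the shell:

```sh
robustmatch run --config config.yaml          # end-to-end with a report
robustmatch simulate --seed 1 --out sim/      # individual stages
robustmatch preprocess --probes sim/probe_intensities.tsv --out expr.tsv
```

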