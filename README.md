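# vectorniche

Ecological niche modeling (ENM) of disease-vector distributions under
present-day and future climates, as a tested, reusable Python pipeline.

Mosquito vectors such as *Aedes aegypti* and *Ae. albopictus* transmit
dengue, chikungunya and Zika; anticipating where climate will let them
establish is a core question for surveillance planning. The standard
workflow — clean and spatially thin occurrence records, reduce correlated
bioclimatic layers by PCA, fit a maximum-entropy presence-background model
on an accessible area *M*, project it onto GCM × RCP climate scenarios,
threshold at an allowable omission rate, and test significance and niche
overlap — is usually assembled ad hoc from GUI tools and scripts.
`vectorniche` implements every stage as library functions with a thin CLI,
and ships a synthetic virtual-species world with known ground truth so the
whole chain is testable without downloading occurrence compilations or
climate rasters.

It is aimed at spatial epidemiologists and ecologists who want a
scriptable, reproducible ENM chain, and at methodologists who want a
benchmark where the true niche is known.

## The model

Suitability is a Gibbs (maximum-entropy) density over a background sample
of the accessible area. With features $f_j(x)$ — linear and quadratic terms
(optionally pairwise products) of the principal components, standardized
over the background — the weights $\lambda$ minimize the convex objective

$$
-\frac{1}{m}\sum_{i \in \text{presences}} \eta(x_i)
+ \log\!\Big[\frac{1}{B}\sum_{b \in \text{background}} e^{\eta(x_b)}\Big]
+ \sum_j \beta\,\frac{s_j}{\sqrt{m}}\,|\lambda_j|,
\qquad \eta(x) = \sum_j \lambda_j f_j(x),
$$

where $s_j$ is feature $j$'s standard deviation over the presence sample —
the MaxEnt-style regularization that penalizes each feature by the sampling
uncertainty of the constraint it enforces. Predictions are $e^{\eta}$
rescaled by its maximum to $[0,1]$; extrapolation is deactivated (cells
outside the per-layer training ranges get suitability 0 and a novelty
flag). Downstream products and tests:

- **E% threshold** — the largest cutoff $\tau$ leaving at most E (default
  5%) of calibration points below it; binary maps are suitability ≥ τ.
- **Replicates and ensembles** — 10 bootstrap replicates summarized by
  per-cell median and range; future scenarios summarized as medians across
  GCM medians, with per-RCP uncertainty ranges and stability categories
  (stable / gain agreed by all GCMs / partial agreement / loss).
- **Partial ROC** — bootstrap AUC ratios restricted to sensitivity ≥ 1−E,
  with proportional predicted area standing in for 1−specificity; and an
  exact one-tailed cumulative binomial test of independent records.
- **Niche overlap** — Schoener's $D = 1 - \tfrac12\sum_i |p_{1i}-p_{2i}|$
  and Hellinger-derived $I = 1 - \tfrac12\sum_i(\sqrt{p_{1i}}-\sqrt{p_{2i}})^2$
  on normalized suitability surfaces, with the background-similarity
  randomization test (reject niche similarity if observed D or I falls
  below the 5th percentile of 100 background replicates).

## Worked example

```python
import vectorniche as vn
from scipy.stats import spearmanr

grid = vn.default_grid()                      # 100x120 cells, 0.5 degree
env, latent = vn.make_environment(grid, seed=42)
truth = vn.make_species(latent, vn.TrueNiche((0.0, 0.0), (1.0, 1.0)))

raw = vn.sample_occurrences(truth, n=400, seed=1, species="aedes_sim")
thinned = vn.thin_to_grid(vn.deduplicate(vn.filter_precision(raw)),
                          grid, env.valid_mask)
cal, eva = vn.split_calibration(thinned, 0.5, seed=2)

pca = vn.fit_pca(env)
pcs = vn.transform(env, pca, n_components=8)
models, reps = vn.fit_replicates(cal, pcs, n_replicates=10, seed=3)

tau, binary = vn.threshold_E(reps.median_map, cal, E=0.05)
proc = vn.partial_roc(reps.median_map, eva, n_iterations=1000, seed=4)

rho = spearmanr(reps.median_map.values[env.valid_mask],
                truth.values[env.valid_mask]).statistic
print(f"cleaning cascade: {raw.counts_log['raw']} raw -> {len(thinned)} thinned")
print(f"threshold tau = {tau.tau:.3f}, calibration omission = {tau.omission:.3f}")
print(f"pROC mean AUC ratio = {proc.mean:.2f} (p = {proc.p_value:.3g})")
print(f"true-niche recovery: Spearman rho = {rho:.3f}")
```

prints

```
cleaning cascade: 440 raw -> 357 thinned
threshold tau = 0.373, calibration omission = 0.045
pROC mean AUC ratio = 1.12 (p = 0)
true-niche recovery: Spearman rho = 0.987
```

The 400 sampled records arrive contaminated (10% exact duplicates, 10%
coordinate-rounded), so the cascade removes 83 of 440; the E=5% threshold
omits 4.5% of calibration points; the partial-ROC ratio sits well above the
null value of 1 in all 1000 bootstrap iterations; and the median of the 10
replicate models ranks the landscape almost exactly like the true niche.

The same analysis runs from the shell: `vectorniche pipeline --seed 7
--outdir run/` (add `--quick` for a reduced grid), with `simulate`, `prep`,
`pca`, `fit`, `threshold`, `evaluate` available as individual stages. Each
run directory contains suitability/binary/stability GeoTIFFs, cleaned
occurrence CSVs, `results.json` and a `manifest.json` recording parameters
and seeds.

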