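# honeyjsdm

Hurdle joint species distribution modelling of honey metagenomes.

Honey is an archive of a bee colony's interactions: shotgun sequencing
("genome skimming") of honey DNA yields read counts for the plant, bacterial,
fungal and viral genera a colony contacted. `honeyjsdm` turns such
genus × sample count tables — collected under a hierarchical apiary design
(beekeepers → hives → sites, sampled repeatedly over a season) — into
estimates of how much of each genus's occurrence and abundance is driven by
the time of season, sequencing effort, and the crossed random imprints of
sample, site, hive and beekeeper, and into a posterior network of which
genera co-occur in time.

## The model

Relative read abundance (RRA) is zero-inflated, so a hurdle pair of joint
species distribution models shares one explanatory structure:

* **Occurrence**: multivariate probit,
  `P(y_ij = 1) = Φ(x_i' β_j + Σ_l η_l[u_l(i)]' λ_lj)`
* **Abundance given presence**: Gaussian on `z_ij = log RRA_ij`, with
  per-genus residual variance σ²_j.

Fixed effects `x_i` are the sampling period (June as reference; July = T2,
August = T3 indicators) and centred log total reads. Genus coefficients
β_j are shrunk toward trait-group expectations (taxonomic and functional
groups) via a linear trait regression Γ with inverse-Wishart covariance V.
Each random level l (sample, site, hive, beekeeper) is a latent-factor
term: factors η over units, loadings λ over genera, with multiplicative
gamma shrinkage on the loadings; site factors are spatially correlated
with an exponential kernel `exp(−d/ρ)` whose range ρ is sampled over a
grid. Fitting is by a blocked Gibbs sampler (Albert–Chib augmentation for
the probit part).

Post-fit, the package computes

* **variance partitioning** — per genus, the fraction of explained
  variance due to time, sequencing depth, and each random level;
* **fit metrics** — Tjur R² and AUC (occurrence), R² (abundance),
  explanatory and via twofold cross-validation predictive;
* **seasonal trends** — fixed-effects-only occurrence probabilities per
  time point, with `increase`/`decrease` calls at ≥95% posterior
  probability that August exceeds (falls below) June;
* **temporal co-occurrence** — `Ω_{j1,j2} = β_T2,j1 β_T2,j2 + β_T3,j1 β_T3,j2`
  per posterior draw, with pairwise sign calls at ≥90% posterior
  probability.

Before modelling, counts pass the conservative filtering chain used for
diet metabarcoding data: blank-control subtraction, removal of cells below
0.001% within-sample RRA, removal of genera below 0.01% mean RRA, optional
removal of dominant taxa (renormalising), and a 5% prevalence filter.

A synthetic-data module (`honeyjsdm.simulate`) generates datasets from the
exact generative structure above — 14 beekeepers, 41 hives, 30 sites,
3 time points, ≈115 samples, log-normal depths, multinomial read
allocation, optional single-taxon dominance spikes and blank contamination
— with known ground truth, so every stage is testable end to end.

## Worked example

```python
import honeyjsdm as hj
from honeyjsdm.model import ModelSpec, McmcSchedule, build_fixed_design
from honeyjsdm.postfit import variance_partition, predict_seasonal, omega

ds = hj.simulate_dataset(n_genera=40, seed=1)
occ, ab, log = hj.run_filter_chain(ds.counts, ds.samples, blank=ds.blank)
sched = McmcSchedule(n_chains=2, n_iterations=1500, n_burnin=500, thin=2)
spec = ModelSpec()
d_occ = hj.fit_occurrence(occ.Y, ds.samples, ds.traits, spec, sched, seed=11)

X, _ = build_fixed_design(ds.samples.loc[occ.Y.columns], spec)
vp = variance_partition(d_occ, X, ds.traits)
print((vp.fractions.mean(axis=0) * 100).round(1))
```

prints the mean variance fractions (percent) across the 40 genera:

```
time                 9.8
total_reads          2.5
random_sample       33.8
random_site         26.1
random_hive         12.4
random_beekeeper    15.4
```

i.e. under the generator's defaults the season accounts for ~10% of the
explained variance while the crossed random structure dominates — the
sample level most, as it absorbs residual genus-to-genus association.
Continuing,

```python
trends = predict_seasonal(d_occ)
print(trends.trend_call.value_counts().to_dict())
#> {'none': 24, 'decrease': 14, 'increase': 2}
print(len(omega(d_occ).edge_list()))
#> 156
```

classifies each genus's seasonal occurrence trend at the 95% rule and
counts genus pairs with statistically supported (90%) temporal
co-occurrence. The same analysis runs from the shell:

```bash
honeyjsdm simulate --out-dir data --seed 1
honeyjsdm preprocess --counts data/counts.tsv --samples data/samples.csv \
    --blank data/blank.tsv --out-dir filtered
honeyjsdm fit --responses-dir filtered --samples data/samples.csv \
    --traits data/traits.csv --out-dir fitted
honeyjsdm postfit --draws-dir fitted --responses-dir filtered \
    --samples data/samples.csv --traits data/traits.csv --out-dir reports
```

or end to end from a YAML config with `honeyjsdm run --config pipeline.yaml`.

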