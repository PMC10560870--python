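# Methods

This note documents the statistical model, the sampler, the synthetic-data
generator, the numerical choices, and what the test suite does and does
not establish.

## Data model and filtering

The observable is a genus × sample table of integer read counts from
shotgun-sequenced honey, with a sample metadata table (beekeeper, hive,
site with planar coordinates, time point ∈ {June, July, August}, total
reads) and a genus trait table (taxonomic group; functional group).
Counts are compositional: only relative read abundance (RRA), a genus's
count divided by the sample total, carries meaning.

Filtering proceeds in a fixed order, each step recorded in a JSON filter
log:

1. **Blank subtraction.** Reads seen in the extraction blank are
   subtracted per genus from every sample, clamped at zero. The blank is
   applied uniformly across samples (no per-sample scaling).
2. **Cellwise rarity.** Cells with within-sample RRA strictly below
   0.001% are zeroed (tag jumping / misassignment removal).
3. **Genus inclusion.** Genera whose unweighted mean RRA across samples
   (recomputed after step 2) is below 0.01% are dropped; genera at or
   above the threshold are kept. The mean is over per-sample RRAs, not
   pooled reads.
4. **Dominant taxa.** For abundance analyses, named dominant genera
   (defaults: *Apilactobacillus*, *Zygosaccharomyces*, AmFV — taxa that
   can reach >85% of a sample's reads) are removed and RRA renormalised,
   so their blooms do not distort every other genus's proportions.
   Occurrence analyses keep all genera.
5. **Prevalence.** Genera present in strictly fewer than 5% of samples
   are excluded from both models.

Removal thresholds are strict inequalities and the inclusion threshold is
inclusive, matching the usual phrasing of these rules ("< 0.001%",
"≥ 0.01%", "less than 5%"). All filters are idempotent, and removing
dominants from counts commutes with computing RRA on the subset.

The hurdle responses are then `Y = (RRA > 0)` and `Z = ln RRA` where
present (natural log; the base only rescales abundance coefficients).

## The hurdle JSDM

For sample i and genus j, with one shared explanatory structure:

```
L_ij   = x_i' β_j + Σ_l η_l[u_l(i)]' λ_l[:, j]
y_ij   ~ Bernoulli(Φ(L_ij))                     (occurrence, probit)
z_ij   ~ N(L_ij, σ²_j)   on cells with y=1     (abundance, log-normal)
```

* `x_i`: intercept, July (T2) and August (T3) indicators with June (T1)
  the reference level, and log total reads centred on its mean over the
  modelled samples. Centring leaves seasonal contrasts, variance
  fractions, predictions at mean depth and Ω unchanged; it only
  decorrelates the intercept from the depth slope (log reads is ≈14 with
  small spread, so the uncentred design is nearly collinear).
* `β_j ~ N(Γ' t_j, V)` with `t_j` the genus's trait design (intercept +
  one-hot taxonomic and functional groups, reference levels dropped);
  entries of Γ have independent N(0, 100) priors and
  `V ~ InvWishart(K + 2, I)`.
* Each random level (sample, site, hive, beekeeper) contributes latent
  factors `η` over its units and loadings `λ` over genera. Factors are
  standard normal; loadings carry the Bhattacharya–Dunson multiplicative
  gamma process (local precisions ψ ~ Ga(ν/2, ν/2) with ν = 3; column
  multipliers δ₁ ~ Ga(2, 1), δ_h ~ Ga(3, 1)) with a fixed maximum of
  2 factors per level (configurable). The sample-level term is what
  encodes residual genus-to-genus association; it is retained in fitting
  and marginalised at prediction.
* The site level is spatially explicit: each factor is a zero-mean
  Gaussian field over sites with exponential correlation `exp(−d/ρ)`;
  ρ has a discrete uniform prior over a 12-point geometric grid from 2%
  to 100% of the maximum inter-site distance.
* `σ²_j ~ InvGamma(2, 1)` (abundance only).

All prior settings are implementation defaults surfaced in
`honeyjsdm.gibbs.Priors`, not field-measured quantities. Setting
`gamma_fixed` / `v_fixed` freezes the trait hierarchy, reducing the
coefficient prior to a plain normal — used by the conjugate-sub-case
oracle tests and available for fixed-effect-only fits.

### Gibbs sweep

One sweep updates, in this fixed order: truncated-normal liabilities
(probit only, Albert–Chib) → β (per-genus conjugate normal, batched) →
Γ (conjugate normal on vec(Γ)) → V (inverse-Wishart) → per level: factors
(conjugate normal per unit; one joint solve across units for the spatial
level), loadings, shrinkage precisions, spatial range (grid Gibbs) →
σ² (inverse gamma). Missing abundance cells contribute nothing to any
sufficient statistic (they are never imputed: "conditional on presence"
defines the support). Chains are seeded from one `SeedSequence`, so a
seed plus a schedule reproduces every draw bit for bit.

Retained draws follow `floor((iterations − burn-in)/thin)` per chain; the
published-scale schedule (4 × 375,000, burn-in 125,000, thin 1000 → 250
per chain, 1000 total) is exercised as an accounting check, while the
desk-scale default for tests is 2–4 chains × 1,500–3,000 sweeps. At the
packaged problem sizes (30–60 genera, 100–150 samples — large enough for
parameter recovery, small enough for minutes-scale runs) the full crossed
model mixes well within that budget (max β PSRF ≈ 1.1 in the shipped
checks).

Latent-factor models are rotation-invariant, so raw loadings and factors
are never compared across runs; only identified functionals are reported
(linear predictors, loading Gram matrices λ'λ, variance fractions,
predictions).

### Convergence

`psrf` implements the classic Gelman–Rubin estimator
`sqrt(((n−1)/n W + B/n)/W)` per scalar parameter; `convergence_report`
tabulates it over β (and σ²). It requires ≥2 chains; duplicated identical
chains give `sqrt((n−1)/n)` ≈ 1 by construction.

## Post-fit quantities

* **Variance partition.** Per draw and genus: the time block contributes
  the empirical variance over samples of `X_time β_time,j`, the depth
  block likewise, and each random level contributes `Σ_f λ²_lfj` (unit
  marginal factor variance, also under the spatial kernel). Contributions
  are normalised per draw and averaged over draws, so fractions are
  nonnegative and sum to one per genus; group summaries average fractions
  over taxonomic / functional groups. Cross-covariance between fixed
  blocks is not attributed (season and depth are near-orthogonal by
  design).
* **Metrics.** Tjur R² = mean predicted probability over presences minus
  over absences; AUC with ties counted half (via scikit-learn, checked
  against pairwise brute force); abundance R² = squared Pearson
  correlation of observed and predicted log RRA over present cells.
  Genera with a single observed class are flagged NaN and excluded from
  averages with a logged count.
* **Explanatory vs predictive power.** Explanatory metrics use
  predictions on the fitted data with random effects at their estimated
  values. Predictive metrics use twofold cross-validation with samples
  (the substrate units) assigned to folds uniformly at random; held-out
  samples' sample-level effects — and any other unit unseen in training —
  are marginalised over their prior, turning Φ(lp) into
  Φ(lp/√(1 + λ'λ)). This is why sample-level structure inflates
  explanatory but not predictive power.
* **Hurdle combination.** For unconditional expected RRA the two models
  predict simultaneously: `P(presence) · exp(lp + σ²/2)`
  (`expected_rra`); conditional metrics are evaluated on presence-only
  cells to match the abundance model's definition.
* **Seasonal trends.** Fixed effects only, with centred log depth held at
  0 (the mean-depth sample): per draw, `Φ(β₀ + β_t)` for each time point.
  `p_increase` is the posterior probability that the August probability
  exceeds June's (exact ties split half-half); calls are `increase` at
  ≥95% and `decrease` at ≤5%, the symmetric tail.
* **Temporal co-occurrence.** Per draw,
  `Ω = outer(β_T2, β_T2) + outer(β_T3, β_T3)`; the posterior mean, the
  sign probabilities, and ±1 calls where either reaches 90%. The diagonal
  is a sum of squares, hence nonnegative in every draw; the vectorised
  path is tested against a brute-force pair/draw loop to 1e-12.

## The synthetic-data generator

`simulate_dataset` draws, in order: a design (14 beekeepers with 3 hives
each but one with 2 → 41 hives; 30 sites, every site hosting ≥1 hive;
3 time points; scheduled hive × time samples dropped independently at
rate 0.065, landing near the 115 realised samples of a season-long
campaign; per-sample depths log-normal, median 10⁶ reads, σ_log 0.6), a
trait table (taxonomic weights ≈ 0.41/0.37/0.19/0.03 for
plants/bacteria/fungi/viruses; plants split into nectar/no-nectar,
microbes into six functional classes), ground-truth parameters, and
counts.

Truth: trait-group expectations γ per predictor (occurrence intercepts
centred at −0.4, seasonal effects spread 0.6 across groups, depth slope
0.15 ± 0.1) plus genus-level noise (variance 0.25 for intercept/season,
0.01 for the depth slope, which multiplies a covariate of spread ~0.6);
independent factor realisations per level with scales 0.5 (sample) / 0.3
(site, hive, beekeeper) and 2 factors; spatial range 30 on a 100 × 100
site plane; abundance residual variance 0.5. The dropout rate (not
reported for the real campaign) and these effect scales are the
generator's definition of "realistic": they produce genus prevalences
spanning ~5–95%, seasonal trends for a minority of genera, and
random-structure-dominated variance partitions.

Counts are produced by multinomial allocation of each sample's depth over
per-genus expected weights `y_ij · exp(z_ij)` — the simplest mechanism
that yields compositional, depth-dependent integer data. Optional
dominance spikes multiply one genus's weight in randomly chosen samples
(emulating single-taxon blooms reaching ~99% of reads); optional
contamination adds a small weight to named genera in every sample plus a
Poisson blank-control vector.

**Closure and identifiability.** Renormalisation removes any per-sample
constant from log RRA, so absolute abundance levels (intercepts, and the
common component of seasonal shifts in the normaliser) are not
identifiable from RRA. The generator therefore also exposes the
pre-closure latent responses (`latent_Y`, `latent_Z`); abundance-model
parameter recovery is assessed against `latent_Z` (the quantity the model
actually parameterises), while occurrence recovery and all qualitative
structure (variance dominance, guild sign calls, trend classification)
run through the full count path. What passing recovery tests show is that
the sampler recovers the parameters of its own generative law at realistic
scale; they do not certify the unidentifiable absolute-abundance levels of
real compositional data, nor features the generator omits (taxonomic
misassignment, non-exponential spatial structure, within-season
phenology finer than three time points, genus-specific residual variance
heterogeneity).

## Numerical choices and degenerate inputs

* Truncated-normal draws use inverse-CDF sampling with arguments clipped
  to [1e-13, 1−1e-13]; spatial kernels get a 1e-8 diagonal jitter before
  Cholesky.
* Batched precision-form MVN sampling (`x = μ + L⁻ᵀ z`) over genera and
  units; the spatial level solves one (units × factors) system per sweep.
* An all-zero sample column is an error naming the sample; a genus with
  <2 observed abundance cells is rejected with advice to exclude it;
  rank-deficient fixed designs and non-binary occurrence matrices are
  rejected up front. A fold that loses both classes for a genus yields
  NaN metrics for that genus, excluded from averages.
* Exact ties in the seasonal comparison and in AUC are counted half.
* Seeds: every public entry point takes one integer seed;
  internal sub-seeds are spawned deterministically and kept below 2³¹.

## Known limitations

* Priors are stated defaults, not a reimplementation of any particular
  package's defaults; posterior equivalence with other JSDM software is
  statistical, not draw-for-draw.
* The number of latent factors is a fixed small maximum (shrinkage prunes
  surplus columns) rather than adaptively truncated.
* No phylogenetic correlation structure; traits enter only through the
  group-level regression.
* Cross-validation folds samples; folding hives or sites would test
  spatial transferability instead and is not implemented.
* The spatial-range grid is coarse (12 points); range estimates are
  correspondingly coarse, though predictions are insensitive to this.
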