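"""Model specification and fitting interface for the hurdle JSDM pair.

The community of genera detected in honey is modelled with two joint
species distribution models sharing one explanatory structure:

* a multivariate probit model for presence-absence, and
* a Gaussian model for log relative read abundance conditional on presence.

Fixed effects are the sampling period (June reference, July and August
indicators) and log total reads per sample (sequencing effort). Genus
coefficients are shrunk toward trait-group expectations (taxonomic and
functional groups) through a linear trait regression with an
inverse-Wishart coefficient covariance. Crossed random effects for sample,
site, hive and beekeeper are modelled as latent factors with
multiplicative-gamma loading shrinkage; the site level is spatially
explicit with an exponential correlation kernel over site coordinates,
its range sampled over a discrete grid. Posterior sampling is by a blocked
Gibbs sampler (see :mod:`honeyjsdm.gibbs`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gibbs import GibbsSampler, LevelData, PosteriorDraws, Priors

__all__ = [
    "RandomLevel",
    "ModelSpec",
    "McmcSchedule",
    "Priors",
    "PosteriorDraws",
    "retained_draws",
    "build_fixed_design",
    "build_trait_design",
    "build_levels",
    "fit_occurrence",
    "fit_abundance",
    "psrf",
    "convergence_report",
]

FIXED_PREDICTORS = ("intercept", "T2", "T3", "log_total_reads")


@dataclass
class RandomLevel:
    """One crossed random level: its grouping column and factor settings.

    ``column=None`` denotes the sample level (one unit per sample).
    """

    name: str
    column: "str | None" = None
    spatial: bool = False
    n_factors: int = 2


def default_random_levels() -> "list[RandomLevel]":
    return [
        RandomLevel("sample", None),
        RandomLevel("site", "site", spatial=True),
        RandomLevel("hive", "hive"),
        RandomLevel("beekeeper", "beekeeper"),
    ]


@dataclass
class ModelSpec:
    """Explanatory structure shared by the occurrence and abundance models."""

    season_col: str = "timepoint"
    timepoints: tuple = ("June", "July", "August")
    depth_col: str = "total_reads"
    trait_cols: tuple = ("taxonomic_group", "functional_group")
    random_levels: "list[RandomLevel]" = field(default_factory=default_random_levels)
    priors: Priors = field(default_factory=Priors)


@dataclass
class McmcSchedule:
    """Chains x iterations bookkeeping; thinning applies after burn-in."""

    n_chains: int = 4
    n_iterations: int = 3000
    n_burnin: int = 1000
    thin: int = 4

    def validate(self) -> None:
        if self.n_burnin >= self.n_iterations:
            raise ValueError("burn-in must be smaller than the iteration count")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


def retained_draws(schedule: McmcSchedule) -> dict:
    """Number of posterior draws the schedule retains.

    ``per_chain = floor((n_iterations - n_burnin) / thin)`` and the total is
    per-chain times the number of chains; e.g. 4 chains of 375,000
    iterations with 125,000 burn-in thinned by 1,000 retain 250 draws per
    chain, 1,000 in total.
    """
    schedule.validate()
    per_chain = (schedule.n_iterations - schedule.n_burnin) // schedule.thin
    return {"per_chain": per_chain, "total": per_chain * schedule.n_chains}


def build_fixed_design(samples: pd.DataFrame, spec: ModelSpec):
    """Per-sample fixed design: intercept, T2/T3 indicators, log depth.

    Log total reads is centred on its mean over the modelled samples, so
    the intercept is the liability at average sequencing depth; centring
    leaves seasonal contrasts, variance fractions and co-occurrence
    statistics unchanged while decorrelating intercept and depth slope.
    """
    tps = spec.timepoints
    bad = set(samples[spec.season_col]) - set(tps)
    if bad:
        raise ValueError(f"unknown timepoint label(s): {sorted(bad)}")
    n = len(samples)
    X = np.ones((n, 4))
    X[:, 1] = (samples[spec.season_col] == tps[1]).to_numpy(float)
    X[:, 2] = (samples[spec.season_col] == tps[2]).to_numpy(float)
    logd = np.log(samples[spec.depth_col].astype(float).to_numpy())
    X[:, 3] = logd - logd.mean()
    return X, list(FIXED_PREDICTORS)


def build_trait_design(traits: pd.DataFrame, spec: ModelSpec):
    """Per-genus trait design: intercept + one-hot groups (reference dropped)."""
    cols = [c for c in spec.trait_cols if c in traits.columns]
    parts = [pd.Series(1.0, index=traits.index, name="intercept")]
    for c in cols:
        dummies = pd.get_dummies(traits[c], prefix=c, drop_first=True, dtype=float)
        parts.append(dummies)
    design = pd.concat(parts, axis=1)
    return design.to_numpy(float), list(design.columns)


def build_levels(samples: pd.DataFrame, spec: ModelSpec) -> "list[LevelData]":
    levels = []
    for rl in spec.random_levels:
        if rl.column is None:
            units = samples.index.to_numpy()
        else:
            units = samples[rl.column].to_numpy()
        uniq, idx = np.unique(units, return_inverse=True)
        coords = None
        rho_grid = None
        if rl.spatial:
            coord_cols = [f"{rl.column}_x", f"{rl.column}_y"]
            coords = (
                samples.drop_duplicates(subset=[rl.column])
                .set_index(rl.column)
                .loc[uniq, coord_cols]
                .to_numpy(float)
            )
            d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
            dmax = d.max()
            if dmax == 0:
                raise ValueError(f"spatial level '{rl.name}' has identical coordinates")
            rho_grid = np.geomspace(0.02, 1.0, spec.priors.n_rho_grid) * dmax
        levels.append(
            LevelData(
                name=rl.name,
                idx=idx,
                unit_ids=[str(u) for u in uniq],
                n_factors=rl.n_factors,
                coords=coords,
                rho_grid=rho_grid,
            )
        )
    return levels


def _align(resp: pd.DataFrame, samples: pd.DataFrame, traits: "pd.DataFrame | None"):
    if not resp.columns.isin(samples.index).all():
        raise ValueError("response columns not all present in sample metadata")
    meta = samples.loc[resp.columns]
    if traits is None:
        traits = pd.DataFrame(index=resp.index)
    else:
        missing = resp.index.difference(traits.index)
        if len(missing):
            raise ValueError(f"traits missing for genera: {list(missing)[:5]}")
        traits = traits.loc[resp.index]
    return meta, traits


def fit_occurrence(
    Y: pd.DataFrame,
    samples: pd.DataFrame,
    traits: "pd.DataFrame | None",
    spec: ModelSpec,
    schedule: McmcSchedule,
    seed: int = 0,
) -> PosteriorDraws:
    """Fit the multivariate probit occurrence model by Gibbs sampling.

    ``Y`` is a binary genus x sample matrix (already prevalence-filtered);
    rows of ``samples`` supply the fixed design and random-level units.
    """
    arr = Y.to_numpy(float)
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError("Y must be binary")
    meta, traits = _align(Y, samples, traits)
    X, xnames = build_fixed_design(meta, spec)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    T, tnames = build_trait_design(traits, spec)
    levels = build_levels(meta, spec)
    sampler = GibbsSampler(
        kind="probit", Y=arr.T, X=X, T=T, levels=levels,
        priors=spec.priors, schedule=schedule,
    )
    draws = sampler.run(seed)
    draws.predictors = xnames
    draws.trait_predictors = tnames
    draws.genus_ids = list(Y.index)
    draws.sample_ids = list(Y.columns)
    return draws


def fit_abundance(
    Z: pd.DataFrame,
    samples: pd.DataFrame,
    traits: "pd.DataFrame | None",
    spec: ModelSpec,
    schedule: McmcSchedule,
    seed: int = 0,
) -> PosteriorDraws:
    """Fit the Gaussian log-abundance-given-presence model.

    ``Z`` holds log RRA where the genus is present and NaN elsewhere;
    missing cells contribute nothing to the likelihood. Each genus must
    retain at least two observed cells.
    """
    arr = Z.to_numpy(float)
    n_obs = np.isfinite(arr).sum(axis=1)
    if (n_obs < 2).any():
        bad = list(Z.index[n_obs < 2])
        raise ValueError(
            f"genus(era) with <2 observed cells: {bad}; exclude them "
            "(e.g. via prevalence_filter) before fitting the abundance model"
        )
    meta, traits = _align(Z, samples, traits)
    X, xnames = build_fixed_design(meta, spec)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    T, tnames = build_trait_design(traits, spec)
    levels = build_levels(meta, spec)
    sampler = GibbsSampler(
        kind="gaussian", Y=arr.T, X=X, T=T, levels=levels,
        priors=spec.priors, schedule=schedule,
    )
    draws = sampler.run(seed)
    draws.predictors = xnames
    draws.trait_predictors = tnames
    draws.genus_ids = list(Z.index)
    draws.sample_ids = list(Z.columns)
    return draws


def psrf(x: np.ndarray, chain: np.ndarray) -> np.ndarray:
    """Gelman-Rubin potential scale reduction factor per scalar parameter.

    ``x`` has draws on the first axis, ``chain`` labels each draw's chain.
    Computed as sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B the between-chain variance of chain means. Requires at
    least two chains with at least two draws each.
    """
    x = np.asarray(x, float)
    chain = np.asarray(chain)
    labels = np.unique(chain)
    if len(labels) < 2:
        raise ValueError("PSRF needs >= 2 chains (or use a split-chain variant)")
    per_chain = [x[chain == c] for c in labels]
    n = min(len(p) for p in per_chain)
    if n < 2:
        raise ValueError("PSRF needs >= 2 draws per chain")
    per_chain = np.stack([p[:n] for p in per_chain])   # (m, n, ...)
    W = per_chain.var(axis=1, ddof=1).mean(axis=0)
    means = per_chain.mean(axis=1)
    B_over_n = means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(var_plus / W)
    return np.where(W > 0, out, 1.0)


def convergence_report(draws: PosteriorDraws) -> pd.DataFrame:
    """PSRF summary over genus coefficients (and residual variances)."""
    rows = []
    r_beta = psrf(draws.beta, draws.chain)
    for k, pname in enumerate(draws.predictors):
        for j, g in enumerate(draws.genus_ids):
            rows.append({"parameter": "beta", "predictor": pname,
                         "genus": g, "psrf": r_beta[k, j]})
    if draws.sigma2 is not None:
        r_s = psrf(draws.sigma2, draws.chain)
        for j, g in enumerate(draws.genus_ids):
            rows.append({"parameter": "sigma2", "predictor": "",
                         "genus": g, "psrf": r_s[j]})
    return pd.DataFrame(rows)
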