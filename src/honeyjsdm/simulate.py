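"""Synthetic honey-metagenome generator with known ground truth.

Emulates the post-annotation genus x sample count tables produced by
genome skimming of honey collected under a hierarchical apiary design:
beekeepers manage one or more hives, hives sit at georeferenced sites, and
each hive is sampled at up to three time points over the season (June,
July, August), with some scheduled samples missing.

The generative model mirrors the analysis model exactly:

* occurrence of genus j in sample i is Bernoulli(Phi(L_ij)) with
  L = X beta_occ + sum_levels scale_l * eta_l[unit(i)] @ lambda_l,
* conditional log-abundance is the analogous Gaussian linear predictor
  plus N(0, sigma2_j) noise,
* genus coefficients beta_j are drawn around a trait-group expectation
  (gamma) with genus-level spread sigma2_beta, so taxonomic/functional
  groups share seasonal tendencies,
* site-level latent factors are spatially correlated with an exponential
  kernel exp(-d / range),
* reads are allocated by a multinomial draw of the sample's log-normally
  distributed total depth over the per-genus expected weights
  (occurrence x exp(log-abundance)), which makes the data compositional
  and depth-dependent;
* optional dominance spikes multiply one genus's weight in randomly chosen
  samples (mimicking single-taxon blooms reaching ~99% of reads), and
  optional low-level contamination adds a small weight to a few genera in
  every sample along with a matching blank-control count vector.

Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

__all__ = [
    "DesignSpec",
    "TruthConfig",
    "TruthParams",
    "SyntheticDataset",
    "generate_design",
    "make_traits",
    "draw_truth",
    "generate_counts",
    "simulate_dataset",
]

PREDICTORS = ("intercept", "T2", "T3", "log_total_reads")
LEVELS = ("sample", "site", "hive", "beekeeper")


@dataclass
class DesignSpec:
    """Study design: who keeps which hive where, and when honey is drawn.

    Defaults reproduce the scale of the field campaign the generator
    emulates: 14 beekeepers, 41 hives, 30 sites, 3 monthly time points,
    with enough dropout to land near 115 realised samples.
    """

    n_beekeepers: int = 14
    hives_per_beekeeper: "int | list[int] | None" = None
    n_sites: int = 30
    site_coords: "np.ndarray | None" = None  # (n_sites, 2), arbitrary units
    timepoints: tuple = ("June", "July", "August")
    missingness_rate: float = 0.065
    depth_median: float = 1.0e6
    depth_sigma_log: float = 0.6

    def hive_counts(self) -> np.ndarray:
        if self.hives_per_beekeeper is None:
            # 13 x 3 + 1 x 2 = 41 hives
            counts = [3] * (self.n_beekeepers - 1) + [2]
        elif np.isscalar(self.hives_per_beekeeper):
            counts = [int(self.hives_per_beekeeper)] * self.n_beekeepers
        else:
            counts = list(self.hives_per_beekeeper)
            if len(counts) != self.n_beekeepers:
                raise ValueError("hives_per_beekeeper list length != n_beekeepers")
        return np.asarray(counts, dtype=int)

    def validate(self) -> None:
        if len(self.timepoints) < 2:
            raise ValueError("need at least 2 time points")
        if not 0 <= self.missingness_rate < 1:
            raise ValueError("missingness_rate must be in [0, 1)")
        if self.hive_counts().sum() < self.n_sites:
            raise ValueError(
                f"n_sites={self.n_sites} exceeds number of hives "
                f"({self.hive_counts().sum()}); no assignment rule exists"
            )


def generate_design(spec: DesignSpec, seed: int) -> pd.DataFrame:
    """Realise the sampling design as one row per obtained sample.

    Hive-to-beekeeper and hive-to-site assignments are fixed across time
    points; every site hosts at least one hive; scheduled hive x time
    samples are dropped independently with ``missingness_rate``. Columns:
    beekeeper, hive, site, site_x, site_y, timepoint, total_reads.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    counts = spec.hive_counts()
    n_hives = int(counts.sum())

    beekeepers = [f"B{b + 1:02d}" for b in range(spec.n_beekeepers)]
    hives = [f"H{h + 1:02d}" for h in range(n_hives)]
    hive_keeper = np.repeat(np.arange(spec.n_beekeepers), counts)

    if spec.site_coords is not None:
        coords = np.asarray(spec.site_coords, dtype=float)
        if coords.shape != (spec.n_sites, 2):
            raise ValueError("site_coords must have shape (n_sites, 2)")
    else:
        coords = rng.uniform(0.0, 100.0, size=(spec.n_sites, 2))

    # every site gets at least one hive; surplus hives assigned at random
    order = rng.permutation(n_hives)
    hive_site = np.empty(n_hives, dtype=int)
    hive_site[order[: spec.n_sites]] = np.arange(spec.n_sites)
    if n_hives > spec.n_sites:
        hive_site[order[spec.n_sites:]] = rng.integers(
            0, spec.n_sites, size=n_hives - spec.n_sites
        )

    rows = []
    for h in range(n_hives):
        for t, tp in enumerate(spec.timepoints):
            if rng.random() < spec.missingness_rate:
                continue
            s = hive_site[h]
            rows.append(
                {
                    "sample": f"{hives[h]}-T{t + 1}",
                    "beekeeper": beekeepers[hive_keeper[h]],
                    "hive": hives[h],
                    "site": f"S{s + 1:02d}",
                    "site_x": coords[s, 0],
                    "site_y": coords[s, 1],
                    "timepoint": tp,
                }
            )
    frame = pd.DataFrame(rows).set_index("sample")
    mu = np.log(spec.depth_median)
    depths = rng.lognormal(mean=mu, sigma=spec.depth_sigma_log, size=len(frame))
    frame["total_reads"] = np.maximum(depths.round().astype(np.int64), 1)
    return frame


def make_traits(
    n_genera: int,
    seed: int = 0,
    taxonomic_groups: tuple = ("plant", "bacterium", "fungus", "virus"),
    taxonomic_weights: tuple = (0.41, 0.37, 0.19, 0.03),
    functional_groups: tuple = (
        "nectar_producing",
        "no_nectar_producing",
        "bee_gut",
        "beehive",
        "bee_pathogen",
        "plant_pathogen",
        "neutral_or_positive",
        "animal_pathogen",
    ),
) -> pd.DataFrame:
    """Draw a genus trait table (taxonomic group + functional group).

    Plants receive one of the two nectar classes; microbes one of the six
    microbial functional classes. Group weights default to the rough
    taxonomic composition of a honey metagenome (plants and bacteria
    dominant, a handful of viral groups).
    """
    rng = np.random.default_rng(seed)
    tax = rng.choice(taxonomic_groups, size=n_genera, p=np.asarray(taxonomic_weights))
    # ensure every taxonomic group is realised so trait designs are full rank
    for k, g in enumerate(taxonomic_groups):
        if g not in tax and n_genera >= len(taxonomic_groups):
            tax[k] = g
    func = np.empty(n_genera, dtype=object)
    plant_classes = functional_groups[:2]
    microbe_classes = functional_groups[2:]
    for i, t in enumerate(tax):
        if t == "plant":
            func[i] = rng.choice(plant_classes)
        else:
            func[i] = rng.choice(microbe_classes)
    genera = [f"Genus{i + 1:03d}" for i in range(n_genera)]
    return pd.DataFrame(
        {"taxonomic_group": tax, "functional_group": func},
        index=pd.Index(genera, name="genus"),
    )


@dataclass
class TruthConfig:
    """Hyper-settings for drawing ground-truth parameters.

    ``gamma_mean``/``gamma_sd`` give, per fixed predictor, the centre and
    spread of the trait-group expectations of the genus coefficients;
    ``sigma2_beta`` is the genus-level variance around that expectation.
    ``level_scales`` multiply the latent-factor contribution of each random
    level; a scale of 0 switches the level off. ``dominance`` maps genus id
    to a (log-spike, probability) pair; ``blank_rates`` maps genus id to an
    expected blank read count, with a matching relative contamination
    weight added to every sample.
    """

    gamma_mean: dict = field(default_factory=lambda: {
        "intercept": -0.4, "T2": 0.0, "T3": 0.0, "log_total_reads": 0.15})
    gamma_sd: dict = field(default_factory=lambda: {
        "intercept": 0.6, "T2": 0.6, "T3": 0.6, "log_total_reads": 0.1})
    gamma_mean_abund: dict = field(default_factory=lambda: {
        "intercept": 0.0, "T2": 0.0, "T3": 0.0, "log_total_reads": 0.0})
    gamma_sd_abund: dict = field(default_factory=lambda: {
        "intercept": 1.0, "T2": 0.5, "T3": 0.5, "log_total_reads": 0.1})
    # genus-level coefficient variance around the trait expectation, per
    # predictor; the depth slope (per unit centred log-reads) spreads less
    sigma2_beta: dict = field(default_factory=lambda: {
        "intercept": 0.25, "T2": 0.25, "T3": 0.25, "log_total_reads": 0.01})
    sigma2_beta_abund: dict = field(default_factory=lambda: {
        "intercept": 0.25, "T2": 0.25, "T3": 0.25, "log_total_reads": 0.01})
    n_factors: int = 2
    level_scales: dict = field(default_factory=lambda: {
        "sample": 0.5, "site": 0.3, "hive": 0.3, "beekeeper": 0.3})
    spatial_range: float = 30.0
    sigma2_resid: float = 0.5
    dominance: "dict | None" = None
    blank_rates: "dict | None" = None
    gamma_occ_fixed: "np.ndarray | None" = None  # (Q, K) override, row per group
    gamma_abund_fixed: "np.ndarray | None" = None


@dataclass
class TruthParams:
    """Ground-truth parameters of one synthetic dataset."""

    genus_ids: list
    predictors: tuple
    beta_occ: np.ndarray        # (K, J)
    beta_abund: np.ndarray      # (K, J)
    gamma_occ: np.ndarray       # (Q, K) trait-group expectations
    gamma_abund: np.ndarray
    trait_groups: list          # row labels of gamma
    sigma2_beta: "dict | float"
    loadings_occ: dict          # level -> (F, J)
    loadings_abund: dict
    level_scales: dict
    spatial_range: float
    sigma2_resid: np.ndarray    # (J,)
    dominance: "dict | None"
    blank_rates: "dict | None"

    def to_dict(self) -> dict:
        return {
            "genus_ids": list(self.genus_ids),
            "predictors": list(self.predictors),
            "beta_occ": self.beta_occ.tolist(),
            "beta_abund": self.beta_abund.tolist(),
            "gamma_occ": self.gamma_occ.tolist(),
            "gamma_abund": self.gamma_abund.tolist(),
            "trait_groups": list(self.trait_groups),
            "sigma2_beta": self.sigma2_beta,
            "loadings_occ": {k: v.tolist() for k, v in self.loadings_occ.items()},
            "loadings_abund": {k: v.tolist() for k, v in self.loadings_abund.items()},
            "level_scales": dict(self.level_scales),
            "spatial_range": self.spatial_range,
            "sigma2_resid": self.sigma2_resid.tolist(),
            "dominance": self.dominance,
            "blank_rates": self.blank_rates,
        }


def draw_truth(
    spec: DesignSpec,
    traits: pd.DataFrame,
    config: "TruthConfig | None" = None,
    seed: int = 0,
) -> TruthParams:
    """Draw ground-truth coefficients with trait-structured seasonal effects.

    Genus coefficients are the trait-group expectation (``gamma``) plus
    N(0, sigma2_beta) genus noise, independently for the occurrence and
    abundance processes, so that genera of one taxonomic group share
    seasonal tendencies while still varying individually.
    """
    cfg = config or TruthConfig()
    rng = np.random.default_rng(seed)
    genera = list(traits.index)
    J = len(genera)
    if J == 0:
        raise ValueError("traits table is empty")
    groups = list(dict.fromkeys(traits["taxonomic_group"]))
    if any(traits["taxonomic_group"].value_counts().get(g, 0) == 0 for g in groups):
        raise ValueError("empty trait group")
    group_idx = np.array([groups.index(g) for g in traits["taxonomic_group"]])
    Q, K = len(groups), len(PREDICTORS)

    def _sigma_vec(s2):
        if np.isscalar(s2):
            return np.full(K, float(s2))
        return np.array([s2[p] for p in PREDICTORS], float)

    def _draw(mean, sd, fixed, s2):
        if fixed is not None:
            gamma = np.asarray(fixed, dtype=float)
            if gamma.shape != (Q, K):
                raise ValueError(f"fixed gamma must have shape {(Q, K)}")
        else:
            gamma = np.column_stack([
                rng.normal(mean[p], sd[p], size=Q) for p in PREDICTORS
            ])
        spread = np.sqrt(_sigma_vec(s2))
        beta = gamma[group_idx].T + spread[:, None] * rng.standard_normal((K, J))
        return gamma, beta

    gamma_occ, beta_occ = _draw(cfg.gamma_mean, cfg.gamma_sd,
                                cfg.gamma_occ_fixed, cfg.sigma2_beta)
    gamma_ab, beta_ab = _draw(cfg.gamma_mean_abund, cfg.gamma_sd_abund,
                              cfg.gamma_abund_fixed, cfg.sigma2_beta_abund)

    F = cfg.n_factors
    loadings_occ = {lv: rng.normal(0.0, 1.0, size=(F, J)) for lv in LEVELS}
    loadings_ab = {lv: rng.normal(0.0, 1.0, size=(F, J)) for lv in LEVELS}
    return TruthParams(
        genus_ids=genera,
        predictors=PREDICTORS,
        beta_occ=beta_occ,
        beta_abund=beta_ab,
        gamma_occ=gamma_occ,
        gamma_abund=gamma_ab,
        trait_groups=groups,
        sigma2_beta=cfg.sigma2_beta,
        loadings_occ=loadings_occ,
        loadings_abund=loadings_ab,
        level_scales=dict(cfg.level_scales),
        spatial_range=cfg.spatial_range,
        sigma2_resid=np.full(J, cfg.sigma2_resid),
        dominance=cfg.dominance,
        blank_rates=cfg.blank_rates,
    )


@dataclass
class SyntheticDataset:
    """Counts, design, traits, blank vector and the truth that produced them.

    ``latent_Y`` and ``latent_Z`` hold the pre-closure responses: the true
    occurrence indicators and the Gaussian log-abundance linear predictor
    plus noise *before* per-sample renormalisation and multinomial read
    allocation. Absolute abundance levels are not identifiable from
    relative read abundances (closure removes any per-sample constant), so
    parameter-recovery checks of the abundance model are run against these
    latent responses, while the count table exercises the full
    compositional pipeline.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    traits: pd.DataFrame
    blank: pd.Series
    truth: TruthParams
    latent_Y: pd.DataFrame
    latent_Z: pd.DataFrame


def _design_matrix(samples: pd.DataFrame, timepoints) -> np.ndarray:
    """Matches the analysis design: log depth centred over the samples."""
    n = len(samples)
    X = np.ones((n, 4))
    X[:, 1] = (samples["timepoint"] == timepoints[1]).to_numpy(float)
    X[:, 2] = (samples["timepoint"] == timepoints[2]).to_numpy(float)
    logd = np.log(samples["total_reads"].astype(float).to_numpy())
    X[:, 3] = logd - logd.mean()
    return X


def _draw_factors(samples, truth, rng):
    """Per-level latent factor realisations; site factors spatially correlated."""
    F = next(iter(truth.loadings_occ.values())).shape[0]
    effects = {}
    for lv in LEVELS:
        units = samples[lv].to_numpy() if lv != "sample" else samples.index.to_numpy()
        uniq, idx = np.unique(units, return_inverse=True)
        if lv == "site":
            coords = (
                samples.drop_duplicates(subset=["site"])
                .set_index("site")
                .loc[uniq, ["site_x", "site_y"]]
                .to_numpy()
            )
            d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
            if truth.spatial_range <= 0:
                raise ValueError("spatial_range must be > 0")
            C = np.exp(-d / truth.spatial_range)
            L = np.linalg.cholesky(C + 1e-10 * np.eye(len(uniq)))
            eta = L @ rng.standard_normal((len(uniq), F))
        else:
            eta = rng.standard_normal((len(uniq), F))
        effects[lv] = (eta, idx)
    return effects


def generate_counts(
    design: pd.DataFrame,
    truth: TruthParams,
    seed: int = 0,
    traits: "pd.DataFrame | None" = None,
    timepoints: tuple = ("June", "July", "August"),
) -> SyntheticDataset:
    """Realise genus counts from the hurdle generative model.

    Occurrence and conditional log-abundance are drawn from their linear
    predictors (sharing the design but with independent factor
    realisations); per-sample reads are then allocated multinomially over
    the expected weights, so each sample's counts sum exactly to its drawn
    depth. Dominance spikes and blank contamination apply if specified in
    the truth.
    """
    rng = np.random.default_rng(seed)
    if (design["total_reads"] <= 0).any():
        raise ValueError("total_reads must be positive")
    J = len(truth.genus_ids)
    n = len(design)
    X = _design_matrix(design, timepoints)

    occ_fac = _draw_factors(design, truth, rng)
    ab_fac = _draw_factors(design, truth, rng)

    def _random_part(fac, loadings):
        R = np.zeros((n, J))
        for lv in LEVELS:
            s = truth.level_scales.get(lv, 0.0)
            if s == 0.0:
                continue
            eta, idx = fac[lv]
            R += s * eta[idx] @ loadings[lv]
        return R

    lp_occ = X @ truth.beta_occ + _random_part(occ_fac, truth.loadings_occ)
    Y = (rng.random((n, J)) < ndtr(lp_occ)).astype(np.int8)

    lp_ab = X @ truth.beta_abund + _random_part(ab_fac, truth.loadings_abund)
    Z = lp_ab + rng.normal(0.0, np.sqrt(truth.sigma2_resid)[None, :], size=(n, J))

    weights = np.where(Y == 1, np.exp(Z), 0.0)

    if truth.dominance:
        for g, (log_spike, prob) in truth.dominance.items():
            j = truth.genus_ids.index(g)
            hit = rng.random(n) < prob
            weights[hit, j] = np.maximum(weights[hit, j], 1e-3) * np.exp(log_spike)

    # low-level contamination enters each sample's weight pool so the
    # multinomial depth constraint still holds exactly
    blank = pd.Series(0, index=pd.Index(truth.genus_ids, name="genus"), dtype=int)
    if truth.blank_rates:
        row_tot = weights.sum(axis=1)
        ref = np.median(row_tot[row_tot > 0]) if (row_tot > 0).any() else 1.0
        for g, rate in truth.blank_rates.items():
            j = truth.genus_ids.index(g)
            # contamination RRA on the order of rate / depth_median
            weights[:, j] += ref * rate / 1e4
            blank.loc[g] = rng.poisson(rate)

    row_tot = weights.sum(axis=1)
    dead = row_tot == 0
    if dead.any():  # pathological corner: nothing present, spread depth evenly
        weights[dead] = 1.0
        row_tot = weights.sum(axis=1)
    probs = weights / row_tot[:, None]

    depths = design["total_reads"].to_numpy()
    counts = np.empty((n, J), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(depths[i], probs[i])

    counts_df = pd.DataFrame(
        counts.T, index=pd.Index(truth.genus_ids, name="genus"), columns=design.index
    )
    if traits is None:
        traits = pd.DataFrame(index=pd.Index(truth.genus_ids, name="genus"))
    latent_Y = pd.DataFrame(Y.T, index=counts_df.index, columns=design.index)
    latent_Z = pd.DataFrame(
        np.where(Y == 1, Z, np.nan).T, index=counts_df.index, columns=design.index
    )
    return SyntheticDataset(
        counts=counts_df, samples=design, traits=traits, blank=blank,
        truth=truth, latent_Y=latent_Y, latent_Z=latent_Z,
    )


def simulate_dataset(
    n_genera: int = 50,
    spec: "DesignSpec | None" = None,
    config: "TruthConfig | None" = None,
    seed: int = 0,
) -> SyntheticDataset:
    """One-call simulation: design, traits, truth, counts.

    Sub-seeds for the design, trait, truth and count draws are spawned
    deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    spec = spec or DesignSpec()
    design = generate_design(spec, int(ss[0]))
    traits = make_traits(n_genera, seed=int(ss[1]))
    truth = draw_truth(spec, traits, config=config, seed=int(ss[2]))
    return generate_counts(design, truth, seed=int(ss[3]), traits=traits,
                           timepoints=spec.timepoints)
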