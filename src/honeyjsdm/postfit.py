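"""Post-fit statistics: variance partitioning, fit metrics, cross-validation,
seasonal occurrence trends, and the temporal co-occurrence matrix.

All quantities are computed from retained posterior draws, never from a
single point estimate, and all operate on identified functionals (linear
predictors, loading Gram matrices), which are invariant to the rotational
non-identifiability of raw factors and loadings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr
from sklearn.metrics import roc_auc_score

from .gibbs import PosteriorDraws
from .model import McmcSchedule, ModelSpec, build_fixed_design, fit_abundance, fit_occurrence

__all__ = [
    "VariancePartition",
    "SeasonalPrediction",
    "OmegaSummary",
    "variance_partition",
    "group_variance_table",
    "tjur_r2",
    "auc",
    "r2_linear",
    "predict_occurrence_prob",
    "predict_abundance_mean",
    "expected_rra",
    "evaluate_fit",
    "cross_validate",
    "predict_seasonal",
    "omega",
]

FIXED_BLOCKS = {"time": ("T2", "T3"), "total_reads": ("log_total_reads",)}


# ---------------------------------------------------------------------------
# variance partitioning

@dataclass
class VariancePartition:
    """Per-genus variance fractions plus group-averaged summaries."""

    fractions: pd.DataFrame            # genus x component, rows sum to 1
    by_taxonomic_group: "pd.DataFrame | None" = None
    by_functional_group: "pd.DataFrame | None" = None


def variance_partition(
    draws: PosteriorDraws,
    X: np.ndarray,
    traits: "pd.DataFrame | None" = None,
    blocks: "dict | None" = None,
) -> VariancePartition:
    """Partition each genus's explained variance over predictors and levels.

    Per draw and genus, the fixed-effect blocks contribute the empirical
    variance of their sub-predictor over samples, and each random level
    contributes its latent-factor variance, the sum of squared loadings
    (factors have unit marginal variance, also for the spatial kernel).
    Contributions are normalised to fractions per draw, then averaged over
    draws, so fractions are >= 0 and sum to 1 for every genus.
    """
    blocks = blocks or FIXED_BLOCKS
    names = list(draws.predictors)
    D, K, J = draws.beta.shape
    covX = np.cov(np.asarray(X, float).T, ddof=0)
    parts = {}
    for bname, cols in blocks.items():
        kidx = [names.index(c) for c in cols]
        missing_all = set(cols) - set(names)
        if missing_all:
            raise ValueError(f"block '{bname}' names absent from design: {missing_all}")
        sub = covX[np.ix_(kidx, kidx)]
        b = draws.beta[:, kidx, :]                      # (D, k, J)
        parts[bname] = np.einsum("dkj,kl,dlj->dj", b, sub, b)
    for name, lev in draws.levels.items():
        parts[f"random_{name}"] = (lev.loadings**2).sum(axis=1)   # (D, J)

    comp_names = list(parts)
    stacked = np.stack([parts[c] for c in comp_names], axis=-1)   # (D, J, C)
    total = stacked.sum(axis=-1, keepdims=True)
    if (total == 0).any():
        raise ValueError("a genus has zero total variance in some draw")
    fractions = (stacked / total).mean(axis=0)                    # (J, C)
    frame = pd.DataFrame(fractions, index=pd.Index(draws.genus_ids, name="genus"),
                         columns=comp_names)

    vp = VariancePartition(fractions=frame)
    if traits is not None:
        for col, attr in (("taxonomic_group", "by_taxonomic_group"),
                          ("functional_group", "by_functional_group")):
            if col in traits.columns:
                grouped = frame.groupby(traits.loc[frame.index, col]).mean()
                setattr(vp, attr, grouped)
    return vp


def group_variance_table(vp: VariancePartition) -> pd.DataFrame:
    """Mean variance fractions (percent): components as rows, one column per
    taxonomic / functional group plus an all-genera total."""
    cols = {"Total": vp.fractions.mean(axis=0)}
    for grouped in (vp.by_taxonomic_group, vp.by_functional_group):
        if grouped is not None:
            for g, row in grouped.iterrows():
                cols[str(g)] = row
    return (pd.DataFrame(cols) * 100.0).round(2)


# ---------------------------------------------------------------------------
# fit metrics

def _as_2d(a) -> np.ndarray:
    arr = np.asarray(a, float)
    return arr[None, :] if arr.ndim == 1 else arr


def tjur_r2(Y, P) -> np.ndarray:
    """Tjur's discrimination coefficient per genus.

    Mean predicted probability over presences minus the mean over absences;
    NaN for genera with a single observed class.
    """
    Y, P = _as_2d(Y), _as_2d(P)
    out = np.full(Y.shape[0], np.nan)
    for j in range(Y.shape[0]):
        y, p = Y[j], P[j]
        ok = np.isfinite(p)
        y, p = y[ok], p[ok]
        if 0 < y.sum() < len(y):
            out[j] = p[y == 1].mean() - p[y == 0].mean()
    return out


def auc(Y, P) -> np.ndarray:
    """Area under the ROC curve per genus (ties count one half).

    NaN for genera missing either class.
    """
    Y, P = _as_2d(Y), _as_2d(P)
    out = np.full(Y.shape[0], np.nan)
    for j in range(Y.shape[0]):
        y, p = Y[j], P[j]
        ok = np.isfinite(p)
        y, p = y[ok], p[ok]
        if 0 < y.sum() < len(y):
            out[j] = roc_auc_score(y, p)
    return out


def r2_linear(Z_obs, Z_pred) -> np.ndarray:
    """Squared Pearson correlation of observed vs predicted log abundance,
    over observed (present) cells only; NaN when degenerate."""
    Z_obs, Z_pred = _as_2d(Z_obs), _as_2d(Z_pred)
    out = np.full(Z_obs.shape[0], np.nan)
    for j in range(Z_obs.shape[0]):
        ok = np.isfinite(Z_obs[j]) & np.isfinite(Z_pred[j])
        if ok.sum() < 2:
            continue
        zo, zp = Z_obs[j][ok], Z_pred[j][ok]
        if zo.std() == 0 or zp.std() == 0:
            continue
        out[j] = np.corrcoef(zo, zp)[0, 1] ** 2
    return out


# ---------------------------------------------------------------------------
# posterior predictions

def _linear_predictor(draws, X, level_units, d_slice):
    """Fixed + random linear predictor for a slice of draws; unseen units
    contribute zero mean and extra variance (returned separately)."""
    beta = draws.beta[d_slice]                      # (d, K, J)
    lp = np.einsum("ik,dkj->dij", X, beta)          # (d, n, J)
    n = X.shape[0]
    extra_var = np.zeros((len(beta), n, lp.shape[2]))
    for name, lev in draws.levels.items():
        units = level_units.get(name) if level_units else None
        lam = lev.loadings[d_slice]                 # (d, F, J)
        if units is None:
            units = np.full(n, -1)
        units = np.asarray(units)
        seen = units >= 0
        if seen.any():
            eta = lev.eta[d_slice]                  # (d, U, F)
            lp[:, seen, :] += np.einsum(
                "duf,dfj->duj", eta[:, units[seen], :], lam
            )
        if (~seen).any():
            v = (lam**2).sum(axis=1)                # (d, J)
            extra_var[:, ~seen, :] += v[:, None, :]
    return lp, extra_var


def predict_occurrence_prob(
    draws: PosteriorDraws, X, level_units=None, chunk: int = 200
) -> np.ndarray:
    """Posterior mean occurrence probability per sample x genus.

    ``level_units[name]`` gives each sample's unit index into the level's
    fitted units, with -1 for units unseen at fit time; unseen units are
    marginalised over their standard-normal factor prior, which turns
    Phi(lp) into Phi(lp / sqrt(1 + sum_f lambda_f^2)).
    """
    D = draws.n_draws
    acc = None
    for start in range(0, D, chunk):
        sl = slice(start, min(start + chunk, D))
        lp, ev = _linear_predictor(draws, np.asarray(X, float), level_units, sl)
        p = ndtr(lp / np.sqrt(1.0 + ev))
        acc = p.sum(axis=0) if acc is None else acc + p.sum(axis=0)
    return acc / D


def predict_abundance_mean(
    draws: PosteriorDraws, X, level_units=None, chunk: int = 200
) -> np.ndarray:
    """Posterior mean of the log-abundance linear predictor per sample x genus."""
    D = draws.n_draws
    acc = None
    for start in range(0, D, chunk):
        sl = slice(start, min(start + chunk, D))
        lp, _ = _linear_predictor(draws, np.asarray(X, float), level_units, sl)
        acc = lp.sum(axis=0) if acc is None else acc + lp.sum(axis=0)
    return acc / D


def expected_rra(
    draws_occ: PosteriorDraws, draws_ab: PosteriorDraws, X,
    level_units=None,
) -> np.ndarray:
    """Hurdle-combined unconditional expectation on the RRA scale.

    The two models predict simultaneously: occurrence probability times the
    log-normal mean exp(lp + sigma2/2). Useful for ranking; conditional
    metrics use the presence-only predictions instead.
    """
    P = predict_occurrence_prob(draws_occ, X, level_units)
    D = draws_ab.n_draws
    acc = None
    for start in range(0, D, 200):
        sl = slice(start, min(start + 200, D))
        lp, ev = _linear_predictor(draws_ab, np.asarray(X, float), level_units, sl)
        s2 = draws_ab.sigma2[sl][:, None, :]
        m = np.exp(lp + 0.5 * (s2 + ev))
        acc = m.sum(axis=0) if acc is None else acc + m.sum(axis=0)
    return P * acc / D


def _seen_level_units(draws: PosteriorDraws) -> dict:
    """Unit assignment of the fitting samples themselves (explanatory use)."""
    return {name: lev.sample_assignment for name, lev in draws.levels.items()}


def evaluate_fit(
    draws_occ: "PosteriorDraws | None",
    draws_ab: "PosteriorDraws | None",
    Y: "pd.DataFrame | None",
    Z: "pd.DataFrame | None",
    samples: pd.DataFrame,
    spec: ModelSpec,
) -> pd.DataFrame:
    """Explanatory power: metrics of predictions made on the fitted data,
    with all random effects at their estimated values."""
    out = {}
    if draws_occ is not None:
        X, _ = build_fixed_design(samples.loc[Y.columns], spec)
        P = predict_occurrence_prob(draws_occ, X, _seen_level_units(draws_occ))
        out["tjur_r2"] = pd.Series(tjur_r2(Y.to_numpy(), P.T), index=Y.index)
        out["auc"] = pd.Series(auc(Y.to_numpy(), P.T), index=Y.index)
    if draws_ab is not None:
        X, _ = build_fixed_design(samples.loc[Z.columns], spec)
        Zhat = predict_abundance_mean(draws_ab, X, _seen_level_units(draws_ab))
        out["r2"] = pd.Series(r2_linear(Z.to_numpy(), Zhat.T), index=Z.index)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# cross-validation

def _map_units(draws: PosteriorDraws, samples: pd.DataFrame, spec: ModelSpec) -> dict:
    """Map new samples onto the fitted units of each level; -1 = unseen."""
    level_units = {}
    for rl in spec.random_levels:
        if rl.name not in draws.levels:
            continue
        lev = draws.levels[rl.name]
        lookup = {u: k for k, u in enumerate(lev.unit_ids)}
        if rl.column is None:
            vals = samples.index
        else:
            vals = samples[rl.column]
        level_units[rl.name] = np.array([lookup.get(str(v), -1) for v in vals])
    return level_units


def cross_validate(
    Y: pd.DataFrame,
    Z: "pd.DataFrame | None",
    samples: pd.DataFrame,
    traits: "pd.DataFrame | None",
    spec: ModelSpec,
    schedule: McmcSchedule,
    n_folds: int = 2,
    seed: int = 0,
) -> dict:
    """Predictive power by k-fold cross-validation over samples.

    Samples are assigned to folds uniformly at random; each fold is
    predicted from models fitted to the remaining folds. Random effects of
    units absent from the training fold (always the held-out samples'
    sample-level effects) are marginalised over their priors. Genera whose
    held-out cells contain a single class get NaN metrics and are excluded
    from averages.

    Returns ``{"metrics": per-genus DataFrame, "fold": per-sample Series}``.
    """
    rng = np.random.default_rng(seed)
    sample_ids = list(Y.columns)
    perm = rng.permutation(len(sample_ids))
    fold = np.empty(len(sample_ids), dtype=int)
    for f in range(n_folds):
        fold[perm[f::n_folds]] = f
    fold = pd.Series(fold, index=sample_ids, name="fold")

    P_pred = pd.DataFrame(np.nan, index=Y.index, columns=Y.columns)
    Z_pred = pd.DataFrame(np.nan, index=Z.index, columns=Z.columns) if Z is not None else None

    for f in range(n_folds):
        train = fold.index[fold != f]
        test = fold.index[fold == f]
        meta_test = samples.loc[test]
        X_test, _ = build_fixed_design(meta_test, spec)

        y_train = Y[train]
        keep = (y_train.mean(axis=1) > 0) & (y_train.mean(axis=1) < 1)
        d_occ = fit_occurrence(y_train.loc[keep], samples, traits, spec, schedule,
                               seed=int(rng.integers(2**31)))
        P = predict_occurrence_prob(d_occ, X_test, _map_units(d_occ, meta_test, spec))
        P_pred.loc[keep, test] = P.T

        if Z is not None:
            z_train = Z[train]
            ok = np.isfinite(z_train).sum(axis=1) >= 2
            d_ab = fit_abundance(z_train.loc[ok], samples, traits, spec, schedule,
                                 seed=int(rng.integers(2**31)))
            Zhat = predict_abundance_mean(d_ab, X_test, _map_units(d_ab, meta_test, spec))
            Z_pred.loc[ok, test] = Zhat.T

    metrics = {
        "tjur_r2": pd.Series(tjur_r2(Y.to_numpy(), P_pred.to_numpy()), index=Y.index),
        "auc": pd.Series(auc(Y.to_numpy(), P_pred.to_numpy()), index=Y.index),
    }
    if Z is not None:
        metrics["r2"] = pd.Series(
            r2_linear(Z.to_numpy(), Z_pred.to_numpy()), index=Z.index
        )
    return {"metrics": pd.DataFrame(metrics), "fold": fold,
            "P_pred": P_pred, "Z_pred": Z_pred}


# ---------------------------------------------------------------------------
# seasonal trends

@dataclass
class SeasonalPrediction:
    """Fixed-effects-only occurrence probabilities per time point.

    ``p_increase`` is the posterior probability that the late-season
    (August) occurrence probability exceeds the early-season (June) one;
    the trend call is 'increase' at >= 0.95, 'decrease' at <= 0.05
    (the symmetric tail), 'none' otherwise.
    """

    occ_prob: pd.DataFrame             # genus x timepoint posterior means
    p_increase: pd.Series
    trend_call: pd.Series
    threshold: float = 0.95


def predict_seasonal(
    draws: PosteriorDraws,
    log_depth: float = 0.0,
    timepoints: tuple = ("June", "July", "August"),
    threshold: float = 0.95,
) -> SeasonalPrediction:
    """Seasonal occurrence trends from the fixed-effect part of the model.

    Per draw and genus the probit probability is evaluated for each time
    point with centred log total reads fixed at ``log_depth`` (0 = the
    sample-mean depth) and random effects excluded.
    """
    names = list(draws.predictors)
    for req in ("intercept", "T2", "T3", "log_total_reads"):
        if req not in names:
            raise ValueError(f"missing predictor in draws: {req}")
    b0 = draws.beta[:, names.index("intercept"), :]
    b2 = draws.beta[:, names.index("T2"), :]
    b3 = draws.beta[:, names.index("T3"), :]
    br = draws.beta[:, names.index("log_total_reads"), :]
    base = b0 + br * log_depth
    probs = np.stack([ndtr(base), ndtr(base + b2), ndtr(base + b3)])  # (3, D, J)

    # ties (exactly zero August effect) split half-half for symmetry
    p_inc = ((probs[2] > probs[0]).mean(axis=0)
             + 0.5 * (probs[2] == probs[0]).mean(axis=0))
    genus = pd.Index(draws.genus_ids, name="genus")
    call = np.where(p_inc >= threshold, "increase",
                    np.where(p_inc <= 1.0 - threshold, "decrease", "none"))
    return SeasonalPrediction(
        occ_prob=pd.DataFrame(probs.mean(axis=1).T, index=genus,
                              columns=list(timepoints)),
        p_increase=pd.Series(p_inc, index=genus, name="p_increase"),
        trend_call=pd.Series(call, index=genus, name="trend_call"),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# temporal co-occurrence matrix

@dataclass
class OmegaSummary:
    """Posterior summary of the temporal co-occurrence matrix.

    For genus pair (j1, j2), each draw contributes
    ``omega = bT2_j1 * bT2_j2 + bT3_j1 * bT3_j2``: positive when the two
    genera shift in the same seasonal direction, negative when opposite.
    ``sign_call`` is +1 / -1 where the posterior sign probability reaches
    the threshold (default 90%), else 0; the diagonal is a sum of squares
    and hence nonnegative in every draw.
    """

    omega_mean: pd.DataFrame
    p_pos: pd.DataFrame
    p_neg: pd.DataFrame
    sign_call: pd.DataFrame
    threshold: float = 0.90

    def edge_list(self) -> pd.DataFrame:
        g = list(self.omega_mean.index)
        rows = []
        sc = self.sign_call.to_numpy()
        om = self.omega_mean.to_numpy()
        pp = self.p_pos.to_numpy()
        for a in range(len(g)):
            for b in range(a + 1, len(g)):
                if sc[a, b] != 0:
                    rows.append({"genus_1": g[a], "genus_2": g[b],
                                 "omega_mean": om[a, b], "sign": int(sc[a, b]),
                                 "p_pos": pp[a, b]})
        return pd.DataFrame(rows, columns=["genus_1", "genus_2", "omega_mean",
                                           "sign", "p_pos"])


def omega(draws: PosteriorDraws, threshold: float = 0.90, chunk: int = 500) -> OmegaSummary:
    """Temporal co-occurrence matrix from the seasonal coefficients."""
    names = list(draws.predictors)
    J = len(draws.genus_ids)
    if J < 2:
        raise ValueError("omega needs at least 2 genera")
    b2 = draws.beta[:, names.index("T2"), :]
    b3 = draws.beta[:, names.index("T3"), :]
    D = b2.shape[0]
    s_mean = np.zeros((J, J))
    s_pos = np.zeros((J, J))
    s_neg = np.zeros((J, J))
    for start in range(0, D, chunk):
        sl = slice(start, min(start + chunk, D))
        om = (np.einsum("dj,dk->djk", b2[sl], b2[sl])
              + np.einsum("dj,dk->djk", b3[sl], b3[sl]))
        s_mean += om.sum(axis=0)
        s_pos += (om > 0).sum(axis=0)
        s_neg += (om < 0).sum(axis=0)
    genus = pd.Index(draws.genus_ids, name="genus")
    p_pos = s_pos / D
    p_neg = s_neg / D
    call = np.where(p_pos >= threshold, 1, np.where(p_neg >= threshold, -1, 0))
    return OmegaSummary(
        omega_mean=pd.DataFrame(s_mean / D, index=genus, columns=genus),
        p_pos=pd.DataFrame(p_pos, index=genus, columns=genus),
        p_neg=pd.DataFrame(p_neg, index=genus, columns=genus),
        sign_call=pd.DataFrame(call, index=genus, columns=genus),
        threshold=threshold,
    )
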