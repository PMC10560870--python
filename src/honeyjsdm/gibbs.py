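"""Blocked Gibbs sampler for the latent-factor probit / Gaussian JSDM.

Model, for sample i = 1..n and genus j = 1..J:

    L_ij = x_i' beta_j + sum_l eta_l[u_l(i)]' lambda_l[:, j]

* probit ("occurrence") likelihood: y_ij ~ Bernoulli(Phi(L_ij)), handled
  by Albert-Chib truncated-normal data augmentation with unit residual
  variance;
* Gaussian ("abundance") likelihood: z_ij ~ N(L_ij, sigma2_j), with
  missing cells simply excluded from every sufficient statistic.

Hierarchy: beta_j ~ N(Gamma' t_j, V) with a normal prior on the trait
regression Gamma and inverse-Wishart on V; per random level the factors
eta are standard normal over units (spatially correlated with an
exponential kernel for spatial levels, kernel range sampled over a
discrete grid) and the loadings lambda carry the multiplicative-gamma
shrinkage prior of Bhattacharya & Dunson; sigma2_j is inverse-gamma.

One sweep updates, in this fixed order: liabilities (probit only), beta,
Gamma, V, then per level factors / loadings / shrinkage / spatial range,
and finally residual variances (Gaussian only). Everything is vectorised
over genera and units; all randomness flows from one SeedSequence so runs
are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.special import ndtr, ndtri
from scipy.stats import invwishart

__all__ = ["Priors", "LevelData", "LevelDraws", "PosteriorDraws", "GibbsSampler"]


@dataclass
class Priors:
    """Hyperparameters; all are implementation defaults, surfaced in config.

    ``gamma_fixed`` / ``v_fixed`` freeze the trait regression and the
    coefficient covariance instead of sampling them, which reduces the
    coefficient prior to a plain fixed normal (useful for conjugate
    sub-case checks and for fixed-effect-only fits).
    """

    gamma_prior_var: float = 100.0   # prior variance of trait-regression entries
    v_nu0: "float | None" = None     # inverse-Wishart df; default K + 2
    v_s0_scale: float = 1.0          # inverse-Wishart scale = s0 * I
    shrink_nu: float = 3.0           # local shrinkage t-dof
    shrink_a1: float = 2.0           # first-column global shrinkage shape
    shrink_a2: float = 3.0           # later-column global shrinkage shape
    sigma_a: float = 2.0             # residual-variance inverse-gamma shape
    sigma_b: float = 1.0             # residual-variance inverse-gamma rate
    n_rho_grid: int = 12             # spatial-range grid resolution
    gamma_fixed: "np.ndarray | None" = None   # (Q, K)
    v_fixed: "np.ndarray | None" = None       # (K, K)


@dataclass
class LevelData:
    """A random level as seen by the sampler."""

    name: str
    idx: np.ndarray          # (n,) unit index per sample
    unit_ids: list
    n_factors: int
    coords: "np.ndarray | None" = None     # (n_units, 2) for spatial levels
    rho_grid: "np.ndarray | None" = None   # candidate kernel ranges

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def spatial(self) -> bool:
        return self.coords is not None


@dataclass
class LevelDraws:
    """Retained draws for one random level plus its unit bookkeeping."""

    name: str
    unit_ids: list
    sample_assignment: np.ndarray         # unit index per fitting sample
    loadings: np.ndarray                  # (D, F, J)
    eta: np.ndarray                       # (D, U, F)
    rho: "np.ndarray | None" = None       # (D,) spatial range, if spatial


@dataclass
class PosteriorDraws:
    """Retained MCMC draws of the full parameter set.

    Axes are (draw, ...) throughout; ``chain`` labels each draw's chain.
    Raw loadings and factors are rotation-dependent between runs; only
    identified functionals (linear predictors, loading Gram matrices,
    variance fractions, predictions) should be compared across fits.
    """

    kind: str
    beta: np.ndarray                      # (D, K, J)
    gamma: np.ndarray                     # (D, Q, K)
    V: np.ndarray                         # (D, K, K)
    sigma2: "np.ndarray | None"           # (D, J) for the Gaussian model
    levels: "dict[str, LevelDraws]"
    chain: np.ndarray                     # (D,)
    predictors: list = field(default_factory=list)
    trait_predictors: list = field(default_factory=list)
    genus_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def validate(self) -> None:
        if not np.isfinite(self.beta).all():
            raise ValueError("non-finite beta draws")
        if self.sigma2 is not None and (self.sigma2 <= 0).any():
            raise ValueError("non-positive residual variance draws")


def _sample_mvn_prec(P: np.ndarray, b: np.ndarray, rng) -> np.ndarray:
    """Draw from N(P^-1 b, P^-1) for a batch: P (J,K,K), b (J,K)."""
    L = np.linalg.cholesky(P)
    mean = np.linalg.solve(P, b[..., None])[..., 0]
    z = rng.standard_normal(b.shape)
    noise = np.linalg.solve(np.swapaxes(L, -1, -2), z[..., None])[..., 0]
    return mean + noise


def _truncated_liabilities(mu: np.ndarray, y: np.ndarray, rng) -> np.ndarray:
    """Albert-Chib step: w ~ N(mu, 1) truncated by the sign pattern of y."""
    a = ndtr(-mu)
    u = rng.random(mu.shape)
    p = np.where(y == 1.0, a + u * (1.0 - a), u * a)
    return mu + ndtri(np.clip(p, 1e-13, 1.0 - 1e-13))


class _LevelState:
    """Mutable per-chain state of one random level."""

    def __init__(self, data: LevelData, J: int, rng):
        self.data = data
        F, U = data.n_factors, data.n_units
        self.Lambda = 0.1 * rng.standard_normal((F, J))
        self.eta = np.zeros((U, F))
        self.psi = np.ones((F, J))
        self.delta = np.ones(F)
        self.rho_idx = (len(data.rho_grid) // 2) if data.spatial else None
        # per-unit mask row counts (likelihood weights) are accumulated on
        # the fly because sigma2 changes each sweep for the Gaussian model

    @property
    def tau(self) -> np.ndarray:
        return np.cumprod(self.delta)

    def contribution(self) -> np.ndarray:
        return self.eta[self.data.idx] @ self.Lambda


class GibbsSampler:
    """Fits one of the two hurdle components; see module docstring.

    Parameters
    ----------
    kind : "probit" or "gaussian".
    Y : (n, J) response; binary for probit, real with NaN for missing
        cells for gaussian.
    X : (n, K) fixed design.  T : (J, Q) trait design.
    levels : random levels (may be empty for fixed-effect-only fits).
    """

    def __init__(self, kind, Y, X, T, levels, priors, schedule):
        if kind not in ("probit", "gaussian"):
            raise ValueError(f"unknown model kind: {kind}")
        self.kind = kind
        self.X = np.asarray(X, float)
        self.T = np.asarray(T, float)
        self.n, self.K = self.X.shape
        self.J, self.Q = self.T.shape
        Y = np.asarray(Y, float)
        if Y.shape != (self.n, self.J):
            raise ValueError(f"response shape {Y.shape} != {(self.n, self.J)}")
        self.Y = Y
        self.mask = np.isfinite(Y) if kind == "gaussian" else np.ones_like(Y, bool)
        self.levels = levels
        self.priors = priors
        self.schedule = schedule
        schedule.validate()
        self.nu0 = priors.v_nu0 if priors.v_nu0 is not None else self.K + 2
        self.S0 = priors.v_s0_scale * np.eye(self.K)
        # spatial kernels are fixed given coordinates; factorise once per grid point
        self._spatial_cache = {}
        for lv in levels:
            if lv.spatial:
                d = np.linalg.norm(lv.coords[:, None] - lv.coords[None, :], axis=-1)
                entries = []
                for rho in lv.rho_grid:
                    C = np.exp(-d / rho) + 1e-8 * np.eye(lv.n_units)
                    L = np.linalg.cholesky(C)
                    Cinv = sla.cho_solve((L, True), np.eye(lv.n_units))
                    logdet = 2.0 * np.log(np.diag(L)).sum()
                    entries.append((Cinv, logdet))
                self._spatial_cache[lv.name] = entries

    # ----- per-sweep updates -------------------------------------------

    def _update_beta(self, W, R, Mw, state, rng):
        E = (W - R) * Mw
        A = np.einsum("ik,ij,il->jkl", self.X, Mw, self.X)
        Vinv = state["Vinv"]
        prior_mean = (self.T @ state["gamma"]).T          # (K, J)
        b = (self.X.T @ E).T + (Vinv @ prior_mean).T      # (J, K)
        P = A + Vinv[None]
        state["beta"] = _sample_mvn_prec(P, b, rng).T     # (K, J)

    def _update_gamma_V(self, state, rng):
        pri = self.priors
        B = state["beta"].T                               # (J, K)
        if pri.gamma_fixed is None:
            Vinv = state["Vinv"]
            TtT = self.T.T @ self.T
            P = np.kron(Vinv, TtT) + np.eye(self.K * self.Q) / pri.gamma_prior_var
            rhs = (self.T.T @ B @ Vinv).flatten(order="F")
            g = _sample_mvn_prec(P[None], rhs[None], rng)[0]
            state["gamma"] = g.reshape((self.Q, self.K), order="F")
        if pri.v_fixed is None:
            Eres = B - self.T @ state["gamma"]
            scale = self.S0 + Eres.T @ Eres
            V = invwishart.rvs(df=self.nu0 + self.J, scale=scale, random_state=rng)
            V = np.atleast_2d(V)
            state["V"] = V
            state["Vinv"] = np.linalg.inv(V)

    def _update_level(self, st: _LevelState, C, Mw, rng):
        """Factors, loadings, shrinkage and (if spatial) kernel range."""
        lv = st.data
        F, U, J = lv.n_factors, lv.n_units, self.J
        Lam = st.Lambda

        w_u = np.zeros((U, J))
        np.add.at(w_u, lv.idx, Mw)
        cw = np.zeros((U, J))
        np.add.at(cw, lv.idx, C * Mw)
        rhs = cw @ Lam.T                                  # (U, F)
        like_prec = np.einsum("fj,uj,gj->ufg", Lam, w_u, Lam)

        if lv.spatial:
            Cinv, _ = self._spatial_cache[lv.name][st.rho_idx]
            P = np.kron(Cinv, np.eye(F))
            for u in range(U):
                P[u * F:(u + 1) * F, u * F:(u + 1) * F] += like_prec[u]
            eta = _sample_mvn_prec(P[None], rhs.reshape(-1)[None], rng)[0]
            st.eta = eta.reshape(U, F)
            # discrete posterior over the range grid given the factors
            logp = np.empty(len(lv.rho_grid))
            for g, (Ci, logdet) in enumerate(self._spatial_cache[lv.name]):
                quad = np.einsum("uf,uv,vf->", st.eta, Ci, st.eta)
                logp[g] = -0.5 * (F * logdet + quad)
            logp -= logp.max()
            p = np.exp(logp)
            st.rho_idx = int(rng.choice(len(p), p=p / p.sum()))
        else:
            P = like_prec + np.eye(F)[None]
            st.eta = _sample_mvn_prec(P, rhs, rng)

        # loadings given factors, with per-element shrinkage precision
        Es = st.eta[lv.idx]                               # (n, F)
        A = np.einsum("if,ij,ig->jfg", Es, Mw, Es)
        tau = st.tau
        A += (st.psi * tau[:, None]).T[:, :, None] * np.eye(F)[None]
        b = (Es.T @ (C * Mw)).T                           # (J, F)
        st.Lambda = _sample_mvn_prec(A, b, rng).T         # (F, J)

        nu = self.priors.shrink_nu
        lam2 = st.Lambda**2
        st.psi = rng.gamma((nu + 1.0) / 2.0,
                           2.0 / (nu + tau[:, None] * lam2))
        a1, a2 = self.priors.shrink_a1, self.priors.shrink_a2
        for h in range(F):
            shape = (a1 if h == 0 else a2) + 0.5 * J * (F - h)
            tau_excl = st.tau / st.delta[h]
            rate = 1.0 + 0.5 * np.sum(
                tau_excl[h:] * (st.psi[h:] * lam2[h:]).sum(axis=1)
            )
            st.delta[h] = rng.gamma(shape, 1.0 / rate)

    # ----- main loop ---------------------------------------------------

    def run(self, seed: int) -> PosteriorDraws:
        sched = self.schedule
        per_chain = (sched.n_iterations - sched.n_burnin) // sched.thin
        D = per_chain * sched.n_chains
        K, J, Q = self.K, self.J, self.Q

        beta_d = np.empty((D, K, J))
        gamma_d = np.empty((D, Q, K))
        V_d = np.empty((D, K, K))
        sigma2_d = np.empty((D, J)) if self.kind == "gaussian" else None
        lev_d = {
            lv.name: LevelDraws(
                name=lv.name, unit_ids=lv.unit_ids, sample_assignment=lv.idx,
                loadings=np.empty((D, lv.n_factors, J)),
                eta=np.empty((D, lv.n_units, lv.n_factors)),
                rho=np.empty(D) if lv.spatial else None,
            )
            for lv in self.levels
        }
        chain_d = np.empty(D, dtype=int)

        seeds = np.random.SeedSequence(seed).spawn(sched.n_chains)
        pos = 0
        for c in range(sched.n_chains):
            rng = np.random.default_rng(seeds[c])
            pos = self._run_chain(rng, c, pos, per_chain, beta_d, gamma_d,
                                  V_d, sigma2_d, lev_d, chain_d)
        draws = PosteriorDraws(
            kind=self.kind, beta=beta_d, gamma=gamma_d, V=V_d,
            sigma2=sigma2_d, levels=lev_d, chain=chain_d,
        )
        draws.validate()
        return draws

    def _run_chain(self, rng, c, pos, per_chain, beta_d, gamma_d, V_d,
                   sigma2_d, lev_d, chain_d):
        pri = self.priors
        sched = self.schedule
        state = {
            "beta": np.zeros((self.K, self.J)),
            "gamma": (np.array(pri.gamma_fixed, float)
                      if pri.gamma_fixed is not None
                      else np.zeros((self.Q, self.K))),
            "V": (np.array(pri.v_fixed, float)
                  if pri.v_fixed is not None else np.eye(self.K)),
        }
        state["Vinv"] = np.linalg.inv(state["V"])
        lstates = [_LevelState(lv, self.J, rng) for lv in self.levels]
        sigma2 = np.ones(self.J)
        W = self.Y.copy() if self.kind == "gaussian" else np.zeros_like(self.Y)
        if self.kind == "gaussian":
            W[~self.mask] = 0.0
        n_obs = self.mask.sum(axis=0)

        kept = 0
        for t in range(sched.n_iterations):
            contribs = [ls.contribution() for ls in lstates]
            R = sum(contribs) if contribs else np.zeros_like(W)
            XB = self.X @ state["beta"]

            if self.kind == "probit":
                W = _truncated_liabilities(XB + R, self.Y, rng)
                Mw = self.mask.astype(float)
            else:
                Mw = self.mask / sigma2[None, :]

            self._update_beta(W, R, Mw, state, rng)
            XB = self.X @ state["beta"]
            self._update_gamma_V(state, rng)

            for li, ls in enumerate(lstates):
                others = sum(
                    (contribs[m] for m in range(len(lstates)) if m != li),
                    np.zeros_like(W),
                )
                Cres = W - XB - others
                self._update_level(ls, Cres, Mw, rng)
                contribs[li] = ls.contribution()

            if self.kind == "gaussian":
                R = sum(contribs) if contribs else np.zeros_like(W)
                resid2 = np.where(self.mask, (W - XB - R) ** 2, 0.0).sum(axis=0)
                a_post = pri.sigma_a + 0.5 * n_obs
                b_post = pri.sigma_b + 0.5 * resid2
                sigma2 = b_post / rng.gamma(a_post, 1.0)

            if t >= sched.n_burnin and (t - sched.n_burnin + 1) % sched.thin == 0:
                if kept < per_chain:
                    beta_d[pos] = state["beta"]
                    gamma_d[pos] = state["gamma"]
                    V_d[pos] = state["V"]
                    if sigma2_d is not None:
                        sigma2_d[pos] = sigma2
                    for ls in lstates:
                        ld = lev_d[ls.data.name]
                        ld.loadings[pos] = ls.Lambda
                        ld.eta[pos] = ls.eta
                        if ld.rho is not None:
                            ld.rho[pos] = ls.data.rho_grid[ls.rho_idx]
                    chain_d[pos] = c
                    pos += 1
                    kept += 1
        return pos
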