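"""Sampler correctness, schedule accounting and convergence diagnostics."""

import numpy as np
import pytest
from scipy.special import ndtr

import honeyjsdm as hj
from honeyjsdm.gibbs import GibbsSampler, Priors
from honeyjsdm.model import (
    McmcSchedule,
    ModelSpec,
    fit_abundance,
    fit_occurrence,
    psrf,
    retained_draws,
)
from honeyjsdm.simulate import LEVELS, PREDICTORS


class TestRetainedDraws:
    @pytest.mark.parametrize(
        "sched,per_chain,total",
        [
            (McmcSchedule(4, 375_000, 125_000, 1000), 250, 1000),
            (McmcSchedule(1, 100, 0, 1), 100, 100),
            (McmcSchedule(2, 1000, 500, 10), 50, 100),
        ],
    )
    def test_accounting(self, sched, per_chain, total):
        out = retained_draws(sched)
        assert out == {"per_chain": per_chain, "total": total}

    def test_burnin_must_be_smaller(self):
        with pytest.raises(ValueError, match="burn-in"):
            retained_draws(McmcSchedule(1, 100, 100, 1))


@pytest.fixture(scope="module")
def no_random_fit():
    """Shared recovery fit on data generated without random structure."""
    cfg = hj.TruthConfig(level_scales={lv: 0.0 for lv in LEVELS})
    ds = hj.simulate_dataset(
        n_genera=40, spec=hj.DesignSpec(missingness_rate=0.0), config=cfg, seed=7
    )
    occ, _, _ = hj.run_filter_chain(ds.counts, ds.samples)
    spec = ModelSpec(random_levels=[])
    sched = McmcSchedule(2, 1500, 500, 2)
    d_occ = fit_occurrence(occ.Y, ds.samples, ds.traits, spec, sched, seed=3)
    Z = ds.latent_Z.loc[occ.Y.index]
    d_ab = fit_abundance(Z, ds.samples, ds.traits, spec, sched, seed=4)
    return ds, occ, d_occ, d_ab


class TestGibbsCorrectness:
    def test_intercept_only_probit_matches_integration_oracle(self):
        """Albert-Chib Gibbs vs exact 1-parameter posterior by quadrature."""
        rng = np.random.default_rng(0)
        n = 200
        y = (rng.random(n) < 0.5).astype(float)[:, None]
        pri = Priors(gamma_fixed=np.array([[0.0]]), v_fixed=np.array([[100.0]]))
        sched = McmcSchedule(2, 4000, 500, 1)
        d = GibbsSampler("probit", y, np.ones((n, 1)), np.ones((1, 1)),
                         [], pri, sched).run(11)
        phi = ndtr(d.beta[:, 0, 0])

        grid = np.linspace(-1.5, 1.5, 20001)
        logpost = (np.log(ndtr(grid)) * y.sum()
                   + np.log(ndtr(-grid)) * (n - y.sum())
                   - 0.5 * grid**2 / 100.0)
        w = np.exp(logpost - logpost.max())
        oracle = float((ndtr(grid) * w).sum() / w.sum())

        import arviz as az

        ess = float(az.ess(phi.reshape(2, -1)))
        mcse = phi.std() / np.sqrt(ess)
        assert abs(phi.mean() - oracle) < 3 * mcse

    def test_reduces_to_genuswise_ml_without_random_effects(self, no_random_fit):
        """With random scales zero the joint fit matches per-genus probit ML."""
        import statsmodels.api as sm

        ds, occ, d_occ, _ = no_random_fit
        from honeyjsdm.model import build_fixed_design

        X, _ = build_fixed_design(ds.samples.loc[occ.Y.columns], ModelSpec())
        post_mean = d_occ.beta.mean(axis=0)
        prev = occ.Y.mean(axis=1).to_numpy()
        usable = (prev > 0.2) & (prev < 0.8)  # avoid quasi-separated genera
        diffs = []
        for j in np.flatnonzero(usable)[:10]:
            ml = sm.Probit(occ.Y.iloc[j].to_numpy(), X).fit(disp=0)
            diffs.append(post_mean[:, j] - ml.params)
        assert np.abs(np.mean(diffs, axis=0)).max() < 0.25

    def test_gaussian_noiseless_concentrates_on_truth(self):
        rng = np.random.default_rng(1)
        n, J = 120, 3
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        beta = rng.standard_normal((2, J))
        Z = X @ beta + 1e-2 * rng.standard_normal((n, J))
        sched = McmcSchedule(2, 800, 300, 1)
        d = GibbsSampler("gaussian", Z, X, np.ones((J, 1)), [],
                         Priors(), sched).run(5)
        assert np.abs(d.beta.mean(axis=0) - beta).max() < 0.05
        assert d.sigma2.mean() < 0.5  # well below the prior mean b/(a-1)=1

    def test_identical_seeds_identical_draws(self):
        cfg = hj.TruthConfig()
        ds = hj.simulate_dataset(n_genera=10, config=cfg, seed=2)
        occ, _, _ = hj.run_filter_chain(ds.counts, ds.samples)
        spec = ModelSpec()
        sched = McmcSchedule(2, 200, 50, 2)
        a = fit_occurrence(occ.Y, ds.samples, ds.traits, spec, sched, seed=42)
        b = fit_occurrence(occ.Y, ds.samples, ds.traits, spec, sched, seed=42)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.levels["site"].rho, b.levels["site"].rho)

    def test_thin_one_keeps_every_post_burnin_sweep(self):
        cfg = hj.TruthConfig(level_scales={lv: 0.0 for lv in LEVELS})
        ds = hj.simulate_dataset(n_genera=5, config=cfg, seed=3)
        occ, _, _ = hj.run_filter_chain(ds.counts, ds.samples)
        sched = McmcSchedule(2, 50, 0, 1)
        d = fit_occurrence(occ.Y, ds.samples, ds.traits,
                           ModelSpec(random_levels=[]), sched, seed=1)
        assert d.n_draws == 100


class TestRecovery:
    def test_occurrence_beta_recovery(self, no_random_fit):
        ds, occ, d_occ, _ = no_random_fit
        jidx = [ds.truth.genus_ids.index(g) for g in occ.Y.index]
        truth = ds.truth.beta_occ[:, jidx]
        est = d_occ.beta.mean(axis=0)
        assert np.corrcoef(est.ravel(), truth.ravel())[0, 1] >= 0.8

    def test_abundance_interval_coverage(self, no_random_fit):
        ds, occ, _, d_ab = no_random_fit
        jidx = [ds.truth.genus_ids.index(g) for g in occ.Y.index]
        truth = ds.truth.beta_abund[:, jidx]
        lo = np.quantile(d_ab.beta, 0.025, axis=0)
        hi = np.quantile(d_ab.beta, 0.975, axis=0)
        cover = ((truth >= lo) & (truth <= hi)).mean()
        assert 0.85 <= cover <= 1.0


class TestErrorContracts:
    def test_non_binary_occurrence_rejected(self, small_samples):
        import pandas as pd

        Y = pd.DataFrame([[2] * 12], index=["g0"], columns=small_samples.index)
        with pytest.raises(ValueError, match="binary"):
            fit_occurrence(Y, small_samples, None, ModelSpec(random_levels=[]),
                           McmcSchedule(1, 10, 0, 1), seed=0)

    def test_abundance_needs_two_observations(self, small_samples):
        import pandas as pd

        Z = pd.DataFrame([[np.nan] * 12], index=["g0"], columns=small_samples.index)
        with pytest.raises(ValueError, match="exclude"):
            fit_abundance(Z, small_samples, None, ModelSpec(random_levels=[]),
                          McmcSchedule(1, 10, 0, 1), seed=0)


class TestPsrf:
    def test_same_distribution_chains_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20_000)
        chain = np.repeat([0, 1], 10_000)
        assert psrf(x, chain) < 1.05

    def test_diverged_chains_flagged(self):
        x = np.concatenate([np.zeros(100), np.full(100, 100.0)])
        x += np.random.default_rng(1).normal(0, 1e-3, 200)
        r = psrf(x, np.repeat([0, 1], 100))
        assert r > 10

    def test_duplicated_chain_closed_form(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(500)
        r = psrf(np.concatenate([x, x]), np.repeat([0, 1], 500))
        assert r == pytest.approx(np.sqrt((500 - 1) / 500))

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            psrf(np.arange(10.0), np.zeros(10))
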