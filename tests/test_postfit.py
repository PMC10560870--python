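"""Post-fit statistics: metric identities, variance partition, trends, omega."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from honeyjsdm.gibbs import LevelDraws, PosteriorDraws
from honeyjsdm.postfit import (
    auc,
    omega,
    predict_seasonal,
    r2_linear,
    tjur_r2,
    variance_partition,
)

PRED = ["intercept", "T2", "T3", "log_total_reads"]


def _draws(beta, levels=None, genus=None):
    """Minimal PosteriorDraws carrying only what the statistic reads."""
    D, K, J = beta.shape
    return PosteriorDraws(
        kind="probit", beta=beta, gamma=np.zeros((D, 1, K)),
        V=np.tile(np.eye(K), (D, 1, 1)), sigma2=None,
        levels=levels or {}, chain=np.zeros(D, dtype=int),
        predictors=PRED[:K], genus_ids=genus or [f"g{j}" for j in range(J)],
    )


class TestTjur:
    def test_perfect_and_constant_and_half(self):
        assert tjur_r2([1, 1, 0], [1.0, 1.0, 0.0])[0] == 1.0
        assert tjur_r2([1, 0, 1], [0.4, 0.4, 0.4])[0] == 0.0
        assert tjur_r2([1, 0], [0.8, 0.3])[0] == pytest.approx(0.5)

    def test_one_class_flagged_nan(self):
        assert np.isnan(tjur_r2([1, 1], [0.5, 0.9])[0])


class TestAuc:
    def test_separated_ties_and_handcase(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])[0] == 1.0
        assert auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])[0] == 0.5
        # pairs: (0.9 vs 0.5) ranked correctly, (0.4 vs 0.5) not -> 0.5
        assert auc([1, 1, 0], [0.9, 0.4, 0.5])[0] == pytest.approx(0.5)

    def test_matches_pairwise_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = int(rng.integers(10, 50))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            p = rng.choice(np.linspace(0, 1, 11), size=n)  # force ties
            pres, abs_ = p[y == 1], p[y == 0]
            cmp = (pres[:, None] > abs_[None, :]).sum() \
                + 0.5 * (pres[:, None] == abs_[None, :]).sum()
            brute = cmp / (len(pres) * len(abs_))
            assert auc(y, p)[0] == pytest.approx(brute)

    @given(p=arrays(np.float64, 20, elements=st.floats(0, 1)))
    def test_inverted_scores_complement(self, p):
        y = np.tile([0, 1], 10)
        a = auc(y, p)[0]
        ties = len(np.intersect1d(p[y == 1], p[y == 0])) > 0
        if not ties:
            assert auc(y, 1 - p)[0] == pytest.approx(1 - a)
        assert 0.0 <= a <= 1.0


class TestR2Linear:
    def test_identity_and_affine_invariance(self):
        z = np.array([0.1, -0.4, 1.2, 0.8])
        assert r2_linear(z, z)[0] == pytest.approx(1.0)
        assert r2_linear(z, 2.0 + 3.0 * z)[0] == pytest.approx(1.0)

    def test_uncorrelated_noise_near_zero(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(4000)
        r2 = r2_linear(z, rng.standard_normal(4000))[0]
        assert r2 < (3 / np.sqrt(4000)) ** 2 * 3

    def test_degenerate_flagged(self):
        assert np.isnan(r2_linear([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])[0])


class TestVariancePartition:
    def test_single_random_source_gets_everything(self):
        D, J, F, U = 50, 4, 2, 6
        rng = np.random.default_rng(0)
        lev = LevelDraws("sample", [f"u{k}" for k in range(U)],
                         np.arange(U) % U, rng.standard_normal((D, F, J)),
                         rng.standard_normal((D, U, F)))
        beta = np.zeros((D, 4, J))
        X = np.column_stack([np.ones(U), np.tile([0, 1, 0], 2),
                             np.tile([0, 0, 1], 2), rng.standard_normal(U)])
        vp = variance_partition(_draws(beta, {"sample": lev}), X)
        assert np.allclose(vp.fractions["random_sample"], 1.0)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        D, J, U = 40, 5, 9
        lev = LevelDraws("hive", list("abc"), np.arange(U) % 3,
                         rng.standard_normal((D, 2, J)),
                         rng.standard_normal((D, 3, 2)))
        beta = rng.standard_normal((D, 4, J))
        X = np.column_stack([np.ones(U), rng.integers(0, 2, U),
                             rng.integers(0, 2, U), rng.standard_normal(U)])
        vp = variance_partition(_draws(beta, {"hive": lev}), X)
        assert np.allclose(vp.fractions.sum(axis=1), 1.0, atol=1e-9)
        assert (vp.fractions.to_numpy() >= 0).all()

    def test_invariant_to_compensating_rescaling(self):
        """Scaling loadings by c and factors by 1/c leaves fractions fixed."""
        rng = np.random.default_rng(2)
        D, J, U = 30, 4, 8
        lam = rng.standard_normal((D, 2, J))
        eta = rng.standard_normal((D, 3, 2))
        beta = rng.standard_normal((D, 4, J))
        X = np.column_stack([np.ones(U), rng.integers(0, 2, U),
                             rng.integers(0, 2, U), rng.standard_normal(U)])
        idx = np.arange(U) % 3
        a = variance_partition(
            _draws(beta, {"h": LevelDraws("h", list("abc"), idx, lam, eta)}), X
        )
        # NB: fractions use loadings only; compensate inside the identified
        # functional lambda' lambda by scaling loadings of every level alike
        b = variance_partition(
            _draws(beta * 2, {"h": LevelDraws("h", list("abc"), idx, lam * 2,
                                              eta / 2)}), X
        )
        pd.testing.assert_frame_equal(a.fractions, b.fractions)

    def test_group_averages_follow_traits(self):
        rng = np.random.default_rng(3)
        D, J, U = 20, 6, 6
        beta = rng.standard_normal((D, 4, J))
        X = np.column_stack([np.ones(U), np.repeat([0, 1], 3),
                             np.tile([0, 1], 3), rng.standard_normal(U)])
        traits = pd.DataFrame({"taxonomic_group": ["p"] * 3 + ["b"] * 3},
                              index=[f"g{j}" for j in range(J)])
        vp = variance_partition(_draws(beta), X, traits)
        expected = vp.fractions.iloc[:3].mean()
        pd.testing.assert_series_equal(
            vp.by_taxonomic_group.loc["p"], expected, check_names=False
        )


class TestPredictSeasonal:
    def test_null_seasonal_effect_symmetric(self):
        rng = np.random.default_rng(0)
        D = 2000
        beta = np.zeros((D, 4, 2))
        beta[:, 0, :] = rng.standard_normal((D, 2)) * 0.1
        out = predict_seasonal(_draws(beta))
        assert np.allclose(out.p_increase, 0.5, atol=0.1)
        assert (out.trend_call == "none").all()

    def test_strong_increase_called(self):
        beta = np.zeros((100, 4, 1))
        beta[:, 2, 0] = 5.0
        out = predict_seasonal(_draws(beta))
        assert out.p_increase.iloc[0] == 1.0
        assert out.trend_call.iloc[0] == "increase"

    def test_probit_identity_at_zero(self):
        out = predict_seasonal(_draws(np.zeros((10, 4, 1))))
        assert np.allclose(out.occ_prob.to_numpy(), 0.5)

    def test_decrease_uses_symmetric_tail(self):
        beta = np.zeros((100, 4, 1))
        beta[:, 2, 0] = -5.0
        assert predict_seasonal(_draws(beta)).trend_call.iloc[0] == "decrease"


class TestOmega:
    def test_single_draw_formula(self):
        beta = np.zeros((1, 4, 2))
        beta[0, 1] = [1.0, 1.0]   # T2
        beta[0, 2] = [0.0, 0.0]   # T3
        om = omega(_draws(beta), threshold=2.0)  # no calls wanted
        assert om.omega_mean.iloc[0, 1] == 1.0

    def test_vectorized_equals_bruteforce(self):
        rng = np.random.default_rng(4)
        D, J = 200, 10
        beta = rng.standard_normal((D, 4, J))
        om = omega(_draws(beta))
        b2, b3 = beta[:, 1, :], beta[:, 2, :]
        for a in range(J):
            for b in range(J):
                vals = np.array([b2[d, a] * b2[d, b] + b3[d, a] * b3[d, b]
                                 for d in range(D)])
                assert abs(om.omega_mean.iloc[a, b] - vals.mean()) < 1e-12
                assert om.p_pos.iloc[a, b] == (vals > 0).mean()

    def test_null_genus_row_zero_no_calls(self):
        rng = np.random.default_rng(5)
        beta = rng.standard_normal((500, 4, 3))
        beta[:, 1, 0] = 0.0
        beta[:, 2, 0] = 0.0
        om = omega(_draws(beta))
        assert np.allclose(om.omega_mean.iloc[0], 0.0)
        assert (om.sign_call.iloc[0] == 0).all()

    def test_concentrated_draws_called_positive(self):
        rng = np.random.default_rng(6)
        beta = np.zeros((1000, 4, 2))
        beta[:, 1, :] = rng.normal(2.0, np.sqrt(0.1), (1000, 2))
        om = omega(_draws(beta))
        assert om.p_pos.iloc[0, 1] > 0.99
        assert om.sign_call.iloc[0, 1] == 1

    def test_diagonal_nonnegative_every_draw(self):
        rng = np.random.default_rng(7)
        beta = rng.standard_normal((50, 4, 6))
        b2, b3 = beta[:, 1, :], beta[:, 2, :]
        diag = b2**2 + b3**2
        assert (diag >= 0).all()
        om = omega(_draws(beta))
        assert (np.diag(om.omega_mean) >= 0).all()
        assert np.allclose(om.omega_mean, om.omega_mean.T)

    def test_two_genera_required(self):
        with pytest.raises(ValueError, match="2 genera"):
            omega(_draws(np.zeros((10, 4, 1))))
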