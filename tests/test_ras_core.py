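"""Effect estimation, LPRS, association scores and the RAS series."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from rascan import (CovariateMatrix, PhenotypeVector, SampleSplit, ScanConfig,
                    association_score, estimate_effects, lprs, ras_at,
                    ras_series, split_samples)
from rascan.ras_core import _as_matrix_gaussian

from conftest import make_dataset


def full_split(n):
    return SampleSplit(estimation_ids=np.arange(n),
                       evaluation_ids=np.empty(0, dtype=int))


@pytest.fixture(scope="module")
def gaussian_instance(small_geno):
    """Genotypes + one covariate + a phenotype with a few real effects."""
    rng = np.random.default_rng(7)
    n = small_geno.n
    X = CovariateMatrix(values=rng.standard_normal((n, 1)), names=["pc1"])
    beta = np.zeros(small_geno.p)
    beta[30:40] = 0.3
    y = PhenotypeVector(
        values=small_geno.dosages @ beta + 0.5 * X.values[:, 0]
        + rng.standard_normal(n),
        family="gaussian")
    return small_geno, y, X


class TestEstimateEffects:
    def test_noiseless_marginal_effect_is_exact(self, small_geno):
        j = 12
        y = PhenotypeVector(values=0.5 * small_geno.dosages[:, j])
        X = CovariateMatrix.empty(small_geno.n)
        eff = estimate_effects(small_geno, y, X, split=full_split(small_geno.n))
        assert eff.beta_hat[j] == pytest.approx(0.5, abs=1e-12)

    def test_constant_dosage_column_gets_zero(self):
        G = make_dataset([[1, 1, 1, 1, 1, 1], [0, 1, 2, 0, 1, 2]])
        y = PhenotypeVector(values=np.array([1.0, 2, 3, 1, 2, 3]))
        eff = estimate_effects(G, y, CovariateMatrix.empty(6),
                               split=full_split(6))
        assert eff.beta_hat[0] == 0.0

    def test_matches_per_snp_normal_equations(self, gaussian_instance):
        G, y, X = gaussian_instance
        split = split_samples(G.n, 0.5, seed=3)
        eff = estimate_effects(G, y, X, split=split)
        est = split.estimation_ids
        for j in range(0, G.p, 4):  # brute-force per-SNP OLS oracle
            design = np.column_stack([np.ones(len(est)),
                                      G.dosages[est, j], X.values[est]])
            coef, *_ = np.linalg.lstsq(design, y.values[est], rcond=None)
            assert eff.beta_hat[j] == pytest.approx(coef[1], abs=1e-10)

    def test_logistic_matches_statsmodels(self, small_geno):
        rng = np.random.default_rng(1)
        lin = 0.5 * small_geno.dosages[:, 5] - 1.0
        y = PhenotypeVector(
            values=(rng.random(small_geno.n) < 1 / (1 + np.exp(-lin)))
            .astype(float),
            family="binomial")
        X = CovariateMatrix.empty(small_geno.n)
        eff = estimate_effects(small_geno, y, X, family="binomial",
                               split=full_split(small_geno.n))
        for j in (0, 5, 17):
            fit = sm.Logit(y.values, sm.add_constant(
                small_geno.dosages[:, j])).fit(disp=0)
            assert eff.beta_hat[j] == pytest.approx(fit.params[1], abs=1e-6)


class TestLPRS:
    def test_zero_weights_give_zero_scores(self, small_geno):
        out = lprs(small_geno, np.zeros(small_geno.p), np.arange(10))
        assert np.all(out == 0.0)

    def test_single_snp_arithmetic(self):
        G = make_dataset([[0, 1, 2]])
        out = lprs(G, np.array([2.0]), np.array([0]))
        assert np.allclose(out, [0, 2, 4])

    def test_matches_bruteforce_dot_products(self, small_geno):
        rng = np.random.default_rng(2)
        beta = rng.standard_normal(small_geno.p)
        idx = np.sort(rng.choice(small_geno.p, 30, replace=False))
        out = lprs(small_geno, beta, idx)
        expected = np.array([
            sum(beta[j] * small_geno.dosages[i, j] for j in idx)
            for i in range(small_geno.n)])
        assert np.allclose(out, expected, atol=1e-12)

    def test_full_index_set_reduces_to_prs(self, small_geno):
        rng = np.random.default_rng(3)
        beta = rng.standard_normal(small_geno.p)
        out = lprs(small_geno, beta, np.arange(small_geno.p))
        assert np.allclose(out, small_geno.dosages @ beta)


class TestAssociationScore:
    def test_matches_statsmodels_ols_ttest(self):
        rng = np.random.default_rng(4)
        n = 100
        l = rng.standard_normal(n)
        X = rng.standard_normal((n, 1))
        y = 0.3 * l + 0.5 * X[:, 0] + rng.standard_normal(n)
        a = association_score(l, y, X, "gaussian")
        fit = sm.OLS(y, sm.add_constant(np.column_stack([l, X]))).fit()
        assert fit.df_resid == n - 3  # (n - 3)-df t reference
        expected = -np.log10(fit.pvalues[1])
        assert a == pytest.approx(expected, rel=1e-10)

    def test_minus_log10_transform(self):
        # a fit whose p-value is exactly 0.01 must score AS = 2: build one
        # by inverting the t CDF at the target p on a fixed-correlation pair
        n, df = 52, 50
        t_target = stats.t.isf(0.005, df)  # two-sided p = 0.01
        r = t_target / np.sqrt(df + t_target ** 2)
        rng = np.random.default_rng(8)
        l = rng.standard_normal(n)
        l = (l - l.mean()) / l.std()
        resid = rng.standard_normal(n)
        resid -= resid.mean()
        resid -= l * (l @ resid) / (l @ l)  # orthogonal to l
        y = r * l + np.sqrt(1 - r ** 2) * resid / np.std(resid)
        a = association_score(l, y, None, "gaussian")
        assert a == pytest.approx(2.0, abs=1e-9)

    def test_constant_lprs_scores_zero(self):
        y = np.random.default_rng(0).standard_normal(50)
        assert association_score(np.ones(50), y, None, "gaussian") == 0.0
        assert association_score(np.zeros(50), (y > 0).astype(float),
                                 None, "binomial") == 0.0

    def test_binomial_wald_matches_statsmodels(self):
        rng = np.random.default_rng(5)
        n = 300
        l = rng.standard_normal(n)
        prob = 1 / (1 + np.exp(-(-1.0 + 0.8 * l)))
        y = (rng.random(n) < prob).astype(float)
        a = association_score(l, y, None, "binomial")
        fit = sm.Logit(y, sm.add_constant(l)).fit(disp=0)
        z = fit.params[1] / fit.bse[1]
        expected = -np.log10(2 * stats.norm.sf(abs(z)))
        assert a == pytest.approx(expected, rel=1e-6)

    def test_perfect_fit_capped(self):
        l = np.arange(50, dtype=float)
        assert association_score(l, 2 * l + 1, None, "gaussian") == 300.0

    def test_null_score_mean_matches_uniform_pvalues(self):
        # under independence p ~ U(0,1), so AS = -log10 U has mean 1/ln 10
        vals = []
        for s in range(2000):
            rng = np.random.default_rng(s)
            vals.append(association_score(rng.standard_normal(80),
                                          rng.standard_normal(80),
                                          None, "gaussian"))
        assert np.mean(vals) == pytest.approx(1 / np.log(10), abs=0.05)


class TestRasAt:
    def test_singleton_candidate_set(self, gaussian_instance):
        G, y, X = gaussian_instance
        eff = estimate_effects(G, y, X, split=full_split(G.n))
        j, t0 = 34, 7
        ras, t_star = ras_at(j, G, eff.beta_hat, y.values, X.values, [t0])
        window = np.arange(max(j - t0, 0), min(j + t0, G.p - 1) + 1)
        expected = association_score(lprs(G, eff.beta_hat, window),
                                     y.values, X.values, "gaussian")
        assert ras == pytest.approx(expected) and t_star == t0

    def test_left_boundary_clipping(self, gaussian_instance):
        G, y, X = gaussian_instance
        beta = np.random.default_rng(6).standard_normal(G.p)
        ras, _ = ras_at(0, G, beta, y.values, X.values, [5])
        expected = association_score(lprs(G, beta, np.arange(0, 6)),
                                     y.values, X.values, "gaussian")
        assert ras == pytest.approx(expected)

    def test_equals_explicit_max_over_windows(self, gaussian_instance):
        G, y, X = gaussian_instance
        eff = estimate_effects(G, y, X, split=full_split(G.n))
        j = 35
        scores = {}
        for t in (5, 10, 20):
            window = np.arange(max(j - t, 0), min(j + t, G.p - 1) + 1)
            scores[t] = association_score(lprs(G, eff.beta_hat, window),
                                          y.values, X.values, "gaussian")
        ras, t_star = ras_at(j, G, eff.beta_hat, y.values, X.values,
                             [5, 10, 20])
        assert ras == pytest.approx(max(scores.values()))
        assert scores[t_star] == pytest.approx(ras)

    def test_monotone_in_candidate_set(self, gaussian_instance):
        G, y, X = gaussian_instance
        eff = estimate_effects(G, y, X, split=full_split(G.n))
        for j in (0, 20, 40, 79):
            small, _ = ras_at(j, G, eff.beta_hat, y.values, X.values, [5, 15])
            large, _ = ras_at(j, G, eff.beta_hat, y.values, X.values,
                              [5, 10, 15, 25])
            assert large >= small - 1e-12


class TestBatchedScores:
    def test_batch_equals_scalar_association_scores(self, small_geno):
        rng = np.random.default_rng(9)
        n, p = small_geno.n, small_geno.p
        beta = rng.standard_normal(p) * 0.05
        y = rng.standard_normal(n)
        X = rng.standard_normal((n, 2))
        pivots = np.array([0, 10, 40, p - 1])
        Ts = [3, 8, 20]
        A = _as_matrix_gaussian(small_geno.dosages, beta, y, X, pivots, Ts)
        for i, j in enumerate(pivots):
            for b, t in enumerate(Ts):
                window = np.arange(max(j - t, 0), min(j + t, p - 1) + 1)
                expected = association_score(
                    lprs(small_geno, beta, window), y, X, "gaussian")
                assert A[i, b] == pytest.approx(expected, abs=1e-10)


class TestRasSeries:
    CFG = dict(candidate_T=(3, 6, 9), pivotal_interval=10, n_split_reps=2,
               cp_window=8, seed=21)

    def test_pivotal_grid(self, gaussian_instance):
        G, y, X = gaussian_instance
        s = ras_series(G, y, X, config=ScanConfig(**self.CFG))
        # p = 80, every 10th SNP anchored at the first -> indices 1, 11, ..., 71
        assert list(s.pivotal_index) == list(range(1, 80, 10))
        assert np.array_equal(s.position_bp,
                              G.position_bp[s.pivotal_index - 1])

    def test_pivotal_grid_count_matches_every_tenth_rule(self):
        # a 5,718-SNP chromosome at interval 10 has 572 pivotal SNPs
        assert len(np.arange(0, 5718, 10)) == 572

    def test_same_seed_bitwise_identical(self, gaussian_instance):
        G, y, X = gaussian_instance
        a = ras_series(G, y, X, config=ScanConfig(**self.CFG))
        b = ras_series(G, y, X, config=ScanConfig(**self.CFG))
        assert np.array_equal(a.ras, b.ras)
        assert np.array_equal(a.t_star, b.t_star)

    def test_mean_over_repetitions(self, gaussian_instance):
        # recompute the two repetitions independently through public ops
        G, y, X = gaussian_instance
        cfg = ScanConfig(**self.CFG)
        s = ras_series(G, y, X, config=cfg)
        root = np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 101])
        per_rep = []
        for child in root.spawn(2):
            split = split_samples(G.n, 0.5, child)
            eff = estimate_effects(G, y, X, split=split)
            ev = split.evaluation_ids
            per_rep.append([
                ras_at(j, G, eff.beta_hat, y.values, X.values,
                       cfg.candidate_T, "gaussian", sample_indices=ev)[0]
                for j in range(0, G.p, 10)])
        assert np.allclose(s.ras, np.mean(per_rep, axis=0), atol=1e-10)

    def test_split_hygiene_alters_in_sample_scores(self, gaussian_instance):
        # the association fit must not reuse the estimation samples:
        # scoring in-sample is an explicit, different mode
        G, y, X = gaussian_instance
        out = ras_series(G, y, X, config=ScanConfig(**self.CFG))
        cfg_in = ScanConfig(**{**self.CFG, "in_sample_as": True})
        in_sample = ras_series(G, y, X, config=cfg_in)
        assert not np.allclose(out.ras, in_sample.ras)

    def test_monotone_under_candidate_enlargement(self, gaussian_instance):
        G, y, X = gaussian_instance
        small = ras_series(G, y, X, config=ScanConfig(**self.CFG))
        big_cfg = ScanConfig(**{**self.CFG, "candidate_T": (3, 6, 9, 12, 15)})
        big = ras_series(G, y, X, config=big_cfg)
        assert np.all(big.ras >= small.ras - 1e-12)

    def test_zero_reps_rejected(self):
        with pytest.raises(ValueError, match="n_split_reps"):
            ScanConfig(n_split_reps=0)
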