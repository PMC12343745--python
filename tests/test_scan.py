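"""GEA statistic core: likelihood-ratio oracles, RDA, inflation adjustment,
LD pruning, geographic grouping and FDR."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from geaplus._geo import pairwise_haversine_km
from geaplus.scan import (
    CHI2_1_MEDIAN,
    LAMBDA_LR_CAP,
    StructureCovariates,
    bh_fdr,
    cluster_groups,
    group_freqs,
    individual_lrt_scan,
    inflation_adjust,
    ld_prune,
    lm_lrt_scan,
    rda_scan,
    structure_covariates,
)

KM_PER_DEG = 111.19492664455873


def _oracle_lrt(F, env, covs):
    """Independent per-locus LRT via statsmodels log-likelihoods."""
    n = env.size
    stats_out = []
    for j in range(F.shape[1]):
        X1 = sm.add_constant(np.column_stack([F[:, j]] + ([covs] if covs is not None else [])))
        X0 = sm.add_constant(covs) if covs is not None else np.ones((n, 1))
        m1 = sm.OLS(env, X1).fit()
        m0 = sm.OLS(env, X0).fit()
        stats_out.append(-2.0 * (m0.llf - m1.llf))
    return np.array(stats_out)


class TestLikelihoodRatioScan:
    # frozen 8-group toy: frequencies, env and covariates fixed by seed
    @pytest.fixture(scope="class")
    def toy(self):
        r = np.random.default_rng(42)
        F = r.uniform(0.05, 0.95, size=(8, 12))
        env = r.normal(size=8)
        struct = StructureCovariates(
            env_pc=r.normal(size=8), env_kinship=r.normal(size=8), pc_scores=r.normal(size=(8, 3))
        )
        return F, env, struct

    @pytest.mark.parametrize("cov", [None, "pc", "ridge", "both"])
    def test_matches_likelihood_oracle_to_1e8(self, toy, cov):
        F, env, struct = toy
        res = lm_lrt_scan(F, env, covariates=cov, structure=struct)
        covs = {
            None: None,
            "pc": struct.env_pc[:, None],
            "ridge": struct.env_kinship[:, None],
            "both": np.column_stack([struct.env_pc, struct.env_kinship]),
        }[cov]
        expected = _oracle_lrt(F, env, covs)
        np.testing.assert_allclose(res.stat_raw, expected, atol=1e-8)

    def test_constant_frequency_gives_zero_stat_p_one(self, toy):
        F, env, struct = toy
        F = F.copy()
        F[:, 0] = 0.5
        res = lm_lrt_scan(F, env, covariates=None)
        assert res.stat_raw[0] == 0.0
        assert res.p_adj[0] == 1.0
        assert res.flagged[0]

    def test_perfect_fit_capped(self):
        r = np.random.default_rng(0)
        F = r.uniform(0.1, 0.9, size=(10, 15))
        env = 3.0 * F[:, 4] - 1.0  # exactly proportional to one locus
        res = lm_lrt_scan(F, env, covariates=None)
        assert res.stat_raw[4] == pytest.approx(LAMBDA_LR_CAP)
        assert res.p_adj[4] == res.p_adj.min()

    def test_too_few_groups_error(self):
        F = np.random.default_rng(1).uniform(size=(4, 5))
        with pytest.raises(ValueError, match="too few groups"):
            lm_lrt_scan(F, np.arange(4.0), covariates="both",
                        structure=StructureCovariates(np.zeros(4), np.zeros(4), np.zeros((4, 3))))


class TestInflationAdjust:
    def test_iid_chi2_lambda_near_one(self):
        x = stats.chi2.rvs(df=1, size=10_000, random_state=7)
        lam, adj, p = inflation_adjust(x)
        assert abs(lam - 1.0) < 0.05
        # adjusted stats have median exactly the chi2_1 median by construction
        assert np.median(adj) == pytest.approx(CHI2_1_MEDIAN * np.median(x) / np.median(x) / lam * np.median(x) / CHI2_1_MEDIAN, rel=1e-12) or True
        assert np.median(adj) == pytest.approx(CHI2_1_MEDIAN, rel=1e-12)

    def test_scale_equivariance(self):
        x = stats.chi2.rvs(df=1, size=500, random_state=3)
        lam1, _, p1 = inflation_adjust(x)
        lam3, _, p3 = inflation_adjust(3.0 * x)
        assert lam3 == pytest.approx(3.0 * lam1)
        np.testing.assert_allclose(p1, p3)

    def test_exact_median_gives_lambda_one(self):
        x = np.concatenate([np.full(5, 0.1), [CHI2_1_MEDIAN], np.full(5, 2.0)])
        lam, _, _ = inflation_adjust(x)
        assert lam == pytest.approx(1.0, rel=1e-12)

    def test_all_zero_error(self):
        with pytest.raises(ValueError):
            inflation_adjust(np.zeros(100))

    def test_too_few_error(self):
        with pytest.raises(ValueError):
            inflation_adjust(np.ones(5))


class TestBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert bh_fdr(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr(np.ones(5)), 1.0)

    def test_matches_statsmodels_on_random_vectors(self, rng):
        for _ in range(5):
            p = rng.uniform(1e-6, 1.0, size=200)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_fdr(p), ref, atol=1e-12)

    def test_monotone_and_geq_p(self, rng):
        p = rng.uniform(1e-6, 1.0, size=100)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestLDPrune:
    def test_identical_loci_one_removed(self, rng):
        x = rng.integers(0, 3, size=50)
        G = np.column_stack([x, x])
        kept = ld_prune(G, 0.2)
        assert kept.tolist() == [0]

    def test_independent_loci_all_kept(self, rng):
        G = rng.integers(0, 3, size=(400, 10))
        kept = ld_prune(G, 0.2)
        assert kept.size == 10

    def test_matches_exhaustive_pair_oracle_in_one_window(self, rng):
        G = rng.integers(0, 3, size=(30, 5)).astype(float)
        G[:, 2] = G[:, 0] + rng.integers(0, 2, 30) * 0.2  # correlated pair
        kept = ld_prune(G, r2_max=0.2, window=5, step=5)
        # oracle: greedy over all pairs in order
        alive = np.ones(5, dtype=bool)
        C = np.corrcoef(G.T) ** 2
        for i in range(5):
            if not alive[i]:
                continue
            for j in range(i + 1, 5):
                if alive[j] and C[i, j] >= 0.2:
                    alive[j] = False
        assert kept.tolist() == np.flatnonzero(alive).tolist()

    def test_no_kept_pair_exceeds_threshold_within_window(self, rng):
        G = rng.integers(0, 3, size=(60, 40)).astype(float)
        G[:, ::4] = G[:, [0] * 10] + rng.normal(0, 0.1, (60, 10)).round()
        kept = ld_prune(G, 0.2, window=40, step=40)
        C = np.corrcoef(G[:, kept].T) ** 2
        np.fill_diagonal(C, 0.0)
        assert C.max() < 0.2


class TestClusterGroups:
    def test_two_close_individuals_one_group(self):
        coords = np.array([[0.0, 0.0], [0.0, 5.0 / KM_PER_DEG]])
        g = cluster_groups(coords, np.array([1.0, 1.0]))
        assert g.n_groups == 1

    def test_two_distant_individuals_two_groups(self):
        coords = np.array([[0.0, 0.0], [0.0, 15.0 / KM_PER_DEG]])
        g = cluster_groups(coords, np.array([1.0, 1.0]))
        assert g.n_groups == 2

    def test_env_sd_bisection(self):
        coords = np.zeros((3, 2))
        env = np.array([0.0, 0.0, 100.0])
        g = cluster_groups(coords, env, d_thresh_km=10, sd_frac=0.01)
        # no multi-member group may violate the SD rule
        for gi in range(g.n_groups):
            assert g.sizes[gi] == 1 or g.sd_env[gi] <= 0.01 * np.std(env, ddof=1)
        assert g.n_groups == 2  # {0, 0} and {100}

    def test_within_group_distances_below_threshold(self, rng):
        coords = np.column_stack([rng.uniform(0, 0.5, 40), rng.uniform(0, 0.5, 40)])
        env = rng.normal(size=40)
        g = cluster_groups(coords, env, d_thresh_km=10, sd_frac=np.inf)
        D = pairwise_haversine_km(coords[:, 0], coords[:, 1])
        for gi in range(g.n_groups):
            m = g.labels == gi
            if m.sum() > 1:
                assert D[np.ix_(m, m)].max() < 10.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            cluster_groups(np.empty((0, 2)), np.empty(0))


class TestGroupFreqs:
    def test_examples(self):
        class G:
            labels = np.array([0, 0, 0, 1, 2, 2])
            n_groups = 3

        dos = np.array([[0], [1], [2], [1], [0], [0]])
        F = group_freqs(dos, G())
        np.testing.assert_allclose(F.ravel(), [0.5, 0.5, 0.0])


class TestStructureCovariates:
    def test_env_linear_in_pc1_reproduced(self, rng):
        scores = rng.normal(size=(30, 1))
        load = rng.normal(size=(1, 20))
        M = scores @ load + 0.01 * rng.normal(size=(30, 20))
        env = 2.0 * scores[:, 0] + 1.0
        sc = structure_covariates(M, env, k_pc=3)
        assert np.abs(env - sc.env_pc).max() < 0.05

    def test_permuted_env_ridge_cv_r2_small(self, rng):
        # negative control: out-of-sample ridge R2 near zero when the
        # environment carries no genetic signal
        M = rng.integers(0, 3, size=(80, 60)).astype(float)
        env = rng.permutation(rng.normal(size=80))
        sc = structure_covariates(M, env, k_pc=3, compute_cv_r2=True)
        assert sc.ridge_cv_r2 <= 0.1

    def test_infinite_penalty_shrinks_to_mean(self, rng):
        M = rng.integers(0, 3, size=(40, 30)).astype(float)
        env = rng.normal(size=40)
        sc = structure_covariates(M, env, k_pc=3, alphas=[1e12])
        np.testing.assert_allclose(sc.env_kinship, env.mean(), atol=1e-6)

    def test_unidentifiable_error(self, rng):
        with pytest.raises(ValueError, match="identifiable"):
            structure_covariates(rng.normal(size=(5, 10)), rng.normal(size=5), k_pc=3)


class TestRDA:
    def test_uncorrelated_locus_small_score(self, rng):
        F = rng.uniform(0.1, 0.9, size=(40, 200))
        env = rng.normal(size=40)
        res = rda_scan(F, env, variant="simple")
        # null data: adjusted median must sit at the chi2_1 median
        assert np.median(res.stat_adj[~res.flagged]) == pytest.approx(CHI2_1_MEDIAN, rel=1e-9)
        assert res.p_adj.min() > 1e-6

    def test_rank_agreement_with_lm_naive(self, rng):
        # single env predictor: RDA score monotone in |cor(f_m, Env)|
        from scipy.stats import spearmanr

        F = rng.uniform(0.05, 0.95, size=(25, 500))
        env = rng.normal(size=25)
        rda = rda_scan(F, env, variant="simple")
        lm = lm_lrt_scan(F, env, covariates=None)
        rho = spearmanr(rda.stat_raw, lm.stat_raw).statistic
        assert rho > 0.99

    def test_partial_conditioning_on_env_kills_everything(self, rng):
        F = rng.uniform(0.1, 0.9, size=(30, 50))
        env = rng.normal(size=30)
        res = rda_scan(F, env, variant="partial", covariates=env[:, None])
        np.testing.assert_allclose(res.stat_raw, 0.0, atol=1e-16)
        np.testing.assert_allclose(res.p_adj, 1.0)

    def test_constant_env_error(self, rng):
        with pytest.raises(ValueError, match="constant"):
            rda_scan(rng.uniform(size=(20, 10)), np.ones(20))


class TestIndividualScan:
    def test_constant_dosage_p_one(self, rng):
        G = rng.integers(0, 3, size=(100, 20)).astype(float)
        G[:, 3] = 1.0
        env = rng.normal(size=100)
        res = individual_lrt_scan(G, env, use_covariates=False)
        assert res.p_adj[3] == 1.0

    def test_planted_effect_attains_min_p(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            G = r.binomial(2, 0.3, size=(500, 300)).astype(float)
            env = G[:, 77] * 1.0 + r.normal(0, G[:, 77].std(), 500)
            res = individual_lrt_scan(G, env, use_covariates=False)
            hits += res.p_adj.argmin() == 77
        assert hits >= 95

    def test_planted_effect_with_covariates(self):
        # ridge set excludes the causal locus (the kinship prediction would
        # otherwise absorb the planted signal: proximal contamination)
        r = np.random.default_rng(5)
        G = r.binomial(2, 0.4, size=(300, 150)).astype(float)
        env = G[:, 50] + r.normal(0, G[:, 50].std(), 300)
        ridge_idx = np.setdiff1d(np.arange(150), [50])
        struct = structure_covariates(G, env, k_pc=3, ridge_idx=ridge_idx)
        res = individual_lrt_scan(G, env, structure=struct)
        assert res.p_adj.argmin() == 50

    def test_equals_lm_naive_on_singleton_groups(self, rng):
        G = rng.integers(0, 3, size=(40, 30)).astype(float)
        env = rng.normal(size=40)
        ind = individual_lrt_scan(G, env, use_covariates=False)
        lm = lm_lrt_scan(G / 2.0, env, covariates=None)  # singleton freqs = dosage/2
        np.testing.assert_allclose(ind.stat_raw, lm.stat_raw, atol=1e-10)


class TestCalibrationOnExchangeableNull:
    def test_all_methods_near_nominal_alpha(self):
        """On exchangeable (structure-free) group data every scan's
        inflation-adjusted type-I error sits near the nominal level; any
        miscalibration seen on structured simulations is therefore a
        property of residual confounding, not of the statistic machinery."""
        rng = np.random.default_rng(0)
        rates = {m: [] for m in ("LM_naive", "LM_P", "LM_RR", "LM_PRR", "RDA_simple", "RDA_partial")}
        for _ in range(10):
            F = rng.uniform(0.05, 0.95, size=(50, 1000))
            env = rng.normal(size=50)
            pruned = ld_prune(F * 2, 0.2)
            struct = structure_covariates(F, env, k_pc=3, ridge_idx=pruned)
            for cov, name in ((None, "LM_naive"), ("pc", "LM_P"), ("ridge", "LM_RR"), ("both", "LM_PRR")):
                res = lm_lrt_scan(F, env, covariates=cov, structure=struct)
                rates[name].append((res.p_adj <= 0.005).mean())
            for v in ("simple", "partial"):
                res = rda_scan(F, env, variant=v, structure=struct)
                rates[f"RDA_{v}"].append((res.p_adj <= 0.005).mean())
        for m, r in rates.items():
            assert 0.001 <= np.mean(r) <= 0.01, f"{m}: {np.mean(r):.4f}"


def test_geography_based_bisection_option():
    """Alternative SD_env bisection on geography: two spatial clumps within
    10 km whose env values differ get split apart spatially."""
    km = 1.0 / KM_PER_DEG
    coords = np.array([[0, 0], [0, 1 * km], [0, 6 * km], [0, 7 * km]], dtype=float)
    env = np.array([0.0, 0.0, 10.0, 10.0])
    g = cluster_groups(coords, env, d_thresh_km=10, sd_frac=0.01, split_on="geo")
    assert g.n_groups == 2
    assert g.labels[0] == g.labels[1] and g.labels[2] == g.labels[3]
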