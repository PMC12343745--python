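"""Genome-environment association statistics.

Population-based scans regress a group-mean environmental variable on
group allele frequencies via Gaussian likelihood-ratio tests, optionally
with structure covariates: Env_PC (environmental variation explained by the
leading principal components of the genotype matrix) and Env_Kinship
(environmental variation explained by genome-wide ridge regression on an
LD-pruned SNP set).  The four linear models are

    LM_naive : Env ~ f_m
    LM_P     : Env ~ f_m + Env_PC
    LM_RR    : Env ~ f_m + Env_Kinship
    LM_PRR   : Env ~ f_m + Env_PC + Env_Kinship

with lambda_LR = -2 ln L(null)/L(alt) = n ln(RSS_null/RSS_alt) referred to a
chi-squared distribution with one degree of freedom after division by the
genomic inflation factor lambda = median(stat)/median(chi2_1).

Redundancy-analysis (RDA) scans project standardized frequencies onto the
environmental axis (residualized on genotype PCs for partial RDA) and treat
the squared robust-standardized locus loading as a chi-squared df=1
statistic.  The individual-based scan applies the LM_PRR construction to
individual dosages, standing in for two-stage whole-genome regression
association methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.linear_model import RidgeCV

from ._geo import pairwise_haversine_km

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # ~0.4549364
LAMBDA_LR_CAP = 2.0 * np.log(1e300)  # perfect-fit guard


# --------------------------------------------------------------------------
# geographic grouping and frequencies
# --------------------------------------------------------------------------


@dataclass
class GeoGroups:
    labels: np.ndarray  # group id per individual, 0..G-1
    sizes: np.ndarray
    mean_lon: np.ndarray
    mean_lat: np.ndarray
    mean_env: np.ndarray
    sd_env: np.ndarray

    @property
    def n_groups(self) -> int:
        return self.sizes.size


def _split_group(env_g: np.ndarray, coords_g: np.ndarray | None = None) -> np.ndarray:
    """Bisect a group by complete-linkage clustering on the environmental
    value (or on geography when coords are given); returns 0/1 sub-labels."""
    if coords_g is not None:
        d = pairwise_haversine_km(coords_g[:, 0], coords_g[:, 1])
    else:
        d = np.abs(env_g[:, None] - env_g[None, :])
    Z = linkage(squareform(d, checks=False), method="complete")
    return fcluster(Z, t=2, criterion="maxclust") - 1


def cluster_groups(
    coords, env, d_thresh_km: float = 10.0, sd_frac: float = 0.01, split_on: str = "env"
) -> GeoGroups:
    """Group individuals by complete-linkage clustering on great-circle
    distances (within-group distances below ``d_thresh_km``), then
    recursively bisect any group whose environmental SD exceeds
    ``sd_frac`` of the overall environmental SD.  ``split_on`` chooses the
    bisection space: the environmental value itself (default, targets the
    violated criterion directly) or geography."""
    coords = np.asarray(coords, dtype=float)
    env = np.asarray(env, dtype=float)
    n = coords.shape[0]
    if n == 0:
        raise ValueError("no individuals to cluster")
    if np.isnan(env).any():
        raise ValueError("env must be non-missing for all individuals passed")
    if n == 1:
        labels = np.zeros(1, dtype=int)
    else:
        D = pairwise_haversine_km(coords[:, 0], coords[:, 1])
        Z = linkage(squareform(D, checks=False), method="complete")
        labels = fcluster(Z, t=d_thresh_km * (1 - 1e-12), criterion="distance") - 1

    sd_total = float(np.std(env, ddof=1)) if n > 1 else 0.0
    limit = sd_frac * sd_total
    # recursive environmental bisection
    queue = list(np.unique(labels))
    next_label = labels.max() + 1
    while queue:
        g = queue.pop()
        m = np.flatnonzero(labels == g)
        if m.size < 2:
            continue
        if np.std(env[m], ddof=1) > limit:
            sub = _split_group(env[m], coords[m] if split_on == "geo" else None)
            if sub.min() == sub.max():  # degenerate (e.g. co-located, geo mode)
                sub = _split_group(env[m])
            if sub.min() == sub.max():
                continue
            labels[m[sub == 1]] = next_label
            queue.extend([g, next_label])
            next_label += 1

    # relabel compactly in order of appearance
    _, labels = np.unique(labels, return_inverse=True)
    G = labels.max() + 1
    sizes = np.bincount(labels, minlength=G)
    mean_lon = np.bincount(labels, weights=coords[:, 0]) / sizes
    mean_lat = np.bincount(labels, weights=coords[:, 1]) / sizes
    mean_env = np.bincount(labels, weights=env) / sizes
    sd_env = np.array([np.std(env[labels == g], ddof=1) if sizes[g] > 1 else 0.0 for g in range(G)])
    return GeoGroups(labels, sizes, mean_lon, mean_lat, mean_env, sd_env)


def group_freqs(dosages, groups: GeoGroups):
    """Allele frequencies per (group, locus): ALT-dosage sum / (2 n_group)."""
    G = np.asarray(dosages, dtype=float)
    ng = groups.n_groups
    F = np.zeros((ng, G.shape[1]))
    for g in range(ng):
        m = groups.labels == g
        F[g] = G[m].sum(axis=0) / (2.0 * m.sum())
    return F


# --------------------------------------------------------------------------
# LD pruning and structure covariates
# --------------------------------------------------------------------------


def ld_prune(dosages, r2_max: float = 0.2, window: int = 50, step: int = 25) -> np.ndarray:
    """Sliding-window greedy LD pruning on squared dosage correlation.

    Within each window, the later locus of any pair with r^2 >= ``r2_max``
    is dropped; the window advances by ``step``.  Returns kept locus indices
    in original order."""
    G = np.asarray(dosages, dtype=float)
    if G.shape[0] < 2:
        raise ValueError("need at least 2 individuals for LD pruning")
    L = G.shape[1]
    kept = np.ones(L, dtype=bool)
    sd = G.std(axis=0)
    kept &= sd > 0  # monomorphic columns carry no information
    Z = (G - G.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    n = G.shape[0]
    for start in range(0, L, step):
        idx = np.flatnonzero(kept[start : start + window]) + start
        if idx.size < 2:
            continue
        C = (Z[:, idx].T @ Z[:, idx]) / n
        R2 = C**2
        alive = np.ones(idx.size, dtype=bool)
        for i in range(idx.size):
            if not alive[i]:
                continue
            hits = np.flatnonzero(alive & (R2[i] >= r2_max))
            hits = hits[hits > i]
            alive[hits] = False
        kept[idx[~alive]] = False
    return np.flatnonzero(kept)


@dataclass
class StructureCovariates:
    env_pc: np.ndarray  # fitted Env from first k genotype PCs
    env_kinship: np.ndarray  # fitted Env from genome-wide ridge regression
    pc_scores: np.ndarray  # (n, k)
    ridge_alpha: float = np.nan
    ridge_cv_r2: float = np.nan  # out-of-sample R2 of the ridge prediction


def _pca_scores(M: np.ndarray, k: int) -> np.ndarray:
    Mc = M - M.mean(axis=0)
    U, s, _ = np.linalg.svd(Mc, full_matrices=False)
    return U[:, :k] * s[:k]


def _ols_fit(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Fitted values of y ~ [1, X]."""
    A = np.column_stack([np.ones(y.size), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return A @ beta


def structure_covariates(
    matrix,
    env,
    k_pc: int = 3,
    ridge_idx=None,
    alphas=None,
    cv: int | None = None,
    compute_cv_r2: bool = False,
) -> StructureCovariates:
    """Env_PC and Env_Kinship covariates from a frequency or dosage matrix.

    Env_PC is the least-squares fit of Env on the first ``k_pc`` principal
    components; Env_Kinship is the in-sample ridge prediction of Env from
    the LD-pruned locus set, with the penalty chosen by cross-validation
    over a grid of 10^{-2..4} times n (``cv=None`` uses the efficient
    leave-one-out generalized CV; an integer gives k-fold)."""
    M = np.asarray(matrix, dtype=float)
    env = np.asarray(env, dtype=float)
    n = env.size
    if n <= k_pc + 2:
        raise ValueError(f"model not identifiable: n={n} <= k_pc+2={k_pc + 2}")
    scores = _pca_scores(M, k_pc)
    env_pc = _ols_fit(env, scores)

    X = M[:, ridge_idx] if ridge_idx is not None else M
    sd = X.std(axis=0)
    X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    if alphas is None:
        alphas = np.logspace(-2, 4, 13) * n
    ridge = RidgeCV(alphas=alphas, cv=cv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ridge.fit(X, env)
    env_kin = ridge.predict(X)
    cv_r2 = np.nan
    if compute_cv_r2:
        from sklearn.linear_model import Ridge
        from sklearn.model_selection import KFold, cross_val_predict

        pred = cross_val_predict(Ridge(alpha=ridge.alpha_), X, env, cv=KFold(5, shuffle=True, random_state=0))
        sst = ((env - env.mean()) ** 2).sum()
        cv_r2 = float(1.0 - ((env - pred) ** 2).sum() / sst) if sst > 0 else np.nan
    return StructureCovariates(
        env_pc=env_pc, env_kinship=env_kin, pc_scores=scores,
        ridge_alpha=float(ridge.alpha_), ridge_cv_r2=cv_r2,
    )


# --------------------------------------------------------------------------
# scan results and the inflation / FDR machinery
# --------------------------------------------------------------------------


@dataclass
class ScanResult:
    method: str
    stat_raw: np.ndarray  # lambda_LR or chi-square per locus
    lambda_: float
    stat_adj: np.ndarray
    p_adj: np.ndarray
    q: np.ndarray
    flagged: np.ndarray  # monomorphic / degenerate loci (stat forced to 0, p to 1)
    locus_ids: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.method,
                "stat": self.stat_raw,
                "lambda": self.lambda_,
                "stat_adj": self.stat_adj,
                "p_adj": self.p_adj,
                "q": self.q,
                "flagged": self.flagged,
            }
        )


def inflation_adjust(statistics):
    """Genomic-inflation adjustment: lambda = median(stat) / median(chi2_1);
    adjusted statistic = stat / lambda; p from the upper chi2_1 tail."""
    stat = np.asarray(statistics, dtype=float)
    finite = np.isfinite(stat)
    if finite.sum() < 10:
        raise ValueError("need at least 10 finite statistics for inflation adjustment")
    med = float(np.median(stat[finite]))
    if med <= 0:
        raise ValueError("median statistic is zero; inflation factor undefined")
    lam = med / CHI2_1_MEDIAN
    adj = stat / lam
    p = stats.chi2.sf(adj, df=1)
    return lam, adj, np.clip(p, np.nextafter(0, 1), 1.0)


def bh_fdr(p):
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _finalize(method, stat, flagged, locus_ids):
    """Shared tail of every scan: inflation adjustment on clean loci, BH FDR."""
    stat = np.asarray(stat, dtype=float)
    flagged = np.asarray(flagged, dtype=bool)
    clean = ~flagged
    if clean.sum() >= 10 and np.median(stat[clean]) > 0:
        lam, _, _ = inflation_adjust(stat[clean])
    else:
        lam = np.nan
    if np.isfinite(lam):
        adj = stat / lam
        p = stats.chi2.sf(adj, df=1)
    else:  # degenerate scan (e.g. everything conditioned out): no evidence anywhere
        adj = stat.copy()
        p = np.ones_like(stat)
    p[flagged] = 1.0
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    q = bh_fdr(p)
    return ScanResult(method, stat, float(lam), adj, p, q, flagged, locus_ids)


# --------------------------------------------------------------------------
# the scans
# --------------------------------------------------------------------------


def _partial_lrt_stats(Y_cols: np.ndarray, env: np.ndarray, covs: np.ndarray | None):
    """Vectorized one-regressor LRT: for each column x of Y_cols, the LRT of
    env ~ x + covs against env ~ covs, via the partial-correlation identity
    lambda_LR = -n ln(1 - r^2)."""
    n = env.size
    if covs is not None and covs.size:
        X0 = np.column_stack([np.ones(n), covs])
    else:
        X0 = np.ones((n, 1))
    Q, _ = np.linalg.qr(X0)
    e = env - Q @ (Q.T @ env)
    R = Y_cols - Q @ (Q.T @ Y_cols)
    se = float(np.sqrt((e**2).sum()))
    sr = np.sqrt((R**2).sum(axis=0))
    flagged = (sr <= 1e-12 * max(1.0, np.abs(Y_cols).max())) | (se <= 1e-12)
    sr_safe = np.where(flagged, 1.0, sr)
    r = (R.T @ e) / (sr_safe * max(se, 1e-300))
    r2 = np.clip(r**2, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        stat = -n * np.log1p(-r2)
    stat = np.where(np.isfinite(stat), stat, LAMBDA_LR_CAP)
    stat = np.minimum(stat, LAMBDA_LR_CAP)
    stat[flagged] = 0.0
    return stat, flagged


class LikelihoodRatioScan(BaseEstimator):
    """Population-based LM likelihood-ratio GEA scan.

    ``covariates`` selects the model: ``None`` (LM_naive), ``"pc"`` (LM_P),
    ``"ridge"`` (LM_RR) or ``"both"`` (LM_PRR).  ``fit(F, env)`` takes the
    groups x loci frequency matrix and group-mean environments; per-locus
    statistics land in ``result_``.
    """

    _names = {None: "LM_naive", "pc": "LM_P", "ridge": "LM_RR", "both": "LM_PRR"}

    def __init__(self, covariates=None, k_pc: int = 3, r2_prune: float = 0.2, prune_window: int = 50, prune_step: int = 25):
        self.covariates = covariates
        self.k_pc = k_pc
        self.r2_prune = r2_prune
        self.prune_window = prune_window
        self.prune_step = prune_step

    def fit(self, F, env, locus_ids=None, structure: StructureCovariates | None = None):
        F = np.asarray(F, dtype=float)
        env = np.asarray(env, dtype=float)
        if self.covariates not in self._names:
            raise ValueError(f"covariates must be one of {list(self._names)}")
        n_cov = {"pc": 1, "ridge": 1, "both": 2}.get(self.covariates, 0)
        if F.shape[0] <= n_cov + 2:
            raise ValueError("too few groups for the requested covariates")
        covs = None
        if self.covariates is not None:
            if structure is None:
                pruned = ld_prune(2 * F, self.r2_prune, self.prune_window, self.prune_step)
                structure = structure_covariates(F, env, k_pc=self.k_pc, ridge_idx=pruned)
            pieces = {
                "pc": [structure.env_pc],
                "ridge": [structure.env_kinship],
                "both": [structure.env_pc, structure.env_kinship],
            }[self.covariates]
            covs = np.column_stack(pieces)
        stat, flagged = _partial_lrt_stats(F, env, covs)
        self.structure_ = structure
        self.result_ = _finalize(self._names[self.covariates], stat, flagged, locus_ids)
        return self

    def fit_scan(self, F, env, **kw) -> ScanResult:
        return self.fit(F, env, **kw).result_


def lm_lrt_scan(freqs, env, covariates=None, structure: StructureCovariates | None = None, **params) -> ScanResult:
    """Functional wrapper over :class:`LikelihoodRatioScan`."""
    return LikelihoodRatioScan(covariates=covariates, **params).fit_scan(freqs, env, structure=structure)


class RDAScan(BaseEstimator):
    """Simple or partial redundancy-analysis GEA scan.

    Locus columns are unit-variance standardized; the per-locus score is the
    loading on the environmental axis (residualized on genotype PCs for the
    partial variant), robust-standardized (median / 1.4826*MAD) and squared
    into a chi-squared df=1 statistic, then inflation-adjusted.
    """

    def __init__(self, variant: str = "simple", k_pc: int = 3, covariates=None):
        self.variant = variant
        self.k_pc = k_pc
        self.covariates = covariates  # explicit covariate matrix overriding genotype PCs

    def fit(self, F, env, locus_ids=None, structure: StructureCovariates | None = None):
        if self.variant not in ("simple", "partial"):
            raise ValueError("variant must be 'simple' or 'partial'")
        F = np.asarray(F, dtype=float)
        env = np.asarray(env, dtype=float)
        if np.std(env) == 0:
            raise ValueError("environmental variable is constant")
        n = F.shape[0]
        if n <= (self.k_pc if self.variant == "partial" else 0) + 2:
            raise ValueError("too few groups")
        sd = F.std(axis=0)
        flagged = sd <= 1e-12
        Y = (F - F.mean(axis=0)) / np.where(flagged, 1.0, sd)
        Y[:, flagged] = 0.0
        x = env - env.mean()
        if self.variant == "partial":
            if self.covariates is not None:
                scores = np.atleast_2d(np.asarray(self.covariates, dtype=float))
                if scores.shape[0] != n:
                    scores = scores.T
            elif structure is not None:
                scores = structure.pc_scores
            else:
                scores = _pca_scores(F, self.k_pc)
            A = np.column_stack([np.ones(n), scores])
            Q, _ = np.linalg.qr(A)
            x = x - Q @ (Q.T @ x)
            Y = Y - Q @ (Q.T @ Y)
        nx = float(np.linalg.norm(x))
        if nx <= 1e-12 * max(1.0, float(np.abs(env).max())):
            # everything conditioned out: no constrained axis remains
            stat = np.zeros(F.shape[1])
            self.result_ = ScanResult(
                f"RDA_{self.variant}", stat, np.nan, stat.copy(), np.ones_like(stat), np.ones_like(stat),
                np.ones_like(stat, dtype=bool), locus_ids,
            )
            return self
        loadings = Y.T @ (x / nx)
        med = np.median(loadings[~flagged])
        mad = np.median(np.abs(loadings[~flagged] - med))
        scale = 1.4826 * mad if mad > 0 else loadings[~flagged].std() or 1.0
        z = (loadings - med) / scale
        stat = z**2
        stat[flagged] = 0.0
        self.loadings_ = loadings
        self.result_ = _finalize(f"RDA_{self.variant}", stat, flagged, locus_ids)
        return self

    def fit_scan(self, F, env, **kw) -> ScanResult:
        return self.fit(F, env, **kw).result_


def rda_scan(freqs, env, variant: str = "simple", structure: StructureCovariates | None = None, **params) -> ScanResult:
    return RDAScan(variant=variant, **params).fit_scan(freqs, env, structure=structure)


class IndividualScan(BaseEstimator):
    """Individual-based GEA scan: per-locus OLS likelihood-ratio test of the
    environment on dosage, with the first ``k_pc`` genotype PCs plus the
    ridge-regression kinship prediction as covariates (the individual-level
    analogue of LM_PRR, standing in for two-stage whole-genome regression)."""

    def __init__(self, k_pc: int = 3, r2_prune: float = 0.2, prune_window: int = 50, prune_step: int = 25, use_covariates: bool = True):
        self.k_pc = k_pc
        self.r2_prune = r2_prune
        self.prune_window = prune_window
        self.prune_step = prune_step
        self.use_covariates = use_covariates

    def fit(self, dosages, env, locus_ids=None, structure: StructureCovariates | None = None):
        G = np.asarray(dosages, dtype=float)
        env = np.asarray(env, dtype=float)
        if np.isnan(env).any():
            raise ValueError("individuals with missing env must be excluded")
        covs = None
        if self.use_covariates:
            if structure is None:
                pruned = ld_prune(G, self.r2_prune, self.prune_window, self.prune_step)
                structure = structure_covariates(G, env, k_pc=self.k_pc, ridge_idx=pruned)
            covs = np.column_stack([structure.pc_scores, structure.env_kinship])
        stat, flagged = _partial_lrt_stats(G, env, covs)
        self.structure_ = structure
        self.result_ = _finalize("IND_LRT", stat, flagged, locus_ids)
        return self

    def fit_scan(self, G, env, **kw) -> ScanResult:
        return self.fit(G, env, **kw).result_


def individual_lrt_scan(dosages, env, structure: StructureCovariates | None = None, **params) -> ScanResult:
    return IndividualScan(**params).fit_scan(dosages, env, structure=structure)
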