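"""Geographic-origin inference: masking design, neural-network coordinate
prediction with k-fold ensembling, and Type 1 / Type 2 accuracy metrics.

The masking design mimics a genebank where most accessions lack passport
coordinates: a fraction of sites is selected, a handful of individuals per
selected site keep their coordinates (the training set) and everything else
is masked.  Masked individuals from unselected sites are "Type 1" (their
site is absent from training); masked individuals from selected sites are
"Type 2" (data leakage through site overlap with the training set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._geo import haversine_km
from ._mlp import MLPRegressorNP


@dataclass
class MaskDesign:
    selected_sites: np.ndarray  # site ids used for training
    train_ids: list[str]
    predict_ids: list[str]
    type_labels: pd.Series  # index predict_ids, values "Type1"/"Type2"
    seed: int

    @property
    def masked_fraction(self) -> float:
        n = len(self.train_ids) + len(self.predict_ids)
        return len(self.predict_ids) / n


def make_mask(sample_table: pd.DataFrame, site_frac: float, n_train_per_site: int, seed: int) -> MaskDesign:
    """Select ``site_frac`` of the sites and ``n_train_per_site`` individuals
    from each as the geo-referenced training set; everything else becomes the
    prediction set, labelled Type 1 (site unselected) or Type 2 (site
    selected)."""
    rng = np.random.default_rng(seed)
    sites = np.sort(sample_table["site"].unique())
    n_sel = int(round(site_frac * sites.size))
    selected = rng.choice(sites, n_sel, replace=False)
    selected_set = set(selected.tolist())

    train_ids: list[str] = []
    for s in selected:
        members = sample_table.loc[sample_table["site"] == s, "id"].to_numpy()
        if members.size < n_train_per_site:
            raise ValueError(f"site {s} has only {members.size} sampled individuals, need {n_train_per_site}")
        train_ids.extend(rng.choice(members, n_train_per_site, replace=False).tolist())
    train_set = set(train_ids)
    predict_ids = [i for i in sample_table["id"] if i not in train_set]
    site_of = dict(zip(sample_table["id"], sample_table["site"]))
    labels = pd.Series(
        ["Type2" if site_of[i] in selected_set else "Type1" for i in predict_ids],
        index=predict_ids,
        name="type",
    )
    return MaskDesign(np.sort(selected), train_ids, predict_ids, labels, seed)


class OriginEnsembleRegressor(BaseEstimator, RegressorMixin):
    """k-fold x replicate ensemble of fully connected networks mapping SNP
    dosages to (lon, lat).

    Each member holds out one fold for early stopping; the final prediction
    is the arithmetic mean of all members' back-transformed coordinates.
    Inputs are mean-imputed and per-locus standardized; coordinates are
    standardized per axis for the Euclidean-distance loss.

    Parameters follow the scikit-learn convention; fitted attributes carry a
    trailing underscore.
    """

    def __init__(
        self,
        n_folds: int = 10,
        n_replicates: int = 8,
        hidden_layer_sizes: tuple[int, ...] = (128, 128, 128, 128, 128, 128),
        dropout: float = 0.25,
        learning_rate: float = 1e-3,
        max_epochs: int = 300,
        patience: int = 20,
        batch_size: int | None = None,
        random_state: int | None = None,
        max_members: int | None = None,
    ):
        self.n_folds = n_folds
        self.n_replicates = n_replicates
        self.max_members = max_members
        self.hidden_layer_sizes = hidden_layer_sizes
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("X must be (n, loci) and y must be (n, 2) lon/lat")
        n = X.shape[0]
        if n < 2 * self.n_folds:
            raise ValueError(f"need >= 2 training individuals per fold ({n} for {self.n_folds} folds)")
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean, X)
        sd = X.std(axis=0)
        keep = sd > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} all-constant locus column(s)")
        self.column_mask_ = keep
        self.x_mean_ = X[:, keep].mean(axis=0)
        self.x_sd_ = X[:, keep].std(axis=0)
        Z = (X[:, keep] - self.x_mean_) / self.x_sd_
        self.y_mean_ = y.mean(axis=0)
        self.y_sd_ = y.std(axis=0)
        if np.any(self.y_sd_ == 0):
            self.y_sd_ = np.where(self.y_sd_ == 0, 1.0, self.y_sd_)
        Yz = (y - self.y_mean_) / self.y_sd_

        root = np.random.default_rng(self.random_state)
        self.models_ = []
        self.provenance_ = []
        self.member_val_km_ = []
        for rep in range(self.n_replicates):
            fold_of = root.permutation(np.arange(n) % self.n_folds)
            for fold in range(self.n_folds):
                if self.max_members is not None and len(self.models_) >= self.max_members:
                    break
                val = fold_of == fold
                net = MLPRegressorNP(
                    n_in=Z.shape[1],
                    n_out=2,
                    hidden=tuple(self.hidden_layer_sizes),
                    dropout=self.dropout,
                    learning_rate=self.learning_rate,
                    max_epochs=self.max_epochs,
                    patience=self.patience,
                    batch_size=self.batch_size,
                    rng=np.random.default_rng(root.integers(2**31)),
                )
                net.fit(Z[~val], Yz[~val], Z[val], Yz[val])
                self.models_.append(net)
                self.provenance_.append((rep, fold))
                pred = net.predict(Z[val]) * self.y_sd_ + self.y_mean_
                err = haversine_km(pred[:, 0], pred[:, 1], y[val, 0], y[val, 1])
                self.member_val_km_.append(float(np.mean(err)))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "models_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"locus mismatch: model was fitted on {self.n_features_in_} loci, got {X.shape[1]}"
            )
        X = np.where(np.isnan(X), 0.0, X)
        Z = (X[:, self.column_mask_] - self.x_mean_) / self.x_sd_
        preds = np.stack([net.predict(Z) for net in self.models_])
        return preds.mean(axis=0) * self.y_sd_ + self.y_mean_

    def member_predict(self, X, k: int):
        """Back-transformed prediction of a single ensemble member."""
        check_is_fitted(self, "models_")
        X = np.asarray(X, dtype=float)
        Z = (X[:, self.column_mask_] - self.x_mean_) / self.x_sd_
        return self.models_[k].predict(Z) * self.y_sd_ + self.y_mean_


@dataclass
class PredictorEnsemble:
    """Fitted coordinate predictor plus the locus bookkeeping needed to apply
    it to new panels (QTLs are excluded from training and prediction)."""

    estimator: OriginEnsembleRegressor
    n_panel_loci: int
    kept_loci: np.ndarray  # indices into the panel's locus axis

    @property
    def ensemble_size(self) -> int:
        return len(self.estimator.models_)


def train_predictor(
    genotypes,
    coords,
    qtl_indices=None,
    n_folds: int = 10,
    n_replicates: int = 8,
    seed: int | None = None,
    **net_params,
) -> PredictorEnsemble:
    """Train the fold-ensemble coordinate predictor, excluding QTL loci."""
    G = np.asarray(genotypes, dtype=float)
    keep = np.ones(G.shape[1], dtype=bool)
    if qtl_indices is not None and len(qtl_indices) > 0:
        keep[np.asarray(qtl_indices, dtype=int)] = False
    est = OriginEnsembleRegressor(
        n_folds=n_folds, n_replicates=n_replicates, random_state=seed, **net_params
    )
    est.fit(G[:, keep], np.asarray(coords, dtype=float))
    return PredictorEnsemble(est, n_panel_loci=G.shape[1], kept_loci=np.flatnonzero(keep))


@dataclass
class OriginPrediction:
    ids: list[str]
    pred: np.ndarray  # (n, 2) lon/lat
    table: pd.DataFrame = field(default=None)


def predict_origins(ensemble: PredictorEnsemble, genotypes, ids=None) -> OriginPrediction:
    """Ensemble-mean predicted coordinates for a panel aligned with the
    training panel's loci (QTLs dropped automatically)."""
    G = np.asarray(genotypes, dtype=float)
    if G.shape[1] == ensemble.n_panel_loci:
        G = G[:, ensemble.kept_loci]
    elif G.shape[1] != ensemble.kept_loci.size:
        raise ValueError(
            f"locus mismatch: panel has {G.shape[1]} loci; predictor expects "
            f"{ensemble.n_panel_loci} (full panel) or {ensemble.kept_loci.size} (QTLs dropped)"
        )
    pred = ensemble.estimator.predict(G)
    ids = list(ids) if ids is not None else [str(i) for i in range(G.shape[0])]
    return OriginPrediction(ids=ids, pred=pred)


def cross_validate_predictor(
    genotypes,
    coords,
    qtl_indices=None,
    n_folds: int = 10,
    n_replicates: int = 10,
    seed: int | None = None,
    **net_params,
) -> pd.DataFrame:
    """k-fold cross-validation with replicates for geo-referenced panels.

    The mode used to benchmark prediction accuracy on an empirical
    collection: each replicate shuffles individuals into ``n_folds`` folds,
    each fold is predicted by a single network trained on the remaining
    folds (with a nested tenth of the training part held out for early
    stopping), and per-(replicate, fold) R2 and distance errors are
    returned — one row per fold model.
    """
    G = np.asarray(genotypes, dtype=float)
    y = np.asarray(coords, dtype=float)
    keep = np.ones(G.shape[1], dtype=bool)
    if qtl_indices is not None and len(qtl_indices) > 0:
        keep[np.asarray(qtl_indices, dtype=int)] = False
    G = G[:, keep]
    root = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        fold_of = root.permutation(np.arange(G.shape[0]) % n_folds)
        for fold in range(n_folds):
            test = fold_of == fold
            # one network per (replicate, fold); an internal tenth of the
            # training part serves as the early-stopping validation set
            est = OriginEnsembleRegressor(
                n_folds=10 if (~test).sum() >= 20 else 2,
                n_replicates=1,
                max_members=1,
                random_state=int(root.integers(2**31)),
                **net_params,
            )
            est.fit(G[~test], y[~test])
            pred = est.predict(G[test])
            err = haversine_km(pred[:, 0], pred[:, 1], y[test, 0], y[test, 1])
            rows.append(
                {
                    "replicate": rep,
                    "fold": fold,
                    "n_test": int(test.sum()),
                    "r2_lon": _r2_pearson(y[test, 0], pred[:, 0]),
                    "r2_lat": _r2_pearson(y[test, 1], pred[:, 1]),
                    "err_mean_km": float(err.mean()),
                    "err_median_km": float(np.median(err)),
                }
            )
    return pd.DataFrame(rows)


def _r2_pearson(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def _r2_cod(true, pred):
    true = np.asarray(true, dtype=float)
    sst = ((true - true.mean()) ** 2).sum()
    if sst == 0:
        return np.nan
    return float(1.0 - ((true - pred) ** 2).sum() / sst)


def accuracy_metrics(pred_coords, true_coords, type_labels=None) -> pd.DataFrame:
    """Per-axis R2 (squared Pearson, with 1-SSE/SST alongside) and haversine
    errors (km), stratified by prediction type.  R2 is NaN (flagged missing,
    not 0) when the truth has zero variance."""
    pred = np.asarray(pred_coords, dtype=float)
    true = np.asarray(true_coords, dtype=float)
    if pred.shape != true.shape or pred.ndim != 2 or pred.shape[0] < 2:
        raise ValueError("need aligned (n>=2, 2) coordinate arrays")
    labels = pd.Series(type_labels) if type_labels is not None else pd.Series(["all"] * pred.shape[0])
    err = haversine_km(pred[:, 0], pred[:, 1], true[:, 0], true[:, 1])
    rows = []
    groups = [("all", np.ones(pred.shape[0], dtype=bool))]
    groups += [(t, (labels == t).to_numpy()) for t in sorted(labels.unique()) if t != "all"]
    for name, m in groups:
        if m.sum() < 2:
            continue
        rows.append(
            {
                "type": name,
                "n": int(m.sum()),
                "r2_lon": _r2_pearson(true[m, 0], pred[m, 0]),
                "r2_lat": _r2_pearson(true[m, 1], pred[m, 1]),
                "r2_cod_lon": _r2_cod(true[m, 0], pred[m, 0]),
                "r2_cod_lat": _r2_cod(true[m, 1], pred[m, 1]),
                "err_mean_km": float(err[m].mean()),
                "err_median_km": float(np.median(err[m])),
                "err_sd_km": float(err[m].std(ddof=1)),
            }
        )
    return pd.DataFrame(rows).set_index("type")
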