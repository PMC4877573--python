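"""Feature tables, classifiers and cross-validation protocols.

Descriptor vectors are assembled into a *feature table* — a pandas DataFrame
with identifier columns ``sample_id``, ``species``, ``environment`` followed
by feature columns ``f0..fn`` — which is the substrate for every evaluation
protocol:

* stratified k-fold cross-validation (6 folds, repeated 10 times by
  default) with optional per-fold z-scoring and PCA, reporting pooled
  accuracy, its standard deviation over repeats, and per-class success
  rates;
* a split-environment protocol that trains on one environment and tests on
  held-out samples from another, quantifying robustness to phenotypic
  plasticity;
* fusion of texture features with manually measured stomatal traits
  (density, guard-cell length, stomatal-complex width).

Classification uses 1-nearest-neighbour (Euclidean) or a pooled-covariance
Gaussian linear discriminant; both are implemented as sklearn-style
estimators with deterministic tie-breaking so runs reproduce bit-for-bit
given (table, seed, config).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

logger = logging.getLogger(__name__)

ID_COLUMNS = ["sample_id", "species", "environment"]

#: component-count grid searched by pca='auto' (capped per training fold)
DEFAULT_PCA_GRID = (2, 5, 10, 20, 40, 80)


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def make_feature_table(
    features: np.ndarray,
    species: list[str],
    sample_ids: list[str] | None = None,
    environment: list[str] | str = "default",
) -> pd.DataFrame:
    """Assemble descriptor rows and labels into a feature table."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2:
        raise ValueError("features must be a 2-D (samples x features) array")
    n = features.shape[0]
    if len(species) != n:
        raise ValueError("species labels do not match feature rows")
    if sample_ids is None:
        sample_ids = [f"s{i:04d}" for i in range(n)]
    if isinstance(environment, str):
        environment = [environment] * n
    df = pd.DataFrame(
        {"sample_id": sample_ids, "species": list(species), "environment": list(environment)}
    )
    feat = pd.DataFrame(features, columns=[f"f{i}" for i in range(features.shape[1])])
    return pd.concat([df, feat.set_index(df.index)], axis=1)


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ID_COLUMNS]


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a feature table into (X, y) arrays."""
    cols = feature_columns(table)
    if not cols:
        raise ValueError("table has no feature columns")
    X = table[cols].to_numpy(dtype=np.float64)
    y = table["species"].to_numpy()
    return X, y


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_feature_table(table: pd.DataFrame, path, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        table.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

class KNearestNeighbors(BaseEstimator, ClassifierMixin):
    """k-nearest-neighbour classifier with pinned deterministic tie rules.

    Majority vote among the ``k`` nearest training rows under Euclidean
    distance.  Distance ties are broken by the lowest training-row index
    (stable sort) and vote ties by the smallest class label, so predictions
    are order-independent and reproducible.

    Parameters
    ----------
    k : int, default 1
        Neighbourhood size; ``k=1`` reduces to the nearest neighbour.
    """

    def __init__(self, k: int = 1):
        self.k = k

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > X.shape[0]:
            raise ValueError(f"k={self.k} exceeds n_train={X.shape[0]}")
        self.classes_ = unique_labels(y)
        self.X_ = X
        self.y_ = y
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "X_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature length mismatch between train and test")
        D = cdist(X, self.X_)
        # stable argsort: equidistant rows keep ascending training index
        order = np.argsort(D, axis=1, kind="stable")[:, : self.k]
        preds = []
        for row in order:
            votes = self.y_[row]
            labels, counts = np.unique(votes, return_counts=True)
            preds.append(sorted(labels[counts == counts.max()])[0])  # smallest label wins ties
        return np.asarray(preds)


class RidgeLDA(BaseEstimator, ClassifierMixin):
    """Gaussian linear discriminant with pooled covariance and a ridge.

    Maximises between- to within-class separation with a shared
    (pooled) within-class covariance and empirical class priors; the
    discriminant score of class c at x is

        delta_c(x) = x' S^-1 mu_c - mu_c' S^-1 mu_c / 2 + log pi_c

    where ``S`` is the pooled covariance plus a stabilising ridge
    ``reg * trace(S)/d`` on the diagonal (post-PCA covariances can remain
    ill-conditioned).

    Parameters
    ----------
    reg : float, default 1e-6
        Ridge magnitude relative to the mean covariance eigenvalue.
    """

    def __init__(self, reg: float = 1e-6):
        self.reg = reg

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        self.classes_ = unique_labels(y)
        n, d = X.shape
        k = len(self.classes_)
        if k < 2:
            raise ValueError("LDA needs at least 2 classes")
        if n <= k:
            singles = [str(c) for c in self.classes_ if np.sum(y == c) < 2]
            raise ValueError(
                "cannot pool within-class covariance: no residual degrees of "
                f"freedom (singleton classes: {', '.join(singles) or 'none'})"
            )
        self.means_ = np.vstack([X[y == c].mean(axis=0) for c in self.classes_])
        self.priors_ = np.array([np.mean(y == c) for c in self.classes_])
        S = np.zeros((d, d))
        for c, mu in zip(self.classes_, self.means_):
            R = X[y == c] - mu
            S += R.T @ R
        S /= n - k
        tr = np.trace(S)
        ridge = self.reg * (tr / d if tr > 0 else 1.0)
        self.covariance_ = S + ridge * np.eye(d)
        self._Sinv_means = np.linalg.solve(self.covariance_, self.means_.T)  # d x k
        self.n_features_in_ = d
        return self

    def decision_scores(self, X) -> np.ndarray:
        check_is_fitted(self, "means_")
        X = check_array(X, dtype=np.float64)
        lin = X @ self._Sinv_means
        offs = -0.5 * np.sum(self.means_.T * self._Sinv_means, axis=0) + np.log(self.priors_)
        return lin + offs

    def predict(self, X):
        scores = self.decision_scores(X)
        return self.classes_[np.argmax(scores, axis=1)]


def _make_classifier(classifier, k: int = 1):
    if isinstance(classifier, BaseEstimator):
        return clone(classifier)
    if classifier == "knn":
        return KNearestNeighbors(k=k)
    if classifier == "lda":
        return RidgeLDA()
    raise ValueError(f"unknown classifier {classifier!r}")


# ---------------------------------------------------------------------------
# dimensionality reduction
# ---------------------------------------------------------------------------

def pca_reduce(table: pd.DataFrame, n_components: int) -> pd.DataFrame:
    """Project a feature table onto its top principal components.

    Components are ordered by decreasing explained variance of the
    mean-centred data; fitting on a full table leaks information into any
    subsequent CV, so the CV protocols below refit PCA per training fold
    instead of calling this.
    """
    X, _ = feature_matrix(table)
    if n_components > min(X.shape):
        raise ValueError(f"n_components={n_components} exceeds min(n_samples, n_features)")
    Z = PCA(n_components=n_components, svd_solver="full").fit_transform(X)
    out = table[ID_COLUMNS].copy()
    for i in range(Z.shape[1]):
        out[f"f{i}"] = Z[:, i]
    return out


def _fit_transform_fold(X_tr, X_te, n_components, standardize):
    if standardize:
        scaler = StandardScaler().fit(X_tr)
        X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
    if n_components:
        n_components = min(n_components, X_tr.shape[0], X_tr.shape[1])
        p = PCA(n_components=n_components, svd_solver="full").fit(X_tr)
        X_tr, X_te = p.transform(X_tr), p.transform(X_te)
    return X_tr, X_te


def _select_n_components(X, y, clf, grid, standardize, rng) -> int:
    """Pick the grid entry maximising inner 3-fold CV accuracy."""
    grid = sorted({min(g, X.shape[0] - 2, X.shape[1]) for g in grid if g >= 1})
    if not grid:
        return 0
    _, counts = np.unique(y, return_counts=True)
    inner = min(3, counts.min())
    if inner < 2:
        return grid[-1]
    skf = StratifiedKFold(n_splits=inner, shuffle=True, random_state=int(rng.integers(2**31)))
    best, best_acc = grid[0], -1.0
    for g in grid:
        hits = total = 0
        for tr, te in skf.split(X, y):
            Xt, Xe = _fit_transform_fold(X[tr], X[te], g, standardize)
            pred = clone(clf).fit(Xt, y[tr]).predict(Xe)
            hits += int(np.sum(pred == y[te]))
            total += len(te)
        acc = hits / total
        if acc > best_acc:
            best, best_acc = g, acc
    return best


# ---------------------------------------------------------------------------
# evaluation protocols
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Aggregate of a repeated stratified cross-validation run.

    Accuracies are percentages; ``per_class_rate`` maps each species to its
    mean success rate over repeats; ``n_components`` records the retained
    PCA dimension (0 when PCA is off; the modal selection in auto mode).
    """

    mean_accuracy: float
    std_accuracy: float
    per_class_rate: dict[str, float]
    n_components: int
    repeat_accuracies: list[float] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.mean_accuracy <= 100.0):
            raise ValueError("mean accuracy out of [0, 100]")
        if self.std_accuracy < 0:
            raise ValueError("std must be >= 0")


def knn_predict(train: pd.DataFrame, test: pd.DataFrame, k: int = 1) -> np.ndarray:
    """Label test rows by the majority class of the k nearest training rows."""
    X_tr, y_tr = feature_matrix(train)
    X_te, _ = feature_matrix(test) if feature_columns(test) == feature_columns(train) else (None, None)
    if X_te is None:
        raise ValueError("feature columns of train and test tables differ")
    return KNearestNeighbors(k=k).fit(X_tr, y_tr).predict(X_te)


def lda_predict(train: pd.DataFrame, test: pd.DataFrame, reg: float = 1e-6) -> np.ndarray:
    """Label test rows with the pooled-covariance linear discriminant."""
    X_tr, y_tr = feature_matrix(train)
    if feature_columns(test) != feature_columns(train):
        raise ValueError("feature columns of train and test tables differ")
    X_te, _ = feature_matrix(test)
    return RidgeLDA(reg=reg).fit(X_tr, y_tr).predict(X_te)


def stratified_cv(
    table: pd.DataFrame,
    classifier="knn",
    k: int = 1,
    folds: int = 6,
    repeats: int = 10,
    seed: int = 0,
    pca: int | str | None = None,
    pca_grid: tuple[int, ...] = DEFAULT_PCA_GRID,
    standardize: bool = True,
    reduce_folds: bool = True,
) -> CVResult:
    """Repeated stratified k-fold cross-validation of a feature table.

    Per repeat, samples are shuffled (seeded) into ``folds`` near-equal
    class-preserving subsets; each subset serves once as the test set.
    Standardisation and PCA — ``pca`` is a component count, ``'auto'``
    (inner-CV grid selection per fold) or None/0/'off' — are fitted on
    training folds only.  Accuracy per repeat is pooled over folds (% of all
    samples correctly labelled); the result aggregates mean/std over repeats
    and mean per-class rates.

    Classes smaller than the fold count reduce the fold count with a warning
    when ``reduce_folds`` is set, and raise otherwise.  Rows are put in
    canonical (sample_id) order before splitting, so results are invariant
    to the order samples arrive in.
    """
    table = table.sort_values("sample_id", kind="stable").reset_index(drop=True)
    X, y = feature_matrix(table)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("stratified CV requires >= 2 samples per class")
    if counts.min() < folds:
        if not reduce_folds:
            raise ValueError(
                f"smallest class has {counts.min()} samples < {folds} folds"
            )
        folds_eff = int(counts.min())
        warnings.warn(
            f"reducing folds from {folds} to {folds_eff}: smallest class has "
            f"{counts.min()} samples"
        )
    else:
        folds_eff = folds

    if pca in (None, "off", 0):
        pca_mode = None
    elif pca == "auto":
        pca_mode = "auto"
    else:
        pca_mode = int(pca)

    clf_proto = _make_classifier(classifier, k=k)
    master = np.random.default_rng(seed)
    repeat_seeds = master.integers(2**31, size=repeats)

    accs = []
    class_hits = {c: [] for c in np.unique(y)}
    chosen_components: list[int] = []
    for rseed in repeat_seeds:
        rng = np.random.default_rng(int(rseed))
        skf = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=int(rseed))
        pred_all = np.empty(len(y), dtype=y.dtype)
        for tr, te in skf.split(X, y):
            if pca_mode == "auto":
                g = _select_n_components(X[tr], y[tr], clf_proto, pca_grid, standardize, rng)
            else:
                g = pca_mode or 0
            Xt, Xe = _fit_transform_fold(X[tr], X[te], g, standardize)
            pred_all[te] = clone(clf_proto).fit(Xt, y[tr]).predict(Xe)
            chosen_components.append(g)
        accs.append(100.0 * np.mean(pred_all == y))
        for c in class_hits:
            mask = y == c
            class_hits[c].append(100.0 * np.mean(pred_all[mask] == y[mask]))

    comp = int(np.bincount(chosen_components).argmax()) if chosen_components else 0
    return CVResult(
        mean_accuracy=float(np.mean(accs)),
        std_accuracy=float(np.std(accs)),
        per_class_rate={str(c): float(np.mean(v)) for c, v in class_hits.items()},
        n_components=comp,
        repeat_accuracies=[float(a) for a in accs],
        config={
            "classifier": getattr(classifier, "__class__", type("", (), {})).__name__
            if isinstance(classifier, BaseEstimator)
            else classifier,
            "k": k,
            "folds": folds_eff,
            "repeats": repeats,
            "seed": seed,
            "pca": pca,
            "standardize": standardize,
        },
    )


def split_environment_eval(
    train: pd.DataFrame,
    test: pd.DataFrame,
    classifier="knn",
    k: int = 1,
    pca: int | str | None = None,
    pca_grid: tuple[int, ...] = DEFAULT_PCA_GRID,
    standardize: bool = True,
    seed: int = 0,
) -> dict:
    """Train on one table, evaluate on a held-out (other-environment) table.

    The model (standardiser, PCA, classifier) is fitted on the full training
    table only.  Returns overall and per-class success percentages for the
    held-out samples.  Every test class must appear in training.
    """
    if feature_columns(test) != feature_columns(train):
        raise ValueError("feature columns of train and test tables differ")
    X_tr, y_tr = feature_matrix(train)
    X_te, y_te = feature_matrix(test)
    missing = sorted(set(y_te) - set(y_tr))
    if missing:
        raise ValueError(f"test classes absent from training: {', '.join(map(str, missing))}")

    clf = _make_classifier(classifier, k=k)
    if pca == "auto":
        g = _select_n_components(X_tr, y_tr, clf, pca_grid, standardize, np.random.default_rng(seed))
    else:
        g = 0 if pca in (None, "off", 0) else int(pca)
    Xt, Xe = _fit_transform_fold(X_tr, X_te, g, standardize)
    pred = clf.fit(Xt, y_tr).predict(Xe)

    per_class = {}
    for c in np.unique(y_te):
        mask = y_te == c
        per_class[str(c)] = 100.0 * float(np.mean(pred[mask] == y_te[mask]))
    return {
        "overall": 100.0 * float(np.mean(pred == y_te)),
        "per_class": per_class,
        "n_components": g,
        "n_test": len(y_te),
    }


def fuse_features(texture: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Append manual stomatal traits to each sample's texture features.

    ``traits`` must carry ``sample_id`` plus ``density``,
    ``guard_cell_length`` and ``complex_width`` columns; the fused feature
    vector is the texture vector followed by the three trait values, so the
    feature length grows by exactly 3.  Samples without a trait row raise,
    listing the orphan ids.
    """
    required = ["density", "guard_cell_length", "complex_width"]
    for col in required:
        if col not in traits.columns:
            raise ValueError(f"traits table is missing column {col!r}")
    t = traits.set_index("sample_id")
    orphans = [sid for sid in texture["sample_id"] if sid not in t.index]
    if orphans:
        raise ValueError(f"missing trait rows for samples: {', '.join(map(str, orphans))}")
    cols = feature_columns(texture)
    out = texture[ID_COLUMNS + cols].copy()
    n = len(cols)
    aligned = t.loc[texture["sample_id"], required].to_numpy(dtype=np.float64)
    for i, _ in enumerate(required):
        out[f"f{n + i}"] = aligned[:, i]
    return out


def traits_only_table(labels: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Feature table whose only features are the three manual traits."""
    empty = labels[ID_COLUMNS].copy()
    return fuse_features(empty, traits)
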