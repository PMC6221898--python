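"""Sparse-LDA feature ranking and subject-independent SVM classification.

Sparse linear discriminant analysis is implemented in its optimal-scoring
form: the K−1 discriminant vectors w_q successively maximize between- to
within-class variance subject to an elastic-net penalty, obtained by
alternating (i) a penalized regression of the scored class indicators on
the features and (ii) an update of the class scores under D-orthogonality
to the earlier score vectors (D = diag of class proportions).  The ℓ1
term zeroes many coefficients; surviving features are ranked by the
largest absolute coefficient across the discriminant vectors, ties broken
by column order.

Classification uses a soft-margin linear SVM on the top-ranked features,
evaluated by leave-one-subject-out cross-validation: per fold, feature
standardization, SLDA ranking and the SVM are all fitted on the training
subjects only, so accuracies are subject-independent and leakage-free.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet
from sklearn.svm import SVC

from .features import FeatureTable, SET_IDS, assemble_feature_set
from .signal import BandPowerTable

TASKS: dict[str, tuple[str, ...]] = {
    "tender_vs_amuse": ("tenderness", "amusement"),
    "anger_vs_fear": ("anger", "fear"),
    "four_class": ("amusement", "tenderness", "anger", "fear"),
}


@dataclass
class SldaParams:
    """Penalties and iteration controls for the optimal-scoring solver."""

    l1: float = 0.01            # sparsity weight
    l2: float = 0.01            # ridge weight
    max_iter: int = 50
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.l1 < 0 or self.l2 < 0:
            raise ValueError("penalties must be non-negative")


@dataclass
class SldaModel:
    vectors: np.ndarray                 # (n_features, K-1)
    feature_names: list[str]
    classes: np.ndarray
    ranking: list[str]                  # support features, best first
    params: SldaParams
    mean_: np.ndarray = field(repr=False, default=None)
    scale_: np.ndarray = field(repr=False, default=None)

    @property
    def support(self) -> list[str]:
        return self.ranking


def _elastic_net_step(X: np.ndarray, target: np.ndarray, params: SldaParams
                      ) -> np.ndarray:
    n = X.shape[0]
    alpha = params.l1 + params.l2
    if alpha == 0:
        w, *_ = np.linalg.lstsq(X, target, rcond=None)
        return w
    l1_ratio = params.l1 / alpha
    en = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, fit_intercept=False,
                    max_iter=10_000, tol=1e-8)
    with warnings.catch_warnings():
        # near-converged fits (duality gap ~1e-7) are fine for ranking
        warnings.simplefilter("ignore", ConvergenceWarning)
        en.fit(X, target)
    return en.coef_.copy()


def slda_rank(X, y, params: SldaParams | None = None) -> SldaModel:
    """Fit sparse discriminant vectors and rank features by |coefficient|.

    ``X`` may be a DataFrame (column names become feature names) or an
    array.  Features are standardized internally with the statistics of
    the data supplied (training folds only, in cross-validation use).
    Deterministic: score vectors are initialized from fixed indicator
    contrasts, and the coordinate-descent solver is deterministic.
    """
    params = params or SldaParams()
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xa.shape[1])]
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    K = classes.size
    if K < 2:
        raise ValueError("need at least two classes")
    counts = np.bincount(y_idx, minlength=K)
    if counts.min() < 2:
        raise ValueError("each class needs at least two instances")
    n, p = Xa.shape

    mean = Xa.mean(axis=0)
    scale = Xa.std(axis=0, ddof=0)
    if np.all(scale == 0):
        raise ValueError("all features are constant")
    scale = np.where(scale == 0, 1.0, scale)
    Z = (Xa - mean) / scale

    Y = np.zeros((n, K))
    Y[np.arange(n), y_idx] = 1.0
    D = counts / n                               # class proportions (diag of YᵀY/n)

    def d_orth(theta: np.ndarray, prev: list[np.ndarray]) -> np.ndarray:
        for q in prev:
            theta = theta - q * (theta * D) @ q
        return theta

    prev_thetas = [np.ones(K)]                   # trivial constant score
    W = np.zeros((p, K - 1))
    for q in range(K - 1):
        # deterministic init: indicator contrast for class q, D-orthogonalized
        theta = np.zeros(K)
        theta[q] = 1.0
        theta = d_orth(theta, prev_thetas)
        norm = np.sqrt((theta ** 2 * D).sum())
        if norm == 0:
            theta = d_orth(np.arange(K, dtype=float), prev_thetas)
            norm = np.sqrt((theta ** 2 * D).sum())
        theta /= norm
        w = np.zeros(p)
        for _ in range(params.max_iter):
            w_new = _elastic_net_step(Z, Y @ theta, params)
            theta_new = d_orth((Y.T @ (Z @ w_new)) / (n * D), prev_thetas)
            norm = np.sqrt((theta_new ** 2 * D).sum())
            if norm < 1e-12:
                w, theta = w_new, theta
                break
            theta_new /= norm
            delta = np.abs(w_new - w).max()
            w, theta = w_new, theta_new
            if delta < params.tol:
                break
        W[:, q] = w
        prev_thetas.append(theta)

    strength = np.abs(W).max(axis=1)
    support = np.flatnonzero(strength > 0)
    order = support[np.argsort(-strength[support], kind="stable")]
    ranking = [names[j] for j in order]
    return SldaModel(vectors=W, feature_names=names, classes=classes,
                     ranking=ranking, params=params, mean_=mean, scale_=scale)


@dataclass
class ClassificationReport:
    """Fold-level predictions and summary accuracy of one LOSO run."""

    predictions: pd.DataFrame       # columns subject, truth, prediction
    confusion: pd.DataFrame
    accuracy: float
    n_folds: int
    task: str = ""
    set_id: str = ""
    #: per held-out subject: digest of the fold's selected features and SVM
    #: coefficients; depends on the training subjects only.
    fold_models: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")
        if int(self.confusion.to_numpy().sum()) != len(self.predictions):
            raise ValueError("confusion matrix total must equal #test instances")


def loso_cv(X, y, subject_ids, classifier_params: dict | None = None,
            top_k: int | None = None, slda_params: SldaParams | None = None,
            task: str = "", set_id: str = "") -> ClassificationReport:
    """Leave-one-subject-out evaluation of SLDA-selected-feature SVM.

    One fold per unique subject.  Standardization statistics, the SLDA
    ranking and the SVM are computed on the training subjects only.
    ``top_k`` limits the ranking (default: all features with nonzero
    sparse coefficients; if the sparse support is empty the fold falls
    back to all features).
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xa.shape[1])]
    y = np.asarray(y)
    subjects = np.asarray(subject_ids)
    classes = np.unique(y)
    cparams = {"kernel": "linear", "C": 1.0}
    cparams.update(classifier_params or {})

    rows = []
    fold_models: dict = {}
    unique_subjects = pd.unique(subjects)
    for subj in unique_subjects:
        test = subjects == subj
        train = ~test
        y_train = y[train]
        if np.unique(y_train).size < classes.size:
            raise ValueError(f"training set for held-out subject {subj!r} "
                             "lost a class")
        model = slda_rank(pd.DataFrame(Xa[train], columns=names), y_train,
                          slda_params)
        selected = model.ranking if model.ranking else list(names)
        if top_k is not None:
            selected = selected[:top_k] if len(selected) >= 1 else selected
        idx = [names.index(f) for f in selected]
        mean = Xa[train][:, idx].mean(axis=0)
        sd = Xa[train][:, idx].std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        clf = SVC(**cparams)
        clf.fit((Xa[train][:, idx] - mean) / sd, y_train)
        digest = hashlib.sha256()
        digest.update("|".join(selected).encode())
        digest.update(np.ascontiguousarray(clf.dual_coef_).tobytes())
        digest.update(np.ascontiguousarray(clf.intercept_).tobytes())
        fold_models[subj] = digest.hexdigest()
        pred = clf.predict((Xa[test][:, idx] - mean) / sd)
        for truth, hat in zip(y[test], pred):
            rows.append({"subject": subj, "truth": truth, "prediction": hat})

    predictions = pd.DataFrame(rows)
    confusion = pd.crosstab(predictions["truth"], predictions["prediction"]
                            ).reindex(index=classes, columns=classes, fill_value=0)
    accuracy = float((predictions["truth"] == predictions["prediction"]).mean())
    return ClassificationReport(predictions=predictions, confusion=confusion,
                                accuracy=accuracy, n_folds=len(unique_subjects),
                                task=task, set_id=set_id, fold_models=fold_models)


def run_feature_set_experiment(powers: BandPowerTable,
                               set_ids=SET_IDS, tasks=tuple(TASKS),
                               classifier_params: dict | None = None,
                               top_k: int | None = None,
                               slda_params: SldaParams | None = None,
                               value: str = "normalized"
                               ) -> dict[tuple[str, str], ClassificationReport]:
    """LOSO accuracy for every (task, feature set) combination.

    Returns a dict keyed by (task, set_id); use :func:`experiment_table`
    for the feature-set × task accuracy summary.
    """
    tables = {sid: assemble_feature_set(powers, sid, value) for sid in set_ids}
    out: dict[tuple[str, str], ClassificationReport] = {}
    for task in tasks:
        conditions = TASKS[task]
        for sid, table in tables.items():
            df = table.data
            mask = df.index.get_level_values("condition").isin(conditions)
            sub = df[mask]
            subjects = sub.index.get_level_values("subject").to_numpy()
            labels = sub.index.get_level_values("condition").to_numpy()
            out[(task, sid)] = loso_cv(
                sub.reset_index(drop=True), labels, subjects,
                classifier_params=classifier_params, top_k=top_k,
                slda_params=slda_params, task=task, set_id=sid)
    return out


def experiment_table(reports: dict[tuple[str, str], ClassificationReport]
                     ) -> pd.DataFrame:
    """Accuracy summary: rows = feature sets, columns = tasks."""
    rows = sorted({sid for _, sid in reports})
    cols = sorted({task for task, _ in reports})
    table = pd.DataFrame(index=rows, columns=cols, dtype=float)
    for (task, sid), rep in reports.items():
        table.loc[sid, task] = rep.accuracy
    table.index.name = "feature_set"
    return table
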