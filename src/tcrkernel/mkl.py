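"""Multiple kernel learning over percentile-tuned Gaussian kernel banks.

For each feature set, seven RBF kernels are built whose widths come from a
data-driven heuristic: all Euclidean distances between positive and negative
training rows are collected, σ is read off at the 1st, 2nd, 5th, 50th, 95th,
98th and 99th percentiles, and γ = 1/(2σ²).  The kernels are combined by
EasyMKL (Aiolli & Donini's margin-based weighting): with λ = 0, the problem

    minimise γᵀ Ŷ K̄ Ŷ γ   over the bi-simplex (γ ≥ 0, each class sums to 1)

finds the nearest points of the two class convex hulls in the feature space
of the average kernel K̄; each kernel's weight is its quadratic form at the
optimum, η_r ∝ γ*ᵀ Ŷ K_r Ŷ γ*.  A support-vector classifier on the weighted
kernel sum, with C selected by internal stratified cross-validation, gives
the final decision function.  Generalisation is estimated by repeated
stratified 70/30 holdout with the whole pipeline refit inside each split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .features import FeatureTable, PreprocessState, apply_preprocess, fit_preprocess

__all__ = [
    "SIGMA_PERCENTILES",
    "GAMMA_CAP",
    "DEFAULT_C_GRID",
    "KernelBank",
    "MklModel",
    "gamma_heuristic",
    "build_bank",
    "easymkl_weights",
    "fit",
    "predict",
    "train_model",
    "repeated_holdout",
    "HoldoutResult",
    "evaluate",
]

#: Percentiles of the positive-negative distance distribution defining σ.
SIGMA_PERCENTILES = (1, 2, 5, 50, 95, 98, 99)

#: γ ceiling when duplicate positive/negative rows give σ = 0.
GAMMA_CAP = 1e6

#: Decade grid over the regulariser search range 1e-5 … 1e2.
DEFAULT_C_GRID = tuple(10.0 ** e for e in range(-5, 3))


@dataclass(frozen=True)
class KernelEntry:
    feature_set: str
    percentile: float
    gamma: float
    gram: np.ndarray


@dataclass(frozen=True)
class KernelBank:
    """Per-feature-set collections of Gaussian Gram matrices."""

    entries: tuple[KernelEntry, ...]
    sample_ids: tuple

    @property
    def grams(self) -> list[np.ndarray]:
        return [e.gram for e in self.entries]

    def gammas(self, feature_set: str) -> np.ndarray:
        return np.array([e.gamma for e in self.entries if e.feature_set == feature_set])

    @property
    def feature_sets(self) -> list[str]:
        return list(dict.fromkeys(e.feature_set for e in self.entries))


def _columns_of(table: FeatureTable, feature_set: str) -> np.ndarray:
    X = table.data[feature_set].to_numpy(dtype=float)
    if X.shape[1] == 0:
        raise ValueError(f"feature set {feature_set!r} has no columns")
    return X


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=float)
    classes = set(np.unique(y))
    if not classes <= {-1.0, 1.0} or len(classes) < 2:
        raise ValueError("labels must contain both classes, coded +1/-1")
    return y


def gamma_heuristic(
    table: FeatureTable, labels, feature_set: str
) -> tuple[np.ndarray, np.ndarray]:
    """σ percentiles of the cross-class distance distribution and their γ.

    Computes every Euclidean distance between a positive and a negative
    training row over the feature set's columns, takes the
    :data:`SIGMA_PERCENTILES` (linear interpolation), and maps each σ to
    γ = 1/(2σ²).  Duplicate rows across classes give σ = 0; those γ are
    capped at :data:`GAMMA_CAP`.  Returns ``(sigmas, gammas)``.
    """
    y = _check_labels(labels)
    X = _columns_of(table, feature_set)
    d = cdist(X[y > 0], X[y < 0]).ravel()
    sigmas = np.percentile(d, SIGMA_PERCENTILES)
    with np.errstate(divide="ignore"):
        gammas = 1.0 / (2.0 * sigmas**2)
    if np.any(sigmas == 0):
        warnings.warn(
            "duplicate positive/negative rows give sigma=0; capping gamma", stacklevel=2
        )
        gammas = np.minimum(gammas, GAMMA_CAP)
    return sigmas, gammas


def _rbf(X: np.ndarray, Z: np.ndarray, gamma: float) -> np.ndarray:
    return np.exp(-gamma * cdist(X, Z, "sqeuclidean"))


def build_bank(
    table: FeatureTable, labels, feature_sets: Sequence[str]
) -> KernelBank:
    """Seven Gaussian Grams per feature set, widths from the γ heuristic."""
    _check_labels(labels)
    entries = []
    for fset in feature_sets:
        X = _columns_of(table, fset)
        _, gammas = gamma_heuristic(table, labels, fset)
        sq = cdist(X, X, "sqeuclidean")
        for pct, g in zip(SIGMA_PERCENTILES, gammas):
            entries.append(
                KernelEntry(feature_set=fset, percentile=pct, gamma=g, gram=np.exp(-g * sq))
            )
    return KernelBank(entries=tuple(entries), sample_ids=tuple(table.sample_ids))


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex (sum 1, ≥ 0)."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u - css / np.arange(1, len(v) + 1) > 0)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def _project_bisimplex(g: np.ndarray, pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    out = np.empty_like(g)
    out[pos] = _project_simplex(g[pos])
    out[neg] = _project_simplex(g[neg])
    return out


def easymkl_weights(
    bank: KernelBank | Sequence[np.ndarray],
    labels,
    lam: float = 0.0,
    max_iter: int = 5000,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """EasyMKL kernel weights.

    Solves ``min (1-λ)·γᵀŶK̄Ŷγ + λ‖γ‖²`` over the bi-simplex (γ ≥ 0 with
    each class summing to 1), where K̄ is the unweighted mean Gram and
    Ŷ = diag(labels), by accelerated projected gradient descent.  Weights
    are the per-kernel quadratic forms ``η_r ∝ γ*ᵀŶK_rŶγ*`` (nonnegative
    for PSD Grams), normalised to sum to 1.

    Returns ``(eta, gamma_star)``.
    """
    grams = bank.grams if isinstance(bank, KernelBank) else list(bank)
    if not grams:
        raise ValueError("empty kernel bank")
    y = _check_labels(labels)
    n = len(y)
    K_bar = sum(grams) / len(grams)
    YKY = (1.0 - lam) * (y[:, None] * K_bar * y[None, :]) + lam * np.eye(n)

    pos, neg = y > 0, y < 0
    g = np.zeros(n)
    g[pos] = 1.0 / pos.sum()
    g[neg] = 1.0 / neg.sum()

    # Lipschitz constant of the gradient 2·YKY·γ
    L = 2.0 * max(np.linalg.eigvalsh(YKY).max(), 1e-12)
    step = 1.0 / L
    z, t = g.copy(), 1.0
    obj_prev = np.inf
    for it in range(max_iter):
        grad = 2.0 * YKY @ z
        g_new = _project_bisimplex(z - step * grad, pos, neg)
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        z = g_new + ((t - 1.0) / t_new) * (g_new - g)
        g, t = g_new, t_new
        obj = g @ YKY @ g
        if abs(obj_prev - obj) < tol * max(1.0, abs(obj)):
            break
        obj_prev = obj
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("EasyMKL projected-gradient iteration diverged")

    yg = y * g
    eta = np.array([yg @ Kr @ yg for Kr in grams])
    eta = np.maximum(eta, 0.0)
    total = eta.sum()
    if total <= 0:
        eta = np.full(len(grams), 1.0 / len(grams))
    else:
        eta = eta / total
    return eta, g


@dataclass
class MklModel:
    """Frozen EasyMKL + SVC model: everything needed to score new samples."""

    eta: np.ndarray
    kernel_meta: tuple  # (feature_set, percentile, gamma) per kernel
    C: float
    svc: SVC
    preprocess: PreprocessState
    train_data: pd.DataFrame  # preprocessed training rows
    labels: np.ndarray
    internal_cv_auc: Mapping[float, float] = field(default_factory=dict)

    @property
    def feature_sets(self) -> list[str]:
        return list(dict.fromkeys(m[0] for m in self.kernel_meta))

    def combined_train_gram(self) -> np.ndarray:
        X = {f: self.train_data[f].to_numpy(dtype=float) for f in self.feature_sets}
        K = np.zeros((len(self.train_data),) * 2)
        for w, (fset, _, g) in zip(self.eta, self.kernel_meta):
            K += w * _rbf(X[fset], X[fset], g)
        return K

    def summary(self) -> dict:
        return {
            "C": self.C,
            "eta": [round(float(w), 12) for w in self.eta],
            "kernels": [
                {"feature_set": f, "percentile": p, "gamma": float(g)}
                for f, p, g in self.kernel_meta
            ],
            "n_train": int(len(self.train_data)),
            "intercept": round(float(self.svc.intercept_[0]), 12),
            "dual_coef": [round(float(v), 12) for v in self.svc.dual_coef_[0]],
        }


def fit(
    bank: KernelBank,
    labels,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    preprocess: PreprocessState | None = None,
    train_table: FeatureTable | None = None,
    n_internal_folds: int = 10,
    seed: int = 0,
) -> MklModel:
    """EasyMKL weighting followed by an internal-CV search for the SVC C.

    The combined Gram ``K* = Σ η_r K_r`` is fixed once from the whole
    training set; for every C on the (decade) grid, stratified internal
    cross-validation measures mean ROC AUC, and the best C — ties broken
    toward the smaller, more strongly regularised value — trains the final
    classifier on all rows.
    """
    y = _check_labels(labels)
    if len(y) < 20:
        raise ValueError(f"need at least 20 training samples for internal CV, got {len(y)}")
    eta, _ = easymkl_weights(bank, y)
    K = np.zeros_like(bank.grams[0])
    for w, Kr in zip(eta, bank.grams):
        K += w * Kr

    min_class = int(min((y > 0).sum(), (y < 0).sum()))
    n_folds = min(n_internal_folds, min_class)
    if n_folds < n_internal_folds:
        warnings.warn(
            f"reducing internal CV folds from {n_internal_folds} to {n_folds} "
            "(minority class too small)",
            stacklevel=2,
        )
    if n_folds < 2:
        raise ValueError("internal CV needs at least 2 samples per class")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))
    cv_auc: dict[float, float] = {}
    for C in C_grid:
        fold_aucs = []
        for tr, te in splits:
            clf = SVC(kernel="precomputed", C=C)
            clf.fit(K[np.ix_(tr, tr)], y[tr])
            scores = clf.decision_function(K[np.ix_(te, tr)])
            if len(np.unique(y[te])) < 2:
                continue
            fold_aucs.append(roc_auc_score(y[te], scores))
        cv_auc[C] = float(np.mean(fold_aucs)) if fold_aucs else float("nan")

    best = max(sorted(cv_auc), key=lambda c: (round(cv_auc[c], 12), -c))
    svc = SVC(kernel="precomputed", C=best)
    svc.fit(K, y)

    meta = tuple((e.feature_set, e.percentile, e.gamma) for e in bank.entries)
    return MklModel(
        eta=eta,
        kernel_meta=meta,
        C=best,
        svc=svc,
        preprocess=preprocess,
        train_data=train_table.data if train_table is not None else None,
        labels=y,
        internal_cv_auc=cv_auc,
    )


def predict(model: MklModel, new_table: FeatureTable, preprocessed: bool = False) -> np.ndarray:
    """Decision scores for new samples (higher = more binder-like).

    Applies the model's frozen preprocessing, evaluates every stored kernel
    between the new rows and the training rows, and scores with the trained
    classifier on the η-weighted kernel sum.
    """
    if model.train_data is None:
        raise ValueError("model was fitted without stored training rows")
    if not preprocessed:
        new_table = apply_preprocess(model.preprocess, new_table)
    if list(new_table.data.columns) != list(model.train_data.columns):
        raise ValueError("feature columns of the new table do not match the model")
    K = np.zeros((len(new_table.data), len(model.train_data)))
    for w, (fset, _, g) in zip(model.eta, model.kernel_meta):
        Xn = new_table.data[fset].to_numpy(dtype=float)
        Xt = model.train_data[fset].to_numpy(dtype=float)
        K += w * _rbf(Xn, Xt, g)
    return model.svc.decision_function(K)


def train_model(
    raw_table: FeatureTable,
    labels,
    feature_sets: Sequence[str],
    row_norm: str = "l2",
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    seed: int = 0,
) -> MklModel:
    """Full pipeline on a raw (unpreprocessed) training table."""
    y = _check_labels(labels)
    cols = [c for c in raw_table.feature_sets if c in feature_sets]
    missing = set(feature_sets) - set(cols)
    if missing:
        raise ValueError(f"table lacks feature sets: {sorted(missing)}")
    sub = FeatureTable(raw_table.data[list(feature_sets)], raw_table.labels)
    state = fit_preprocess(sub, row_norm=row_norm)
    train = apply_preprocess(state, sub)
    bank = build_bank(train, y, feature_sets)
    return fit(bank, y, C_grid=C_grid, preprocess=state, train_table=train, seed=seed)


@dataclass
class HoldoutResult:
    aucs: np.ndarray
    mean_fpr: np.ndarray
    mean_tpr: np.ndarray
    tpr_sd: np.ndarray

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.aucs, ddof=1)) if len(self.aucs) > 1 else 0.0


def repeated_holdout(
    raw_table: FeatureTable,
    labels,
    feature_sets: Sequence[str],
    n_repeats: int = 10,
    test_frac: float = 0.30,
    seed: int = 0,
    row_norm: str = "l2",
    C_grid: Sequence[float] = DEFAULT_C_GRID,
) -> HoldoutResult:
    """Repeated stratified 70/30 Monte-Carlo holdout of the full pipeline.

    Preprocessing, the γ heuristic, the kernel bank, EasyMKL and the C
    search are all refit inside each training split; ROC AUC is measured on
    the held-out fraction.  Returns per-repeat AUCs and the interpolated
    mean ROC curve (± sd) on a common false-positive-rate grid.
    """
    y = _check_labels(labels)
    ids = np.asarray(raw_table.sample_ids, dtype=object)
    mean_fpr = np.linspace(0.0, 1.0, 101)
    tprs, aucs = [], []
    rep = 0
    attempt = 0
    while rep < n_repeats:
        rs = seed + attempt
        attempt += 1
        tr_ids, te_ids = train_test_split(
            ids, test_size=test_frac, stratify=y, random_state=rs
        )
        tr_mask = np.isin(ids, tr_ids)
        y_tr, y_te = y[tr_mask], y[~tr_mask]
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
            warnings.warn(f"degenerate split at seed {rs}; resplitting", stacklevel=2)
            continue
        sub_tr = raw_table.subset(list(ids[tr_mask]))
        sub_te = raw_table.subset(list(ids[~tr_mask]))
        model = train_model(
            sub_tr, y_tr, feature_sets, row_norm=row_norm, C_grid=C_grid, seed=rs
        )
        te_for_predict = FeatureTable(sub_te.data[list(feature_sets)], sub_te.labels)
        scores = predict(model, te_for_predict)
        aucs.append(roc_auc_score(y_te, scores))
        fpr, tpr, _ = roc_curve(y_te, scores)
        interp = np.interp(mean_fpr, fpr, tpr)
        interp[0] = 0.0
        tprs.append(interp)
        rep += 1
    tprs = np.array(tprs)
    return HoldoutResult(
        aucs=np.array(aucs),
        mean_fpr=mean_fpr,
        mean_tpr=tprs.mean(axis=0),
        tpr_sd=tprs.std(axis=0, ddof=1) if len(tprs) > 1 else np.zeros_like(mean_fpr),
    )


def evaluate(
    scores,
    labels,
    epitopes: Sequence[str] | None = None,
    threshold: float = 0.0,
) -> dict:
    """Ranking and thresholded classification metrics.

    Reports ROC AUC, average precision, and accuracy / precision / recall at
    the given decision threshold (default 0, the separating hyperplane).
    With per-sample ``epitopes``, adds per-epitope ROC AUC restricted to
    epitopes with at least 2 positive and 2 negative examples.
    """
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    pred = np.where(s > threshold, 1.0, -1.0)
    out = {
        "roc_auc": float(roc_auc_score(y, s)),
        "average_precision": float(average_precision_score(y, s)),
        "accuracy": float(accuracy_score(y, pred)),
        "precision": float(precision_score(y, pred, zero_division=0)),
        "recall": float(recall_score(y, pred, zero_division=0)),
    }
    if epitopes is not None:
        eps = np.asarray(epitopes, dtype=object)
        per_epitope = {}
        for ep in dict.fromkeys(eps):
            mask = eps == ep
            n_pos = int((y[mask] > 0).sum())
            n_neg = int((y[mask] < 0).sum())
            if n_pos >= 2 and n_neg >= 2:
                per_epitope[ep] = float(roc_auc_score(y[mask], s[mask]))
        out["per_epitope_auc"] = per_epitope
    return out
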