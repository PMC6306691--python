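"""Multi-kernel SVM fusion classification with nested cross-validation.

Two feature views (ALFF and fALFF region features) are each reduced by
elastic-net feature selection, embedded with a linear kernel
``K_n(x_i, x_j) = <x_i, x_j>``, and fused as the convex combination
``K = sum_n beta_n K_n`` with ``beta_n >= 0, sum beta_n = 1``.  A
maximal-margin SVM is trained on the fused precomputed kernel and predicts
through the dual decision function ``f(x) = sum_m alpha_m y_m K(x, x_m) + b``.

Hyperparameters (elastic-net penalty and mixing per modality, SVM cost C,
and the fusion weights beta on a 0.1-step grid) are chosen by inner
cross-validation inside each outer training fold; standardization and
feature selection are always fitted on training rows only.  The protocol
is repeated (default 10 times) with different fold shuffles and metrics
reported as means and SDs over repeats.  The patient class (+1) is
"positive" for sensitivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

DUAL_TOL = 1e-6


@dataclass(frozen=True)
class ModalityViews:
    """Aligned feature matrices per modality with labels in {+1, -1}."""

    views: tuple[np.ndarray, ...]
    labels: np.ndarray
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.labels)
        if any(v.shape[0] != n for v in self.views):
            raise ValueError("all views must have one row per subject")
        u = set(np.unique(self.labels).tolist())
        if not u <= {-1, 1} or len(u) < 2:
            raise ValueError("labels must contain both +1 and -1")


@dataclass
class CvConfig:
    outer_k: int = 10
    inner_k: int = 5
    repeats: int = 10
    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    enet_alpha_grid: tuple[float, ...] = (0.01, 0.1, 1.0)
    enet_l1_grid: tuple[float, ...] = (0.2, 0.5, 0.8)
    beta_grid: tuple[tuple[float, ...], ...] | None = None  # None -> 0.1 steps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_k < 2 or self.inner_k < 2 or self.repeats < 1:
            raise ValueError("need outer_k, inner_k >= 2 and repeats >= 1")

    def betas_for(self, n_views: int) -> tuple[tuple[float, ...], ...]:
        if self.beta_grid is not None:
            for b in self.beta_grid:
                if len(b) != n_views or any(x < 0 or x > 1 for x in b):
                    raise ValueError(f"invalid beta vector {b}")
            return self.beta_grid
        if n_views == 1:
            return ((1.0,),)
        if n_views == 2:
            return tuple((round(b1, 1), round(1 - b1, 1))
                         for b1 in np.arange(0.0, 1.0001, 0.1))
        raise ValueError("default beta grid supports at most two views")


@dataclass(frozen=True)
class KernelFusionModel:
    """Fitted fused-kernel SVM: fusion weights, dual weights, bias, and the
    per-modality training embeddings needed to evaluate test kernels."""

    betas: tuple[float, ...]
    train_views: tuple[np.ndarray, ...]  # standardized, selected features
    alpha_signed: np.ndarray  # alpha_m * y_m over support vectors
    support: np.ndarray  # indices into training rows
    bias: float
    C: float
    labels: np.ndarray
    scalers: tuple[tuple[np.ndarray, np.ndarray], ...]  # (mean, sd) per view
    selected: tuple[np.ndarray, ...]  # feature indices per view


@dataclass(frozen=True)
class CvResult:
    per_repeat: pd.DataFrame  # accuracy, sensitivity, specificity, auc
    means: dict[str, float]
    sds: dict[str, float]
    roc_points: pd.DataFrame  # fpr, tpr pooled over repeats
    chosen_params: pd.DataFrame


# ------------------------------------------------------------- primitives


def elastic_net_select(X: np.ndarray, y: np.ndarray, alpha: float,
                       l1_ratio: float) -> np.ndarray:
    """Indices of features with nonzero elastic-net coefficient.

    Assumes X is already standardized on training rows.  Constant columns
    are ignored.  If no coefficient survives, falls back to the single
    feature with the largest absolute univariate correlation (the selected
    set is never empty).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    sd = X.std(axis=0)
    usable = np.nonzero(sd > 0)[0]
    if len(usable) == 0:
        raise ValueError("all feature columns are constant")
    model = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=10000, tol=1e-4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X[:, usable], y)
    nz = usable[np.abs(model.coef_) > 1e-12]
    if len(nz) == 0:
        r = np.abs(X[:, usable].T @ (y - y.mean()))
        nz = usable[[int(np.argmax(r))]]
    return np.sort(nz)


def linear_gram(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise inner products <a_i, b_j> (the linear-kernel Gram block)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"feature dimensions differ: {A.shape[1]} vs {B.shape[1]}")
    return A @ B.T


def fuse_kernels(grams: list[np.ndarray], betas: tuple[float, ...]) -> np.ndarray:
    """Convex combination of per-modality Gram matrices."""
    if len(grams) != len(betas):
        raise ValueError("one beta per Gram matrix required")
    if any(b < 0 for b in betas):
        raise ValueError("betas must be nonnegative")
    if abs(sum(betas) - 1.0) > 1e-9:
        raise ValueError(f"betas must sum to 1, got {sum(betas)}")
    shape = grams[0].shape
    if any(g.shape != shape for g in grams):
        raise ValueError("Gram matrices must share a shape")
    out = np.zeros(shape)
    for b, g in zip(betas, grams):
        out += b * g
    return out


@dataclass(frozen=True)
class SvmFit:
    alpha_signed: np.ndarray
    support: np.ndarray
    bias: float
    C: float


def train_svm_precomputed(K_train: np.ndarray, y: np.ndarray, C: float) -> SvmFit:
    """Maximal-margin SVM on a precomputed kernel; dual feasibility asserted.

    The returned dual weights satisfy ``sum_m alpha_m y_m = 0`` and
    ``0 <= alpha_m <= C``.
    """
    y = np.asarray(y)
    if len(set(np.unique(y).tolist())) < 2:
        raise ValueError("both classes must be present")
    svc = SVC(kernel="precomputed", C=C, tol=1e-6)
    svc.fit(K_train, y)
    alpha_signed = svc.dual_coef_.ravel()  # alpha_i * y_i
    support = svc.support_
    if abs(alpha_signed.sum()) > DUAL_TOL * max(1.0, np.abs(alpha_signed).max()):
        raise AssertionError("dual equality constraint violated")
    if np.any(np.abs(alpha_signed) > C * (1 + 1e-9)):
        raise AssertionError("dual box constraint violated")
    return SvmFit(alpha_signed=alpha_signed, support=support,
                  bias=float(svc.intercept_[0]), C=C)


def decision_scores(fit: SvmFit, K_test_train: np.ndarray) -> np.ndarray:
    """Dual decision function: ``sum_m alpha_m y_m K(x, x_m) + b``."""
    K = np.atleast_2d(np.asarray(K_test_train, dtype=float))
    if K.shape[1] <= int(fit.support.max()):
        raise ValueError("kernel block columns do not cover training samples")
    return K[:, fit.support] @ fit.alpha_signed + fit.bias


def predict_labels(scores: np.ndarray) -> np.ndarray:
    """Sign of the decision score; ties (exact zero) go to the patient class."""
    return np.where(scores >= 0, 1, -1)


def classification_metrics(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """Accuracy / sensitivity / specificity at threshold 0 and rank-based AUC."""
    labels = np.asarray(labels)
    if len(set(np.unique(labels).tolist())) < 2:
        raise ValueError("both classes must be present")
    pred = predict_labels(np.asarray(scores, dtype=float))
    pos = labels == 1
    neg = ~pos
    acc = float((pred == labels).mean())
    sens = float((pred[pos] == 1).mean())
    spec = float((pred[neg] == -1).mean())
    # Mann-Whitney AUC with midranks for ties
    ranks = rankdata(scores)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    auc = float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec, "auc": auc}


def roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """ROC curve by sweeping score thresholds (descending)."""
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    y = np.asarray(labels)[order]
    tp = np.concatenate([[0], np.cumsum(y == 1)])
    fp = np.concatenate([[0], np.cumsum(y == -1)])
    n_pos = max(int((y == 1).sum()), 1)
    n_neg = max(int((y == -1).sum()), 1)
    return pd.DataFrame({"fpr": fp / n_neg, "tpr": tp / n_pos})


# ---------------------------------------------------------- nested CV core


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def _apply(X: np.ndarray, scaler: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    mu, sd = scaler
    return (X - mu) / sd


def _inner_folds(y: np.ndarray, k: int, seed: int):
    k = min(k, int(np.min(np.bincount(((y + 1) // 2).astype(int)))))
    if k < 2:
        raise ValueError("too few per-class samples for inner stratification")
    return list(StratifiedKFold(n_splits=k, shuffle=True,
                                random_state=seed).split(np.zeros(len(y)), y))


def _select_enet_params(X: np.ndarray, y: np.ndarray, cfg: CvConfig,
                        seed: int) -> tuple[float, float]:
    """Per-modality elastic-net parameters by inner-CV single-view SVM accuracy
    (C fixed at 1 during this stage; ties keep the earliest grid entry)."""
    folds = _inner_folds(y, cfg.inner_k, seed)
    best, best_acc = None, -1.0
    for alpha, l1 in product(cfg.enet_alpha_grid, cfg.enet_l1_grid):
        correct = 0
        total = 0
        for tr, te in folds:
            scaler = _standardize_fit(X[tr])
            Xtr = _apply(X[tr], scaler)
            Xte = _apply(X[te], scaler)
            sel = elastic_net_select(Xtr, y[tr], alpha, l1)
            fit = train_svm_precomputed(linear_gram(Xtr[:, sel], Xtr[:, sel]),
                                        y[tr], C=1.0)
            pred = predict_labels(decision_scores(
                fit, linear_gram(Xte[:, sel], Xtr[:, sel])))
            correct += int((pred == y[te]).sum())
            total += len(te)
        acc = correct / total
        if acc > best_acc:
            best, best_acc = (alpha, l1), acc
    return best


def _select_c_beta(views_tr: tuple[np.ndarray, ...], y: np.ndarray,
                   enet_params: list[tuple[float, float]], cfg: CvConfig,
                   seed: int) -> tuple[float, tuple[float, ...]]:
    """Joint (C, beta) choice by inner-CV accuracy of the fused SVM.

    Tie-breaks: smaller C first, then larger beta_1 (grid scan order makes
    the first strict maximum win).
    """
    folds = _inner_folds(y, cfg.inner_k, seed)
    betas_grid = cfg.betas_for(len(views_tr))
    # precompute per-fold per-view kernels with fold-local scaling/selection
    fold_kernels = []
    for tr, te in folds:
        per_view = []
        for v, (alpha, l1) in zip(views_tr, enet_params):
            scaler = _standardize_fit(v[tr])
            Xtr = _apply(v[tr], scaler)
            Xte = _apply(v[te], scaler)
            sel = elastic_net_select(Xtr, y[tr], alpha, l1)
            per_view.append((linear_gram(Xtr[:, sel], Xtr[:, sel]),
                             linear_gram(Xte[:, sel], Xtr[:, sel])))
        fold_kernels.append((tr, te, per_view))
    best, best_acc = None, -1.0
    betas_sorted = sorted(betas_grid, key=lambda b: -b[0])
    for C in sorted(cfg.c_grid):
        for betas in betas_sorted:
            correct = total = 0
            for tr, te, per_view in fold_kernels:
                K_tr = fuse_kernels([pv[0] for pv in per_view], betas)
                K_te = fuse_kernels([pv[1] for pv in per_view], betas)
                fit = train_svm_precomputed(K_tr, y[tr], C=C)
                pred = predict_labels(decision_scores(fit, K_te))
                correct += int((pred == y[te]).sum())
                total += len(te)
            acc = correct / total
            if acc > best_acc:
                best, best_acc = (C, betas), acc
    return best


def fit_fused_model(views_tr: tuple[np.ndarray, ...], y: np.ndarray,
                    cfg: CvConfig, seed: int,
                    ) -> tuple[KernelFusionModel, dict]:
    """Inner-CV hyperparameter choice plus a final fit on the training rows."""
    enet_params = [_select_enet_params(v, y, cfg, seed + 17 * i)
                   for i, v in enumerate(views_tr)]
    C, betas = _select_c_beta(views_tr, y, enet_params, cfg, seed + 101)
    scalers, selected, embedded = [], [], []
    for v, (alpha, l1) in zip(views_tr, enet_params):
        scaler = _standardize_fit(v)
        Xs = _apply(v, scaler)
        sel = elastic_net_select(Xs, y, alpha, l1)
        scalers.append(scaler)
        selected.append(sel)
        embedded.append(Xs[:, sel])
    K = fuse_kernels([linear_gram(e, e) for e in embedded], betas)
    fit = train_svm_precomputed(K, y, C=C)
    model = KernelFusionModel(
        betas=tuple(betas), train_views=tuple(embedded),
        alpha_signed=fit.alpha_signed, support=fit.support, bias=fit.bias,
        C=C, labels=y.copy(), scalers=tuple(scalers),
        selected=tuple(np.asarray(s) for s in selected))
    info = dict(C=C, betas=betas,
                enet=[dict(alpha=a, l1_ratio=l) for a, l in enet_params],
                n_selected=[len(s) for s in selected])
    return model, info


def score_fused_model(model: KernelFusionModel,
                      views_te: tuple[np.ndarray, ...]) -> np.ndarray:
    grams = []
    for v, scaler, sel, emb in zip(views_te, model.scalers, model.selected,
                                   model.train_views):
        grams.append(linear_gram(_apply(v, scaler)[:, sel], emb))
    K = fuse_kernels(grams, model.betas)
    fit = SvmFit(alpha_signed=model.alpha_signed, support=model.support,
                 bias=model.bias, C=model.C)
    return decision_scores(fit, K)


def nested_cv(views: ModalityViews, cfg: CvConfig,
              unsafe_full_data_selection: bool = False) -> CvResult:
    """Repeated stratified nested cross-validation of the fused classifier.

    Metrics are computed on the pooled outer-fold predictions of each
    repeat; repeats differ only in the fold shuffling seed, and the result
    is bit-identical for a fixed ``cfg.seed``.

    ``unsafe_full_data_selection`` is a validation control that deliberately
    fits feature selection on all rows (training + test) to demonstrate how
    information leakage inflates apparent accuracy.  Never use it for real
    results.
    """
    y = views.labels
    per_class = np.bincount(((y + 1) // 2).astype(int))
    if per_class.min() < 3:
        raise ValueError("need at least 3 subjects per class")
    leak_sel: list[np.ndarray] | None = None
    if unsafe_full_data_selection:
        leak_sel = []
        for v in views.views:
            scaler = _standardize_fit(v)
            leak_sel.append(elastic_net_select(_apply(v, scaler), y,
                                               cfg.enet_alpha_grid[0],
                                               cfg.enet_l1_grid[0]))

    rows = []
    chosen = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for rep in range(cfg.repeats):
        rep_seed = cfg.seed + 1000 * rep
        outer_k = min(cfg.outer_k, int(per_class.min()))
        outer = StratifiedKFold(n_splits=outer_k, shuffle=True,
                                random_state=rep_seed)
        scores = np.zeros(len(y))
        for fold, (tr, te) in enumerate(outer.split(np.zeros(len(y)), y)):
            views_tr = tuple(v[tr] for v in views.views)
            views_te = tuple(v[te] for v in views.views)
            if leak_sel is not None:
                views_tr = tuple(v[:, s] for v, s in zip(views_tr, leak_sel))
                views_te = tuple(v[:, s] for v, s in zip(views_te, leak_sel))
            model, info = fit_fused_model(views_tr, y[tr], cfg,
                                          seed=rep_seed + fold)
            scores[te] = score_fused_model(model, views_te)
            chosen.append(dict(repeat=rep, fold=fold, **{
                "C": info["C"], "beta1": info["betas"][0],
                "n_selected": sum(info["n_selected"])}))
        m = classification_metrics(scores, y)
        rows.append(m)
        pooled_scores.append(scores)
        pooled_labels.append(y)
    per_repeat = pd.DataFrame(rows)
    means = per_repeat.mean().to_dict()
    sds = per_repeat.std(ddof=1).fillna(0.0).to_dict() if len(rows) > 1 else \
        {k: 0.0 for k in per_repeat.columns}
    roc = roc_points(np.concatenate(pooled_scores), np.concatenate(pooled_labels))
    return CvResult(per_repeat=per_repeat, means=means, sds=sds,
                    roc_points=roc, chosen_params=pd.DataFrame(chosen))


def make_views(table: pd.DataFrame, group_pair: tuple[str, str],
               bands: tuple[str, ...] = ("classic", "slow4", "slow5"),
               modalities: tuple[str, ...] = ("mALFF", "mfALFF"),
               ) -> ModalityViews:
    """Build per-modality views from a feature table for a two-group contrast.

    ``group_pair`` is (patient_group, control_group); the patient group is
    coded +1.
    """
    pat, ctl = group_pair
    sub = table[table["group"].isin([pat, ctl])]
    for g in group_pair:
        if not (sub["group"] == g).any():
            raise ValueError(f"group {g!r} has no subjects in the table")
    y = np.where(sub["group"] == pat, 1, -1)
    views = []
    for modality in modalities:
        cols = [c for c in table.columns
                if c.startswith(modality + "__") and c.split("__")[1] in bands]
        if not cols:
            raise ValueError(f"no feature columns found for modality {modality}")
        views.append(sub[cols].to_numpy(dtype=float))
    return ModalityViews(views=tuple(views), labels=y,
                         names=tuple(modalities))
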