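"""One-against-all SVM classification with stratified cross-validation.

The evaluation harness mirrors the experimental protocol of the study this
package operationalizes: a multiclass SVM decomposed one-against-all,
hyperparameters chosen by exhaustive grid search (kernels RBF/Poly/Sigmoid,
γ ∈ [1e-4, 1e3] and C ∈ [1e-3, 1e4] at decade steps, polynomial degree
1–6) with inner 3-fold accuracy, all inside a stratified 5-fold outer
cross-validation.  Feature standardization and any dimensionality
reduction are fit on training folds only.  Test-fold predictions are
pooled into one confusion matrix from which accuracy, Cohen's kappa and
F1 are computed; AUC is the one-vs-rest macro average of per-class ROC
areas, reported as mean ± sd across outer folds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn.multiclass import OneVsRestClassifier
from sklearn.preprocessing import StandardScaler, label_binarize
from sklearn.svm import SVC

from .errors import InvalidInputError
from .features import (AutoencoderSpec, fit_pca, minmax_scale, project_pca,
                       train_autoencoder)

KERNEL_ORDER = ("rbf", "poly", "sigmoid")
GAMMA_GRID = tuple(10.0**e for e in range(-4, 4))  # [1e-4, 1e3]
C_GRID = tuple(10.0**e for e in range(-3, 5))  # [1e-3, 1e4]
DEGREE_GRID = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: float = 1.0
    degree: int = 3

    def __post_init__(self) -> None:
        if self.kernel not in KERNEL_ORDER:
            raise InvalidInputError(f"unknown kernel {self.kernel!r}")
        if not 1e-3 <= self.C <= 1e4:
            raise InvalidInputError("C outside [1e-3, 1e4]")
        if not 1e-4 <= self.gamma <= 1e3:
            raise InvalidInputError("gamma outside [1e-4, 1e3]")
        if self.degree not in DEGREE_GRID:
            raise InvalidInputError("degree outside {1..6}")

    @property
    def tiebreak_key(self) -> tuple:
        return (self.C, self.gamma, self.degree, KERNEL_ORDER.index(self.kernel))


def default_grid(kernels: tuple[str, ...] = KERNEL_ORDER) -> list[SVMConfig]:
    """Exhaustive decade-step grid over the searched kernels."""
    grid: list[SVMConfig] = []
    for kernel in kernels:
        degrees = DEGREE_GRID if kernel == "poly" else (3,)
        for C in C_GRID:
            for gamma in GAMMA_GRID:
                for degree in degrees:
                    grid.append(SVMConfig(kernel=kernel, C=C, gamma=gamma,
                                          degree=degree))
    return grid


def rbf_grid() -> list[SVMConfig]:
    """RBF-only decade grid (64 candidates)."""
    return default_grid(kernels=("rbf",))


def make_classifier(config: SVMConfig) -> OneVsRestClassifier:
    """One-against-all SVM for the given hyperparameters."""
    return OneVsRestClassifier(
        SVC(kernel=config.kernel, C=config.C, gamma=config.gamma,
            degree=config.degree, max_iter=200_000)
    )


def stratified_kfold(labels: np.ndarray, k: int = 5,
                     seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment (values in 0..k-1).

    Within each class, samples are shuffled with the seeded generator and
    dealt round-robin, so per-fold class counts differ by at most one from
    exact proportionality.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise InvalidInputError("k must be at least 2")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise InvalidInputError(
            f"class {classes[np.argmin(counts)]!r} has fewer than k={k} members")
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=int)
    for cls in classes:
        idx = np.nonzero(labels == cls)[0]
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(len(idx)) % k
    return assignment


def _inner_cv_accuracy(config: SVMConfig, X: np.ndarray, y: np.ndarray,
                       folds: np.ndarray) -> float:
    correct = 0
    for f in np.unique(folds):
        train, test = folds != f, folds == f
        clf = make_classifier(config)
        clf.fit(X[train], y[train])
        correct += int((clf.predict(X[test]) == y[test]).sum())
    return correct / len(y)


def grid_search_svm(X: np.ndarray, y: np.ndarray,
                    grid: list[SVMConfig] | None = None,
                    inner_k: int = 3, seed: int = 0,
                    return_score: bool = False
                    ) -> SVMConfig | tuple[SVMConfig, float]:
    """Select hyperparameters by inner stratified CV accuracy.

    Ties are broken toward smaller C, then smaller gamma, lower degree,
    and kernel order RBF < Poly < Sigmoid, so the result is independent of
    grid enumeration order and of sample order.
    """
    X, y = np.asarray(X), np.asarray(y)
    if len(np.unique(y)) < 2:
        raise InvalidInputError("grid search needs at least two classes")
    grid = grid if grid is not None else default_grid()
    # canonical sample order (label, then feature values) so the selected
    # configuration cannot depend on how the caller happened to order rows
    keys = tuple(X[:, j] for j in reversed(range(X.shape[1]))) + (y,)
    order = np.lexsort(keys)
    Xs, ys = X[order], y[order]
    folds = stratified_kfold(ys, k=inner_k, seed=seed)
    best: tuple[float, tuple, SVMConfig] | None = None
    for config in grid:
        acc = _inner_cv_accuracy(config, Xs, ys, folds)
        if best is None or (-acc, config.tiebreak_key) < (best[0], best[1]):
            best = (-acc, config.tiebreak_key, config)
    assert best is not None
    if return_score:
        return best[2], -best[0]
    return best[2]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class Metrics:
    accuracy: float
    kappa: float
    f1_weighted: float
    f1_macro: float


def compute_metrics(cm: np.ndarray) -> Metrics:
    """Accuracy, Cohen's kappa and F1 scores from a confusion matrix.

    Rows are actual classes, columns predicted.  F1 is reported both
    weighted by class support and as an unweighted macro average.
    """
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total <= 0:
        raise InvalidInputError("empty confusion matrix")
    accuracy = np.trace(cm) / total
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    p_o = accuracy
    p_e = float((row * col).sum()) / total**2
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    tp = np.diag(cm)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(2 * tp + (row - tp) + (col - tp) > 0,
                      2 * tp / (2 * tp + (row - tp) + (col - tp)), 0.0)
    support = row / total
    return Metrics(accuracy=float(accuracy), kappa=float(kappa),
                   f1_weighted=float((f1 * support).sum()),
                   f1_macro=float(f1[row > 0].mean()))


def _macro_ovr_auc(y_true: np.ndarray, scores: np.ndarray,
                   classes: np.ndarray) -> float:
    """One-vs-rest macro-averaged ROC AUC from decision scores."""
    from sklearn.metrics import roc_auc_score

    if scores.ndim == 1:
        scores = np.column_stack([-scores, scores])
    onehot = label_binarize(y_true, classes=classes)
    if onehot.shape[1] == 1:  # label_binarize collapses the binary case
        onehot = np.column_stack([1 - onehot[:, 0], onehot[:, 0]])
    aucs = []
    for j in range(len(classes)):
        pos = onehot[:, j]
        if 0 < pos.sum() < len(pos):
            aucs.append(roc_auc_score(pos, scores[:, j]))
    return float(np.mean(aucs)) if aucs else float("nan")


def paired_ttest(acc_a: np.ndarray, acc_b: np.ndarray) -> float:
    """Two-tailed paired t-test on fold-wise accuracy differences.

    Degenerate cases: identical sequences give p = 1; zero-variance
    differences with nonzero mean give p = 0.
    """
    a, b = np.asarray(acc_a, dtype=float), np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise InvalidInputError("paired samples of equal length >= 2 required")
    diff = a - b
    if np.allclose(diff, 0.0):
        return 1.0
    if np.allclose(diff, diff[0]):
        return 0.0
    return float(stats.ttest_rel(a, b).pvalue)


def binarize_labels(labels: np.ndarray) -> np.ndarray:
    """Collapse BI-RADS I/II to 'low' density and III/IV to 'high'."""
    mapping = {"I": "low", "II": "low", "III": "high", "IV": "high"}
    labels = np.asarray(labels)
    out = np.empty(labels.shape, dtype=object)
    for i, lab in enumerate(labels.ravel()):
        if lab not in mapping:
            raise InvalidInputError(f"unknown BI-RADS label {lab!r}")
        out.ravel()[i] = mapping[lab]
    return out.astype(str)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    classes: tuple[str, ...]
    fold_accuracies: list[float]
    confusion: np.ndarray  # pooled, rows actual / columns predicted
    accuracy: float
    auc_mean: float
    auc_sd: float
    kappa: float
    f1_weighted: float
    f1_macro: float
    best_configs: list[SVMConfig]
    selected_components: list[int] | None = None

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "fold_accuracies": self.fold_accuracies,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "kappa": self.kappa,
            "f1_weighted": self.f1_weighted,
            "f1_macro": self.f1_macro,
            "best_configs": [vars(c) for c in self.best_configs],
            "selected_components": self.selected_components,
        }


def _class_order(labels: np.ndarray) -> np.ndarray:
    preferred = ["I", "II", "III", "IV", "low", "high"]
    present = list(np.unique(labels))
    present.sort(key=lambda c: (preferred.index(c) if c in preferred else 99, c))
    return np.asarray(present)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
    selection: str = "none",
    n_components: int = 45,
    n_components_scan: tuple[int, ...] | None = None,
    ae_spec: AutoencoderSpec | None = None,
    grid: list[SVMConfig] | None = None,
    inner_k: int = 3,
    folds: np.ndarray | None = None,
) -> CVResult:
    """Stratified k-fold evaluation with leakage-free per-fold fitting.

    Per outer fold: standardize on the training portion, optionally reduce
    dimensionality there (``selection`` ∈ {none, pca, autoencoder}), run
    the hyperparameter grid search on the training portion, then score the
    held-out fold.  Test predictions are pooled into one confusion matrix.

    With ``selection="pca"``, either a fixed ``n_components`` is used or,
    when ``n_components_scan`` is given, the retained component count is
    chosen jointly with the SVM hyperparameters by inner-CV accuracy on
    the training portion (ties toward fewer components).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if selection not in ("none", "pca", "autoencoder"):
        raise InvalidInputError(f"unknown selection method {selection!r}")
    if folds is None:
        folds = stratified_kfold(y, k=k, seed=seed)
    classes = _class_order(y)
    cls_index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=np.int64)
    fold_accuracies: list[float] = []
    fold_aucs: list[float] = []
    best_configs: list[SVMConfig] = []
    selected_components: list[int] = []

    for f in range(int(folds.max()) + 1):
        train, test = folds != f, folds == f
        scaler = StandardScaler().fit(X[train])
        Xtr, Xte = scaler.transform(X[train]), scaler.transform(X[test])
        config: SVMConfig | None = None

        if selection == "pca":
            model = fit_pca(Xtr)
            cap = min(Xtr.shape[1], Xtr.shape[0] - 1)
            if n_components_scan:
                candidates = sorted({min(n, cap) for n in n_components_scan})
                n_max = candidates[-1]
                Ztr = project_pca(model, Xtr, n_max)
                Zte = project_pca(model, Xte, n_max)
                best: tuple | None = None
                for n in candidates:
                    cfg_n, score = grid_search_svm(
                        Ztr[:, :n], y[train], grid=grid, inner_k=inner_k,
                        seed=seed + f, return_score=True)
                    key = (-score, n, cfg_n.tiebreak_key)
                    if best is None or key < best[0]:
                        best = (key, n, cfg_n)
                _, n, config = best
                Xtr, Xte = Ztr[:, :n], Zte[:, :n]
            else:
                n = min(n_components, cap)
                Xtr = project_pca(model, Xtr, n)
                Xte = project_pca(model, Xte, n)
            selected_components.append(n)
        elif selection == "autoencoder":
            spec = ae_spec or AutoencoderSpec(input_dim=Xtr.shape[1])
            spec = replace(spec, input_dim=Xtr.shape[1])
            Xs, lo, hi = minmax_scale(Xtr)
            ae = train_autoencoder(Xs, spec)
            Xtr = ae.encode(Xs)
            Xte = ae.encode(minmax_scale(Xte, lo, hi)[0])

        if config is None:
            config = grid_search_svm(Xtr, y[train], grid=grid,
                                     inner_k=inner_k, seed=seed + f)
        best_configs.append(config)
        clf = make_classifier(config)
        clf.fit(Xtr, y[train])
        pred = clf.predict(Xte)
        fold_accuracies.append(float((pred == y[test]).mean()))
        scores = clf.decision_function(Xte)
        fold_aucs.append(_macro_ovr_auc(y[test], scores, classes))
        for actual, predicted in zip(y[test], pred):
            confusion[cls_index[actual], cls_index[predicted]] += 1

    metrics = compute_metrics(confusion)
    aucs = np.asarray(fold_aucs, dtype=float)
    aucs = aucs[np.isfinite(aucs)]
    return CVResult(
        classes=tuple(classes),
        fold_accuracies=fold_accuracies,
        confusion=confusion,
        accuracy=metrics.accuracy,
        auc_mean=float(aucs.mean()) if aucs.size else float("nan"),
        auc_sd=float(aucs.std(ddof=1)) if aucs.size > 1 else 0.0,
        kappa=metrics.kappa,
        f1_weighted=metrics.f1_weighted,
        f1_macro=metrics.f1_macro,
        best_configs=best_configs,
        selected_components=selected_components or None,
    )
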