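"""PC-DFA: ANOVA-gated feature selection, centered PCA with Kaiser-criterion
retention (minimum two components), Fisher discriminant axes on the retained
scores, and Monte Carlo cross-validation with accuracy and Cohen's kappa.

The Kaiser rule on centered-but-unscaled data uses the Kaiser-Guttman
generalization (retain eigenvalues above the mean eigenvalue); the classical
eigenvalue > 1 rule is available via ``kaiser="unit"``.  Classification is by
nearest class centroid in discriminant space.  All cross-validation refits
(centering, PCA, retention, discriminant axes) use training folds only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .feature_io import FeatureTable
from .univariate_stats import anova_matrix, bonferroni

__all__ = [
    "PCDFAModel",
    "MCCVResult",
    "select_features_anova",
    "fit_pcdfa",
    "mccv",
    "cohens_kappa",
]


def select_features_anova(table: FeatureTable, alpha: float = 0.05) -> list[str]:
    """Features whose Bonferroni-adjusted one-way ANOVA p (across study groups)
    falls below ``alpha``.  QC samples are excluded; features not testable
    (any group with < 2 usable values) are dropped from both the test and the
    correction count."""
    study = table.study_sample_ids
    labels = table.samples.loc[study, "group"].to_numpy()
    if len(set(labels)) < 2:
        raise ValueError("feature selection requires >= 2 study groups")
    data = table.areas[study].to_numpy(dtype=float).T  # samples x features
    _, p = anova_matrix(data, labels)
    tested = ~np.isnan(p)
    m = int(tested.sum())
    if m == 0 or alpha <= 0:
        return []
    p_adj = np.full_like(p, np.nan)
    p_adj[tested] = bonferroni(p[tested], m)
    keep = tested & (p_adj < alpha)
    return [fid for fid, k in zip(table.feature_ids, keep) if k]


@dataclass
class PCDFAModel:
    feature_ids: list[str] | None
    classes: list[str]
    mean_: np.ndarray               # centering vector (p,)
    loadings: np.ndarray            # p x r PCA loadings (columns = components)
    eigenvalues: np.ndarray         # r component variances
    n_components: int               # retained by Kaiser rule (floor 2)
    df_axes: np.ndarray             # n_components x n_df discriminant axes
    df_scores: np.ndarray           # n_samples x n_df training scores
    labels: np.ndarray
    centroids: np.ndarray           # n_classes x n_df

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new samples into discriminant space."""
        Xc = np.asarray(X, dtype=float) - self.mean_
        return Xc @ self.loadings[:, : self.n_components] @ self.df_axes

    def classify(self, X: np.ndarray) -> np.ndarray:
        """Nearest-centroid (Euclidean, in DF space) class assignment."""
        scores = self.transform(X)
        d2 = ((scores[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return np.asarray(self.classes)[np.argmin(d2, axis=1)]


def fit_pcdfa(matrix: np.ndarray, labels: Sequence[str], kaiser: str = "mean",
              feature_ids: Sequence[str] | None = None) -> PCDFAModel:
    """Fit centered PCA + Fisher DFA on retained component scores.

    Components are retained while their eigenvalue exceeds the retention
    reference (mean eigenvalue, or 1.0 for ``kaiser="unit"``), with a floor
    of two components.  Within-class scatter is ridge-regularized by
    1e-8 x trace when needed, which keeps n = 5 per class workable.
    """
    X = np.asarray(matrix, dtype=float)
    labels = np.asarray([str(l) for l in labels])
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D (samples x features)")
    n, p = X.shape
    if p < 2:
        raise ValueError("fit_pcdfa requires >= 2 features")
    classes = sorted(set(labels))
    counts = {c: int((labels == c).sum()) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError(f"every class needs >= 2 samples, got {counts}")
    if n <= len(classes):
        raise ValueError("DFA undefined: n_samples <= n_classes")

    mean_ = X.mean(axis=0)
    Xc = X - mean_
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s ** 2 / (n - 1)
    reference = eig.mean() if kaiser == "mean" else 1.0
    k = int((eig > reference).sum())
    k = max(k, 2)
    k = min(k, len(eig))
    scores = (U * s)[:, :k]  # n x k PC scores

    # Fisher discriminant on retained scores
    overall = scores.mean(axis=0)
    Sw = np.zeros((k, k))
    Sb = np.zeros((k, k))
    for c in classes:
        sub = scores[labels == c]
        mc = sub.mean(axis=0)
        Sw += (sub - mc).T @ (sub - mc)
        Sb += len(sub) * np.outer(mc - overall, mc - overall)
    tr = np.trace(Sw)
    ridge = 1e-8 * (tr if tr > 0 else 1.0)
    Sw_reg = Sw + ridge * np.eye(k)
    evals, evecs = scipy.linalg.eigh(Sb, Sw_reg)
    order = np.argsort(evals)[::-1]
    n_df = min(len(classes) - 1, k)
    axes = evecs[:, order[:n_df]]
    # deterministic orientation and scale
    axes = axes / np.linalg.norm(axes, axis=0, keepdims=True)
    for j in range(axes.shape[1]):
        pivot = np.argmax(np.abs(axes[:, j]))
        if axes[pivot, j] < 0:
            axes[:, j] = -axes[:, j]

    df_scores = scores @ axes
    centroids = np.vstack([df_scores[labels == c].mean(axis=0) for c in classes])
    return PCDFAModel(
        feature_ids=list(feature_ids) if feature_ids is not None else None,
        classes=classes, mean_=mean_, loadings=Vt.T, eigenvalues=eig,
        n_components=k, df_axes=axes, df_scores=df_scores, labels=labels,
        centroids=centroids,
    )


def cohens_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement from a square confusion matrix (rows = truth)."""
    C = np.asarray(confusion, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (C < 0).any():
        raise ValueError("confusion matrix must be non-negative")
    total = C.sum()
    if total <= 0:
        raise ValueError("confusion matrix total must be > 0")
    p_o = np.trace(C) / total
    p_e = float((C.sum(axis=1) * C.sum(axis=0)).sum()) / total ** 2
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass
class MCCVResult:
    n_iterations: int
    test_fraction: float
    accuracies: np.ndarray          # per-iteration test accuracy
    mean_accuracy: float
    kappa: float                    # from the pooled confusion matrix
    confusion: pd.DataFrame         # rows = truth, columns = prediction


def mccv(matrix: np.ndarray, labels: Sequence[str], n_iter: int = 1000,
         test_fraction: float = 0.3, seed: int = 0,
         kaiser: str = "mean") -> MCCVResult:
    """Monte Carlo cross-validation of the PC-DFA classifier.

    Each iteration draws a stratified random split, refits the complete
    pipeline on the training fold only, and classifies the held-out samples
    by nearest centroid in DF space.  Accuracy is averaged per iteration;
    Cohen's kappa is computed on the confusion matrix pooled over iterations.
    """
    X = np.asarray(matrix, dtype=float)
    labels = np.asarray([str(l) for l in labels])
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    classes = sorted(set(labels))
    idx_by_class = {c: np.flatnonzero(labels == c) for c in classes}
    n_test = {c: max(1, int(round(test_fraction * len(ix))))
              for c, ix in idx_by_class.items()}
    for c, ix in idx_by_class.items():
        if len(ix) - n_test[c] < 2:
            raise ValueError(
                f"test_fraction={test_fraction} leaves class {c!r} with fewer than "
                f"2 training samples"
            )
    rng = np.random.default_rng(seed)
    class_pos = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    accuracies = np.empty(n_iter)
    for it in range(n_iter):
        test_idx, train_idx = [], []
        for c in classes:
            perm = rng.permutation(idx_by_class[c])
            test_idx.extend(perm[: n_test[c]])
            train_idx.extend(perm[n_test[c]:])
        train_idx = np.array(train_idx)
        test_idx = np.array(test_idx)
        model = fit_pcdfa(X[train_idx], labels[train_idx], kaiser=kaiser)
        pred = model.classify(X[test_idx])
        truth = labels[test_idx]
        accuracies[it] = float((pred == truth).mean())
        for t, q in zip(truth, pred):
            confusion[class_pos[t], class_pos[q]] += 1
    conf_df = pd.DataFrame(confusion, index=classes, columns=classes)
    return MCCVResult(
        n_iterations=n_iter, test_fraction=test_fraction, accuracies=accuracies,
        mean_accuracy=float(accuracies.mean()), kappa=cohens_kappa(confusion),
        confusion=conf_df,
    )
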