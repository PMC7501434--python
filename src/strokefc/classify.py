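"""Shrinkage-regularized linear discriminant classification of edge vectors.

With E = 435 edges and at most a few hundred runs, the pooled within-class
covariance is singular; it is shrunk toward its diagonal with the analytic
(variance-of-entries) optimal intensity, which keeps the discriminant
well-defined for any sample size. Cross-validation always leaves out whole
subjects so a subject's runs never straddle the train/test split; the
larger group is repeatedly subsampled to the size of the smaller one to
remove class-imbalance bias; permutation tests rebuild the empirical null
of the mean classification accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve


@dataclass
class EdgeDataset:
    X: np.ndarray                 # N x E
    y: np.ndarray                 # N labels
    subject_of: np.ndarray        # N subject ids
    label_space: list[str]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.subject_of = np.asarray(self.subject_of)
        if np.isnan(self.X).any():
            raise ValueError("edge matrix contains missing values")
        if not set(self.y) <= set(self.label_space):
            raise ValueError("labels outside the declared label space")

    def subjects(self) -> np.ndarray:
        # first-appearance order, stable across row permutations of sorted inputs
        _, idx = np.unique(self.subject_of, return_index=True)
        return self.subject_of[np.sort(idx)]


@dataclass
class ShrinkageLDAModel:
    class_means: np.ndarray        # L x E
    pooled_covariance: np.ndarray  # E x E after shrinkage
    shrinkage_intensity: float
    priors: np.ndarray
    label_space: list[str]
    _weights: np.ndarray = field(repr=False, default=None)   # E x L
    _offsets: np.ndarray = field(repr=False, default=None)   # L

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = np.asarray(X, dtype=float) @ self._weights + self._offsets
        return np.asarray(self.label_space)[np.argmax(scores, axis=1)]


@dataclass
class ClassificationReport:
    confusion: np.ndarray           # L x L, rows true, columns predicted
    per_class_accuracy: np.ndarray
    mean_accuracy: float
    label_space: list[str]
    chance_level: float
    p_perm: float | None = None
    n_permutations: int = 0

    def to_frame(self, task: str = "", seed: int | None = None) -> pd.DataFrame:
        rows = [
            {"task": task, "class": lab, "accuracy": acc,
             "p_perm": self.p_perm, "n_perm": self.n_permutations, "seed": seed}
            for lab, acc in zip(self.label_space, self.per_class_accuracy)
        ]
        rows.append({"task": task, "class": "mean", "accuracy": self.mean_accuracy,
                     "p_perm": self.p_perm, "n_perm": self.n_permutations, "seed": seed})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["confusion matrix (rows true, columns predicted):"]
        header = "          " + " ".join(f"{lab:>10s}" for lab in self.label_space)
        lines.append(header)
        for lab, row in zip(self.label_space, self.confusion):
            lines.append(f"{lab:>10s}" + " ".join(f"{v:10.2f}" for v in row))
        for lab, acc in zip(self.label_space, self.per_class_accuracy):
            lines.append(f"accuracy[{lab}] = {acc:.4f}")
        lines.append(f"mean accuracy  = {self.mean_accuracy:.4f}")
        lines.append(f"chance level   = {self.chance_level:.4f}")
        if self.p_perm is not None:
            lines.append(f"p_perm         = {self.p_perm:.4g} ({self.n_permutations} permutations)")
        return "\n".join(lines)


def dataset_from_edge_table(
    table: pd.DataFrame,
    task: str = "condition",
    condition: str | None = None,
) -> EdgeDataset:
    """Build a labelled dataset from a cohort edge table.

    ``task='condition'`` keeps all rows and labels them by condition;
    ``task='group'`` keeps one row per subject (the given ``condition``)
    and labels rows by group.
    """
    edge_cols = [c for c in table.columns if c.startswith("edge_")]
    if task == "condition":
        sub = table
        y = sub["condition"].to_numpy()
        labels = sorted(pd.unique(y).tolist())
    elif task == "group":
        if condition is None:
            raise ValueError("group task needs a condition")
        sub = table[table["condition"] == condition]
        y = sub["group"].to_numpy()
        labels = sorted(pd.unique(y).tolist())
    else:
        raise ValueError(f"unknown task {task!r}")
    return EdgeDataset(
        X=sub[edge_cols].to_numpy(dtype=float),
        y=y,
        subject_of=sub["subject_id"].to_numpy(),
        label_space=labels,
    )


def _shrinkage_intensity(Z: np.ndarray, S: np.ndarray, n_eff: int) -> float:
    """Analytic optimal intensity for shrinking S toward diag(S).

    Ratio of the summed sampling variances of the off-diagonal entries of
    the empirical covariance to their summed squared values, computed from
    the class-centered data Z (rows) — the variance-of-entries formula of
    analytic covariance shrinkage — clipped to [0, 1].
    """
    n = Z.shape[0]
    if n_eff < 2:
        return 1.0
    # Var(s_ij) ∝ Σ_k (z_ki z_kj − w̄_ij)² = Σ_k z_ki² z_kj² − n·w̄_ij²,
    # computed without materializing the n×E×E outer-product stack
    Z2 = Z * Z
    A = Z2.T @ Z2
    Wbar = (Z.T @ Z) / n
    var_s = (n / n_eff**3) * (A - n * Wbar**2)
    off = ~np.eye(S.shape[0], dtype=bool)
    denom = (S[off] ** 2).sum()
    if denom <= 0:
        return 1.0
    gamma = var_s[off].sum() / denom
    return float(np.clip(gamma, 0.0, 1.0))


def fit_shrinkage_lda(
    X: np.ndarray,
    y: np.ndarray,
    priors: np.ndarray | None = None,
    label_space: list[str] | None = None,
) -> ShrinkageLDAModel:
    """Fit an LDA with pooled covariance shrunk toward its diagonal.

    Σ* = (1−γ)Σ + γ·diag(Σ); γ is the analytic optimal intensity. Priors
    default to uniform (balanced designs after subsampling).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if label_space is None:
        label_space = sorted(pd.unique(y).tolist())
    L = len(label_space)
    if L < 2:
        raise ValueError("need at least 2 classes")
    n, E = X.shape
    means = np.empty((L, E))
    Z = np.empty_like(X)
    pos = 0
    for li, lab in enumerate(label_space):
        sel = X[y == lab]
        if sel.shape[0] < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 samples")
        means[li] = sel.mean(axis=0)
        Z[pos:pos + sel.shape[0]] = sel - means[li]
        pos += sel.shape[0]
    n_eff = n - L
    S = (Z.T @ Z) / n_eff
    gamma = _shrinkage_intensity(Z, S, n_eff)
    Sstar = (1.0 - gamma) * S + gamma * np.diag(np.diag(S))
    d = np.diag(Sstar)
    if np.any(d <= 0):
        Sstar = Sstar + np.eye(E) * max(d.mean(), 1.0) * 1e-8
    if priors is None:
        priors = np.full(L, 1.0 / L)
    priors = np.asarray(priors, dtype=float)
    priors = priors / priors.sum()
    try:
        cf = cho_factor(Sstar)
        W = cho_solve(cf, means.T)             # E x L
    except np.linalg.LinAlgError:
        W = np.linalg.solve(Sstar + np.eye(E) * 1e-8 * np.trace(Sstar) / E, means.T)
    offsets = -0.5 * np.einsum("le,el->l", means, W) + np.log(priors)
    return ShrinkageLDAModel(
        class_means=means,
        pooled_covariance=Sstar,
        shrinkage_intensity=gamma,
        priors=priors,
        label_space=list(label_space),
        _weights=W,
        _offsets=offsets,
    )


def _confusion(y_true, y_pred, label_space) -> np.ndarray:
    L = len(label_space)
    idx = {lab: i for i, lab in enumerate(label_space)}
    C = np.zeros((L, L))
    for t, p in zip(y_true, y_pred):
        C[idx[t], idx[p]] += 1
    return C


def _report_from_confusion(C: np.ndarray, label_space) -> ClassificationReport:
    rowsum = C.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(rowsum > 0, np.diag(C) / rowsum, np.nan)
    return ClassificationReport(
        confusion=C,
        per_class_accuracy=per_class,
        mean_accuracy=float(np.nanmean(per_class)),
        label_space=list(label_space),
        chance_level=1.0 / len(label_space),
    )


def loso_cv(dataset: EdgeDataset, priors: np.ndarray | None = None) -> ClassificationReport:
    """Leave-one-subject-out cross-validation.

    Every fold removes all rows of one subject; the model is refit on the
    rest and the held-out rows are predicted. The confusion matrix is
    accumulated over folds; mean accuracy is the mean of the per-class
    accuracies (the balanced accuracy).
    """
    subjects = dataset.subjects()
    if subjects.size < 3:
        raise ValueError("leave-one-subject-out needs at least 3 subjects")
    C = np.zeros((len(dataset.label_space),) * 2)
    for s in subjects:
        test = dataset.subject_of == s
        model = fit_shrinkage_lda(
            dataset.X[~test], dataset.y[~test], priors=priors, label_space=dataset.label_space
        )
        pred = model.predict(dataset.X[test])
        C += _confusion(dataset.y[test], pred, dataset.label_space)
    return _report_from_confusion(C, dataset.label_space)


def balanced_group_classification(
    dataset: EdgeDataset,
    n_iterations: int = 100,
    seed: int = 0,
    priors: np.ndarray | None = None,
) -> ClassificationReport:
    """Group classification with repeated subsampling of the larger class.

    Each iteration draws, without replacement, as many majority-class
    subjects as there are minority-class subjects, then runs LOSO CV on
    the balanced subset. Per-class accuracies and the confusion matrix are
    averaged across iterations. Degenerates to plain LOSO when the groups
    are already equal in size.
    """
    if n_iterations < 1:
        raise ValueError("need at least 1 iteration")
    labels = dataset.label_space
    if len(labels) != 2:
        raise ValueError("balanced subsampling is defined for 2 classes")
    subj_label = {}
    for s, lab in zip(dataset.subject_of, dataset.y):
        subj_label.setdefault(s, lab)
    subs = dataset.subjects()
    by_class = {lab: np.array([s for s in subs if subj_label[s] == lab]) for lab in labels}
    sizes = {lab: len(v) for lab, v in by_class.items()}
    if {"patient", "control"} <= set(labels) and sizes["control"] < sizes["patient"]:
        raise ValueError("expected at least as many controls as patients")
    minority = min(labels, key=lambda lab: sizes[lab])
    majority = labels[1] if minority == labels[0] else labels[0]
    if sizes[minority] < 3:
        raise ValueError("minority class needs at least 3 subjects")
    rng = np.random.default_rng(seed)
    Csum = np.zeros((2, 2))
    acc = np.zeros(2)
    for _ in range(n_iterations):
        if sizes[majority] == sizes[minority]:
            chosen = by_class[majority]
        else:
            chosen = rng.choice(by_class[majority], size=sizes[minority], replace=False)
        keep = np.isin(dataset.subject_of, np.concatenate([by_class[minority], chosen]))
        sub = EdgeDataset(dataset.X[keep], dataset.y[keep], dataset.subject_of[keep], labels)
        rep = loso_cv(sub, priors=priors)
        Csum += rep.confusion
        acc += rep.per_class_accuracy
    C = Csum / n_iterations
    per_class = acc / n_iterations
    return ClassificationReport(
        confusion=C,
        per_class_accuracy=per_class,
        mean_accuracy=float(per_class.mean()),
        label_space=list(labels),
        chance_level=0.5,
    )


def permute_dataset(dataset: EdgeDataset, scheme: str, rng: np.random.Generator) -> EdgeDataset:
    """Label permutation respecting the dependence structure.

    ``scheme='subject'`` permutes group labels across subjects (each
    subject keeps one coherent label); ``scheme='within_subject'``
    shuffles condition labels within each subject's rows.
    """
    y = dataset.y.copy()
    if scheme == "subject":
        subs = dataset.subjects()
        subj_label = {s: dataset.y[dataset.subject_of == s][0] for s in subs}
        labels = np.array([subj_label[s] for s in subs])
        perm = rng.permutation(labels)
        new_label = dict(zip(subs, perm))
        y = np.array([new_label[s] for s in dataset.subject_of])
    elif scheme == "within_subject":
        for s in dataset.subjects():
            idx = np.flatnonzero(dataset.subject_of == s)
            y[idx] = dataset.y[idx][rng.permutation(idx.size)]
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    return EdgeDataset(dataset.X, y, dataset.subject_of, dataset.label_space)


def permutation_test(
    dataset: EdgeDataset,
    observed_accuracy: float,
    n_permutations: int,
    seed: int = 0,
    classifier_runner=None,
    scheme: str = "subject",
) -> float:
    """Permutation p-value for a classification accuracy.

    p = (1 + #{null ≥ observed}) / (n_permutations + 1), the add-one
    convention, so p is a valid finite-sample level and never exactly 0.
    """
    if n_permutations < 1:
        raise ValueError("need at least 1 permutation")
    if classifier_runner is None:
        classifier_runner = lambda ds: loso_cv(ds).mean_accuracy  # noqa: E731
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        null_ds = permute_dataset(dataset, scheme, rng)
        if classifier_runner(null_ds) >= observed_accuracy:
            count += 1
    return (1 + count) / (n_permutations + 1)
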