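"""Supervised binary discrimination of *Prototaxites* from other chert
fossils: stratified 70/30 split, train-only PCA projection, SMOTE
balancing, LDA with escalation to an RBF SVM under leave-one-out
grid search, and the five-metric report (accuracy, precision, recall,
F1, MCC) with *Prototaxites* as the positive class throughout.

PCA and SMOTE are fitted on the training rows only — never on test rows —
so the test set stays untouched by any data-dependent transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .io import SpectralDataset, SpectrumError
from .explore import PCAModel, fit_pca
from .preprocess import apply_recipe

POSITIVE_CLASS = "Prototaxites"

#: binary task → negative-class set
TASKS = {
    "vs-bacteria": ("Bacteria",),
    "vs-fungi": ("Fungi",),
    "vs-chitinous": ("Fungi", "Arthropoda"),
    "vs-plants": ("Plantae",),
}

#: PCs retained per task (2 for the bacteria task, 4 for the rest)
DEFAULT_TASK_PCS = {
    "vs-bacteria": 2,
    "vs-fungi": 4,
    "vs-chitinous": 4,
    "vs-plants": 4,
}

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (0.001, 0.01, 0.1, 1.0)


@dataclass
class SplitPlan:
    """Stratified train/test allocation (largest-remainder per class)."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    test_fraction: float
    seed: int
    per_class: dict


def stratified_split(labels, test_fraction: float = 0.30, seed: int = 0) -> SplitPlan:
    """Split by largest-remainder allocation toward the global test count.

    Per-class quotas n_c·f are floored; leftover test slots go to the
    classes with the largest fractional remainders (ties broken toward the
    larger class, then label order).  Membership within a class is random
    given the seed.
    """
    labels = np.asarray(labels)
    n = len(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        small = classes[counts < 2]
        raise SpectrumError(f"cannot stratify classes with < 2 samples: {small}")
    target = int(round(n * test_fraction))
    if target < 1 or target >= n:
        raise SpectrumError(f"test_fraction={test_fraction} gives no usable split")
    quotas = counts * test_fraction
    alloc = np.floor(quotas).astype(int)
    remainders = quotas - alloc
    # order: remainder desc, class size desc, label asc
    order = sorted(
        range(len(classes)),
        key=lambda i: (-remainders[i], -counts[i], str(classes[i])),
    )
    short = target - alloc.sum()
    for i in order:
        if short <= 0:
            break
        if alloc[i] < counts[i]:
            alloc[i] += 1
            short -= 1
    rng = np.random.default_rng(seed)
    test_idx, per_class = [], {}
    for cls, k in zip(classes, alloc):
        members = np.flatnonzero(labels == cls)
        chosen = rng.choice(members, size=k, replace=False)
        test_idx.extend(chosen.tolist())
        per_class[str(cls)] = {"n": int(len(members)), "n_test": int(k)}
    test_idx = np.sort(np.array(test_idx, dtype=int))
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    return SplitPlan(
        train_indices=train_idx,
        test_indices=test_idx,
        test_fraction=test_fraction,
        seed=seed,
        per_class=per_class,
    )


def smote(features, labels, k: int = 5, seed: int = 0):
    """Balance classes by synthetic minority oversampling.

    Each synthetic point is x + u·(x_nn − x), u ~ U(0,1), with x a
    minority sample and x_nn one of its k nearest minority neighbors
    (Euclidean).  Enough points are generated to equalize class counts;
    k shrinks to n_minority − 1 with a warning when needed.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    rng = np.random.default_rng(seed)
    new_x, new_y = [x], [y]
    for cls, count in zip(classes, counts):
        need = n_max - count
        if need == 0:
            continue
        if count < 2:
            raise SpectrumError(f"SMOTE needs >= 2 samples of class {cls!r}")
        k_eff = min(k, count - 1)
        if k_eff < k:
            warnings.warn(
                f"SMOTE k reduced to {k_eff} for class {cls!r} (n={count})",
                stacklevel=2,
            )
        members = x[y == cls]
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(members)
        _, neigh = nn.kneighbors(members)
        base = rng.integers(0, count, need)
        pick = rng.integers(1, k_eff + 1, need)    # skip self at column 0
        u = rng.uniform(0.0, 1.0, need)
        x0 = members[base]
        x1 = members[neigh[base, pick]]
        new_x.append(x0 + u[:, None] * (x1 - x0))
        new_y.append(np.full(need, cls, dtype=y.dtype))
    return np.vstack(new_x), np.concatenate(new_y)


@dataclass
class ClassifierModel:
    """Fitted binary classifier plus its train-only PCA projection."""

    kind: str                     # "lda" or "svm-rbf"
    estimator: object
    pca: PCAModel = None
    positive_class: str = POSITIVE_CLASS
    best_C: float = None
    best_gamma: float = None
    loo_accuracy: float = None

    def predict(self, features) -> np.ndarray:
        x = np.asarray(features, dtype=float)
        if self.pca is not None:
            x = self.pca.transform(x)
        return self.estimator.predict(x)


def fit_lda(features, labels) -> ClassifierModel:
    """Gaussian LDA with pooled covariance (sklearn SVD solver, which
    stays stable when the pooled covariance is singular)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise SpectrumError("LDA needs two classes")
    est = LinearDiscriminantAnalysis(solver="svd")
    est.fit(np.asarray(features, dtype=float), y)
    return ClassifierModel(kind="lda", estimator=est)


def loo_accuracy(make_estimator, features, labels) -> float:
    """Leave-one-out cross-validated accuracy."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    hits = 0
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            continue
        est = make_estimator()
        est.fit(x[mask], y[mask])
        hits += int(est.predict(x[i:i + 1])[0] == y[i])
    return hits / len(y)


def fit_svm_grid(
    features,
    labels,
    C_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
) -> ClassifierModel:
    """RBF SVM with (C, γ) chosen by leave-one-out accuracy on the
    training set; ties break toward the smallest C, then smallest γ."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2 or len(y) < 3:
        raise SpectrumError("SVM grid search needs two classes and >= 3 samples")
    best = None
    for c in sorted(C_grid):
        for g in sorted(gamma_grid):
            acc = loo_accuracy(lambda: SVC(C=c, gamma=g, kernel="rbf"),
                               features, y)
            if best is None or acc > best[0]:
                best = (acc, c, g)
    acc, c, g = best
    est = SVC(C=c, gamma=g, kernel="rbf")
    est.fit(np.asarray(features, dtype=float), y)
    return ClassifierModel(
        kind="svm-rbf", estimator=est, best_C=c, best_gamma=g, loo_accuracy=acc
    )


@dataclass
class MetricsReport:
    """Confusion matrix and the five binary metrics, positive class fixed."""

    tp: int
    fp: int
    fn: int
    tn: int
    positive_class: str = POSITIVE_CLASS

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / max(self.tp + self.fp + self.fn + self.tn, 1)

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    @property
    def mcc(self) -> float:
        tp, fp, fn, tn = self.tp, self.fp, self.fn, self.tn
        denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if denom2 == 0:
            warnings.warn("MCC denominator zero; reporting 0", stacklevel=2)
            return 0.0
        return (tp * tn - fp * fn) / np.sqrt(denom2)

    def as_dict(self) -> dict:
        return {
            "confusion": [[self.tp, self.fn], [self.fp, self.tn]],
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
        }


def evaluate(model: ClassifierModel, features, labels) -> MetricsReport:
    """Score a fitted model; labels must lie in its two training classes."""
    y = np.asarray(labels)
    if len(y) == 0:
        raise SpectrumError("empty test set")
    known = set(np.asarray(model.estimator.classes_).tolist())
    unknown = set(y.tolist()) - known
    if unknown:
        raise SpectrumError(f"labels outside the model's classes: {unknown}")
    pred = model.predict(features)
    pos = model.positive_class
    tp = int(np.sum((pred == pos) & (y == pos)))
    fp = int(np.sum((pred == pos) & (y != pos)))
    fn = int(np.sum((pred != pos) & (y == pos)))
    tn = int(np.sum((pred != pos) & (y != pos)))
    return MetricsReport(tp=tp, fp=fp, fn=fn, tn=tn, positive_class=pos)


@dataclass
class TaskReport:
    """Full audit trail of one binary discrimination task."""

    task: str
    model: ClassifierModel
    train_metrics: MetricsReport
    test_metrics: MetricsReport
    split: SplitPlan
    params: dict = field(default_factory=dict)


def run_binary_task(
    dataset: SpectralDataset,
    task: str,
    test_fraction: float = 0.30,
    n_pcs: int = None,
    smote_k: int = 5,
    smote_imbalance_threshold: float = 1.25,
    lda_escalation_threshold: float = 0.95,
    C_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    seed: int = 0,
    recipe: str = "atr-paper",
) -> TaskReport:
    """End-to-end binary task: subset → (preprocess if raw) → split →
    PCA on train → project test → SMOTE on train when imbalance ratio
    exceeds the threshold → LDA, escalating to the SVM grid when LDA's
    LOO accuracy falls below the threshold → train and test metrics."""
    if task not in TASKS:
        raise SpectrumError(f"unknown task {task!r}; choose from {sorted(TASKS)}")
    negatives = TASKS[task]
    wanted = (POSITIVE_CLASS,) + negatives
    present = set(dataset.labels.tolist())
    missing = [c for c in wanted if c not in present]
    if missing:
        raise SpectrumError(f"dataset lacks classes {missing} for task {task!r}")
    sub = dataset.subset_classes(wanted)
    if any(not sp.history for sp in sub.spectra):
        sub = apply_recipe(sub, recipe)
    # binary labels: positive class vs pooled negative group
    y = np.where(sub.labels == POSITIVE_CLASS, POSITIVE_CLASS, "other")
    x = sub.matrix()
    split = stratified_split(y, test_fraction=test_fraction, seed=seed)
    n_pcs = n_pcs if n_pcs is not None else DEFAULT_TASK_PCS[task]
    x_train, y_train = x[split.train_indices], y[split.train_indices]
    x_test, y_test = x[split.test_indices], y[split.test_indices]
    pca = fit_pca(x_train, n_components=n_pcs)
    z_train = pca.transform(x_train)
    counts = np.unique(y_train, return_counts=True)[1]
    smote_applied = counts.max() / counts.min() > smote_imbalance_threshold
    if smote_applied:
        z_fit, y_fit = smote(z_train, y_train, k=smote_k, seed=seed)
    else:
        z_fit, y_fit = z_train, y_train
    lda = fit_lda(z_fit, y_fit)
    lda_loo = loo_accuracy(lambda: LinearDiscriminantAnalysis(solver="svd"),
                           z_fit, y_fit)
    if lda_loo >= lda_escalation_threshold:
        model = ClassifierModel(kind="lda", estimator=lda.estimator, pca=pca,
                                loo_accuracy=lda_loo)
    else:
        svm = fit_svm_grid(z_fit, y_fit, C_grid=C_grid, gamma_grid=gamma_grid)
        model = ClassifierModel(
            kind="svm-rbf", estimator=svm.estimator, pca=pca,
            best_C=svm.best_C, best_gamma=svm.best_gamma,
            loo_accuracy=svm.loo_accuracy,
        )
    train_metrics = evaluate(model, x_train, y_train)
    test_metrics = evaluate(model, x_test, y_test)
    return TaskReport(
        task=task,
        model=model,
        train_metrics=train_metrics,
        test_metrics=test_metrics,
        split=split,
        params={
            "n_pcs": n_pcs,
            "test_fraction": test_fraction,
            "smote_applied": bool(smote_applied),
            "smote_k": smote_k,
            "lda_loo_accuracy": lda_loo,
            "escalated_to_svm": model.kind == "svm-rbf",
            "recipe": recipe,
            "seed": seed,
            "n_train": int(len(split.train_indices)),
            "n_test": int(len(split.test_indices)),
        },
    )


def learning_curve(
    features,
    labels,
    fractions=(0.3, 0.5, 0.7, 1.0),
    n_repeats: int = 5,
    seed: int = 0,
):
    """LOO accuracy of LDA on stratified subsamples of growing size.

    Returns a list of (fraction, mean, sd) rows, one per feasible
    fraction; infeasible fractions (under 2 samples in a class) are
    skipped with a warning.  At fraction 1.0 the repeats collapse to a
    single deterministic value.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        if not 0 < frac <= 1:
            warnings.warn(f"skipping invalid fraction {frac}", stacklevel=2)
            continue
        scores = []
        reps = 1 if frac == 1.0 else n_repeats
        for _ in range(reps):
            idx = []
            feasible = True
            for cls in np.unique(y):
                members = np.flatnonzero(y == cls)
                k = int(round(frac * len(members)))
                if k < 2:
                    feasible = False
                    break
                idx.extend(rng.choice(members, size=k, replace=False).tolist())
            if not feasible:
                break
            idx = np.array(sorted(idx))
            scores.append(
                loo_accuracy(lambda: LinearDiscriminantAnalysis(solver="svd"),
                             x[idx], y[idx])
            )
        if not scores:
            warnings.warn(f"fraction {frac} infeasible; skipped", stacklevel=2)
            continue
        rows.append((float(frac), float(np.mean(scores)), float(np.std(scores))))
    return rows
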