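"""Data exploration: PCA diagnostics, bootstrap stability, Hotelling
T²/Q-residual outlier screening, and canonical correspondence analysis.

PCA is mean-centered (never autoscaled — standard for spectra); the
component-sign indeterminacy is fixed by making the largest-magnitude
loading entry of each component positive, so scores, loadings and
bootstrap cosines are reproducible.

Outlier screening follows the usual chemometric pair of distances from a
PCA model: Hotelling's T² (within-model, thresholded through the
F-distribution) and the Q residual (off-model, Jackson–Mudholkar
threshold).  A sample is flagged when either statistic exceeds its limit
at the chosen confidence (the OR rule; configurable).

CCA is the ter Braak constrained ordination: the chi-square standardized
response matrix is projected, with row-total weights, onto the span of
the explanatory variables, and the fitted matrix is decomposed by SVD.
Scaling 1 (site-focused) scores are the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import SpectralDataset, SpectrumError


@dataclass
class PCAModel:
    """Mean-centered PCA fitted by SVD."""

    mean: np.ndarray
    loadings: np.ndarray          # features × components, orthonormal columns
    eigenvalues: np.ndarray       # variances along retained components
    all_eigenvalues: np.ndarray   # full spectrum, for Q-residual thresholds
    n_samples: int

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.all_eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues * 0.0

    @property
    def cumulative_variance_ratio(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratio)

    def transform(self, matrix) -> np.ndarray:
        return (np.asarray(matrix, dtype=float) - self.mean) @ self.loadings

    def inverse_transform(self, scores) -> np.ndarray:
        return np.asarray(scores) @ self.loadings.T + self.mean


def fit_pca(matrix, n_components: int = 10) -> PCAModel:
    """Fit mean-centered PCA; ``n_components`` capped by the data rank
    bound min(samples − 1, features)."""
    x = np.asarray(matrix, dtype=float)
    n, p = x.shape
    if n < 2:
        raise SpectrumError("PCA needs at least 2 samples")
    if n_components > min(n - 1, p) or n_components < 1:
        raise SpectrumError(
            f"n_components={n_components} exceeds bound {min(n - 1, p)}"
        )
    mean = x.mean(axis=0)
    u, s, vt = np.linalg.svd(x - mean, full_matrices=False)
    eig = s**2 / (n - 1)
    loadings = vt[:n_components].T.copy()
    # sign convention: largest-|entry| of each loading is positive
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return PCAModel(
        mean=mean,
        loadings=loadings,
        eigenvalues=eig[:n_components].copy(),
        all_eigenvalues=eig,
        n_samples=n,
    )


@dataclass
class StabilityReport:
    """Bootstrap cosine stability of PCA loadings (1 = perfectly stable)."""

    cosines: np.ndarray    # n_boot_kept × n_components, values in [0, 1]
    n_boot: int
    n_skipped: int

    @property
    def mean_cosines(self) -> np.ndarray:
        return self.cosines.mean(axis=0)


def bootstrap_stability(
    matrix, n_components: int, n_boot: int = 100, seed: int = 0
) -> StabilityReport:
    """Refit PCA on ``n_boot`` row resamples; cosine = |l · l_boot| per PC
    (absolute value absorbs the sign indeterminacy).  Degenerate
    (zero-variance) resamples are skipped and counted."""
    x = np.asarray(matrix, dtype=float)
    if x.shape[0] < 3:
        raise SpectrumError("bootstrap stability needs at least 3 samples")
    ref = fit_pca(x, n_components)
    rng = np.random.default_rng(seed)
    rows = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, x.shape[0], x.shape[0])
        xb = x[idx]
        if np.allclose(xb.std(axis=0), 0.0):
            skipped += 1
            continue
        boot = fit_pca(xb, n_components)
        rows.append(np.abs(np.sum(ref.loadings * boot.loadings, axis=0)))
    if not rows:
        raise SpectrumError("all bootstrap resamples degenerate")
    return StabilityReport(
        cosines=np.clip(np.vstack(rows), 0.0, 1.0),
        n_boot=n_boot,
        n_skipped=skipped,
    )


@dataclass
class OutlierReport:
    """Per-sample T² and Q with thresholds and decision flags."""

    t2: np.ndarray
    q: np.ndarray
    t2_threshold: float
    q_threshold: float    # nan when the Q rule is disabled
    confidence: float
    rule: str
    flags: np.ndarray = field(init=False)

    def __post_init__(self):
        t2_flag = self.t2 > self.t2_threshold
        q_flag = (
            self.q > self.q_threshold
            if np.isfinite(self.q_threshold)
            else np.zeros_like(t2_flag)
        )
        if self.rule == "or":
            self.flags = t2_flag | q_flag
        elif self.rule == "and":
            self.flags = t2_flag & q_flag
        else:
            raise SpectrumError(f"unknown rule {self.rule!r}")


def hotelling_t2_threshold(n_components: int, n_samples: int, confidence: float):
    """T² limit through the F-distribution: a(n−1)/(n−a) · F₁₋α(a, n−a)."""
    a, n = n_components, n_samples
    if n <= a:
        return np.inf
    return a * (n - 1) / (n - a) * stats.f.ppf(confidence, a, n - a)


def q_residual_threshold(residual_eigenvalues, confidence: float) -> float:
    """Jackson–Mudholkar limit from the discarded eigenvalue spectrum;
    nan (rule disabled) when there is no residual variance."""
    lam = np.asarray(residual_eigenvalues, dtype=float)
    lam = lam[lam > 1e-12 * (lam.max() if lam.size else 1.0)]
    if lam.size == 0:
        return np.nan
    t1, t2, t3 = lam.sum(), (lam**2).sum(), (lam**3).sum()
    h0 = 1.0 - 2.0 * t1 * t3 / (3.0 * t2**2)
    if h0 <= 0:
        h0 = 1e-3
    z = stats.norm.ppf(confidence)
    inner = z * np.sqrt(2.0 * t2 * h0**2) / t1 + 1.0 + t2 * h0 * (h0 - 1.0) / t1**2
    if inner <= 0:
        return np.nan
    return float(t1 * inner ** (1.0 / h0))


def detect_outliers(
    model: PCAModel, matrix, confidence: float = 0.99, rule: str = "or"
) -> OutlierReport:
    """T²/Q screening of ``matrix`` against a fitted PCA model."""
    x = np.asarray(matrix, dtype=float)
    scores = model.transform(x)
    t2 = np.sum(scores**2 / model.eigenvalues, axis=1)
    residual = (x - model.mean) - scores @ model.loadings.T
    q = np.sum(residual**2, axis=1)
    q_lim = q_residual_threshold(
        model.all_eigenvalues[model.n_components:], confidence
    )
    if not np.isfinite(q_lim):
        warnings.warn("no residual variance; Q rule disabled", stacklevel=2)
    return OutlierReport(
        t2=t2,
        q=q,
        t2_threshold=float(
            hotelling_t2_threshold(model.n_components, model.n_samples, confidence)
        ),
        q_threshold=q_lim,
        confidence=confidence,
        rule=rule,
    )


def remove_outliers_and_recompile(
    dataset: SpectralDataset, report: OutlierReport
) -> SpectralDataset:
    """Drop flagged samples; labels and one-hot recompile automatically."""
    if len(report.flags) != len(dataset):
        raise SpectrumError("outlier report not aligned with dataset")
    keep = ~report.flags
    if not keep.any():
        raise SpectrumError("all samples flagged as outliers")
    return dataset.subset(keep)


# ---------------------------------------------------------------------------
# canonical correspondence analysis


@dataclass
class CCAResult:
    """ter Braak CCA of a non-negative response matrix constrained by
    explanatory variables."""

    eigenvalues: np.ndarray
    site_scores: np.ndarray     # samples × axes (LC scores)
    class_scores: np.ndarray    # response categories × axes
    biplot_scores: np.ndarray   # explanatory variables × axes
    total_inertia: float
    constrained_inertia: float
    scaling: int


def standardize(matrix) -> np.ndarray:
    """Column-wise (mean 0, sd 1) scaling, the preprocessing applied to
    band intensities before CCA."""
    x = np.asarray(matrix, dtype=float)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - x.mean(axis=0)) / sd


def fit_cca(response, explanatory, scaling: int = 1) -> CCAResult:
    """Constrained correspondence analysis (scaling 1 by default).

    ``response`` is a samples × classes non-negative matrix (here one-hot
    lineage membership) with positive row sums; ``explanatory`` the
    samples × bands matrix, standardized before the weighted regression.
    """
    y = np.asarray(response, dtype=float)
    x = standardize(explanatory)
    if np.any(y < 0):
        raise SpectrumError("response matrix must be non-negative")
    if np.any(y.sum(axis=1) <= 0):
        raise SpectrumError("every sample needs a positive response row sum")
    if np.any(y.sum(axis=0) <= 0):
        raise SpectrumError("a response class has zero total")
    total = y.sum()
    p = y / total
    r = p.sum(axis=1)            # row (site) weights
    c = p.sum(axis=0)            # column (class) weights
    # chi-square standardized residual matrix
    qbar = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    total_inertia = float((qbar**2).sum())
    # weighted least-squares projection onto the explanatory space
    xw = np.sqrt(r)[:, None] * (x - r @ x)    # weighted centering
    b, _, rank, _ = np.linalg.lstsq(xw, qbar, rcond=None)
    if rank < x.shape[1]:
        warnings.warn("rank-deficient explanatory matrix; using pseudoinverse",
                      stacklevel=2)
    fitted = xw @ b
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    n_axes = int(min(rank, y.shape[1] - 1, np.sum(s > 1e-10)))
    u, s, vt = u[:, :n_axes], s[:n_axes], vt[:n_axes]
    # sign convention as for PCA loadings, applied to class scores
    v = vt.T
    for j in range(n_axes):
        k = np.argmax(np.abs(v[:, j]))
        if v[k, j] < 0:
            v[:, j] = -v[:, j]
            u[:, j] = -u[:, j]
    eig = s**2
    if scaling == 1:      # site-focused: sites in chi-square distance
        site = (u / np.sqrt(r)[:, None]) * s
        cls = v / np.sqrt(c)[:, None]
    elif scaling == 2:    # class-focused
        site = u / np.sqrt(r)[:, None]
        cls = (v / np.sqrt(c)[:, None]) * s
    else:
        raise SpectrumError("scaling must be 1 or 2")
    # biplot scores: weighted correlation of explanatory vars with the axes
    norms = np.linalg.norm(xw, axis=0, keepdims=True)
    xs_unit = xw / np.where(norms > 0, norms, 1.0)
    biplot = xs_unit.T @ u
    return CCAResult(
        eigenvalues=eig,
        site_scores=site,
        class_scores=cls,
        biplot_scores=biplot,
        total_inertia=total_inertia,
        constrained_inertia=float(eig.sum()),
        scaling=scaling,
    )
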