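"""Data-driven SIMCA (DD-SIMCA) one-class modelling.

A PCA model of the target class defines two distances for every sample:
the score distance SD (Mahalanobis-type distance within the model plane)
and the orthogonal distance OD (squared residual norm off the plane).
Each distance, scaled by its estimated mean, approximately follows a
scaled chi-square law whose degrees of freedom N are estimated from the
training distances — by moments (N = round(2·mean²/var)) or robustly, by
matching the median/IQR ratio to the chi-square family.  The full
decision distance

    c = N_SD · SD/SD₀ + N_OD · OD/OD₀

is compared to the chi-square quantile χ²(1 − α, N_SD + N_OD): a sample
is accepted as a class member iff c ≤ c_crit.  Sensitivity is the
acceptance fraction of target samples, specificity the rejection
fraction of aliens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import SpectrumError
from .explore import PCAModel, fit_pca


def _moments_dof(d: np.ndarray):
    """Scaled-chi-square DoF and scale by the method of moments."""
    mean = float(d.mean())
    var = float(d.var(ddof=1)) if len(d) > 1 else 0.0
    if var <= 0 or mean <= 0:
        warnings.warn("zero-variance distances; DoF set to 1", stacklevel=3)
        return 1, max(mean, np.finfo(float).tiny)
    return max(1, int(round(2.0 * mean**2 / var))), mean


def _robust_dof(d: np.ndarray, max_dof: int = 250):
    """DoF/scale by quantile matching: the median/IQR ratio of χ²(N) is a
    strictly increasing function of N, inverted by scan."""
    med = float(np.median(d))
    q1, q3 = np.percentile(d, [25, 75])
    iqr = float(q3 - q1)
    if iqr <= 0 or med <= 0:
        warnings.warn("degenerate robust spread; DoF set to 1", stacklevel=3)
        return 1, max(med, np.finfo(float).tiny)
    target = med / iqr
    best_n, best_err = 1, np.inf
    for n in range(1, max_dof + 1):
        m = stats.chi2.median(n)
        spread = stats.chi2.ppf(0.75, n) - stats.chi2.ppf(0.25, n)
        err = abs(m / spread - target)
        if err < best_err:
            best_n, best_err = n, err
    scale = med / stats.chi2.median(best_n)   # mean of d in chi-square units
    return best_n, scale * best_n             # report scale as the mean


@dataclass
class DDSIMCAModel:
    """Fitted one-class model of the target (Prototaxites) class."""

    pca: PCAModel
    sd_train: np.ndarray
    od_train: np.ndarray
    sd0: float
    od0: float
    n_sd: int
    n_od: int
    alpha: float
    mode: str
    training_outlier_flags: np.ndarray

    @property
    def c_crit(self) -> float:
        return float(stats.chi2.ppf(1.0 - self.alpha, self.n_sd + self.n_od))

    def distances(self, features):
        x = np.asarray(features, dtype=float)
        if x.shape[1] != len(self.pca.mean):
            raise SpectrumError(
                f"feature dimension {x.shape[1]} != model {len(self.pca.mean)}"
            )
        scores = self.pca.transform(x)
        sd = np.sum(scores**2 / self.pca.eigenvalues, axis=1)
        resid = (x - self.pca.mean) - scores @ self.pca.loadings.T
        od = np.sum(resid**2, axis=1)
        return sd, od

    def full_distance(self, features) -> np.ndarray:
        sd, od = self.distances(features)
        return self.n_sd * sd / self.sd0 + self.n_od * od / self.od0


def _loo_distances(x: np.ndarray, n_components: int):
    """Out-of-sample SD/OD by leave-one-out: each sample's distances come
    from the model fitted without it, removing the in-sample bias that
    makes training residuals understate fresh-sample residuals."""
    n = x.shape[0]
    sd = np.empty(n)
    od = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        sub = fit_pca(x[mask], n_components)
        t = sub.transform(x[i:i + 1])
        sd[i] = float(np.sum(t**2 / sub.eigenvalues))
        r = (x[i] - sub.mean) - (t @ sub.loadings.T)[0]
        od[i] = float(np.sum(r**2))
    return sd, od


def fit_ddsimca(
    features,
    n_components: int,
    alpha: float = 0.05,
    mode: str = "moments",
    alpha_out: float = 0.01,
    distance_estimation: str = "loo",
) -> DDSIMCAModel:
    """Fit the one-class model on target-class features.

    With ``distance_estimation="loo"`` (default) the chi-square scaling
    factors and degrees of freedom are estimated from leave-one-out
    distances, so the acceptance region is calibrated for fresh samples;
    ``"insample"`` uses the training distances directly.  Training
    outliers (full distance beyond the extreme χ² quantile at
    ``alpha_out``) are flagged and reported, never silently removed.
    """
    x = np.asarray(features, dtype=float)
    if x.shape[0] < n_components + 3:
        raise SpectrumError(
            f"need >= {n_components + 3} target samples for a={n_components}"
        )
    pca = fit_pca(x, n_components)
    scores = pca.transform(x)
    sd = np.sum(scores**2 / pca.eigenvalues, axis=1)
    resid = (x - pca.mean) - scores @ pca.loadings.T
    od = np.sum(resid**2, axis=1)
    if distance_estimation == "loo":
        sd_est, od_est = _loo_distances(x, n_components)
    elif distance_estimation == "insample":
        sd_est, od_est = sd, od
    else:
        raise SpectrumError(
            f"unknown distance_estimation {distance_estimation!r}"
        )
    if mode == "moments":
        n_sd, sd0 = _moments_dof(sd_est)
        n_od, od0 = _moments_dof(od_est)
    elif mode == "robust":
        n_sd, sd0 = _robust_dof(sd_est)
        n_od, od0 = _robust_dof(od_est)
    else:
        raise SpectrumError(f"unknown estimation mode {mode!r}")
    c = n_sd * sd / sd0 + n_od * od / od0
    c_out = stats.chi2.ppf(1.0 - alpha_out, n_sd + n_od)
    return DDSIMCAModel(
        pca=pca,
        sd_train=sd,
        od_train=od,
        sd0=sd0,
        od0=od0,
        n_sd=n_sd,
        n_od=n_od,
        alpha=alpha,
        mode=mode,
        training_outlier_flags=c > c_out,
    )


def predict_membership(model: DDSIMCAModel, features):
    """Accept/reject per sample with the full decision distance.

    Returns ``(accepted, c)`` boolean and float arrays.
    """
    c = model.full_distance(features)
    return c <= model.c_crit, c


def specificity(model: DDSIMCAModel, alien_features_by_class: dict):
    """True-negative (rejection) rate per alien class and pooled."""
    per_class = {}
    rejected = total = 0
    for cls, feats in alien_features_by_class.items():
        feats = np.asarray(feats, dtype=float)
        if feats.shape[0] == 0:
            continue
        accepted, _ = predict_membership(model, feats)
        nrej = int(np.sum(~accepted))
        per_class[cls] = nrej / feats.shape[0]
        rejected += nrej
        total += feats.shape[0]
    if total == 0:
        raise SpectrumError("no alien samples supplied")
    return per_class, rejected / total


def select_components_by_sensitivity(
    features,
    candidates,
    alpha: float = 0.05,
    mode: str = "moments",
):
    """Choose the PCA dimension a by leave-one-out sensitivity.

    For each candidate a, every target sample is held out in turn, the
    model is refit on the rest, and the held-out sample's membership is
    tested; sensitivity is the acceptance fraction.  The a with the
    highest LOO sensitivity wins, ties going to the smallest a.
    """
    x = np.asarray(features, dtype=float)
    n = x.shape[0]
    feasible = [a for a in candidates
                if a + 3 <= n - 1 and a <= x.shape[1]]
    if not feasible:
        raise SpectrumError("no feasible component count for this sample size")
    report = {}
    for a in feasible:
        hits = 0
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            m = fit_ddsimca(x[mask], a, alpha=alpha, mode=mode)
            accepted, _ = predict_membership(m, x[i:i + 1])
            hits += int(accepted[0])
        report[a] = hits / n
    best = max(sorted(report), key=lambda a: report[a])
    return best, report
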