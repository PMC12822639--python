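"""Composable, history-tracked spectral preprocessing steps.

Three named recipes mirror the acquisition modes of chert-fossil FTIR work:

``atr-paper``
    truncate to the informative windows [1445, 1750] + [2760, 3000] cm⁻¹
    (dropping hydroxyl, intense silica, CO₂/diamond and overtone regions),
    ALS baseline correction, light Gaussian smoothing, then normalization
    on the highest silica-overtone absorption within [1585, 1645] cm⁻¹
    (nominal 1615 cm⁻¹ peak; a search window absorbs peak-center jitter).

``benchtop-paper``
    Gaussian smoothing, baseline correction, then a Savitzky-Golay second
    derivative (window 21, order 2).

``synchrotron-paper``
    truncate to [1440, 3000] cm⁻¹, Savitzky-Golay second derivative
    (window 9, order 2), Gaussian smoothing and vector normalization.  A
    ``synchrotron-baseline`` variant replaces the derivative with baseline
    correction, the form used upstream of CH₃/CH₂ ratio work.

Every step appends exactly one history entry to each spectrum.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter1d
from scipy.sparse.linalg import spsolve
from scipy.signal import savgol_filter
from scipy.spatial import ConvexHull

from .io import SpectralDataset, Spectrum, SpectrumError


def truncate(spectrum: Spectrum, windows) -> Spectrum:
    """Keep only grid points inside the closed intervals ``windows``.

    Windows must be disjoint, ordered, and retain at least one point.
    """
    windows = [(float(lo), float(hi)) for lo, hi in windows]
    for lo, hi in windows:
        if hi <= lo:
            raise SpectrumError(f"invalid window [{lo}, {hi}]")
    for (_, hi0), (lo1, _) in zip(windows, windows[1:]):
        if lo1 <= hi0:
            raise SpectrumError("windows must be disjoint and ascending")
    wn = spectrum.wavenumbers
    mask = np.zeros(len(wn), dtype=bool)
    for lo, hi in windows:
        mask |= (wn >= lo) & (wn <= hi)
    if not mask.any():
        raise SpectrumError("no points in windows")
    return spectrum.with_grid(
        wn[mask], spectrum.absorbance[mask], "truncate", windows=windows
    )


def _als_baseline(y: np.ndarray, lam: float, p: float, niter: int) -> np.ndarray:
    """Asymmetric least squares baseline (Whittaker smoother with
    asymmetric weights): minimizes Σ w_i (y_i − z_i)² + λ Σ (Δ²z)²."""
    n = len(y)
    d = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2), format="csc")
    dtd = lam * (d @ d.T)
    w = np.ones(n)
    z = y
    for _ in range(niter):
        a = (sparse.diags(w) + dtd).tocsc()
        z = spsolve(a, w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def _rubberband_baseline(wn: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lower convex hull of the (ν, A) points, interpolated."""
    pts = np.column_stack([wn, y])
    # degenerate: all points collinear → hull is the segment itself
    if np.allclose(y, y[0] + (y[-1] - y[0]) * (wn - wn[0]) / (wn[-1] - wn[0])):
        return y.copy()
    hull = ConvexHull(pts)
    v = hull.vertices
    # lower hull: walk from the leftmost to the rightmost vertex
    start = int(np.argmin(pts[v, 0]))
    order = np.roll(v, -start)
    end = int(np.argmax(pts[order, 0]))
    lower = order[: end + 1]
    lower = lower[np.argsort(pts[lower, 0])]
    return np.interp(wn, pts[lower, 0], pts[lower, 1])


def baseline_correct(
    spectrum: Spectrum,
    method: str = "als",
    lam: float = 1e5,
    p: float = 0.01,
    niter: int = 10,
) -> Spectrum:
    """Subtract an estimated baseline (ALS by default, or rubberband).

    ALS defaults λ=1e5, p=0.01, 10 iterations — robust for the broad
    chert background.  The estimated baseline is kept in the history entry.
    """
    y = spectrum.absorbance
    if len(y) < 8:
        raise SpectrumError("baseline correction needs at least 8 points")
    if not np.all(np.isfinite(y)):
        raise SpectrumError("non-finite absorbance values")
    if method == "als":
        base = _als_baseline(y, lam, p, niter)
        params = {"method": "als", "lam": lam, "p": p, "niter": niter}
    elif method == "rubberband":
        base = _rubberband_baseline(spectrum.wavenumbers, y)
        params = {"method": "rubberband"}
    else:
        raise SpectrumError(f"unknown baseline method {method!r}")
    return spectrum.with_absorbance(
        y - base, "baseline_correct", baseline=base, **params
    )


def gaussian_smooth(spectrum: Spectrum, sigma_points: float = 2.0) -> Spectrum:
    """Convolve with a unit-area Gaussian kernel (reflect padding)."""
    if sigma_points <= 0:
        raise SpectrumError("sigma_points must be > 0")
    smoothed = gaussian_filter1d(spectrum.absorbance, sigma_points, mode="reflect")
    return spectrum.with_absorbance(smoothed, "gaussian_smooth", sigma=sigma_points)


def normalize_silica(spectrum: Spectrum, search_window=(1585.0, 1645.0)) -> Spectrum:
    """Divide by the maximum absorbance within the silica-overtone window.

    The reference is the highest absorption in the window (nominal
    1615 cm⁻¹); after the step that maximum is exactly 1.
    """
    lo, hi = search_window
    wn = spectrum.wavenumbers
    mask = (wn >= lo) & (wn <= hi)
    if not mask.any():
        raise SpectrumError(f"search window [{lo}, {hi}] misses the grid")
    ref = float(spectrum.absorbance[mask].max())
    if ref <= 0:
        raise SpectrumError("non-positive reference peak")
    return spectrum.with_absorbance(
        spectrum.absorbance / ref, "normalize_silica", window=(lo, hi), ref=ref
    )


def vector_normalize(spectrum: Spectrum) -> Spectrum:
    """Divide by the Euclidean norm of the absorbance vector."""
    norm = float(np.linalg.norm(spectrum.absorbance))
    if norm <= 0:
        raise SpectrumError("zero-norm spectrum cannot be vector-normalized")
    return spectrum.with_absorbance(
        spectrum.absorbance / norm, "vector_normalize", norm=norm
    )


def savitzky_golay(
    spectrum: Spectrum, window: int, polyorder: int, deriv: int = 0
) -> Spectrum:
    """Savitzky-Golay filter/derivative on a uniform grid.

    The derivative is scaled by grid-spacing^(−deriv) so units are per
    (cm⁻¹)^deriv.  Edges use scipy's polynomial-extrapolation ('interp')
    mode; endpoint values rest on one-sided fits and should not drive
    derivative-based band picking.
    """
    if window % 2 == 0 or window <= polyorder or polyorder < deriv:
        raise SpectrumError("need odd window > polyorder >= deriv")
    steps = np.diff(spectrum.wavenumbers)
    if not np.allclose(steps, steps[0], rtol=1e-6):
        raise SpectrumError("non-uniform grid; regrid before Savitzky-Golay")
    out = savgol_filter(
        spectrum.absorbance,
        window_length=window,
        polyorder=polyorder,
        deriv=deriv,
        delta=float(steps[0]),
        mode="interp",
    )
    return spectrum.with_absorbance(
        out, "savitzky_golay", window=window, polyorder=polyorder, deriv=deriv
    )


# ---------------------------------------------------------------------------
# recipes

#: step name → callable(spectrum, **params)
_STEP_FUNCS = {
    "truncate": truncate,
    "baseline": baseline_correct,
    "gaussian_smooth": gaussian_smooth,
    "normalize_silica": normalize_silica,
    "vector_normalize": vector_normalize,
    "savitzky_golay": savitzky_golay,
}

RECIPES = {
    "atr-paper": [
        ("truncate", {"windows": [(1445, 1750), (2760, 3000)]}),
        ("baseline", {"method": "als"}),
        ("gaussian_smooth", {"sigma_points": 2.0}),
        ("normalize_silica", {"search_window": (1585, 1645)}),
    ],
    "benchtop-paper": [
        ("gaussian_smooth", {"sigma_points": 2.0}),
        ("baseline", {"method": "als"}),
        ("savitzky_golay", {"window": 21, "polyorder": 2, "deriv": 2}),
    ],
    "synchrotron-paper": [
        ("truncate", {"windows": [(1440, 3000)]}),
        ("savitzky_golay", {"window": 9, "polyorder": 2, "deriv": 2}),
        ("gaussian_smooth", {"sigma_points": 2.0}),
        ("vector_normalize", {}),
    ],
    "synchrotron-baseline": [
        ("truncate", {"windows": [(1440, 3000)]}),
        ("baseline", {"method": "als"}),
        ("gaussian_smooth", {"sigma_points": 2.0}),
        ("vector_normalize", {}),
    ],
}


def apply_recipe(dataset: SpectralDataset, recipe) -> SpectralDataset:
    """Apply a named recipe or an explicit ``[(step, params), ...]`` list
    to every spectrum, in order."""
    if isinstance(recipe, str):
        try:
            steps = RECIPES[recipe]
        except KeyError:
            raise SpectrumError(
                f"unknown recipe {recipe!r}; choose from {sorted(RECIPES)}"
            ) from None
    else:
        steps = list(recipe)
    out = []
    for sp in dataset.spectra:
        for name, params in steps:
            try:
                func = _STEP_FUNCS[name]
            except KeyError:
                raise SpectrumError(f"unknown step {name!r}") from None
            try:
                sp = func(sp, **params)
            except SpectrumError as err:
                raise SpectrumError(f"sample {sp.sample_id!r}: {err}") from err
        out.append(sp)
    return SpectralDataset(out, class_order=dataset.class_order)
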