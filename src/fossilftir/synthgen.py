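"""Synthetic FTIR dataset generator emulating the chert-fossil study design.

Each synthetic spectrum is a sum of Gaussian absorption bands (per-class
mean heights with lognormal multiplicative variation and small peak-center
jitter), a chert silica-overtone band near 1615 cm⁻¹ shared by every class
(all fossils are chert-hosted), a random degree-2 baseline drift, and
i.i.d. Gaussian noise.

The default class profiles encode the chemotaxonomic contrasts the real
data exhibit — chitinous classes (Fungi, Arthropoda, Oomycetes, Amoebae)
rich in amide I/II, N-products and carboxylate; bacteria rich in aliphatic
CHₓ; *Prototaxites* depleted in both but carrying a distinct
carbonyl/aromatic signal.  The numeric levels are generator parameters
chosen to be realistic for kerogenous fossil spectra; they are NOT
measured values from any specimen.

Determinism: sample ``i`` of a dataset built with seed ``s`` uses the RNG
``np.random.default_rng([s, i])``, so any sample can be regenerated alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import CLASSES, SpectralDataset, Spectrum, SpectrumError

#: generator band set: name → (center cm⁻¹, FWHM cm⁻¹); includes a
#: carbonyl band absent from the six-band feature table
GENERATOR_BANDS = {
    "amide_I": (1655.0, 30.0),
    "amide_II": (1545.0, 28.0),
    "n_products": (1590.0, 20.0),
    "carboxylate": (1560.0, 20.0),
    "carbonyl": (1710.0, 30.0),
    "ch2_asym": (2925.0, 30.0),
    "ch3_asym": (2960.0, 24.0),
}

SILICA_CENTER = 1615.0
SILICA_FWHM = 40.0

_FWHM_TO_SD = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: per-class counts of the emulated study (102 samples total)
DEFAULT_COUNTS = {
    "Plantae": 37,
    "Fungi": 24,
    "Arthropoda": 12,
    "Bacteria": 10,
    "Oomycetes": 4,
    "Amoebae": 3,
    "Prototaxites": 12,
}


@dataclass(frozen=True)
class StudyDesign:
    """Per-class sample counts, wavenumber grid, and master seed."""

    counts: dict = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    grid_lo: float = 650.0
    grid_hi: float = 4000.0
    grid_step: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if any(v < 0 for v in self.counts.values()):
            raise SpectrumError("class counts must be >= 0")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def grid(self) -> np.ndarray:
        return np.arange(self.grid_lo, self.grid_hi + 0.5 * self.grid_step,
                         self.grid_step)


@dataclass(frozen=True)
class ClassProfile:
    """Band means, variation, and nuisance parameters for one class.

    ``band_means`` maps generator-band names to mean peak heights
    (dimensionless absorbance); ``band_cv`` is the lognormal coefficient
    of variation shared by all bands; ``baseline_scale`` is the sd of the
    random degree-2 baseline coefficients; ``jitter`` the sd (cm⁻¹) of
    peak-center displacement.
    """

    band_means: dict
    silica_mean: float = 1.2
    band_cv: float = 0.10
    baseline_degree: int = 2
    baseline_scale: float = 0.02
    noise_sd: float = 0.02
    jitter: float = 0.5

    def __post_init__(self):
        if any(v < 0 for v in self.band_means.values()) or self.silica_mean < 0:
            raise SpectrumError("band intensities must be >= 0")
        if self.noise_sd < 0 or self.jitter < 0 or self.band_cv < 0:
            raise SpectrumError("noise sd, jitter and cv must be >= 0")


def default_profiles() -> dict:
    """Class → ClassProfile with the built-in chemotaxonomic contrasts."""
    means = {
        #              amide_I amide_II n_prod carbox carbonyl ch2   ch3
        "Fungi":        (0.80, 0.60, 0.50, 0.45, 0.20, 0.30, 0.21),
        "Arthropoda":   (0.75, 0.58, 0.48, 0.42, 0.18, 0.32, 0.22),
        "Oomycetes":    (0.70, 0.55, 0.45, 0.40, 0.18, 0.28, 0.20),
        "Amoebae":      (0.72, 0.56, 0.46, 0.41, 0.18, 0.30, 0.21),
        "Bacteria":     (0.25, 0.20, 0.15, 0.15, 0.15, 0.90, 0.62),
        "Plantae":      (0.30, 0.22, 0.18, 0.16, 0.30, 0.25, 0.18),
        "Prototaxites": (0.12, 0.10, 0.08, 0.08, 0.35, 0.16, 0.12),
    }
    names = list(GENERATOR_BANDS)
    return {
        cls: ClassProfile(band_means=dict(zip(names, vals)))
        for cls, vals in means.items()
    }


def _gaussian(grid: np.ndarray, center: float, fwhm: float, height: float):
    sd = fwhm * _FWHM_TO_SD
    return height * np.exp(-0.5 * ((grid - center) / sd) ** 2)


def band_sum(profile: ClassProfile, grid: np.ndarray) -> np.ndarray:
    """Noise-free deterministic band sum (mean heights, no jitter),
    including the silica band."""
    out = _gaussian(grid, SILICA_CENTER, SILICA_FWHM, profile.silica_mean)
    for name, (center, fwhm) in GENERATOR_BANDS.items():
        out += _gaussian(grid, center, fwhm, profile.band_means.get(name, 0.0))
    return out


def generate_spectrum(
    profile: ClassProfile,
    grid: np.ndarray,
    seed,
    sample_id: str = "synthetic",
    taxon: str = "unknown",
) -> Spectrum:
    """One synthetic spectrum; deterministic given ``seed`` (an int or a
    sequence fed to ``np.random.default_rng``)."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise SpectrumError("empty grid")
    rng = np.random.default_rng(seed)
    # lognormal multiplier with unit mean and the profile's cv
    sigma2 = np.log1p(profile.band_cv**2)
    absorb = np.zeros_like(grid)
    for name, (center, fwhm) in GENERATOR_BANDS.items():
        mean = profile.band_means.get(name, 0.0)
        mult = np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2))) if sigma2 else 1.0
        shift = rng.normal(0.0, profile.jitter) if profile.jitter else 0.0
        absorb += _gaussian(grid, center + shift, fwhm, mean * mult)
    mult = np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2))) if sigma2 else 1.0
    shift = rng.normal(0.0, profile.jitter) if profile.jitter else 0.0
    absorb += _gaussian(grid, SILICA_CENTER + shift, SILICA_FWHM,
                        profile.silica_mean * mult)
    if profile.baseline_scale:
        coeffs = rng.normal(0.0, profile.baseline_scale,
                            profile.baseline_degree + 1)
        x = 2.0 * (grid - grid[0]) / (grid[-1] - grid[0]) - 1.0
        absorb += np.polyval(coeffs, x)
    if profile.noise_sd:
        absorb += rng.normal(0.0, profile.noise_sd, grid.shape)
    return Spectrum(
        sample_id=sample_id,
        wavenumbers=grid,
        absorbance=absorb,
        taxon=taxon,
        history=[],
    )


def generate_dataset(
    design: StudyDesign = None, profiles: dict = None, seed: int = None
) -> SpectralDataset:
    """Generate the full labeled study: exactly the designed per-class
    counts, in class order, reproducible given the seed."""
    design = design if design is not None else StudyDesign()
    profiles = profiles if profiles is not None else default_profiles()
    seed = design.seed if seed is None else seed
    grid = design.grid()
    ordered = [c for c in CLASSES if design.counts.get(c, 0) > 0]
    missing = [c for c in ordered if c not in profiles]
    if missing:
        raise SpectrumError(f"no profile for classes {missing}")
    extra = [c for c in design.counts if c not in CLASSES and design.counts[c] > 0]
    if extra:
        raise SpectrumError(f"classes outside the vocabulary: {extra}")
    spectra = []
    idx = 0
    for cls in ordered:
        for j in range(design.counts[cls]):
            spectra.append(
                generate_spectrum(
                    profiles[cls],
                    grid,
                    seed=[seed, idx],
                    sample_id=f"{cls}_{j:03d}",
                    taxon=cls,
                )
            )
            idx += 1
    return SpectralDataset(spectra)


OUTLIER_KINDS = ("spike", "baseline-jump", "wrong-class-mixture")


def inject_outlier(
    spectrum: Spectrum,
    kind: str,
    magnitude: float,
    seed,
    mixture_profile: ClassProfile = None,
) -> Spectrum:
    """Return a perturbed copy flagged in history.

    * ``spike`` — narrow Gaussian (FWHM 8 cm⁻¹) of height ``magnitude`` at
      a random position away from the defined band centers;
    * ``baseline-jump`` — step of height ``magnitude`` at a random point;
    * ``wrong-class-mixture`` — blends in ``magnitude`` (clipped to [0,1])
      of another class's noise-free band sum.
    """
    if magnitude <= 0:
        raise SpectrumError("magnitude must be > 0")
    rng = np.random.default_rng(seed)
    wn = spectrum.wavenumbers
    ab = spectrum.absorbance.copy()
    if kind == "spike":
        centers = [c for c, _ in GENERATOR_BANDS.values()] + [SILICA_CENTER]
        # draw from actual grid points so the spike lands on data even
        # when the grid has truncation gaps
        candidates = wn[
            np.all(np.abs(wn[:, None] - np.array(centers)) > 60.0, axis=1)
        ]
        if candidates.size == 0:
            candidates = wn
        pos = float(rng.choice(candidates))
        ab += _gaussian(wn, pos, 8.0, magnitude)
        params = {"position": float(pos)}
    elif kind == "baseline-jump":
        cut = rng.integers(1, len(wn) - 1)
        ab[cut:] += magnitude
        params = {"cut_wavenumber": float(wn[cut])}
    elif kind == "wrong-class-mixture":
        if mixture_profile is None:
            raise SpectrumError("wrong-class-mixture needs a mixture_profile")
        w = min(float(magnitude), 1.0)
        ab = (1.0 - w) * ab + w * band_sum(mixture_profile, wn)
        params = {"weight": w}
    else:
        raise SpectrumError(f"unknown outlier kind {kind!r}")
    return replace(
        spectrum,
        absorbance=ab,
        history=spectrum.history
        + [{"step": "inject_outlier", "kind": kind, "magnitude": magnitude,
            **params}],
    )
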