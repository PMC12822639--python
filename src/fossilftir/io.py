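"""Spectral data model and file I/O.

A :class:`Spectrum` is one sample's absorbance trace on a wavenumber grid
(cm⁻¹); a :class:`SpectralDataset` is a stack of spectra on a shared grid
with taxon labels.  The canonical wavenumber order is ascending everywhere:
inputs printed high-to-low (e.g. "4000 to 650 cm⁻¹") are reversed on load.

Supported on-disk dialects are deliberately plain text:

* wide CSV — first column ``wavenumber``, one column per sample;
* long CSV — columns ``sample_id, wavenumber, absorbance, taxon``;
* minimal JCAMP-DX — a single ``##XYDATA=(X++(Y..Y))`` block with AFFN
  numbers (full JCAMP dialect coverage is a non-goal).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Closed vocabulary of taxon classes, in canonical column order.
CLASSES = (
    "Prototaxites",
    "Fungi",
    "Arthropoda",
    "Bacteria",
    "Plantae",
    "Oomycetes",
    "Amoebae",
)

INSTRUMENT_MODES = ("atr", "transmission", "synchrotron")


class SpectrumError(ValueError):
    """Raised for malformed spectral data or invalid spectral operations."""


@dataclass
class Spectrum:
    """One sample: wavenumber grid, absorbance trace, label, history.

    ``history`` is append-only; each entry is a dict naming the applied
    preprocessing step and its parameters.
    """

    sample_id: str
    wavenumbers: np.ndarray
    absorbance: np.ndarray
    taxon: str = "unknown"
    instrument_mode: str = "atr"
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.ndim != 1 or self.absorbance.ndim != 1:
            raise SpectrumError("wavenumbers and absorbance must be 1-D")
        if len(self.wavenumbers) != len(self.absorbance):
            raise SpectrumError("wavenumbers and absorbance length mismatch")
        if len(self.wavenumbers) < 2:
            raise SpectrumError("a spectrum needs at least 2 points")
        dv = np.diff(self.wavenumbers)
        if np.all(dv < 0):  # descending input: normalize to ascending
            self.wavenumbers = self.wavenumbers[::-1].copy()
            self.absorbance = self.absorbance[::-1].copy()
        elif not np.all(dv > 0):
            raise SpectrumError(
                f"wavenumbers of {self.sample_id!r} not strictly monotonic"
            )
        if np.any(self.wavenumbers <= 0):
            raise SpectrumError("wavenumbers must be positive")
        if self.instrument_mode not in INSTRUMENT_MODES:
            raise SpectrumError(f"unknown instrument_mode {self.instrument_mode!r}")

    def with_absorbance(self, absorbance, step: str, **params) -> "Spectrum":
        """Copy with new absorbance and one appended history entry."""
        out = replace(
            self,
            absorbance=np.asarray(absorbance, dtype=float),
            history=self.history + [{"step": step, **params}],
        )
        return out

    def with_grid(self, wavenumbers, absorbance, step: str, **params) -> "Spectrum":
        """Copy with a new grid (truncation/regridding) and a history entry."""
        return replace(
            self,
            wavenumbers=np.asarray(wavenumbers, dtype=float),
            absorbance=np.asarray(absorbance, dtype=float),
            history=self.history + [{"step": step, **params}],
        )

    def __len__(self) -> int:
        return len(self.wavenumbers)


@dataclass
class SpectralDataset:
    """Spectra on a common grid, with taxon labels and a one-hot matrix."""

    spectra: list
    class_order: tuple = CLASSES

    def __post_init__(self) -> None:
        if not self.spectra:
            raise SpectrumError("dataset needs at least one spectrum")
        grid = self.spectra[0].wavenumbers
        for sp in self.spectra[1:]:
            if len(sp.wavenumbers) != len(grid) or not np.allclose(
                sp.wavenumbers, grid
            ):
                raise SpectrumError(
                    f"spectrum {sp.sample_id!r} not on the shared grid; "
                    "use regrid() first"
                )
        self.class_order = tuple(self.class_order)

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.spectra[0].wavenumbers

    @property
    def labels(self) -> np.ndarray:
        return np.array([sp.taxon for sp in self.spectra])

    @property
    def sample_ids(self) -> list:
        return [sp.sample_id for sp in self.spectra]

    @property
    def onehot(self) -> np.ndarray:
        return one_hot(self.labels, self.class_order)

    def matrix(self) -> np.ndarray:
        """samples × grid-points absorbance matrix."""
        return np.vstack([sp.absorbance for sp in self.spectra])

    def subset(self, indices) -> "SpectralDataset":
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        return SpectralDataset(
            [self.spectra[i] for i in indices], class_order=self.class_order
        )

    def subset_classes(self, classes) -> "SpectralDataset":
        keep = [i for i, sp in enumerate(self.spectra) if sp.taxon in classes]
        if not keep:
            raise SpectrumError(f"no samples from classes {classes}")
        return self.subset(keep)

    def __len__(self) -> int:
        return len(self.spectra)


def one_hot(labels, class_order) -> np.ndarray:
    """Encode labels as a samples × classes 0/1 matrix (rows sum to 1)."""
    class_order = list(class_order)
    out = np.zeros((len(labels), len(class_order)), dtype=int)
    for i, lab in enumerate(labels):
        try:
            out[i, class_order.index(lab)] = 1
        except ValueError:
            raise SpectrumError(
                f"label {lab!r} not in class order {class_order}"
            ) from None
    return out


def regrid(dataset: SpectralDataset, target_grid) -> SpectralDataset:
    """Linearly interpolate every spectrum onto ``target_grid``.

    The target must lie within the span of every spectrum's grid;
    extrapolation is refused.
    """
    target_grid = np.asarray(target_grid, dtype=float)
    if np.any(np.diff(target_grid) <= 0):
        raise SpectrumError("target grid must be strictly ascending")
    spectra = []
    for sp in dataset.spectra:
        if target_grid[0] < sp.wavenumbers[0] or target_grid[-1] > sp.wavenumbers[-1]:
            raise SpectrumError(
                f"target grid extends past the data of {sp.sample_id!r}; "
                "extrapolation is not supported"
            )
        interp = np.interp(target_grid, sp.wavenumbers, sp.absorbance)
        spectra.append(
            sp.with_grid(
                target_grid,
                interp,
                "regrid",
                lo=float(target_grid[0]),
                hi=float(target_grid[-1]),
                n=len(target_grid),
            )
        )
    return SpectralDataset(spectra, class_order=dataset.class_order)


# ---------------------------------------------------------------------------
# file I/O


def _check_numeric(frame: pd.DataFrame, cols, path) -> pd.DataFrame:
    for col in cols:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.values)[0])
            raise SpectrumError(
                f"{path}: non-numeric value {frame[col].iloc[row]!r} "
                f"in column {col!r}, row {row}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().values)[0])
            raise SpectrumError(f"{path}: missing value in column {col!r}, row {row}")
        frame[col] = coerced
    return frame


def load_spectra(path, dialect: str = "wide-csv", labels=None) -> SpectralDataset:
    """Load a dataset from ``path`` in the given dialect.

    ``labels`` may be a mapping sample_id → taxon or a sidecar CSV path
    with columns ``sample_id,taxon``; otherwise taxa default to "unknown".
    """
    label_map = _load_labels(labels)
    if dialect == "wide-csv":
        frame = pd.read_csv(path)
        frame = _check_numeric(frame, frame.columns, path)
        wn = frame.iloc[:, 0].to_numpy(dtype=float)
        if len(np.unique(wn)) != len(wn):
            raise SpectrumError(f"{path}: duplicate wavenumbers")
        spectra = [
            Spectrum(
                sample_id=str(col),
                wavenumbers=wn,
                absorbance=frame[col].to_numpy(dtype=float),
                taxon=label_map.get(str(col), "unknown"),
            )
            for col in frame.columns[1:]
        ]
    elif dialect == "long-csv":
        frame = pd.read_csv(path)
        expected = {"sample_id", "wavenumber", "absorbance"}
        if not expected.issubset(frame.columns):
            raise SpectrumError(f"{path}: long CSV needs columns {sorted(expected)}")
        frame = _check_numeric(frame, ["wavenumber", "absorbance"], path)
        spectra = []
        for sid, grp in frame.groupby("sample_id", sort=False):
            wn = grp["wavenumber"].to_numpy(dtype=float)
            if len(np.unique(wn)) != len(wn):
                raise SpectrumError(f"{path}: duplicate wavenumbers in {sid!r}")
            taxon = "unknown"
            if "taxon" in grp.columns:
                taxon = str(grp["taxon"].iloc[0])
            taxon = label_map.get(str(sid), taxon)
            spectra.append(
                Spectrum(
                    sample_id=str(sid),
                    wavenumbers=wn,
                    absorbance=grp["absorbance"].to_numpy(dtype=float),
                    taxon=taxon,
                )
            )
    elif dialect == "jcamp-minimal":
        spectra = [_read_jcamp_minimal(path, label_map)]
    else:
        raise SpectrumError(f"unknown dialect {dialect!r}")
    try:
        return SpectralDataset(spectra)
    except SpectrumError as err:
        raise SpectrumError(f"{err}; load with a common grid or regrid") from err


def save_spectra(dataset: SpectralDataset, path, dialect: str = "wide-csv") -> None:
    """Write a dataset as wide or long CSV (17 significant digits)."""
    if dialect == "wide-csv":
        frame = pd.DataFrame(
            {"wavenumber": dataset.wavenumbers,
             **{sp.sample_id: sp.absorbance for sp in dataset.spectra}}
        )
        frame.to_csv(path, index=False, float_format="%.17g")
    elif dialect == "long-csv":
        rows = [
            pd.DataFrame(
                {
                    "sample_id": sp.sample_id,
                    "wavenumber": sp.wavenumbers,
                    "absorbance": sp.absorbance,
                    "taxon": sp.taxon,
                }
            )
            for sp in dataset.spectra
        ]
        pd.concat(rows, ignore_index=True).to_csv(
            path, index=False, float_format="%.17g"
        )
    else:
        raise SpectrumError(f"unknown dialect {dialect!r}")


def _load_labels(labels):
    if labels is None:
        return {}
    if isinstance(labels, dict):
        return {str(k): str(v) for k, v in labels.items()}
    frame = pd.read_csv(labels)
    return dict(zip(frame["sample_id"].astype(str), frame["taxon"].astype(str)))


_JCAMP_NUM = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")


def _read_jcamp_minimal(path, label_map) -> Spectrum:
    """Single-block ``##XYDATA=(X++(Y..Y))`` reader with AFFN numbers."""
    title = "jcamp"
    xfactor = yfactor = 1.0
    xs, ys = [], []
    in_xy = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                value = value.strip()
                if key == "TITLE":
                    title = value or title
                elif key == "XFACTOR":
                    xfactor = float(value)
                elif key == "YFACTOR":
                    yfactor = float(value)
                elif key == "XYDATA":
                    in_xy = True
                elif key == "END":
                    in_xy = False
                continue
            if in_xy and line:
                nums = _JCAMP_NUM.findall(line)
                if len(nums) != 2:
                    raise SpectrumError(
                        f"{path}: expected one 'X Y' AFFN pair per line, "
                        f"got {line!r}"
                    )
                xs.append(float(nums[0]) * xfactor)
                ys.append(float(nums[1]) * yfactor)
    if len(xs) < 2:
        raise SpectrumError(f"{path}: no XYDATA found")
    return Spectrum(
        sample_id=title,
        wavenumbers=np.array(xs),
        absorbance=np.array(ys),
        taxon=label_map.get(title, "unknown"),
    )
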