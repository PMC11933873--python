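"""Core containers shared across the pipeline.

Two containers travel through every stage: :class:`SpectralCube` (a hyperspectral
image, ``[row, col, band]``) and :class:`SpectrumSet` (a table of per-sample mean
spectra with a scalar perturbation value — here SOD activity in U/mg — attached
to each row).  Both carry a ``modality`` tag (``"micro"`` for microscope-coupled
hyperspectral imaging, ``"macro"`` for whole-leaf Vis-NIR imaging) because the
two instruments have different wavelength grids and all cross-scale code must
keep them apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

MODALITIES = ("micro", "macro")


class AlignmentError(ValueError):
    """Paired-sample bookkeeping between two modalities is broken."""


class FormatError(ValueError):
    """A file on disk does not match its declared structure."""


def _check_wavelengths(wavelengths: np.ndarray, n_bands: int) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size != n_bands:
        raise ValueError(
            f"wavelength axis has length {wl.size}, expected {n_bands}"
        )
    if wl.size > 1 and not np.all(np.diff(wl) > 0):
        raise ValueError("wavelengths must be strictly increasing")
    return wl


def _check_modality(modality: str) -> str:
    if modality not in MODALITIES:
        raise ValueError(f"modality must be one of {MODALITIES}, got {modality!r}")
    return modality


@dataclass
class SpectralCube:
    """A hyperspectral image: reflectance (or raw counts) indexed [row, col, band].

    Parameters
    ----------
    values
        Array of shape ``(rows, cols, bands)``; finite.
    wavelengths
        Band-centre wavelengths in nm, strictly increasing, length ``bands``.
    modality
        ``"micro"`` or ``"macro"``.
    calibrated
        True once black/white reference calibration has been applied, i.e.
        ``values`` are reflectance rather than raw counts.
    metadata
        Free-form acquisition metadata (exposure, gain, scan speed, ...);
        recorded but never used in computation.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    modality: str
    calibrated: bool = False
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(
                f"cube must be 3-D [row, col, band], got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube values must be finite")
        self.wavelengths = _check_wavelengths(self.wavelengths, self.values.shape[2])
        self.modality = _check_modality(self.modality)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


@dataclass
class SpectrumSet:
    """N samples x B bands of mean spectra plus a per-sample perturbation value.

    The perturbation is the external variable that drives spectral change —
    measured SOD activity (U/mg) by default, or a treatment code.  ``meta``
    optionally carries per-sample covariates (treatment, stage) used for
    stratified splitting; its rows are aligned with ``ids``.
    """

    ids: np.ndarray
    X: np.ndarray
    wavelengths: np.ndarray
    perturbation: np.ndarray
    modality: str
    meta: pd.DataFrame | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D (N, B), got shape {self.X.shape}")
        n, b = self.X.shape
        if self.ids.shape != (n,):
            raise ValueError(f"{self.ids.size} ids for {n} spectra")
        if len(set(self.ids.tolist())) != n:
            raise ValueError("sample ids must be unique")
        self.perturbation = np.asarray(self.perturbation, dtype=float)
        if self.perturbation.shape != (n,):
            raise ValueError(
                f"{self.perturbation.size} perturbation values for {n} spectra"
            )
        self.wavelengths = _check_wavelengths(self.wavelengths, b)
        self.modality = _check_modality(self.modality)
        if self.meta is not None and len(self.meta) != n:
            raise ValueError("meta rows must align with samples")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def take(self, index: np.ndarray) -> "SpectrumSet":
        """Row subset (new object, copied arrays, meta kept aligned)."""
        index = np.asarray(index)
        meta = None
        if self.meta is not None:
            meta = self.meta.iloc[index].reset_index(drop=True)
        return SpectrumSet(
            ids=self.ids[index].copy(),
            X=self.X[index].copy(),
            wavelengths=self.wavelengths.copy(),
            perturbation=self.perturbation[index].copy(),
            modality=self.modality,
            meta=meta,
            provenance=dict(self.provenance),
        )

    def with_X(self, X: np.ndarray, **provenance: Any) -> "SpectrumSet":
        """Same samples and grid, new intensity matrix (for preprocessing)."""
        prov = dict(self.provenance)
        prov.update(provenance)
        return SpectrumSet(
            ids=self.ids.copy(),
            X=np.asarray(X, dtype=float),
            wavelengths=self.wavelengths.copy(),
            perturbation=self.perturbation.copy(),
            modality=self.modality,
            meta=None if self.meta is None else self.meta.copy(),
            provenance=prov,
        )


def nearest_band(wavelengths: np.ndarray, nm: float) -> int:
    """Index of the grid band nearest ``nm``; half-way ties snap downward."""
    wl = np.asarray(wavelengths, dtype=float)
    d = np.abs(wl - nm)
    best = np.min(d)
    # ties (within float fuzz) resolved to the lower-wavelength band
    candidates = np.nonzero(d <= best + 1e-12)[0]
    return int(candidates[0])
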