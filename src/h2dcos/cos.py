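"""Generalized two-dimensional correlation spectroscopy (2D-COS and H2D-COS).

Given spectra measured along an external perturbation sequence p_1 <= ... <= p_N
(here: leaf SOD activity under increasing salt stress), the dynamic spectrum is
the perturbation-ordered intensity minus a reference spectrum,

    y~(v, p_j) = y(v, p_j) - y_bar(v),

with y_bar the mean spectrum by default.  The synchronous and asynchronous
correlation intensities between spectral variables v1 and v2 are

    Phi(v1, v2) = 1/(N-1) * sum_j y~(v1, p_j) z~(v2, p_j)
    Psi(v1, v2) = 1/(N-1) * sum_j y~(v1, p_j) sum_k M_jk z~(v2, p_k)

where M is the Hilbert-Noda transformation matrix (M_jk = 0 on the diagonal,
1/(pi (k-j)) off it).  In matrix form Phi = Y1' Y2 / (N-1) and
Psi = Y1' M Y2 / (N-1); X = Phi + i Psi is the complex correlation intensity.
When y~ and z~ come from two different instruments observed under the same
perturbation sequence, the same formulas give the heterogeneous (H2D-COS)
maps, whose cross-peaks link wavelengths of the two modalities.

Sensitive-peak selection works on slice spectra — single rows/columns of a
map — with two masking rules used on real instruments: bands at the extreme
ends of the grid are excluded (acquisition instability), and bands above a
long-wavelength cutoff are dropped unless their prominence is high enough to
mark an isolated genuine feature (the rule that keeps a strong ~948 nm water
band above a 750 nm cutoff).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from scipy.signal import find_peaks

from .datatypes import AlignmentError, SpectrumSet, nearest_band

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# dynamic spectra


@dataclass
class DynamicSpectra:
    """Perturbation-ordered, reference-subtracted spectra.

    ``Y[j]`` is the dynamic spectrum at perturbation ``perturbation[j]``;
    ``reference`` is the subtracted reference spectrum.
    """

    Y: np.ndarray
    wavelengths: np.ndarray
    perturbation: np.ndarray
    reference: np.ndarray
    ids: np.ndarray
    modality: str

    @property
    def n(self) -> int:
        return self.Y.shape[0]


def make_dynamic(
    spectra: SpectrumSet,
    sort_by: str = "perturbation",
    reference: str = "mean",
) -> DynamicSpectra:
    """Order samples along the perturbation and subtract the reference spectrum.

    Parameters
    ----------
    sort_by
        ``"perturbation"`` (default) orders rows by ascending perturbation
        value, ties broken stably by sample id (and logged); ``"given_order"``
        keeps the input order.
    reference
        ``"mean"`` (default) subtracts the arithmetic mean spectrum.
        ``"printed"`` uses a 1/(N-1)-normalized sum instead — a variant that
        appears in some formula listings; it is not the arithmetic mean and
        leaves the dynamic spectra with a nonzero column mean.
    """
    if spectra.n_samples < 3:
        raise ValueError("need at least 3 samples along the perturbation")
    if sort_by == "perturbation":
        order = np.lexsort((spectra.ids.astype(str), spectra.perturbation))
        p = spectra.perturbation[order]
        if np.any(np.diff(p) == 0):
            logger.info("perturbation ties present; stable order by sample id")
    elif sort_by == "given_order":
        order = np.arange(spectra.n_samples)
    else:
        raise ValueError("sort_by must be 'perturbation' or 'given_order'")
    X = spectra.X[order]
    n = X.shape[0]
    if reference == "mean":
        ref = X.mean(axis=0)
    elif reference == "printed":
        ref = X.sum(axis=0) / (n - 1)
    else:
        raise ValueError("reference must be 'mean' or 'printed'")
    return DynamicSpectra(
        Y=X - ref,
        wavelengths=spectra.wavelengths.copy(),
        perturbation=spectra.perturbation[order],
        reference=ref,
        ids=spectra.ids[order].copy(),
        modality=spectra.modality,
    )


# ---------------------------------------------------------------------------
# correlation maps


def hilbert_noda(n: int) -> np.ndarray:
    """The n x n Hilbert-Noda transformation matrix.

    M_jk = 0 if j = k, else 1 / (pi (k - j)).  Antisymmetric; acting on a
    perturbation series it implements a discrete Hilbert transform, which is
    what makes the asynchronous map sensitive to out-of-phase variation.
    """
    if n < 2:
        raise ValueError("Hilbert-Noda matrix needs n >= 2")
    j = np.arange(n)
    diff = j[None, :] - j[:, None]  # k - j
    with np.errstate(divide="ignore"):
        M = 1.0 / (np.pi * diff)
    np.fill_diagonal(M, 0.0)
    return M


def _check_aligned(d1: DynamicSpectra, d2: DynamicSpectra) -> None:
    if d1.n != d2.n:
        raise AlignmentError(f"perturbation counts differ: {d1.n} vs {d2.n}")
    if not np.array_equal(d1.ids.astype(str), d2.ids.astype(str)):
        mism = [
            (a, b)
            for a, b in zip(d1.ids.astype(str), d2.ids.astype(str))
            if a != b
        ]
        raise AlignmentError(
            f"sample ids not in identical order; first mismatches: {mism[:5]}"
        )


def sync_map(d1: DynamicSpectra, d2: DynamicSpectra) -> np.ndarray:
    """Synchronous correlation map Phi = Y1' Y2 / (N-1)."""
    _check_aligned(d1, d2)
    return d1.Y.T @ d2.Y / (d1.n - 1)


def async_map(d1: DynamicSpectra, d2: DynamicSpectra) -> np.ndarray:
    """Asynchronous correlation map Psi = Y1' M Y2 / (N-1)."""
    _check_aligned(d1, d2)
    M = hilbert_noda(d1.n)
    return d1.Y.T @ (M @ d2.Y) / (d1.n - 1)


@dataclass
class CorrelationMaps:
    """Synchronous and asynchronous maps on a (wl1, wl2) wavelength grid.

    For homogeneous maps (``hetero=False``) wl1 == wl2, ``sync`` is symmetric
    with band variances on its diagonal, and ``async_`` is antisymmetric with
    a zero diagonal.
    """

    sync: np.ndarray
    async_: np.ndarray
    wl1: np.ndarray
    wl2: np.ndarray
    hetero: bool
    n: int
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sync.shape != (self.wl1.size, self.wl2.size):
            raise ValueError("sync shape inconsistent with wavelength axes")
        if self.async_.shape != self.sync.shape:
            raise ValueError("async shape differs from sync shape")

    @property
    def complex_map(self) -> np.ndarray:
        """X = Phi + i Psi, the complex correlation intensity."""
        return self.sync + 1j * self.async_


def correlate(
    set1: SpectrumSet,
    set2: SpectrumSet,
    sort_by: str = "perturbation",
    reference: str = "mean",
) -> CorrelationMaps:
    """2D-COS between two spectrum sets observed under one perturbation.

    With ``set2 is set1`` (or an identical copy) this is ordinary homogeneous
    2D-COS; with sets from two different instruments it is H2D-COS.  Sample
    ids must be paired and in identical order — one leaf measured by both
    instruments.
    """
    if set1.n_samples != set2.n_samples:
        raise AlignmentError(
            f"sample counts differ: {set1.n_samples} vs {set2.n_samples}"
        )
    if not np.array_equal(set1.ids.astype(str), set2.ids.astype(str)):
        only1 = sorted(set(set1.ids.astype(str)) - set(set2.ids.astype(str)))
        only2 = sorted(set(set2.ids.astype(str)) - set(set1.ids.astype(str)))
        if only1 or only2:
            raise AlignmentError(
                f"unpaired samples; only in first: {only1[:5]}, "
                f"only in second: {only2[:5]}"
            )
        raise AlignmentError("paired ids present but not in identical order")
    d1 = make_dynamic(set1, sort_by=sort_by, reference=reference)
    d2 = make_dynamic(set2, sort_by=sort_by, reference=reference)
    hetero = set1.modality != set2.modality
    prov = {
        "sort_by": sort_by,
        "reference": reference,
        "modality_1": set1.modality,
        "modality_2": set2.modality,
        "preprocess_1": set1.provenance.get("preprocess", "none"),
        "preprocess_2": set2.provenance.get("preprocess", "none"),
    }
    return CorrelationMaps(
        sync=sync_map(d1, d2),
        async_=async_map(d1, d2),
        wl1=d1.wavelengths,
        wl2=d2.wavelengths,
        hetero=hetero,
        n=d1.n,
        provenance=prov,
    )


def hetero_corr(
    micro: SpectrumSet,
    macro: SpectrumSet,
    sort_by: str = "perturbation",
    reference: str = "mean",
) -> CorrelationMaps:
    """H2D-COS between the microscopic and macroscopic spectrum sets.

    Axis 1 of the maps is the first argument's wavelength grid.  The reverse
    direction is the transpose: ``hetero_corr(macro, micro).sync`` equals
    ``hetero_corr(micro, macro).sync.T`` (and the async map transposes with a
    sign flip, since M' = -M).
    """
    return correlate(micro, macro, sort_by=sort_by, reference=reference)


# ---------------------------------------------------------------------------
# slices and sensitive peaks


@dataclass
class SliceSpectrum:
    """One row/column of a correlation map at a fixed wavelength."""

    values: np.ndarray
    wavelengths: np.ndarray   # the *other* axis
    source_nm: float          # snapped wavelength the slice was taken at
    which: str                # "sync" or "async"
    axis: int                 # axis that was fixed (1 or 2)


def slice_spectrum(
    maps: CorrelationMaps, which: str, axis: int, at_nm: float
) -> SliceSpectrum:
    """Extract the map's slice at the grid band nearest ``at_nm``.

    ``axis=1`` fixes a wavelength on the first (row) axis and returns a
    spectrum over the second axis; ``axis=2`` the converse.  Requests snap to
    the nearest band (ties downward); requests outside the grid raise.
    """
    if which not in ("sync", "async"):
        raise ValueError("which must be 'sync' or 'async'")
    if axis not in (1, 2):
        raise ValueError("axis must be 1 or 2")
    grid = maps.wl1 if axis == 1 else maps.wl2
    if not (grid[0] <= at_nm <= grid[-1]):
        raise ValueError(
            f"requested {at_nm} nm outside axis-{axis} grid "
            f"[{grid[0]}, {grid[-1]}] nm"
        )
    idx = nearest_band(grid, at_nm)
    snapped = float(grid[idx])
    if snapped != at_nm:
        logger.info("slice request %.3f nm snapped to %.3f nm", at_nm, snapped)
    if idx in (0, grid.size - 1):
        warnings.warn(
            f"slice at grid boundary ({snapped:.1f} nm)", stacklevel=2
        )
    data = maps.sync if which == "sync" else maps.async_
    values = data[idx, :] if axis == 1 else data[:, idx]
    other = maps.wl2 if axis == 1 else maps.wl1
    return SliceSpectrum(
        values=values.copy(),
        wavelengths=other.copy(),
        source_nm=snapped,
        which=which,
        axis=axis,
    )


@dataclass
class PeakList:
    """Sensitive wavelengths found on a slice, with the masking rules applied."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    source_slice: float
    exclusions_applied: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return self.wavelengths.size


def find_sensitive_peaks(
    slc: SliceSpectrum,
    edge_bands: int = 5,
    max_wavelength: float | None = 750.0,
    min_prominence: float = 0.05,
    keep_above_cutoff_prominence: float = 0.5,
) -> PeakList:
    """Local maxima of |slice| with edge and long-wavelength exclusions.

    ``edge_bands`` bands at each end of the grid are masked (instrument
    instability at the scan ends).  Bands above ``max_wavelength`` are
    dropped, except that a peak whose prominence exceeds
    ``keep_above_cutoff_prominence`` times the slice maximum is retained as
    an isolated genuine feature (pass ``max_wavelength=None`` to disable the
    cutoff entirely).  Peaks with prominence below ``min_prominence`` times
    the slice maximum are dropped.  Returned sorted by wavelength.
    """
    a = np.abs(slc.values)
    b = a.size
    if b < 2 * edge_bands + 3:
        raise ValueError(
            f"slice of {b} bands too short for edge_bands={edge_bands}"
        )
    interior = np.zeros(b, dtype=bool)
    interior[edge_bands : b - edge_bands] = True
    if max_wavelength is not None and not np.any(
        interior & (slc.wavelengths <= max_wavelength)
    ):
        raise ValueError("all bands masked by edge/cutoff rules")
    top = a.max()
    if top == 0:
        return PeakList(
            wavelengths=np.array([]),
            intensities=np.array([]),
            source_slice=slc.source_nm,
            exclusions_applied={
                "edge_bands": edge_bands,
                "max_wavelength": max_wavelength,
            },
        )
    idx, props = find_peaks(a, prominence=min_prominence * top)
    prom = props["prominences"]
    keep = interior[idx]
    if max_wavelength is not None:
        above = slc.wavelengths[idx] > max_wavelength
        keep &= ~above | (prom >= keep_above_cutoff_prominence * top)
    idx, prom = idx[keep], prom[keep]
    order = np.argsort(slc.wavelengths[idx])
    idx = idx[order]
    return PeakList(
        wavelengths=slc.wavelengths[idx],
        intensities=a[idx],
        source_slice=slc.source_nm,
        exclusions_applied={
            "edge_bands": edge_bands,
            "max_wavelength": max_wavelength,
            "min_prominence": min_prominence,
            "keep_above_cutoff_prominence": keep_above_cutoff_prominence,
        },
    )


def best_slice_band(maps: CorrelationMaps, axis: int = 1) -> float:
    """Wavelength on the chosen axis with the largest sync-map energy.

    A practical automatic choice of where to take a slice: the band whose row
    (axis=1) or column (axis=2) of |sync| has the greatest L2 norm, i.e. the
    band most strongly correlated with the other modality overall.
    """
    norms = (
        np.linalg.norm(maps.sync, axis=1)
        if axis == 1
        else np.linalg.norm(maps.sync, axis=0)
    )
    grid = maps.wl1 if axis == 1 else maps.wl2
    return float(grid[int(np.argmax(norms))])


# ---------------------------------------------------------------------------
# persistence


def save_maps(maps: CorrelationMaps, path: str | Path) -> Path:
    """Write maps to HDF5 (datasets sync/async/wl1/wl2, provenance attr)."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("sync", data=maps.sync)
        f.create_dataset("async", data=maps.async_)
        f.create_dataset("wl1", data=maps.wl1)
        f.create_dataset("wl2", data=maps.wl2)
        f.attrs["hetero"] = maps.hetero
        f.attrs["n"] = maps.n
        f.attrs["provenance"] = json.dumps(maps.provenance)
    return path


def load_maps(path: str | Path) -> CorrelationMaps:
    import h5py

    with h5py.File(path, "r") as f:
        return CorrelationMaps(
            sync=f["sync"][()],
            async_=f["async"][()],
            wl1=f["wl1"][()],
            wl2=f["wl2"][()],
            hetero=bool(f.attrs["hetero"]),
            n=int(f.attrs["n"]),
            provenance=json.loads(f.attrs.get("provenance", "{}")),
        )
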