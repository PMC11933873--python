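"""Spectral pretreatments: smoothing, polynomial baseline removal, first derivative.

All three operate row-wise on a :class:`~h2dcos.datatypes.SpectrumSet` and are
linear in the spectra, so they commute with sample averaging — a property the
test suite checks.  Savitzky-Golay filtering backs both the smoother and the
derivative; the baseline is a least-squares polynomial detrend per spectrum.

Edge handling: SG uses polynomial extrapolation at the grid ends
(``mode="interp"``), which keeps constants, ramps and their derivatives exact
everywhere; downstream peak selection discards edge bands anyway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .datatypes import SpectrumSet

METHODS = ("none", "smoothing", "baseline", "fd")


@dataclass
class PreprocessSpec:
    """Pretreatment choice and its parameters.

    window/polyorder apply to the SG-based methods (defaults 7 and 2, the
    common chemometric choice); baseline_order is the detrend polynomial
    degree (default 2).
    """

    method: str = "none"
    window: int = 7
    polyorder: int = 2
    baseline_order: int = 2

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.polyorder >= self.window:
            raise ValueError("polyorder must be < window")
        if self.baseline_order < 0:
            raise ValueError("baseline_order must be >= 0")


def _require_window(spectra: SpectrumSet, spec: PreprocessSpec) -> None:
    if spec.window >= spectra.n_bands:
        raise ValueError(
            f"SG window {spec.window} must be smaller than the band count "
            f"{spectra.n_bands}"
        )


def smooth(spectra: SpectrumSet, spec: PreprocessSpec | None = None) -> SpectrumSet:
    """Savitzky-Golay smoothing per spectrum; wavelengths unchanged."""
    spec = spec or PreprocessSpec(method="smoothing")
    _require_window(spectra, spec)
    Xs = savgol_filter(
        spectra.X, spec.window, spec.polyorder, axis=1, mode="interp"
    )
    return spectra.with_X(Xs, preprocess="smoothing", window=spec.window)


def baseline_correct(
    spectra: SpectrumSet, spec: PreprocessSpec | None = None
) -> SpectrumSet:
    """Subtract a per-spectrum least-squares polynomial of degree baseline_order.

    Degree 0 mean-centres each spectrum; degree 1 removes offset and tilt;
    degree 2 (default) additionally removes gentle curvature from scattering
    and illumination drift.
    """
    spec = spec or PreprocessSpec(method="baseline")
    if spectra.n_bands <= spec.baseline_order + 1:
        raise ValueError(
            f"need more than {spec.baseline_order + 1} bands for a degree-"
            f"{spec.baseline_order} baseline"
        )
    # shared Vandermonde basis on a normalized axis for conditioning
    t = np.linspace(-1.0, 1.0, spectra.n_bands)
    V = np.polynomial.polynomial.polyvander(t, spec.baseline_order)
    coef, *_ = np.linalg.lstsq(V, spectra.X.T, rcond=None)
    Xb = spectra.X - (V @ coef).T
    return spectra.with_X(Xb, preprocess="baseline", baseline_order=spec.baseline_order)


def first_derivative(
    spectra: SpectrumSet, spec: PreprocessSpec | None = None
) -> SpectrumSet:
    """Savitzky-Golay first derivative per spectrum, in reflectance per nm.

    The derivative is scaled by the (mean) band spacing so its units do not
    depend on the grid; for the slightly non-uniform macro grid the mean
    spacing is used.
    """
    spec = spec or PreprocessSpec(method="fd")
    _require_window(spectra, spec)
    delta = float(np.mean(np.diff(spectra.wavelengths)))
    Xd = savgol_filter(
        spectra.X,
        spec.window,
        max(spec.polyorder, 1),
        deriv=1,
        delta=delta,
        axis=1,
        mode="interp",
    )
    return spectra.with_X(Xd, preprocess="fd", window=spec.window)


def apply(spectra: SpectrumSet, spec: PreprocessSpec) -> SpectrumSet:
    """Dispatch on ``spec.method`` (``"none"`` returns the input unchanged)."""
    if spec.method == "none":
        return spectra.with_X(spectra.X.copy(), preprocess="none")
    if spec.method == "smoothing":
        return smooth(spectra, spec)
    if spec.method == "baseline":
        return baseline_correct(spectra, spec)
    if spec.method == "fd":
        return first_derivative(spectra, spec)
    raise ValueError(f"unknown method {spec.method!r}")
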