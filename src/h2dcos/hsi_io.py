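"""Hyperspectral I/O and radiometric calibration.

Cubes are exchanged as ENVI header (``.hdr``) + flat binary pairs — the common
denominator of hyperspectral toolchains.  BSQ, BIL and BIP interleaves are all
accepted on read; BSQ double-precision is written, so write/read round-trips
are lossless.  Spectrum tables are CSV with one row per sample and one
``wl_<nm>`` column per band.

Reflectance calibration follows the standard dark/white reference correction

    R = (R0 - D) / (W - D)

where ``R0`` is the raw image and ``D``/``W`` are dark- and white-reference
frames (full images or per-band vectors; numpy broadcasting rules apply).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import FormatError, SpectralCube, SpectrumSet, _check_modality

_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class CalibrationFrames:
    """Dark- and white-reference frames for reflectance calibration.

    Either full images with the same ``(rows, cols, bands)`` shape as the
    target cube, or per-band vectors of length ``bands`` (row-averaged
    references); anything numpy can broadcast against the cube is accepted.
    """

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        if self.dark.shape != self.white.shape:
            raise ValueError(
                f"dark shape {self.dark.shape} != white shape {self.white.shape}"
            )


def calibrate(raw: SpectralCube, frames: CalibrationFrames) -> SpectralCube:
    """Apply dark/white reference correction: R = (R0 - D) / (W - D).

    Raises
    ------
    ValueError
        If the cube is already calibrated, if frame shapes cannot broadcast
        against the cube, or if ``white - dark`` is zero anywhere (the error
        names the first offending band).
    """
    if raw.calibrated:
        raise ValueError("cube is already calibrated")
    try:
        denom = np.broadcast_to(
            np.asarray(frames.white - frames.dark, dtype=float), raw.values.shape
        )
    except ValueError as exc:
        raise ValueError(
            f"calibration frames of shape {frames.dark.shape} do not broadcast "
            f"against cube of shape {raw.values.shape}"
        ) from exc
    zero = denom == 0
    if np.any(zero):
        band = int(np.nonzero(zero.any(axis=(0, 1)))[0][0])
        raise ZeroDivisionError(
            f"white - dark is zero at band index {band} "
            f"({raw.wavelengths[band]:.1f} nm)"
        )
    reflectance = (raw.values - frames.dark) / denom
    return SpectralCube(
        values=reflectance,
        wavelengths=raw.wavelengths.copy(),
        modality=raw.modality,
        calibrated=True,
        metadata=dict(raw.metadata),
    )


def extract_mean_spectrum(cube: SpectralCube, mask: np.ndarray) -> np.ndarray:
    """Per-band mean over the masked pixels (region-of-interest averaging)."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != cube.values.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} != cube spatial shape {cube.values.shape[:2]}"
        )
    if not mask.any():
        raise ValueError("mask selects no pixels")
    return cube.values[mask].mean(axis=0)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask image (PNG etc.); nonzero pixels are selected."""
    from PIL import Image

    img = np.asarray(Image.open(path).convert("L"))
    return img != 0


# ---------------------------------------------------------------------------
# ENVI cube I/O


def _parse_envi_header(text: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_cube(path: str | Path, modality: str | None = None) -> SpectralCube:
    """Read an ENVI header/binary pair into a :class:`SpectralCube`.

    ``path`` may point at either the ``.hdr`` or the data file.  Modality is
    taken from a ``modality`` line in the header if present, otherwise from
    the ``modality`` argument.
    """
    path = Path(path)
    hdr_path = path if path.suffix == ".hdr" else path.with_suffix(path.suffix + ".hdr")
    if not hdr_path.exists():
        hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FormatError(f"no ENVI header found for {path}")
    fields = _parse_envi_header(hdr_path.read_text())

    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
        dtype_code = int(fields.get("data type", "4"))
        interleave = fields.get("interleave", "bsq").lower()
    except (KeyError, ValueError) as exc:
        raise FormatError(f"malformed ENVI header {hdr_path}: {exc}") from exc
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type {dtype_code}")
    dtype = _ENVI_DTYPES[dtype_code]
    offset = int(fields.get("header offset", "0"))

    wl_text = fields.get("wavelength", "")
    wl = np.array(
        [float(t) for t in re.findall(r"[-+0-9.eE]+", wl_text)], dtype=float
    )
    if wl.size != bands:
        raise FormatError(
            f"header lists {wl.size} wavelengths for {bands} bands in {hdr_path}"
        )

    data_path = hdr_path.with_suffix("") if hdr_path != path else path
    if data_path == hdr_path or not data_path.exists():
        for ext in ("", ".img", ".raw", ".dat"):
            cand = hdr_path.with_suffix(ext)
            if cand.exists() and cand != hdr_path:
                data_path = cand
                break
        else:
            raise FormatError(f"no data file found next to {hdr_path}")

    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    expected = lines * samples * bands
    if raw.size != expected:
        raise FormatError(
            f"{data_path}: {raw.size} values on disk, header implies {expected}"
        )
    if interleave == "bsq":
        values = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        values = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        values = raw.reshape(lines, samples, bands)
    else:
        raise FormatError(f"unsupported interleave {interleave!r}")

    mod = fields.get("modality", modality)
    if mod is None:
        raise ValueError("modality not in header; pass modality= explicitly")
    calibrated = fields.get("calibrated", "0").strip() in ("1", "true", "True")
    return SpectralCube(
        values=np.ascontiguousarray(values, dtype=float),
        wavelengths=wl,
        modality=_check_modality(mod),
        calibrated=calibrated,
    )


def write_cube(cube: SpectralCube, path: str | Path) -> Path:
    """Write a cube as ENVI BSQ float64 (.hdr + flat binary). Returns hdr path."""
    path = Path(path)
    data_path = path.with_suffix(".img") if path.suffix == ".hdr" else path
    hdr_path = data_path.with_suffix(data_path.suffix + ".hdr")
    rows, cols, bands = cube.shape
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[np.dtype(np.float64)]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"modality = {cube.modality}\n"
        f"calibrated = {int(cube.calibrated)}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr_path.write_text(hdr)
    cube.values.transpose(2, 0, 1).astype(np.float64).tofile(data_path)
    return hdr_path


# ---------------------------------------------------------------------------
# Spectrum-table I/O

_WL_COL = re.compile(r"^wl_([-+0-9.eE]+)$")


def write_spectra(spectra: SpectrumSet, path: str | Path) -> Path:
    """Write a SpectrumSet as CSV: id, meta columns, sod_u_per_mg, wl_<nm>..."""
    path = Path(path)
    df = pd.DataFrame({"id": spectra.ids})
    if spectra.meta is not None:
        for col in spectra.meta.columns:
            df[col] = spectra.meta[col].to_numpy()
    df["modality"] = spectra.modality
    df["sod_u_per_mg"] = spectra.perturbation
    wl_cols = [f"wl_{w:g}" for w in spectra.wavelengths]
    df = pd.concat(
        [df, pd.DataFrame(spectra.X, columns=wl_cols)], axis=1
    )
    df.to_csv(path, index=False)
    return path


def read_spectra(path: str | Path, modality: str | None = None) -> SpectrumSet:
    """Read a spectrum-table CSV.

    Wavelength columns (``wl_<nm>``) are re-sorted into ascending order if the
    file stores them shuffled.  Remaining non-reserved columns become ``meta``.
    """
    df = pd.read_csv(path)
    if "id" not in df.columns or "sod_u_per_mg" not in df.columns:
        raise FormatError(f"{path}: expected 'id' and 'sod_u_per_mg' columns")
    wl_pairs = []
    for col in df.columns:
        m = _WL_COL.match(col)
        if m:
            wl_pairs.append((float(m.group(1)), col))
    if not wl_pairs:
        raise FormatError(f"{path}: no wl_<nm> columns found")
    wl_pairs.sort()
    wavelengths = np.array([w for w, _ in wl_pairs])
    X = df[[c for _, c in wl_pairs]].to_numpy(dtype=float)
    mod = modality
    if "modality" in df.columns:
        mods = set(df["modality"].astype(str))
        if len(mods) != 1:
            raise FormatError(f"{path}: mixed modalities {mods}")
        mod = mods.pop()
    if mod is None:
        raise ValueError("modality not in file; pass modality= explicitly")
    reserved = {"id", "modality", "sod_u_per_mg"} | {c for _, c in wl_pairs}
    meta_cols = [c for c in df.columns if c not in reserved]
    meta = df[meta_cols].reset_index(drop=True) if meta_cols else None
    return SpectrumSet(
        ids=df["id"].astype(str).to_numpy(dtype=object),
        X=X,
        wavelengths=wavelengths,
        perturbation=df["sod_u_per_mg"].to_numpy(dtype=float),
        modality=mod,
        meta=meta,
    )
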