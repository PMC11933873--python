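"""Paired micro/macro synthetic hyperspectral data with known ground truth.

No public dataset accompanies the cross-scale SOD study this package
implements, so every downstream stage is exercised on simulated data whose
statistical structure matches what the analysis assumes:

* a salt-stress experiment — 4 NaCl treatments (0/1/2/3 g/L) crossed with
  3 growth stages (seedling/flowering/fruiting, encoded A/B/C), 27 plants per
  treatment-stage cell, 324 leaf samples in total;
* leaf SOD activity (U/mg) increasing linearly with salt concentration and
  stage, plus assay noise;
* one mean reflectance spectrum per leaf and per instrument: a microscope-
  coupled hyperspectral camera ("micro", 400-1000 nm at 2 nm) and a whole-leaf
  Vis-NIR imager ("macro", 400-1000 nm at 2.35 nm — a deliberately different
  grid, because the two real instruments differ);
* smooth modality-specific baselines reproducing realistic tomato-leaf curve shapes
  (micro: peaks near 480/560 nm, valleys near 500/690 nm, low plateau past
  700 nm; macro: green peak near 545 nm, red-edge rise to a 755-900 nm
  plateau, small water valley near 950 nm);
* narrow SOD-proportional absorption dips planted at each modality's
  sensitive wavelengths (defaults: the ten micro and ten macro bands the
  cross-scale correlation analysis is expected to recover);
* per-sample smooth baseline drift (offset, tilt, curvature and a broad
  random bump) emulating illumination and scattering variation — the reason
  baseline / first-derivative pretreatments earn their keep — plus i.i.d.
  band noise;
* small image cubes per modality whose pixels share the sample spectrum with
  a planted spatial SOD gradient, for testing pixel-wise activity mapping.

All stochastic terms scale with ``noise_sd``: setting it to zero yields fully
deterministic spectra (no drift, no assay noise), which the generator's
zero-noise contracts rely on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import SpectralCube, SpectrumSet
from . import hsi_io

MICRO_SENSITIVE_NM = (426.0, 458.0, 481.0, 510.0, 527.0, 547.0, 607.0, 631.0, 641.0, 682.0)
MACRO_SENSITIVE_NM = (497.0, 511.0, 516.0, 540.0, 564.0, 607.0, 641.0, 694.0, 723.0, 948.0)

STAGES = ("A", "B", "C")


def _gauss(wl: np.ndarray, centre: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - centre) / sd) ** 2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def micro_baseline(wl: np.ndarray) -> np.ndarray:
    """Smooth stress-free microscopic reflectance curve (400-1000 nm)."""
    return (
        0.18
        + 0.10 * _gauss(wl, 480.0, 18.0)
        - 0.07 * _gauss(wl, 500.0, 10.0)
        + 0.16 * _gauss(wl, 560.0, 28.0)
        - 0.10 * _gauss(wl, 690.0, 30.0)
        - 0.05 * _sigmoid((wl - 700.0) / 20.0)
    )


def macro_baseline(wl: np.ndarray) -> np.ndarray:
    """Smooth whole-leaf Vis-NIR reflectance curve (400-1000 nm)."""
    return (
        0.08
        + 0.10 * _gauss(wl, 545.0, 30.0)
        - 0.03 * _gauss(wl, 490.0, 20.0)
        - 0.04 * _gauss(wl, 680.0, 25.0)
        + 0.42 * _sigmoid((wl - 715.0) / 18.0)
        - 0.05 * _gauss(wl, 950.0, 25.0)
    )


@dataclass
class GeneratorConfig:
    """Study design and noise model for the paired synthetic dataset.

    Defaults are the simulated experiment's fixed conditions, not tuning
    knobs: 27 plants per treatment-stage cell, treatments 0-3 g/L NaCl,
    stages A/B/C, and the two instruments' wavelength grids.  SOD activity is
    ``sod_base + sod_conc_slope*conc + sod_stage_slope*stage_index`` plus
    assay noise, truncated at zero.  Planted absorption dips have depth
    ``effect_size * SOD`` (reflectance per U/mg; negative = dip).
    """

    n_plants_per_cell: int = 27
    treatments: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    stages: tuple[str, ...] = STAGES
    micro_grid: np.ndarray | None = None    # default 400-1000 nm, 2 nm step
    macro_grid: np.ndarray | None = None    # default 400-1000 nm, 2.35 nm step
    sensitive_bands_micro: tuple[float, ...] = MICRO_SENSITIVE_NM
    sensitive_bands_macro: tuple[float, ...] = MACRO_SENSITIVE_NM
    effect_size_micro: float = -0.25        # reflectance per (U/mg), dips
    effect_size_macro: float = -0.25
    feature_sd_micro: float = 4.0           # nm; narrow absorption features
    feature_sd_macro: float = 1.5           # nm; the 511/516 doublet must resolve
    sod_base: float = 0.10                  # U/mg, unstressed seedling
    sod_conc_slope: float = 0.04            # U/mg per g/L NaCl
    sod_stage_slope: float = 0.05           # U/mg per stage step
    sod_noise_frac: float = 8.0             # assay noise sd = frac * noise_sd (U/mg scale)
    noise_sd: float = 0.001                 # i.i.d. reflectance noise per band
    drift_offset_mult: float = 180.0         # per-sample drift sds, in units of noise_sd
    drift_slope_mult: float = 120.0
    drift_curve_mult: float = 72.0
    drift_bump_mult: float = 40.0           # broad random bumps (sd 60-110 nm)
    drift_n_bumps: int = 3
    n_cubes: int = 4
    cube_shape: tuple[int, int] = (24, 24)
    cube_gradient_span: float = 0.08        # U/mg across each cube
    seed: int = 0

    def __post_init__(self) -> None:
        if self.micro_grid is None:
            self.micro_grid = np.arange(400.0, 1000.0 + 1e-9, 2.0)
        if self.macro_grid is None:
            self.macro_grid = np.arange(400.0, 1000.0 + 1e-9, 2.35)
        self.micro_grid = np.asarray(self.micro_grid, dtype=float)
        self.macro_grid = np.asarray(self.macro_grid, dtype=float)
        for name, grid in (("micro_grid", self.micro_grid), ("macro_grid", self.macro_grid)):
            if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
                raise ValueError(f"{name} must be 1-D and strictly increasing")
        if any(c < 0 for c in self.treatments):
            raise ValueError("salt concentrations must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_plants_per_cell < 1:
            raise ValueError("need at least one plant per cell")
        for name, bands, grid in (
            ("sensitive_bands_micro", self.sensitive_bands_micro, self.micro_grid),
            ("sensitive_bands_macro", self.sensitive_bands_macro, self.macro_grid),
        ):
            if len(bands) < 1:
                raise ValueError(f"{name} must contain at least one band")
            for b in bands:
                if not (grid[0] <= b <= grid[-1]):
                    raise ValueError(
                        f"{name}: band {b} nm outside grid "
                        f"[{grid[0]}, {grid[-1]}] nm"
                    )


@dataclass
class Truth:
    """Ground truth planted by the generator, for recovery tests."""

    bands: pd.DataFrame               # modality, wavelength_nm, grid_nm, effect_size
    cube_sod_maps: list[np.ndarray]   # per-cube per-pixel SOD activity
    cube_sample_ids: list[str]
    is_null_model: bool


@dataclass
class SyntheticDataset:
    """Paired micro/macro spectra, labels, small cubes, and planted truth."""

    micro: SpectrumSet
    macro: SpectrumSet
    micro_cubes: list[SpectralCube]
    macro_cubes: list[SpectralCube]
    sod: np.ndarray
    truth: Truth
    config: GeneratorConfig = field(repr=False, default=None)


def _drift(rng: np.random.Generator, wl: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    """One sample's smooth baseline perturbation (illumination/scattering)."""
    s = cfg.noise_sd
    t = (wl - wl.mean()) / ((wl[-1] - wl[0]) / 2.0)
    a0 = rng.normal(0.0, cfg.drift_offset_mult * s)
    a1 = rng.normal(0.0, cfg.drift_slope_mult * s)
    a2 = rng.normal(0.0, cfg.drift_curve_mult * s)
    out = a0 + a1 * t + a2 * t * t
    for _ in range(cfg.drift_n_bumps):
        bump_amp = rng.normal(0.0, cfg.drift_bump_mult * s)
        bump_centre = rng.uniform(wl[0], wl[-1])
        bump_sd = rng.uniform(60.0, 110.0)
        out = out + bump_amp * _gauss(wl, bump_centre, bump_sd)
    return out


def _effect_profile(
    wl: np.ndarray, bands: tuple[float, ...], amp: float, feature_sd: float
) -> np.ndarray:
    """Per-band effect-loading vector: sum of narrow Gaussians at the planted bands."""
    profile = np.zeros_like(wl)
    for b in bands:
        profile += amp * _gauss(wl, b, feature_sd)
    return profile


def generate_dataset(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Draw a full paired dataset; bit-reproducible from ``config.seed``."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)

    ids, sod, rows = [], [], []
    for conc in cfg.treatments:
        for s_idx, stage in enumerate(cfg.stages):
            for plant in range(cfg.n_plants_per_cell):
                mean_sod = (
                    cfg.sod_base
                    + cfg.sod_conc_slope * conc
                    + cfg.sod_stage_slope * s_idx
                )
                value = mean_sod + rng.normal(0.0, cfg.sod_noise_frac * cfg.noise_sd)
                sod.append(max(value, 0.0))
                ids.append(f"C{conc:g}-{stage}-{plant:02d}")
                rows.append({"treatment_g_per_l": conc, "stage": stage, "stage_index": s_idx})
    sod = np.array(sod)
    meta = pd.DataFrame(rows)
    n = len(ids)

    grids = {"micro": cfg.micro_grid, "macro": cfg.macro_grid}
    baselines = {"micro": micro_baseline(cfg.micro_grid), "macro": macro_baseline(cfg.macro_grid)}
    profiles = {
        "micro": _effect_profile(
            cfg.micro_grid, cfg.sensitive_bands_micro, cfg.effect_size_micro, cfg.feature_sd_micro
        ),
        "macro": _effect_profile(
            cfg.macro_grid, cfg.sensitive_bands_macro, cfg.effect_size_macro, cfg.feature_sd_macro
        ),
    }

    sets: dict[str, SpectrumSet] = {}
    for modality in ("micro", "macro"):
        wl, base, prof = grids[modality], baselines[modality], profiles[modality]
        X = np.empty((n, wl.size))
        for i in range(n):
            X[i] = (
                base
                + prof * sod[i]
                + _drift(rng, wl, cfg)
                + rng.normal(0.0, cfg.noise_sd, wl.size)
            )
        sets[modality] = SpectrumSet(
            ids=np.array(ids, dtype=object),
            X=X,
            wavelengths=wl,
            perturbation=sod,
            modality=modality,
            meta=meta.copy(),
            provenance={"generator_seed": cfg.seed},
        )

    # --- small cubes with a planted spatial SOD gradient -------------------
    micro_cubes: list[SpectralCube] = []
    macro_cubes: list[SpectralCube] = []
    sod_maps: list[np.ndarray] = []
    cube_ids: list[str] = []
    h, w = cfg.cube_shape
    yy, xx = np.meshgrid(np.linspace(0, 1, h), np.linspace(0, 1, w), indexing="ij")
    n_cubes = min(cfg.n_cubes, n)
    cube_samples = np.linspace(0, n - 1, n_cubes).astype(int) if n_cubes else []
    for i in cube_samples:
        gradient = cfg.cube_gradient_span * (0.6 * xx + 0.4 * yy - 0.5)
        sod_map = np.maximum(sod[i] + gradient, 0.0)
        sod_maps.append(sod_map)
        cube_ids.append(ids[i])
        for modality, cubes in (("micro", micro_cubes), ("macro", macro_cubes)):
            wl, base, prof = grids[modality], baselines[modality], profiles[modality]
            drift = _drift(rng, wl, cfg)
            values = (
                base[None, None, :]
                + prof[None, None, :] * sod_map[:, :, None]
                + drift[None, None, :]
                + rng.normal(0.0, cfg.noise_sd, (h, w, wl.size))
            )
            cubes.append(
                SpectralCube(
                    values=values,
                    wavelengths=wl,
                    modality=modality,
                    calibrated=True,
                    metadata={"sample_id": ids[i], "synthetic": True},
                )
            )

    band_rows = []
    for modality in ("micro", "macro"):
        wl = grids[modality]
        bands = getattr(cfg, f"sensitive_bands_{modality}")
        amp = getattr(cfg, f"effect_size_{modality}")
        for b in bands:
            gi = int(np.argmin(np.abs(wl - b)))
            band_rows.append(
                {
                    "modality": modality,
                    "wavelength_nm": b,
                    "grid_nm": wl[gi],
                    "effect_size": amp,
                }
            )
    bands_df = pd.DataFrame(band_rows)
    is_null = bool(np.all(bands_df["effect_size"] == 0.0))
    truth = Truth(
        bands=bands_df,
        cube_sod_maps=sod_maps,
        cube_sample_ids=cube_ids,
        is_null_model=is_null,
    )
    return SyntheticDataset(
        micro=sets["micro"],
        macro=sets["macro"],
        micro_cubes=micro_cubes,
        macro_cubes=macro_cubes,
        sod=sod,
        truth=truth,
        config=cfg,
    )


def truth_report(ds: SyntheticDataset) -> pd.DataFrame:
    """Planted-band table (one row per planted wavelength per modality).

    Carries an ``is_null_model`` column flagging datasets generated with all
    effect sizes zero, so recovery tests can refuse to 'recover' nothing.
    """
    df = ds.truth.bands.copy()
    df["is_null_model"] = ds.truth.is_null_model
    return df


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> Path:
    """Write spectra (CSV), cubes (ENVI), truth table (CSV) and config (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hsi_io.write_spectra(ds.micro, outdir / "micro_spectra.csv")
    hsi_io.write_spectra(ds.macro, outdir / "macro_spectra.csv")
    for i, (mc, Mc) in enumerate(zip(ds.micro_cubes, ds.macro_cubes)):
        hsi_io.write_cube(mc, outdir / f"micro_cube_{i:02d}.img")
        hsi_io.write_cube(Mc, outdir / f"macro_cube_{i:02d}.img")
    truth_report(ds).to_csv(outdir / "truth_bands.csv", index=False)
    cfg = asdict(ds.config)
    cfg["micro_grid"] = ds.config.micro_grid.tolist()
    cfg["macro_grid"] = ds.config.macro_grid.tolist()
    (outdir / "config.json").write_text(json.dumps(cfg, indent=2))
    return outdir
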