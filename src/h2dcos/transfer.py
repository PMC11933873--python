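"""Cross-scale model transfer on sensitive wavelengths, and activity maps.

The cross-scale idea: the H2D-COS analysis yields one list of sensitive
wavelengths per instrument, linked by their joint response to the SOD
perturbation.  A CNN-LSTM trained on the source instrument's sensitive bands
is reused on the target instrument's paired bands — either as-is
(``zero_shot``) or with the convolutional feature extractor frozen and the
LSTM/dense head fine-tuned on a small number of labelled target samples
(``feature_frozen_finetune``, the default; transfer exists precisely because
target labels are scarce).  ``full_finetune`` re-trains everything.

Band pairing is by wavelength rank: the i-th sorted source peak maps to the
i-th sorted target peak.  Cross-modality peak pairs need not be nearest
neighbours in nm, so rank order — not proximity — is the default rule; when
list lengths differ, greedy nearest-wavelength matching is used and
leftovers are dropped with a warning.

``predict_map`` applies a trained model pixel-wise to a calibrated cube and
returns a per-pixel SOD activity map, rendered blue (low) to red (high).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .cos import PeakList
from .datatypes import SpectralCube, SpectrumSet, nearest_band
from .nn import CNNLSTMRegressor, EvalMetrics, TrainConfig, evaluate
from .preprocess import PreprocessSpec, apply as apply_preprocess

STRATEGIES = ("feature_frozen_finetune", "full_finetune", "zero_shot")


@dataclass
class TransferPlan:
    """Ordered source->target band pairs plus the transfer strategy."""

    source_modality: str
    target_modality: str
    source_bands: np.ndarray
    target_bands: np.ndarray
    strategy: str = "feature_frozen_finetune"
    n_target_labels: int | None = None       # None = finetune_fraction of cal set
    finetune_fraction: float = 0.25

    def __post_init__(self) -> None:
        self.source_bands = np.asarray(self.source_bands, dtype=float)
        self.target_bands = np.asarray(self.target_bands, dtype=float)
        if self.source_bands.size != self.target_bands.size:
            raise ValueError("source and target band lists must have equal length")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")

    @property
    def pairing(self) -> list[tuple[float, float]]:
        return list(zip(self.source_bands.tolist(), self.target_bands.tolist()))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "source_modality": self.source_modality,
                    "target_modality": self.target_modality,
                    "source_bands": self.source_bands.tolist(),
                    "target_bands": self.target_bands.tolist(),
                    "strategy": self.strategy,
                    "n_target_labels": self.n_target_labels,
                    "finetune_fraction": self.finetune_fraction,
                },
                indent=2,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "TransferPlan":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def pair_bands(
    source_peaks: PeakList,
    target_peaks: PeakList,
    source_modality: str = "micro",
    target_modality: str = "macro",
    strategy: str = "feature_frozen_finetune",
) -> TransferPlan:
    """Pair sensitive peaks of two modalities into a transfer plan.

    Equal-length lists pair by wavelength rank.  Unequal lists fall back to
    greedy nearest-wavelength matching; unmatched peaks are dropped and
    reported in a warning.
    """
    s = np.sort(np.asarray(source_peaks.wavelengths, dtype=float))
    t = np.sort(np.asarray(target_peaks.wavelengths, dtype=float))
    if s.size == 0 or t.size == 0:
        raise ValueError("peak lists must be non-empty")
    if s.size == t.size:
        src, tgt = s, t
    else:
        # greedy nearest-nm matching over all cross pairs
        pairs = sorted(
            ((abs(a - b), i, j) for i, a in enumerate(s) for j, b in enumerate(t))
        )
        used_s: set[int] = set()
        used_t: set[int] = set()
        matched: list[tuple[float, float]] = []
        for _, i, j in pairs:
            if i in used_s or j in used_t:
                continue
            used_s.add(i)
            used_t.add(j)
            matched.append((s[i], t[j]))
        matched.sort()
        src = np.array([a for a, _ in matched])
        tgt = np.array([b for _, b in matched])
        dropped = sorted(
            [s[i] for i in range(s.size) if i not in used_s]
            + [t[j] for j in range(t.size) if j not in used_t]
        )
        warnings.warn(
            f"unequal peak lists: matched {src.size} pairs, dropped {dropped}",
            stacklevel=2,
        )
    return TransferPlan(
        source_modality=source_modality,
        target_modality=target_modality,
        source_bands=src,
        target_bands=tgt,
        strategy=strategy,
    )


def subset_to_bands(spectra: SpectrumSet, bands: np.ndarray) -> SpectrumSet:
    """Restrict a SpectrumSet to the grid bands nearest the requested nm list.

    The order of the requested bands is preserved (so paired source/target
    subsets stay column-aligned); duplicates after snapping are collapsed
    with a warning.
    """
    bands = np.asarray(bands, dtype=float)
    wl = spectra.wavelengths
    for b in bands:
        if not (wl[0] <= b <= wl[-1]):
            raise ValueError(f"band {b} nm outside grid [{wl[0]}, {wl[-1]}] nm")
    idx = [nearest_band(wl, b) for b in bands]
    uniq: list[int] = []
    for i in idx:
        if i in uniq:
            warnings.warn(
                f"bands snap to duplicate grid band {wl[i]:.2f} nm; collapsed",
                stacklevel=2,
            )
        else:
            uniq.append(i)
    sub = SpectrumSet(
        ids=spectra.ids.copy(),
        X=spectra.X[:, uniq].copy(),
        wavelengths=wl[uniq],
        perturbation=spectra.perturbation.copy(),
        modality=spectra.modality,
        meta=None if spectra.meta is None else spectra.meta.copy(),
        provenance=dict(spectra.provenance, band_subset=[float(wl[i]) for i in uniq]),
    )
    return sub


def transfer_model(
    source_model: CNNLSTMRegressor,
    plan: TransferPlan,
    target_cal: SpectrumSet,
    cfg: TrainConfig | None = None,
) -> CNNLSTMRegressor:
    """Adapt a source-modality model to the target modality's paired bands.

    ``target_cal`` must already be restricted to ``plan.target_bands`` (same
    width as the source model input).  Strategies:

    * ``zero_shot`` — copy weights and scalers, no fitting at all;
    * ``feature_frozen_finetune`` (default) — freeze conv blocks, refit input
      standardization and the LSTM/dense head on a small labelled subset of
      ``target_cal`` (``plan.n_target_labels`` samples, or
      ``finetune_fraction`` of the set);
    * ``full_finetune`` — fine-tune every parameter on the same subset.
    """
    cfg = cfg or TrainConfig()
    if target_cal.n_bands != source_model.input_bands:
        raise ValueError(
            f"plan/model width mismatch: model takes {source_model.input_bands} "
            f"bands, target set has {target_cal.n_bands}"
        )
    if plan.source_bands.size != source_model.input_bands:
        raise ValueError(
            f"plan lists {plan.source_bands.size} bands for a model with "
            f"{source_model.input_bands} inputs"
        )
    model = source_model.copy()
    if plan.strategy == "zero_shot":
        return model

    n_labels = plan.n_target_labels
    if n_labels is None:
        n_labels = max(int(round(plan.finetune_fraction * target_cal.n_samples)), 0)
    if n_labels < 2:
        raise ValueError(
            "fine-tuning needs at least 2 labelled target samples; "
            "use strategy='zero_shot' when no target labels exist"
        )
    rng = np.random.default_rng(cfg.seed)
    pick = np.sort(rng.permutation(target_cal.n_samples)[:n_labels])
    subset = target_cal.take(pick)
    trainable = None
    if plan.strategy == "feature_frozen_finetune":
        trainable = {
            k for k in model.params if not k.startswith("conv")
        }
    model.fit(subset, cfg, trainable=trainable, refit_scalers=True)
    return model


def evaluate_transfer(
    model: CNNLSTMRegressor, target_pred: SpectrumSet
) -> EvalMetrics:
    """Metrics of the transferred model on the target-modality prediction set."""
    return evaluate(model, target_pred, split="prediction/target-modality")


# ---------------------------------------------------------------------------
# pixel-wise activity maps


@dataclass
class ActivityMap:
    """Per-pixel predicted SOD activity (U/mg) for one cube."""

    values: np.ndarray
    modality: str
    colormap: str = "jet"      # blue (low) -> red (high)
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activity map contains non-finite values")


def predict_map(
    cube: SpectralCube,
    model: CNNLSTMRegressor,
    preprocess_spec: PreprocessSpec | None = None,
    bands: np.ndarray | None = None,
) -> ActivityMap:
    """Predict SOD activity for every pixel of a calibrated cube.

    Each pixel spectrum runs through the same pretreatment and band subset
    the model was trained with, then through the model.  Preprocessing is
    applied on the full grid *before* band subsetting, exactly as for the
    per-sample mean spectra.
    """
    if not cube.calibrated:
        raise ValueError("cube must be calibrated to reflectance first")
    h, w, b = cube.shape
    flat = SpectrumSet(
        ids=np.array([f"px{i}" for i in range(h * w)], dtype=object),
        X=cube.values.reshape(h * w, b),
        wavelengths=cube.wavelengths,
        perturbation=np.zeros(h * w),
        modality=cube.modality,
    )
    if preprocess_spec is not None:
        flat = apply_preprocess(flat, preprocess_spec)
    if bands is not None:
        flat = subset_to_bands(flat, np.asarray(bands, dtype=float))
    pred = model.predict(flat.X).reshape(h, w)
    return ActivityMap(
        values=pred,
        modality=cube.modality,
        provenance={
            "preprocess": "none" if preprocess_spec is None else preprocess_spec.method,
            "bands": None if bands is None else list(np.asarray(bands, dtype=float)),
        },
    )


def render_map(
    amap: ActivityMap,
    path: str | Path,
    vmin: float | None = None,
    vmax: float | None = None,
) -> Path:
    """Render an activity map to PNG with a blue-to-red colormap.

    Pass shared ``vmin``/``vmax`` to render a figure set on one value scale,
    so identical activities get identical colours across maps.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(4, 3.2))
    im = ax.imshow(amap.values, cmap=amap.colormap, vmin=vmin, vmax=vmax)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="SOD activity (U/mg)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
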