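"""End-to-end analysis workflows on a paired dataset.

These functions chain the library stages the way the full study runs them:
pretreatment comparison of CNN-LSTM models, H2D-COS sensitive-peak recovery,
cross-scale sensitive-band transfer, and pixel-wise activity mapping.  They
exist so the test suite, the acceptance script and the CLI all execute one
shared, seeded code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cos
from .cos import PeakList
from .datatypes import SpectrumSet
from .nn import (
    CNNLSTMRegressor,
    EvalMetrics,
    ModelSpec,
    TrainConfig,
    build_model,
    evaluate,
    split_dataset,
)
from .preprocess import PreprocessSpec, apply as apply_preprocess
from .synthetic import SyntheticDataset, truth_report
from .transfer import (
    TransferPlan,
    evaluate_transfer,
    predict_map,
    subset_to_bands,
    transfer_model,
)

PRETREATMENTS = ("none", "smoothing", "baseline", "fd")


def pretreatment_comparison(
    spectra: SpectrumSet,
    train_cfg: TrainConfig | None = None,
    model_seed: int = 0,
    methods: tuple[str, ...] = PRETREATMENTS,
) -> dict[str, dict[str, EvalMetrics]]:
    """Train one CNN-LSTM per pretreatment and report calibration/prediction
    metrics — the four-way raw/smoothing/baseline/FD model comparison."""
    cfg = train_cfg or TrainConfig()
    out: dict[str, dict[str, EvalMetrics]] = {}
    for method in methods:
        sp = apply_preprocess(spectra, PreprocessSpec(method=method))
        cal, pred = split_dataset(sp, cfg)
        model = build_model(ModelSpec(seed=model_seed), sp.n_bands)
        model.fit(cal, cfg)
        out[method] = {
            "calibration": evaluate(model, cal, "calibration"),
            "prediction": evaluate(model, pred, "prediction"),
        }
    return out


@dataclass
class PeakRecovery:
    """Recovered sensitive peaks per modality plus maps and slice metadata."""

    maps: cos.CorrelationMaps
    micro_peaks: PeakList
    macro_peaks: PeakList
    micro_slice_at: float
    macro_slice_at: float


def recover_sensitive_peaks(
    ds: SyntheticDataset,
    baseline_order: int = 2,
    edge_bands: int = 5,
    max_wavelength: float | None = 750.0,
    min_prominence: float = 0.05,
) -> PeakRecovery:
    """H2D-COS sensitive-peak search on baseline-corrected paired spectra.

    Both modalities are detrended (drift removal without the zero-crossing
    the derivative would put at every feature centre), the heterogeneous
    synchronous map is computed, and a slice is taken through the band of
    each axis with the largest cross-modal correlation energy; peaks of the
    two slices are the candidate sensitive wavelengths of the opposite
    modality.
    """
    spec = PreprocessSpec(method="baseline", baseline_order=baseline_order)
    micro = apply_preprocess(ds.micro, spec)
    macro = apply_preprocess(ds.macro, spec)
    maps = cos.hetero_corr(micro, macro)
    at1 = cos.best_slice_band(maps, axis=1)
    at2 = cos.best_slice_band(maps, axis=2)
    macro_slice = cos.slice_spectrum(maps, "sync", 1, at1)   # over macro axis
    micro_slice = cos.slice_spectrum(maps, "sync", 2, at2)   # over micro axis
    kw = dict(
        edge_bands=edge_bands,
        max_wavelength=max_wavelength,
        min_prominence=min_prominence,
    )
    return PeakRecovery(
        maps=maps,
        micro_peaks=cos.find_sensitive_peaks(micro_slice, **kw),
        macro_peaks=cos.find_sensitive_peaks(macro_slice, **kw),
        micro_slice_at=at1,
        macro_slice_at=at2,
    )


def recovery_counts(ds: SyntheticDataset, rec: PeakRecovery) -> dict[str, int]:
    """How many planted bands each recovered peak list hits within one band."""
    truth = truth_report(ds)
    out = {}
    for modality, peaks, grid in (
        ("micro", rec.micro_peaks, ds.micro.wavelengths),
        ("macro", rec.macro_peaks, ds.macro.wavelengths),
    ):
        step = float(np.max(np.diff(grid)))
        planted = truth.loc[truth.modality == modality, "grid_nm"].to_numpy()
        hits = sum(
            bool(peaks.wavelengths.size)
            and np.min(np.abs(peaks.wavelengths - g)) <= step + 1e-9
            for g in planted
        )
        out[f"{modality}_planted"] = int(planted.size)
        out[f"{modality}_recovered"] = int(hits)
        out[f"{modality}_found"] = int(len(peaks))
    return out


def top_k_peaks(peaks: PeakList, k: int) -> PeakList:
    """The k most intense peaks, re-sorted by wavelength."""
    if len(peaks) <= k:
        return peaks
    idx = np.argsort(-peaks.intensities, kind="stable")[:k]
    idx = idx[np.argsort(peaks.wavelengths[idx])]
    return PeakList(
        wavelengths=peaks.wavelengths[idx],
        intensities=peaks.intensities[idx],
        source_slice=peaks.source_slice,
        exclusions_applied=dict(peaks.exclusions_applied),
    )


@dataclass
class TransferResult:
    plan: TransferPlan
    source_metrics: EvalMetrics     # source model on source prediction set
    target_metrics: EvalMetrics     # transferred model on target prediction set
    target_only_metrics: EvalMetrics  # model trained on target cal alone
    source_model: CNNLSTMRegressor
    transferred_model: CNNLSTMRegressor


def cross_scale_transfer(
    ds: SyntheticDataset,
    source_bands: np.ndarray,
    target_bands: np.ndarray,
    train_cfg: TrainConfig | None = None,
    strategy: str = "feature_frozen_finetune",
    model_seed: int = 0,
) -> TransferResult:
    """Micro-to-macro sensitive-band transfer with a target-only reference.

    Both modalities are baseline-corrected (single-band reflectance keeps its
    SOD-proportional dip depth under detrending, unlike under the derivative,
    which is zero at every feature centre), restricted to the paired bands,
    and split identically.  The source model trains on the source calibration
    set; transfer copies it and fine-tunes per ``strategy`` on a small
    labelled subset of the target calibration set; a target-only model
    trained on the full target calibration set provides the comparison.
    """
    cfg = train_cfg or TrainConfig()
    plan = TransferPlan(
        source_modality=ds.micro.modality,
        target_modality=ds.macro.modality,
        source_bands=np.sort(np.asarray(source_bands, dtype=float)),
        target_bands=np.sort(np.asarray(target_bands, dtype=float)),
        strategy=strategy,
    )
    spec = PreprocessSpec(method="baseline")
    src = subset_to_bands(apply_preprocess(ds.micro, spec), plan.source_bands)
    tgt = subset_to_bands(apply_preprocess(ds.macro, spec), plan.target_bands)
    src_cal, src_pred = split_dataset(src, cfg)
    tgt_cal, tgt_pred = split_dataset(tgt, cfg)

    source_model = build_model(ModelSpec(seed=model_seed), src.n_bands)
    source_model.fit(src_cal, cfg)
    transferred = transfer_model(source_model, plan, tgt_cal, cfg)
    target_only = build_model(ModelSpec(seed=model_seed), tgt.n_bands)
    target_only.fit(tgt_cal, cfg)
    return TransferResult(
        plan=plan,
        source_metrics=evaluate(source_model, src_pred, "prediction/source"),
        target_metrics=evaluate_transfer(transferred, tgt_pred),
        target_only_metrics=evaluate(target_only, tgt_pred, "prediction/target-only"),
        source_model=source_model,
        transferred_model=transferred,
    )


def permutation_null_r(
    model: CNNLSTMRegressor,
    spectra: SpectrumSet,
    n_shuffles: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """|Pearson R| of model predictions against label permutations."""
    rng = np.random.default_rng(seed)
    pred = model.predict(spectra.X)
    return np.array(
        [
            abs(np.corrcoef(pred, rng.permutation(spectra.perturbation))[0, 1])
            for _ in range(n_shuffles)
        ]
    )


def map_gradient_correlation(
    ds: SyntheticDataset,
    model: CNNLSTMRegressor,
    preprocess_spec: PreprocessSpec,
    cube_index: int = 0,
    bands: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Pixel-wise activity map of one micro cube vs the planted SOD field."""
    amap = predict_map(ds.micro_cubes[cube_index], model, preprocess_spec, bands)
    planted = ds.truth.cube_sod_maps[cube_index]
    r = float(np.corrcoef(amap.values.ravel(), planted.ravel())[0, 1])
    return r, amap.values
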