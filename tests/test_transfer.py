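import numpy as np
import pytest

from h2dcos.cos import PeakList
from h2dcos.nn import ModelSpec, TrainConfig, build_model, evaluate, split_dataset
from h2dcos.pipeline import cross_scale_transfer, permutation_null_r
from h2dcos.preprocess import PreprocessSpec, apply as apply_preprocess
from h2dcos.synthetic import (
    GeneratorConfig,
    MACRO_SENSITIVE_NM,
    MICRO_SENSITIVE_NM,
    generate_dataset,
    truth_report,
)
from h2dcos.transfer import (
    TransferPlan,
    pair_bands,
    predict_map,
    subset_to_bands,
    transfer_model,
)


def peaks(wavelengths):
    wl = np.asarray(wavelengths, dtype=float)
    return PeakList(
        wavelengths=wl, intensities=np.ones_like(wl), source_slice=500.0
    )


class TestPairBands:
    def test_default_ten_peak_lists_pair_rank_order(self):
        plan = pair_bands(peaks(MICRO_SENSITIVE_NM), peaks(MACRO_SENSITIVE_NM))
        assert len(plan.pairing) == 10
        # rank pairing: extremes map to extremes even though 948 nm has no
        # nearest-neighbour partner on the micro side
        assert plan.pairing[0] == (426.0, 497.0)
        assert plan.pairing[-1] == (682.0, 948.0)

    def test_identical_lists_pair_identically(self):
        plan = pair_bands(peaks([500.0, 600.0]), peaks([500.0, 600.0]))
        assert plan.pairing == [(500.0, 500.0), (600.0, 600.0)]

    def test_unequal_lists_greedy_matching_drops_leftovers(self):
        with pytest.warns(UserWarning, match="dropped"):
            plan = pair_bands(
                peaks([500.0, 600.0, 700.0]),
                peaks([490.0, 505.0, 610.0, 705.0, 900.0]),
            )
        assert plan.pairing == [(500.0, 505.0), (600.0, 610.0), (700.0, 705.0)]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            pair_bands(peaks([]), peaks([500.0]))


class TestSubset:
    def test_full_grid_unchanged(self, spectrum_set):
        out = subset_to_bands(spectrum_set, spectrum_set.wavelengths)
        assert np.array_equal(out.X, spectrum_set.X)

    def test_requested_bands_snap_to_grid(self, spectrum_set):
        out = subset_to_bands(spectrum_set, np.array([509.0, 531.9]))
        assert out.n_bands == 2
        assert list(out.wavelengths) == [508.0, 532.0]

    def test_out_of_range_rejected_and_duplicates_collapsed(self, spectrum_set):
        with pytest.raises(ValueError, match="outside grid"):
            subset_to_bands(spectrum_set, np.array([300.0]))
        with pytest.warns(UserWarning, match="duplicate"):
            out = subset_to_bands(spectrum_set, np.array([508.0, 508.4]))
        assert out.n_bands == 1


@pytest.fixture(scope="module")
def paired_setup():
    """Small paired dataset with a trained 10-band source model."""
    ds = generate_dataset(GeneratorConfig(n_plants_per_cell=5, n_cubes=1,
                                          cube_shape=(10, 10), seed=9))
    truth = truth_report(ds)
    src_bands = np.sort(truth.loc[truth.modality == "micro", "grid_nm"].to_numpy())
    tgt_bands = np.sort(truth.loc[truth.modality == "macro", "grid_nm"].to_numpy())
    cfg = TrainConfig(epochs=150, seed=0)
    result = cross_scale_transfer(ds, src_bands, tgt_bands, cfg)
    return ds, result, cfg


class TestTransferModel:
    def test_zero_shot_self_transfer_is_identity(self, paired_setup):
        ds, result, cfg = paired_setup
        plan = TransferPlan(
            "micro", "micro", result.plan.source_bands, result.plan.source_bands,
            strategy="zero_shot",
        )
        src = subset_to_bands(
            apply_preprocess(ds.micro, PreprocessSpec(method="baseline")),
            plan.source_bands,
        )
        clone = transfer_model(result.source_model, plan, src, cfg)
        assert np.array_equal(
            clone.predict(src.X), result.source_model.predict(src.X)
        )

    def test_finetune_without_labels_rejected(self, paired_setup):
        ds, result, cfg = paired_setup
        plan = TransferPlan(
            "micro", "macro", result.plan.source_bands, result.plan.target_bands,
            n_target_labels=0,
        )
        tgt = subset_to_bands(
            apply_preprocess(ds.macro, PreprocessSpec(method="baseline")),
            plan.target_bands,
        )
        with pytest.raises(ValueError, match="zero_shot"):
            transfer_model(result.source_model, plan, tgt, cfg)

    def test_width_mismatch_rejected(self, paired_setup):
        ds, result, cfg = paired_setup
        plan = result.plan
        bad = subset_to_bands(ds.macro, plan.target_bands[:4])
        with pytest.raises(ValueError, match="width"):
            transfer_model(result.source_model, plan, bad, cfg)

    def test_transfer_recovers_target_signal(self, paired_setup):
        _, result, _ = paired_setup
        assert result.target_metrics.r >= 0.70
        # and the side-by-side target-only reference is also reported
        assert result.target_only_metrics.n == result.target_metrics.n

    def test_shuffled_labels_give_null_correlation(self, paired_setup):
        ds, result, cfg = paired_setup
        tgt = subset_to_bands(
            apply_preprocess(ds.macro, PreprocessSpec(method="baseline")),
            result.plan.target_bands,
        )
        _, tgt_pred = split_dataset(tgt, cfg)
        nulls = permutation_null_r(result.transferred_model, tgt_pred, 200, seed=0)
        assert np.quantile(nulls, 0.95) < 0.5
        assert result.target_metrics.r > np.quantile(nulls, 0.95)


def test_transfer_r_monotone_in_cross_modal_effect_size():
    """More strongly planted spectral effects give better transfer."""
    rs = []
    for effect in (-0.05, -0.15, -0.35):
        ds = generate_dataset(
            GeneratorConfig(
                n_plants_per_cell=5, n_cubes=0, seed=9,
                effect_size_micro=effect, effect_size_macro=effect,
            )
        )
        truth = truth_report(ds)
        src = np.sort(truth.loc[truth.modality == "micro", "grid_nm"].to_numpy())
        tgt = np.sort(truth.loc[truth.modality == "macro", "grid_nm"].to_numpy())
        res = cross_scale_transfer(ds, src, tgt, TrainConfig(epochs=150, seed=0))
        rs.append(res.target_metrics.r)
    assert rs[0] <= rs[1] + 0.05 and rs[1] <= rs[2] + 0.05


class TestPredictMap:
    def test_uniform_cube_gives_uniform_map(self, paired_setup):
        ds, result, _ = paired_setup
        from h2dcos.datatypes import SpectralCube

        spectrum = ds.micro.X[0]
        cube = SpectralCube(
            values=np.tile(spectrum, (6, 6, 1)),
            wavelengths=ds.micro.wavelengths,
            modality="micro",
            calibrated=True,
        )
        amap = predict_map(
            cube, result.source_model, PreprocessSpec(method="baseline"),
            result.plan.source_bands,
        )
        expected = result.source_model.predict(
            subset_to_bands(
                apply_preprocess(
                    ds.micro.take(np.array([0])), PreprocessSpec(method="baseline")
                ),
                result.plan.source_bands,
            ).X
        )[0]
        assert np.allclose(amap.values, expected, atol=1e-10)

    def test_uncalibrated_cube_rejected(self, paired_setup):
        ds, result, _ = paired_setup
        from h2dcos.datatypes import SpectralCube

        raw = SpectralCube(
            values=np.ones((4, 4, ds.micro.n_bands)),
            wavelengths=ds.micro.wavelengths,
            modality="micro",
            calibrated=False,
        )
        with pytest.raises(ValueError, match="calibrated"):
            predict_map(raw, result.source_model)

    def test_map_mean_matches_mean_spectrum_prediction(self, paired_setup):
        ds, result, _ = paired_setup
        cube = ds.micro_cubes[0]
        amap = predict_map(
            cube, result.source_model, PreprocessSpec(method="baseline"),
            result.plan.source_bands,
        )
        from h2dcos.datatypes import SpectrumSet

        mean_set = SpectrumSet(
            ids=np.array(["mean"], dtype=object),
            X=cube.values.mean(axis=(0, 1))[None, :],
            wavelengths=cube.wavelengths,
            perturbation=np.zeros(1),
            modality="micro",
        )
        mean_pred = result.source_model.predict(
            subset_to_bands(
                apply_preprocess(mean_set, PreprocessSpec(method="baseline")),
                result.plan.source_bands,
            ).X
        )[0]
        assert abs(amap.values.mean() - mean_pred) < 0.02
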