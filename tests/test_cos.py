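import numpy as np
import pytest

from h2dcos.cos import (
    CorrelationMaps,
    SliceSpectrum,
    async_map,
    best_slice_band,
    correlate,
    find_sensitive_peaks,
    hetero_corr,
    hilbert_noda,
    load_maps,
    make_dynamic,
    save_maps,
    slice_spectrum,
    sync_map,
)
from h2dcos.datatypes import AlignmentError, SpectrumSet


def make_set(X, wl=None, perturbation=None, ids=None, modality="micro"):
    X = np.asarray(X, dtype=float)
    n, b = X.shape
    if wl is None:
        wl = 400.0 + 2.0 * np.arange(b)
    return SpectrumSet(
        ids=np.array(ids if ids is not None else [f"s{i}" for i in range(n)], dtype=object),
        X=X,
        wavelengths=np.asarray(wl, dtype=float),
        perturbation=np.asarray(
            perturbation if perturbation is not None else np.arange(n), dtype=float
        ),
        modality=modality,
    )


def brute_force_maps(Y1, Y2):
    """Direct double-loop summation of the defining sums (test oracle)."""
    n, b1 = Y1.shape
    b2 = Y2.shape[1]
    M = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            if j != k:
                M[j, k] = 1.0 / (np.pi * (k - j))
    phi = np.zeros((b1, b2))
    psi = np.zeros((b1, b2))
    for a in range(b1):
        for c in range(b2):
            s_sync = 0.0
            s_async = 0.0
            for j in range(n):
                s_sync += Y1[j, a] * Y2[j, c]
                inner = 0.0
                for k in range(n):
                    inner += M[j, k] * Y2[k, c]
                s_async += Y1[j, a] * inner
            phi[a, c] = s_sync / (n - 1)
            psi[a, c] = s_async / (n - 1)
    return phi, psi


class TestMakeDynamic:
    def test_identical_rows_centre_to_zero(self):
        d = make_dynamic(make_set(np.tile([1.0, 2.0, 3.0], (4, 1))))
        assert np.allclose(d.Y, 0.0)

    def test_hand_centring_three_samples(self):
        d = make_dynamic(make_set(np.array([[1.0], [2.0], [6.0]])))
        assert np.allclose(d.Y[:, 0], [-2.0, -1.0, 3.0])
        assert d.reference[0] == pytest.approx(3.0)

    def test_shuffled_input_sorted_by_perturbation(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 4))
        p = np.array([0.3, 0.1, 0.6, 0.2, 0.5, 0.4])
        base = make_dynamic(make_set(X, perturbation=p))
        perm = rng.permutation(6)
        shuffled = make_dynamic(
            make_set(X[perm], perturbation=p[perm],
                     ids=[f"s{i}" for i in perm])
        )
        assert np.allclose(base.Y, shuffled.Y)
        assert np.all(np.diff(base.perturbation) > 0)

    def test_printed_reference_variant_is_not_the_mean(self):
        X = np.array([[1.0], [2.0], [3.0]])
        d = make_dynamic(make_set(X), reference="printed")
        assert d.reference[0] == pytest.approx(6.0 / 2.0)

    def test_needs_three_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            make_dynamic(make_set(np.ones((2, 3))))


class TestHilbertNoda:
    def test_structure(self):
        M = hilbert_noda(6)
        assert np.allclose(np.diag(M), 0.0)
        assert np.allclose(M + M.T, 0.0)
        assert hilbert_noda(3)[0, 2] == pytest.approx(1.0 / (2.0 * np.pi))
        with pytest.raises(ValueError):
            hilbert_noda(1)


class TestMaps:
    def test_matrix_form_matches_double_loop_oracle(self):
        rng = np.random.default_rng(10)
        s1 = make_set(rng.normal(size=(8, 12)))
        s2 = make_set(rng.normal(size=(8, 12)))
        d1, d2 = make_dynamic(s1), make_dynamic(s2)
        phi, psi = brute_force_maps(d1.Y, d2.Y)
        assert np.allclose(sync_map(d1, d2), phi, atol=1e-10)
        assert np.allclose(async_map(d1, d2), psi, atol=1e-10)

    def test_homo_sync_diagonal_is_band_variance(self, spectrum_set):
        d = make_dynamic(spectrum_set)
        phi = sync_map(d, d)
        assert np.allclose(phi, phi.T)
        assert np.allclose(np.diag(phi), spectrum_set.X.var(axis=0, ddof=1))
        assert np.all(np.diag(phi) >= 0)

    def test_proportional_bands_scale_sync(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=5)
        c = 2.5
        d = make_dynamic(make_set(np.column_stack([y, c * y])))
        phi = sync_map(d, d)
        assert phi[0, 1] == pytest.approx(c * phi[0, 0], rel=1e-12)

    def test_in_phase_signals_have_zero_async(self):
        rng = np.random.default_rng(12)
        y = rng.normal(size=7)
        scales = np.array([1.0, -0.5, 2.0])
        d = make_dynamic(make_set(np.outer(y, scales)))
        assert np.allclose(async_map(d, d), 0.0, atol=1e-12)

    def test_homo_async_antisymmetric_zero_diagonal(self, spectrum_set):
        d = make_dynamic(spectrum_set)
        psi = async_map(d, d)
        assert np.allclose(psi + psi.T, 0.0, atol=1e-12)
        assert np.allclose(np.diag(psi), 0.0, atol=1e-12)

    def test_quarter_period_lag_sign_pattern(self):
        """Sequential-order rule: the band that varies first gets Psi > 0."""
        n = 32
        t = np.arange(n) / n * 2.0 * np.pi
        X = np.column_stack([np.sin(t), np.sin(t - np.pi / 2)])  # band 1 leads
        d = make_dynamic(make_set(X), sort_by="given_order")
        phi_bf, psi_bf = brute_force_maps(d.Y, d.Y)
        psi = async_map(d, d)
        assert np.allclose(psi, psi_bf, atol=1e-10)
        assert psi[0, 1] == pytest.approx(0.4338833709, abs=1e-6)
        assert psi[0, 1] > 0 > psi[1, 0]
        # quarter lag makes the synchronous cross-peak vanish
        assert abs(sync_map(d, d)[0, 1]) < 1e-12

    def test_bilinearity_under_scaling(self, spectrum_set):
        d1 = make_dynamic(spectrum_set)
        scaled = make_dynamic(spectrum_set.with_X(3.0 * spectrum_set.X))
        assert np.allclose(sync_map(scaled, d1), 3.0 * sync_map(d1, d1))
        assert np.allclose(async_map(scaled, d1), 3.0 * async_map(d1, d1))


class TestHetero:
    def test_micro_copy_reduces_to_homo(self, spectrum_set):
        maps = correlate(spectrum_set, spectrum_set.with_X(spectrum_set.X.copy()))
        assert not maps.hetero
        assert np.allclose(maps.sync, maps.sync.T)

    def test_direction_transposes(self, small_dataset):
        fwd = hetero_corr(small_dataset.micro, small_dataset.macro)
        rev = hetero_corr(small_dataset.macro, small_dataset.micro)
        assert fwd.hetero
        assert np.allclose(fwd.sync, rev.sync.T, atol=1e-12)
        # M' = -M, so the asynchronous map transposes with a sign flip
        assert np.allclose(fwd.async_, -rev.async_.T, atol=1e-12)

    def test_shared_planted_band_is_global_sync_maximum(self, small_config):
        """In the noiseless limit the only cross-modal variation is the
        planted SOD effect, so the |sync| maximum sits at the planted pair."""
        import dataclasses

        from h2dcos.preprocess import PreprocessSpec, apply
        from h2dcos.synthetic import generate_dataset, truth_report

        clean = generate_dataset(
            dataclasses.replace(small_config, noise_sd=0.0, n_cubes=0)
        )
        spec = PreprocessSpec(method="baseline")
        maps = hetero_corr(apply(clean.micro, spec), apply(clean.macro, spec))
        i, j = np.unravel_index(np.argmax(np.abs(maps.sync)), maps.sync.shape)
        truth = truth_report(clean)
        planted_micro = truth.loc[truth.modality == "micro", "grid_nm"].iloc[0]
        planted_macro = truth.loc[truth.modality == "macro", "grid_nm"].iloc[0]
        assert abs(maps.wl1[i] - planted_micro) <= 8.0 + 1e-9
        assert abs(maps.wl2[j] - planted_macro) <= 9.4 + 1e-9

    def test_permuted_order_raises_alignment_error(self, spectrum_set):
        perm = np.arange(spectrum_set.n_samples)[::-1]
        other = spectrum_set.take(perm)
        with pytest.raises(AlignmentError, match="order"):
            correlate(spectrum_set, other)

    def test_unpaired_samples_listed(self, spectrum_set):
        other = spectrum_set.take(np.arange(spectrum_set.n_samples))
        other.ids[-1] = "stranger"
        with pytest.raises(AlignmentError, match="stranger"):
            correlate(spectrum_set, other)


class TestSlices:
    def test_homo_sync_slice_row_equals_column(self, spectrum_set):
        maps = correlate(spectrum_set, spectrum_set.with_X(spectrum_set.X.copy()))
        row = slice_spectrum(maps, "sync", 1, 510.0)
        col = slice_spectrum(maps, "sync", 2, 510.0)
        assert np.allclose(row.values, col.values)

    def test_boundary_request_snaps_with_warning(self, spectrum_set):
        maps = correlate(spectrum_set, spectrum_set.with_X(spectrum_set.X.copy()))
        with pytest.warns(UserWarning, match="boundary"):
            slc = slice_spectrum(maps, "sync", 1, spectrum_set.wavelengths[0] + 0.1)
        assert slc.source_nm == spectrum_set.wavelengths[0]
        with pytest.raises(ValueError, match="outside"):
            slice_spectrum(maps, "sync", 1, 9999.0)


class TestFindPeaks:
    @staticmethod
    def make_slice(values, wl):
        return SliceSpectrum(
            values=np.asarray(values, dtype=float),
            wavelengths=np.asarray(wl, dtype=float),
            source_nm=500.0,
            which="sync",
            axis=1,
        )

    def test_flat_slice_has_no_peaks(self):
        wl = np.linspace(400, 1000, 100)
        assert len(find_sensitive_peaks(self.make_slice(np.zeros(100), wl))) == 0

    def test_planted_bumps_recovered_within_one_band(self):
        wl = np.arange(400.0, 1000.0, 2.0)
        centres = [426.0, 458.0, 481.0, 510.0, 527.0, 547.0, 607.0, 631.0, 641.0, 682.0]
        values = sum(np.exp(-0.5 * ((wl - c) / 4.0) ** 2) for c in centres)
        peaks = find_sensitive_peaks(self.make_slice(values, wl))
        assert len(peaks) == len(centres)
        for c in centres:
            assert np.min(np.abs(peaks.wavelengths - c)) <= 2.0 + 1e-9

    def test_edge_peaks_excluded(self):
        wl = np.arange(400.0, 500.0, 2.0)
        values = np.exp(-0.5 * ((wl - wl[2]) / 2.0) ** 2)  # 2 bands from the edge
        peaks = find_sensitive_peaks(self.make_slice(values, wl), edge_bands=5)
        assert len(peaks) == 0

    def test_cutoff_drops_weak_but_keeps_prominent_high_wavelength_peak(self):
        wl = np.arange(400.0, 1000.0, 2.0)
        values = (
            1.0 * np.exp(-0.5 * ((wl - 500.0) / 4.0) ** 2)
            + 0.2 * np.exp(-0.5 * ((wl - 800.0) / 4.0) ** 2)  # weak, above cutoff
            + 0.9 * np.exp(-0.5 * ((wl - 948.0) / 4.0) ** 2)  # strong, kept
        )
        peaks = find_sensitive_peaks(self.make_slice(values, wl), max_wavelength=750.0)
        kept = set(np.round(peaks.wavelengths))
        assert 500.0 in kept and 948.0 in kept and 800.0 not in kept
        # with the cutoff disabled the weak 800 nm peak comes back
        no_cut = find_sensitive_peaks(self.make_slice(values, wl), max_wavelength=None)
        assert 800.0 in set(np.round(no_cut.wavelengths))

    def test_too_short_slice_rejected(self):
        wl = np.arange(400.0, 420.0, 2.0)
        with pytest.raises(ValueError, match="too short"):
            find_sensitive_peaks(self.make_slice(np.ones(10), wl), edge_bands=5)


def test_best_slice_band_targets_strong_band(small_config):
    import dataclasses

    from h2dcos.preprocess import PreprocessSpec, apply
    from h2dcos.synthetic import generate_dataset, truth_report

    clean = generate_dataset(
        dataclasses.replace(small_config, noise_sd=0.0, n_cubes=0)
    )
    spec = PreprocessSpec(method="baseline")
    maps = hetero_corr(apply(clean.micro, spec), apply(clean.macro, spec))
    truth = truth_report(clean)
    planted = truth.loc[truth.modality == "micro", "grid_nm"].iloc[0]
    assert abs(best_slice_band(maps, axis=1) - planted) <= 8.0 + 1e-9


def test_maps_round_trip_hdf5(tmp_path, small_dataset):
    maps = hetero_corr(small_dataset.micro, small_dataset.macro)
    path = save_maps(maps, tmp_path / "maps.h5")
    back = load_maps(path)
    assert np.array_equal(back.sync, maps.sync)
    assert np.array_equal(back.async_, maps.async_)
    assert back.hetero and back.n == maps.n
    assert back.provenance["modality_1"] == "micro"
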