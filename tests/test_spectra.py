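"""Data model, I/O round-trips, notch masking and reference normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import libsclass as L
from libsclass.errors import (
    DimensionError,
    NormalizationError,
    SpectraFormatError,
)


def tiny_set(n=3, channels=5):
    wl = np.linspace(400.0, 800.0, channels)
    rng = np.random.default_rng(0)
    X = rng.uniform(1.0, 5.0, (n, channels))
    return L.SpectraSet(wl, X, [f"c{i % 2}" for i in range(n)])


class TestDataModel:
    def test_wavelengths_must_increase(self):
        with pytest.raises(DimensionError):
            L.Spectrum(np.array([1.0, 1.0, 2.0]), np.zeros(3))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            L.SpectraSet(np.arange(4.0), np.zeros((2, 3)), ["a", "b"])

    def test_nonfinite_on_valid_channel_rejected(self):
        X = np.ones((2, 3))
        X[0, 1] = np.nan
        with pytest.raises(DimensionError):
            L.SpectraSet(np.arange(3.0), X, ["a", "b"])

    def test_nonfinite_on_masked_channel_allowed(self):
        X = np.ones((2, 3))
        X[0, 1] = np.nan
        mask = np.array([True, False, True])
        s = L.SpectraSet(np.arange(3.0), X, ["a", "b"], mask)
        assert s.valid_matrix().shape == (2, 2)

    def test_class_order_is_first_appearance(self):
        s = L.SpectraSet(
            np.arange(3.0), np.ones((4, 3)), ["b", "a", "b", "c"]
        )
        assert s.classes == ["b", "a", "c"]


class TestIO:
    @pytest.mark.parametrize("fmt", ["csv", "xlsx"])
    def test_round_trip(self, tmp_path, fmt):
        s = tiny_set(10, 100)
        path = tmp_path / f"spectra.{fmt}"
        L.write_spectra(s, path)
        back = L.read_spectra(path)
        assert back.labels == s.labels
        np.testing.assert_allclose(back.wavelengths, s.wavelengths, atol=1e-9)
        np.testing.assert_allclose(back.intensities, s.intensities, rtol=1e-12)
        np.testing.assert_array_equal(back.valid_mask, s.valid_mask)

    def test_mask_round_trips(self, tmp_path):
        s = L.apply_notch_mask(
            L.SpectraSet(np.linspace(400, 900, 50), np.ones((3, 50)), ["a"] * 3),
            L.PreprocessConfig(),
        )
        path = tmp_path / "masked.csv"
        L.write_spectra(s, path)
        back = L.read_spectra(path)
        np.testing.assert_array_equal(back.valid_mask, s.valid_mask)

    def test_simple_csv_shape(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "400,500,600,700,800,class\n"
            "1,2,3,4,5,a\n1,2,3,4,5,b\n1,2,3,4,5,a\n"
        )
        s = L.read_spectra(path)
        assert s.n_spectra == 3 and s.n_channels == 5
        assert s.labels == ["a", "b", "a"]

    def test_columns_sorted_ascending(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("600,400,class\n2,1,a\n")
        s = L.read_spectra(path)
        np.testing.assert_array_equal(s.wavelengths, [400.0, 600.0])
        np.testing.assert_array_equal(s.intensities[0], [1.0, 2.0])

    def test_bad_header_names_column(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("400,banana,class\n1,2,a\n")
        with pytest.raises(SpectraFormatError, match="banana"):
            L.read_spectra(path)

    def test_duplicate_wavelengths_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("400,400,class\n1,2,a\n")
        with pytest.raises(SpectraFormatError):
            L.read_spectra(path)

    def test_ragged_rows_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("400,500,class\n1,2,a\n1,,b\n")
        with pytest.raises(DimensionError):
            L.read_spectra(path)

    def test_column_orientation(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("wavelength,a,b\n400,1,4\n500,2,5\n600,3,6\n")
        s = L.read_spectra(path, orientation="columns")
        assert s.labels == ["a", "b"]
        np.testing.assert_array_equal(s.intensities, [[1, 2, 3], [4, 5, 6]])

    def test_report_json(self, tmp_path):
        path = tmp_path / "r.json"
        L.write_report({"rates": [1.0, 0.0, 0.0]}, path)
        assert "1.0" in path.read_text()


class TestNotchMask:
    def test_mask_interval_count(self):
        wl = np.arange(400.0, 901.0)
        s = L.SpectraSet(wl, np.ones((2, wl.size)), ["a", "b"])
        masked = L.apply_notch_mask(s, L.PreprocessConfig())
        assert (~masked.valid_mask).sum() == 31
        assert not masked.valid_mask[(wl >= 517) & (wl <= 547)].any()

    def test_disjoint_grid_is_noop(self):
        wl = np.arange(600.0, 901.0)
        s = L.SpectraSet(wl, np.ones((1, wl.size)), ["a"])
        masked = L.apply_notch_mask(s, L.PreprocessConfig())
        assert masked.valid_mask.all()

    def test_idempotent(self):
        s = tiny_set(2, 200)
        once = L.apply_notch_mask(s)
        twice = L.apply_notch_mask(once)
        np.testing.assert_array_equal(once.valid_mask, twice.valid_mask)

    def test_reference_inside_notch_rejected(self):
        with pytest.raises(ValueError):
            L.PreprocessConfig(notch_center=656.0, reference_line=656.3)


class TestNormalization:
    def test_window_max_becomes_one(self):
        wl = np.linspace(650.0, 660.0, 11)
        X = np.full((1, 11), 0.5)
        X[0, wl.searchsorted(656.0)] = 2.0
        s = L.SpectraSet(wl, X, ["a"])
        out = L.normalize_to_reference_line(s)
        assert out.intensities.max() == pytest.approx(1.0)
        np.testing.assert_allclose(out.intensities[0][X[0] == 0.5], 0.25)

    def test_idempotent(self, default_dataset):
        again = L.normalize_to_reference_line(default_dataset)
        np.testing.assert_array_equal(again.intensities, default_dataset.intensities)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariant(self, c):
        s = tiny_set(3, 300)
        wl = np.linspace(400.0, 800.0, 300)
        s = L.SpectraSet(wl, s.intensities, s.labels)
        a = L.normalize_to_reference_line(s)
        b = L.normalize_to_reference_line(s.with_intensities(s.intensities * c))
        np.testing.assert_allclose(a.intensities, b.intensities, rtol=1e-12)

    def test_synthetic_h_peak_is_one(self, registry, grid800, quiet_noise):
        sp = L.simulate_spectrum(
            registry["Cetirizine dihydrochloride"], grid800, quiet_noise
        )
        s = L.SpectraSet(grid800, sp.intensities[None, :], ["a"])
        out = L.normalize_to_reference_line(s)
        window = np.abs(grid800 - 656.3) <= 2.0
        assert out.intensities[0][window].max() == pytest.approx(1.0)

    def test_zero_reference_raises_with_row(self):
        wl = np.linspace(650.0, 660.0, 11)
        X = np.vstack([np.ones(11), np.zeros(11)])
        s = L.SpectraSet(wl, X, ["a", "b"])
        with pytest.raises(NormalizationError) as err:
            L.normalize_to_reference_line(s)
        assert 1 in err.value.rows

    def test_fully_masked_window_raises(self):
        wl = np.linspace(650.0, 660.0, 11)
        s = L.SpectraSet(wl, np.ones((1, 11)), ["a"], np.zeros(11, bool) | (wl > 659))
        with pytest.raises(NormalizationError):
            L.normalize_to_reference_line(s)


def test_masked_channels_never_influence_results(default_dataset):
    """Replacing masked intensities with garbage leaves every stage bit-identical."""
    ds = default_dataset
    vandal = ds.intensities.copy()
    vandal[:, ~ds.valid_mask] = 1e9
    ds2 = L.SpectraSet(ds.wavelengths, vandal, list(ds.labels), ds.valid_mask)

    pca_a, pca_b = L.fit_pca(ds, 3), L.fit_pca(ds2, 3)
    np.testing.assert_array_equal(pca_a.loadings, pca_b.loadings)
    np.testing.assert_array_equal(L.project(pca_a, ds), L.project(pca_b, ds2))

    sm_a, sm_b = L.fit_simca(ds), L.fit_simca(ds2)
    for a, b in zip(sm_a.submodels, sm_b.submodels):
        assert a.threshold == b.threshold

    tree_a = L.hierarchical_cluster(ds)
    tree_b = L.hierarchical_cluster(ds2)
    np.testing.assert_array_equal(tree_a.merges, tree_b.merges)
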