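"""Forward simulator: registry structure, determinism, noise calibration."""

import numpy as np
import pytest

import libsclass as L


class TestRegistry:
    def test_four_classes_two_with_fluorine(self, registry):
        assert len(registry) == 4
        with_f = [
            name
            for name, p in registry.items()
            if any(line.element == "F" for line in p.lines)
        ]
        assert sorted(with_f) == ["Cipro pure", "Ciprofloxacin hydrochloride"]

    def test_every_profile_has_hydrogen_line(self, registry):
        for p in registry.values():
            assert p.line_amplitude(656.3) > 0

    def test_hard_pair_within_ten_percent(self, registry):
        a, b = (registry[name] for name in L.HARD_PAIR)
        rel = []
        for line in a.lines:
            amp_b = b.line_amplitude(line.center)
            rel.append(abs(line.amplitude - amp_b) / max(line.amplitude, amp_b))
        assert max(rel) <= 0.10
        ca, cb = a.continuum, b.continuum
        assert abs(ca.amplitude - cb.amplitude) / max(ca.amplitude, cb.amplitude) <= 0.10
        assert (ca.center, ca.width, ca.offset) == (cb.center, cb.width, cb.offset)


class TestContinuumCurve:
    def test_zero_amplitude_is_constant_offset(self):
        grid = np.linspace(350, 900, 100)
        c = L.continuum_curve(L.ContinuumSpec(0.0, 500.0, 100.0, 0.7), grid)
        np.testing.assert_allclose(c, 0.7)

    def test_value_at_center(self):
        c = L.continuum_curve(L.ContinuumSpec(2.0, 500.0, 100.0, 0.5), np.array([500.0]))
        assert c[0] == pytest.approx(2.5)

    def test_symmetric_about_center(self):
        grid = np.linspace(400.0, 600.0, 201)
        c = L.continuum_curve(L.ContinuumSpec(1.0, 500.0, 50.0, 0.0), grid)
        np.testing.assert_allclose(c, c[::-1], rtol=1e-12)


class TestSimulateSpectrum:
    def test_single_line_no_noise(self, quiet_noise):
        grid = np.linspace(606.3, 706.3, 501)  # contains 656.3 exactly
        prof = L.FormulationProfile(
            "x", (L.LineSpec(656.3, 5.0, 1.0, "H"),), L.ContinuumSpec(0, 500, 100, 0)
        )
        sp = L.simulate_spectrum(prof, grid, quiet_noise)
        peak = grid[np.argmax(sp.intensities)]
        assert abs(peak - 656.3) <= grid[1] - grid[0]
        assert sp.intensities.max() == pytest.approx(5.0, abs=1e-9)

    def test_linearity_in_amplitudes(self, quiet_noise):
        grid = np.linspace(400.0, 900.0, 400)
        lines = (L.LineSpec(656.3, 5.0, 1.2, "H"), L.LineSpec(479.45, 2.0, 1.0, "Cl"))
        p1 = L.FormulationProfile("x", lines, L.ContinuumSpec(1.0, 470, 130, 0.0))
        p2 = L.FormulationProfile(
            "x",
            tuple(L.LineSpec(l.center, 2 * l.amplitude, l.fwhm, l.element) for l in lines),
            L.ContinuumSpec(2.0, 470, 130, 0.0),
        )
        s1 = L.simulate_spectrum(p1, grid, quiet_noise)
        s2 = L.simulate_spectrum(p2, grid, quiet_noise)
        np.testing.assert_allclose(s2.intensities, 2 * s1.intensities, rtol=1e-12)

    def test_same_seed_identical(self, registry, grid800):
        a = L.simulate_spectrum(registry["Cipro pure"], grid800, L.NoiseModel(), rng=42)
        b = L.simulate_spectrum(registry["Cipro pure"], grid800, L.NoiseModel(), rng=42)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_empty_grid_rejected(self, registry, quiet_noise):
        with pytest.raises(L.DimensionError):
            L.simulate_spectrum(registry["Cipro pure"], np.array([]), quiet_noise)


class TestSimulateDataset:
    def test_row_counts_per_label(self, registry, grid800):
        ds = L.simulate_dataset(registry, 25, grid800, L.NoiseModel(), seed=1)
        assert ds.n_spectra == 100
        for name in registry:
            assert ds.class_indices(name).size == 25

    def test_same_seed_identical(self, registry, grid800):
        a = L.simulate_dataset(registry, 5, grid800, L.NoiseModel(), seed=9)
        b = L.simulate_dataset(registry, 5, grid800, L.NoiseModel(), seed=9)
        np.testing.assert_array_equal(a.intensities, b.intensities)
        assert a.labels == b.labels

    def test_line_scatter_calibration(self, grid800):
        """Peak-height cv across a class matches the configured scatter sd."""
        prof = {
            "x": L.FormulationProfile(
                "x",
                (L.LineSpec(479.45, 2.0, 1.0, "Cl"), L.LineSpec(656.3, 5.0, 1.2, "H")),
                L.ContinuumSpec(0.0, 470.0, 130.0, 0.0),
            )
        }
        noise = L.NoiseModel(shot_scale=0.0, fixed_pattern_sd=0.0, line_scatter_sd=0.15)
        ds = L.simulate_dataset(prof, 1000, grid800, noise, seed=3)
        window = np.abs(grid800 - 479.45) <= 2.0
        peaks = ds.intensities[:, window].max(axis=1)
        assert peaks.std() / peaks.mean() == pytest.approx(0.15, abs=0.03)

    def test_fixed_pattern_gain_shared_across_rows(self, registry, grid800):
        """Noise-free lines + pure fixed pattern: identical-profile rows identical."""
        noise = L.NoiseModel(shot_scale=0.0, fixed_pattern_sd=0.1, line_scatter_sd=0.0)
        ds = L.simulate_dataset(
            {"a": registry["Cipro pure"]}, 3, grid800, noise, seed=5
        )
        np.testing.assert_array_equal(ds.intensities[0], ds.intensities[1])
        np.testing.assert_array_equal(ds.intensities[0], ds.intensities[2])


def _nearest_mean_split_accuracy(ds, rng_seed=0):
    """Train/test nearest-class-mean accuracy plus hard-pair confusion."""
    rng = np.random.default_rng(rng_seed)
    train, test = L.stratified_split(ds, 0.7, rng)
    X = ds.valid_matrix()
    labels = np.asarray(ds.labels, dtype=object)
    classes = ds.classes
    means = np.vstack(
        [X[np.intersect1d(train, ds.class_indices(c))].mean(axis=0) for c in classes]
    )
    d2 = ((X[test][:, None, :] - means[None]) ** 2).sum(axis=-1)
    pred = np.asarray(classes, dtype=object)[np.argmin(d2, axis=1)]
    truth = labels[test]
    hard = np.isin(truth, L.HARD_PAIR)
    confusion = float(np.mean(pred[hard] != truth[hard])) if hard.any() else 0.0
    return float(np.mean(pred == truth)), confusion


class TestSeparability:
    def test_zero_noise_nearest_mean_is_perfect(self, registry, grid800, quiet_noise):
        ds = L.simulate_dataset(registry, 10, grid800, quiet_noise, seed=2)
        ds = L.normalize_to_reference_line(L.apply_notch_mask(ds))
        acc, _ = _nearest_mean_split_accuracy(ds)
        assert acc == 1.0

    def test_hard_pair_confusion_monotone_in_scatter(self, registry, grid800):
        confusions = []
        for sd in (0.0, 0.15, 0.35):
            noise = L.NoiseModel(shot_scale=0.0, fixed_pattern_sd=0.0, line_scatter_sd=sd)
            ds = L.simulate_dataset(registry, 40, grid800, noise, seed=6)
            ds = L.normalize_to_reference_line(L.apply_notch_mask(ds))
            confusions.append(_nearest_mean_split_accuracy(ds, rng_seed=1)[1])
        assert confusions == sorted(confusions)

    def test_continuum_carries_class_information(self, grid800):
        """Classes differing only in continuum: raw spectra classify above
        chance; perfect continuum subtraction drops accuracy to chance."""
        profiles = L.continuum_contrast_profiles(delta=0.3)
        ds, truth = L.simulate_dataset_with_truth(
            profiles, 60, grid800, L.NoiseModel(seed=1), seed=2
        )
        raw = L.normalize_to_reference_line(L.apply_notch_mask(ds))
        raw_acc, _ = _nearest_mean_split_accuracy(raw)

        stripped = ds.intensities.copy()
        for name in profiles:
            rows = ds.class_indices(name)
            stripped[rows] -= truth["continuum"][name] * truth["gains"]
        sub = ds.with_intensities(np.clip(stripped, 0.0, None))
        sub = L.normalize_to_reference_line(L.apply_notch_mask(sub))
        sub_acc, _ = _nearest_mean_split_accuracy(sub)

        assert raw_acc >= 0.7  # well above the 0.5 chance level
        assert abs(sub_acc - 0.5) <= 0.15  # back to chance
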