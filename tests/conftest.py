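import numpy as np
import pytest

import libsclass as L


@pytest.fixture(scope="session")
def grid800():
    """Reduced-resolution grid used throughout the tests for speed."""
    return L.default_grid(800)


@pytest.fixture(scope="session")
def registry():
    return L.default_formulation_profiles()


@pytest.fixture(scope="session")
def quiet_noise():
    """Noise-free generator settings (deterministic spectra)."""
    return L.NoiseModel(shot_scale=0.0, fixed_pattern_sd=0.0, line_scatter_sd=0.0)


@pytest.fixture(scope="session")
def default_dataset(registry, grid800):
    """4 classes x 30 rows at default noise, preprocessed (notch + normalize)."""
    ds = L.simulate_dataset(registry, 30, grid800, L.NoiseModel(seed=11), seed=11)
    return L.normalize_to_reference_line(L.apply_notch_mask(ds))


def well_separated_profiles():
    """Two classes with line-amplitude differences far above any noise."""
    lines_a = (
        L.LineSpec(479.45, 2.0, 1.0, "Cl"),
        L.LineSpec(656.3, 5.0, 1.2, "H"),
        L.LineSpec(777.2, 2.5, 1.0, "O"),
    )
    lines_b = (
        L.LineSpec(479.45, 6.0, 1.0, "Cl"),
        L.LineSpec(656.3, 5.0, 1.2, "H"),
        L.LineSpec(777.2, 0.5, 1.0, "O"),
    )
    cont = L.ContinuumSpec(1.0, 470.0, 130.0, 0.05)
    return {
        "A": L.FormulationProfile("A", lines_a, cont),
        "B": L.FormulationProfile("B", lines_b, cont),
    }


@pytest.fixture(scope="session")
def separable_dataset(grid800):
    """Two well-separated classes with mild noise, preprocessed."""
    noise = L.NoiseModel(shot_scale=0.01, fixed_pattern_sd=0.01, line_scatter_sd=0.10)
    ds = L.simulate_dataset(well_separated_profiles(), 30, grid800, noise, seed=7)
    return L.normalize_to_reference_line(L.apply_notch_mask(ds))
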