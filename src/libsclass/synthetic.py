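"""Forward simulator of non-gated LIBS emission spectra.

A simulated spectrum is built from three physically motivated parts:

* **Characteristic lines** — narrow, element-specific emission peaks,
  modelled as unit-peak Gaussians (``amplitude`` is the peak height in
  arbitrary units, ``fwhm`` the full width at half maximum in nm). The
  Gaussian shape stands in for the instrument-broadened line profile of a
  Czerny-Turner spectrograph; Stark (Lorentzian) wings are not modelled.
* **Continuum** — the broad featureless background from radiative
  recombination and Bremsstrahlung that dominates early, non-gated plasma
  emission. It is represented as a wide Gaussian bump plus a constant
  offset; only its smoothness and breadth matter for the analysis.
* **Noise** — three components mimicking the real measurement chain:
  per-spectrum lognormal scatter of each line amplitude (pellet
  inhomogeneity: each laser shot ablates a slightly different amount of
  material), a fixed-pattern multiplicative gain per channel drawn once
  per dataset (static CCD pixel non-uniformity), and additive shot noise
  with standard deviation proportional to the square root of the signal.

Four default formulation profiles emulate the morphology of real
pharmaceutical LIBS spectra: all classes share H, Cl, N and O lines (the
elements are present in every formulation and in ambient air); only the
two ciprofloxacin-family classes carry fluorine lines; and two designated
classes (the cetirizine/metformin analogs) differ by at most 10% in any
line amplitude and in continuum amplitude, forming the "hard pair" whose
separation stresses every classifier downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DimensionError
from .spectra import SpectraSet, Spectrum

__all__ = [
    "LineSpec",
    "ContinuumSpec",
    "NoiseModel",
    "FormulationProfile",
    "default_grid",
    "default_formulation_profiles",
    "continuum_contrast_profiles",
    "continuum_curve",
    "gaussian_line",
    "simulate_spectrum",
    "simulate_dataset",
    "simulate_dataset_with_truth",
    "HARD_PAIR",
]

#: The two classes constructed to be nearly indistinguishable.
HARD_PAIR = ("Cetirizine dihydrochloride", "Metformin hydrochloride")


@dataclass(frozen=True)
class LineSpec:
    """One atomic emission line: position (nm), peak height (a.u.), width."""

    center: float
    amplitude: float
    fwhm: float
    element: str = ""

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("line amplitude must be >= 0")
        if self.fwhm <= 0:
            raise ValueError("line fwhm must be > 0")


@dataclass(frozen=True)
class ContinuumSpec:
    """Broad background: ``offset + amplitude * exp(-(l-center)^2 / 2 width^2)``."""

    amplitude: float
    center: float
    width: float
    offset: float = 0.0

    def __post_init__(self):
        if self.amplitude < 0 or self.width < 0 or self.offset < 0:
            raise ValueError("continuum amplitude, width and offset must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Noise magnitudes of the simulated measurement chain.

    shot_scale
        Additive noise sd = ``shot_scale * sqrt(intensity)`` per channel.
    fixed_pattern_sd
        Sd of the static per-channel multiplicative gain (mean 1),
        drawn once per dataset.
    line_scatter_sd
        Coefficient of variation of the per-spectrum lognormal multiplier
        applied independently to each line amplitude (pellet
        inhomogeneity). The lognormal is parameterized to have mean
        exactly 1 and sd/mean exactly this value.
    """

    shot_scale: float = 0.02
    fixed_pattern_sd: float = 0.03
    line_scatter_sd: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if min(self.shot_scale, self.fixed_pattern_sd, self.line_scatter_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class FormulationProfile:
    """Generative description of one formulation class."""

    name: str
    lines: tuple[LineSpec, ...]
    continuum: ContinuumSpec

    def __post_init__(self):
        if not self.lines:
            raise ValueError("a profile needs at least one line")
        object.__setattr__(self, "lines", tuple(self.lines))

    def line_amplitude(self, center: float, atol: float = 0.2) -> float:
        for line in self.lines:
            if abs(line.center - center) <= atol:
                return line.amplitude
        raise KeyError(f"no line near {center} nm in profile {self.name!r}")


def default_grid(n_channels: int = 2068, lo: float = 350.0, hi: float = 900.0) -> np.ndarray:
    """Uniform wavelength grid emulating a compact CCD spectrometer."""
    return np.linspace(lo, hi, n_channels)


def gaussian_line(grid: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-peak Gaussian line profile on the grid."""
    return np.exp(-4.0 * math.log(2.0) * ((grid - center) / fwhm) ** 2)


def continuum_curve(spec: ContinuumSpec, grid) -> np.ndarray:
    """Evaluate the continuum background on a wavelength grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise DimensionError("empty grid")
    if spec.width == 0:
        return np.full(grid.shape, spec.offset + spec.amplitude * 0.0) + np.where(
            grid == spec.center, spec.amplitude, 0.0
        )
    return spec.offset + spec.amplitude * np.exp(
        -((grid - spec.center) ** 2) / (2.0 * spec.width**2)
    )


# ---------------------------------------------------------------------------
# Default formulation registry
# ---------------------------------------------------------------------------

# Shared line positions (nm) and widths: Cl I 479.45, N I 500/567/747,
# H-alpha 656.3, O I 777/868. Widths 0.8-1.5 nm emulate the resolution of a
# compact Czerny-Turner instrument.
_SHARED = {
    "Cl": (479.45, 1.0),
    "N500": (500.0, 0.9),
    "N567": (567.0, 0.9),
    "H": (656.3, 1.2),
    "N747": (747.0, 1.1),
    "O777": (777.2, 1.0),
    "O868": (868.0, 1.2),
}
# Fluorine lines present only in the ciprofloxacin-family classes; the
# positions are a simulator choice in the 680-695 nm region.
_F_LINES = ((685.6, 0.9), (690.2, 0.9))


def _profile(name, amplitudes, continuum, f_amps=None) -> FormulationProfile:
    lines = []
    for key, amp in amplitudes.items():
        center, fwhm = _SHARED[key]
        element = "".join(ch for ch in key if ch.isalpha())
        lines.append(LineSpec(center, amp, fwhm, element))
    if f_amps is not None:
        for (center, fwhm), amp in zip(_F_LINES, f_amps):
            lines.append(LineSpec(center, amp, fwhm, "F"))
    return FormulationProfile(name, tuple(lines), continuum)


def default_formulation_profiles() -> dict[str, FormulationProfile]:
    """The four default formulation classes.

    The cetirizine and metformin analogs are the hard pair: identical line
    positions, every shared-line amplitude and the continuum amplitude
    within 10% relative of each other, and identical continuum shape. The
    two ciprofloxacin-family classes additionally carry F-tagged lines.
    """
    profiles = [
        _profile(
            "Cetirizine dihydrochloride",
            {"Cl": 2.0, "N500": 1.2, "N567": 0.9, "H": 5.0, "N747": 1.5,
             "O777": 2.5, "O868": 1.0},
            ContinuumSpec(amplitude=1.20, center=470.0, width=130.0, offset=0.05),
        ),
        _profile(
            "Cipro pure",
            {"Cl": 1.2, "N500": 1.6, "N567": 1.2, "H": 5.0, "N747": 2.0,
             "O777": 3.0, "O868": 1.4},
            ContinuumSpec(amplitude=0.90, center=460.0, width=140.0, offset=0.05),
            f_amps=(0.9, 0.55),
        ),
        _profile(
            "Metformin hydrochloride",
            {"Cl": 1.85, "N500": 1.29, "N567": 0.96, "H": 5.0, "N747": 1.40,
             "O777": 2.35, "O868": 1.08},
            ContinuumSpec(amplitude=1.30, center=470.0, width=130.0, offset=0.05),
        ),
        _profile(
            "Ciprofloxacin hydrochloride",
            {"Cl": 2.6, "N500": 1.4, "N567": 1.05, "H": 5.0, "N747": 1.7,
             "O777": 2.2, "O868": 0.85},
            ContinuumSpec(amplitude=1.55, center=485.0, width=120.0, offset=0.05),
            f_amps=(0.75, 0.45),
        ),
    ]
    return {p.name: p for p in profiles}


def continuum_contrast_profiles(
    delta: float = 0.3, base_amplitude: float = 1.0
) -> dict[str, FormulationProfile]:
    """Two classes whose ONLY difference is the continuum amplitude.

    Used to probe whether classifiers can exploit background information:
    with identical line lists, any above-chance classification on raw
    spectra must come from the continuum, and perfect continuum
    subtraction must drive accuracy back to chance.
    """
    amplitudes = {"Cl": 2.0, "N500": 1.2, "N567": 0.9, "H": 5.0, "N747": 1.5,
                  "O777": 2.5, "O868": 1.0}
    lo = _profile(
        "continuum_lo", amplitudes,
        ContinuumSpec(base_amplitude, center=470.0, width=130.0, offset=0.05),
    )
    hi = _profile(
        "continuum_hi", amplitudes,
        ContinuumSpec(base_amplitude * (1.0 + delta), center=470.0, width=130.0,
                      offset=0.05),
    )
    return {lo.name: lo, hi.name: hi}


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _scatter_sigma(cv: float) -> float:
    # lognormal(mu=-s^2/2, s) has mean 1 and sd/mean = sqrt(exp(s^2)-1) = cv
    return math.sqrt(math.log1p(cv * cv))


def simulate_spectrum(
    profile: FormulationProfile,
    grid,
    noise: NoiseModel = NoiseModel(),
    rng: np.random.Generator | int | None = None,
    gains: np.ndarray | None = None,
) -> Spectrum:
    """Simulate one spectrum: continuum + scattered lines, gain, shot noise.

    ``gains`` is the fixed-pattern per-channel gain vector; pass the
    dataset-level vector when simulating replicate shots, or None for a
    flat detector. ``rng`` may be a Generator, a seed, or None (seeded
    from ``noise.seed``).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise DimensionError("empty grid")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(noise.seed if rng is None else rng)

    clean = continuum_curve(profile.continuum, grid)
    if noise.line_scatter_sd > 0:
        s = _scatter_sigma(noise.line_scatter_sd)
        scatter = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=len(profile.lines))
    else:
        scatter = np.ones(len(profile.lines))
    for line, mult in zip(profile.lines, scatter):
        clean = clean + line.amplitude * mult * gaussian_line(grid, line.center, line.fwhm)

    signal = clean if gains is None else clean * gains
    if noise.shot_scale > 0:
        sd = noise.shot_scale * np.sqrt(np.clip(signal, 0.0, None))
        signal = signal + rng.normal(0.0, 1.0, grid.size) * sd
    return Spectrum(grid, np.clip(signal, 0.0, None))


def simulate_dataset(
    registry: dict[str, FormulationProfile],
    n_per_class: int,
    grid=None,
    noise: NoiseModel = NoiseModel(),
    seed: int | None = None,
) -> SpectraSet:
    """Simulate a labelled dataset: ``n_per_class`` rows per profile.

    One fixed-pattern gain vector is drawn for the whole dataset (it is
    static detector structure); line scatter and shot noise are drawn per
    row. Identical seeds give bit-identical datasets.
    """
    dataset, _ = simulate_dataset_with_truth(registry, n_per_class, grid, noise, seed)
    return dataset


def simulate_dataset_with_truth(
    registry: dict[str, FormulationProfile],
    n_per_class: int,
    grid=None,
    noise: NoiseModel = NoiseModel(),
    seed: int | None = None,
) -> tuple[SpectraSet, dict]:
    """As :func:`simulate_dataset`, also returning the generative ground truth.

    The truth dict carries the per-class true continuum curve, the
    fixed-pattern gain vector, and each row's scattered line amplitudes —
    the oracle used to validate baseline estimation and noise calibration.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(noise.seed if seed is None else seed)

    if noise.fixed_pattern_sd > 0:
        gains = 1.0 + rng.normal(0.0, noise.fixed_pattern_sd, grid.size)
    else:
        gains = np.ones(grid.size)

    rows, labels, provenance = [], [], []
    truth: dict = {
        "grid": grid,
        "gains": gains,
        "continuum": {},
        "line_amplitudes": [],
        "line_centers": {},
    }
    for name, profile in registry.items():
        truth["continuum"][name] = continuum_curve(profile.continuum, grid)
        truth["line_centers"][name] = [line.center for line in profile.lines]
        for i in range(n_per_class):
            s = _scatter_sigma(noise.line_scatter_sd) if noise.line_scatter_sd > 0 else 0.0
            if s > 0:
                scatter = rng.lognormal(-0.5 * s * s, s, size=len(profile.lines))
            else:
                scatter = np.ones(len(profile.lines))
            clean = truth["continuum"][name].copy()
            for line, mult in zip(profile.lines, scatter):
                clean += line.amplitude * mult * gaussian_line(grid, line.center, line.fwhm)
            signal = clean * gains
            if noise.shot_scale > 0:
                sd = noise.shot_scale * np.sqrt(np.clip(signal, 0.0, None))
                signal = signal + rng.normal(0.0, 1.0, grid.size) * sd
            rows.append(np.clip(signal, 0.0, None))
            labels.append(name)
            provenance.append(f"{name}#{i}")
            truth["line_amplitudes"].append(
                [line.amplitude * mult for line, mult in zip(profile.lines, scatter)]
            )
    dataset = SpectraSet(grid, np.vstack(rows), labels, provenance=provenance)
    return dataset, truth
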