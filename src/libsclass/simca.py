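"""Soft Independent Modeling of Class Analogy (SIMCA).

Each class gets its own PCA submodel fitted on that class's training rows
only. A query spectrum is compared to every submodel through its
orthogonal residual distance — the Euclidean norm of the part of the
centered spectrum that the submodel's principal subspace cannot
reconstruct. A class *accepts* the spectrum when that distance is at most
``mean + sigma_multiplier * sd`` of the training residual distances (the
3-sigma rule by default). Because acceptance is per class, a spectrum may
be accepted by several classes, exactly one, or none:

* accepted by none  -> *unclassified* (the soft rejection option),
* otherwise it is *assigned* to the accepted class with the smallest
  standardized distance ``(d - mean) / sd``; the verdict is *correct*
  when the assignment matches the true class, else *misclassified*.

Submodel rank is chosen per class as the smallest number of components
reaching a cumulative-variance target (default 0.95), capped at
``min(max_rank, n_c - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ClassSizeError, DimensionError
from .pca import PCAModel, fit_pca
from .spectra import SpectraSet, Spectrum

__all__ = [
    "SIMCAConfig",
    "SIMCASubmodel",
    "SIMCAModel",
    "ClassificationOutcome",
    "fit_simca",
    "residual_distance",
    "classify",
    "classify_set",
]

_EPS = 1e-12


@dataclass(frozen=True)
class SIMCAConfig:
    """SIMCA hyperparameters: acceptance width, rank rule, rank cap."""

    sigma_multiplier: float = 3.0
    variance_target: float = 0.95
    max_rank: int = 10

    def __post_init__(self):
        if self.sigma_multiplier <= 0:
            raise ValueError("sigma_multiplier must be > 0")
        if not (0 < self.variance_target <= 1):
            raise ValueError("variance_target must be in (0, 1]")
        if self.max_rank < 1:
            raise ValueError("max_rank must be >= 1")


@dataclass(frozen=True)
class SIMCASubmodel:
    """One class's PCA submodel with its residual acceptance threshold."""

    class_name: str
    pca: PCAModel
    residual_mean: float
    residual_sd: float
    threshold: float


@dataclass(frozen=True)
class SIMCAModel:
    """Per-class submodels in class first-appearance order."""

    submodels: tuple[SIMCASubmodel, ...]
    config: SIMCAConfig

    @property
    def classes(self) -> list[str]:
        return [m.class_name for m in self.submodels]


@dataclass(frozen=True)
class ClassificationOutcome:
    """The SIMCA verdict trichotomy for one spectrum."""

    true_class: str
    accepted_classes: frozenset[str]
    assigned_class: str | None
    verdict: str  # "correct" | "misclassified" | "unclassified"


def _choose_rank(fractions: np.ndarray, target: float) -> int:
    cum = np.cumsum(fractions)
    hit = np.flatnonzero(cum >= target - 1e-12)
    return int(hit[0]) + 1 if hit.size else len(fractions)


def _residuals_matrix(sub: SIMCASubmodel, X_valid: np.ndarray) -> np.ndarray:
    centered = X_valid - sub.pca.mean_spectrum
    scores = centered @ sub.pca.loadings.T
    residual = centered - scores @ sub.pca.loadings
    return np.linalg.norm(residual, axis=1)


def fit_simca(train: SpectraSet, config: SIMCAConfig = SIMCAConfig()) -> SIMCAModel:
    """Fit one PCA submodel and acceptance threshold per training class."""
    submodels = []
    for name in train.classes:
        idx = train.class_indices(name)
        n_c = idx.size
        if n_c < 3:
            raise ClassSizeError(
                f"class {name!r} has only {n_c} training rows (need >= 3)",
                class_name=name,
            )
        subset = train.select(idx)
        k_max = min(config.max_rank, n_c - 1)
        probe = fit_pca(subset, k_max)
        k_c = _choose_rank(probe.variance_fractions, config.variance_target)
        pca = PCAModel(
            mean_spectrum=probe.mean_spectrum,
            loadings=probe.loadings[:k_c],
            variance_fractions=probe.variance_fractions[:k_c],
            k=k_c,
            wavelengths=probe.wavelengths,
            valid_mask=probe.valid_mask,
        )
        stub = SIMCASubmodel(name, pca, 0.0, 0.0, 0.0)
        distances = _residuals_matrix(stub, subset.valid_matrix())
        mean = float(distances.mean())
        sd = float(distances.std(ddof=1)) if n_c > 1 else 0.0
        submodels.append(
            SIMCASubmodel(
                class_name=name,
                pca=pca,
                residual_mean=mean,
                residual_sd=sd,
                threshold=mean + config.sigma_multiplier * sd,
            )
        )
    return SIMCAModel(tuple(submodels), config)


def residual_distance(submodel: SIMCASubmodel, spectrum: Spectrum) -> float:
    """Orthogonal residual distance of one spectrum to a class submodel."""
    mask = submodel.pca.valid_mask
    if (
        spectrum.n_channels != submodel.pca.wavelengths.size
        or not np.allclose(spectrum.wavelengths, submodel.pca.wavelengths)
        or not np.array_equal(spectrum.valid_mask, mask)
    ):
        raise DimensionError("spectrum grid/mask does not match the submodel")
    x = spectrum.intensities[mask]
    return float(_residuals_matrix(submodel, x[None, :])[0])


def _outcome(model, true_class, distances) -> ClassificationOutcome:
    accepted = [
        (sub, d)
        for sub, d in zip(model.submodels, distances)
        if d <= sub.threshold
    ]
    if not accepted:
        return ClassificationOutcome(true_class, frozenset(), None, "unclassified")
    standardized = [
        (d - sub.residual_mean) / max(sub.residual_sd, _EPS) for sub, d in accepted
    ]
    assigned = accepted[int(np.argmin(standardized))][0].class_name
    verdict = "correct" if assigned == true_class else "misclassified"
    return ClassificationOutcome(
        true_class,
        frozenset(sub.class_name for sub, _ in accepted),
        assigned,
        verdict,
    )


def classify(model: SIMCAModel, spectrum: Spectrum, true_class: str) -> ClassificationOutcome:
    """Classify one spectrum against every class's acceptance region."""
    distances = [residual_distance(sub, spectrum) for sub in model.submodels]
    return _outcome(model, true_class, distances)


def classify_set(model: SIMCAModel, spectra: SpectraSet) -> list[ClassificationOutcome]:
    """Vectorized classification of every row of a SpectraSet."""
    first = model.submodels[0].pca
    if (
        spectra.n_channels != first.wavelengths.size
        or not np.allclose(spectra.wavelengths, first.wavelengths)
        or not np.array_equal(spectra.valid_mask, first.valid_mask)
    ):
        raise DimensionError("spectra grid/mask does not match the model")
    X = spectra.valid_matrix()
    all_d = np.column_stack([_residuals_matrix(sub, X) for sub in model.submodels])
    return [
        _outcome(model, spectra.labels[i], all_d[i]) for i in range(spectra.n_spectra)
    ]
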