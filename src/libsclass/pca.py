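"""Principal component analysis over valid spectral channels.

Spectra are mean-centered only — no unit-variance scaling — which is the
chemometric default for spectra already normalized to an internal
standard line. The decomposition is computed by singular value
decomposition of the centered matrix; component signs are fixed so the
largest-magnitude loading entry of each component is positive, making
fits reproducible across runs and BLAS builds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError
from .spectra import SpectraSet

__all__ = ["PCAModel", "fit_pca", "variance_explained", "project"]


@dataclass(frozen=True)
class PCAModel:
    """Fitted PCA: mean spectrum, orthonormal loadings, variance fractions.

    ``mean_spectrum`` and the ``loadings`` rows live on the valid channels
    only; ``wavelengths`` and ``valid_mask`` record the grid the model was
    fitted on so projections can check compatibility.
    """

    mean_spectrum: np.ndarray
    loadings: np.ndarray
    variance_fractions: np.ndarray
    k: int
    wavelengths: np.ndarray
    valid_mask: np.ndarray


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    out = loadings.copy()
    for row in out:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    return out


def fit_pca(spectra: SpectraSet, k: int) -> PCAModel:
    """Fit a rank-``k`` PCA to the valid channels of a SpectraSet.

    Variance fractions are singular values squared over the total
    variance of the centered data, so they sum to at most 1 and are
    non-increasing. Deterministic up to the fixed sign convention.
    """
    X = spectra.valid_matrix()
    n, p = X.shape
    if n < 2:
        raise DimensionError("PCA needs at least two spectra")
    if not (1 <= k <= min(n - 1, p)):
        raise DimensionError(f"k={k} out of range for {n} spectra x {p} channels")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 0:
        fractions = np.zeros(k)
        loadings = vt[:k]
    else:
        fractions = (s[:k] ** 2) / total
        loadings = _fix_signs(vt[:k])
    return PCAModel(
        mean_spectrum=mean,
        loadings=loadings,
        variance_fractions=fractions,
        k=k,
        wavelengths=spectra.wavelengths.copy(),
        valid_mask=spectra.valid_mask.copy(),
    )


def variance_explained(model: PCAModel, j: int) -> float:
    """Cumulative variance fraction of the first ``j`` components."""
    if not (1 <= j <= model.k):
        raise DimensionError(f"j={j} out of range 1..{model.k}")
    return float(np.sum(model.variance_fractions[:j]))


def _check_grid(model: PCAModel, spectra: SpectraSet) -> None:
    if spectra.n_channels != model.wavelengths.size or not np.allclose(
        spectra.wavelengths, model.wavelengths
    ):
        raise DimensionError("wavelength grid does not match the fitted model")
    if not np.array_equal(spectra.valid_mask, model.valid_mask):
        raise DimensionError("validity mask does not match the fitted model")


def project(model: PCAModel, spectra: SpectraSet) -> np.ndarray:
    """Score matrix ``(rows - mean) @ loadings.T`` of shape (n, k)."""
    _check_grid(model, spectra)
    return (spectra.valid_matrix() - model.mean_spectrum) @ model.loadings.T
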