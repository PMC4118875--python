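"""Continuum-background estimation by iterative constrained polynomial fitting.

The estimator is the classic modified-polyfit scheme for spectra with
small characteristic peaks riding on a large smooth background: fit a
polynomial of fixed order to the spectrum by least squares, clip the
working vector to the pointwise minimum of itself and the fit, and
repeat. Peaks are progressively excluded from the fit because the clip
pulls the working vector down to the polynomial wherever the spectrum
exceeds it, while smooth background regions are left untouched; the fit
therefore converges to the background. The non-negativity constraint is
applied to the residual: after subtracting the final baseline, negative
values are clipped to zero.

Wavelengths are rescaled to [-1, 1] before fitting for numerical
conditioning. Masked channels are excluded from the fit; the corrected
spectrum passes them through unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly

from .errors import BatchCorrectionError, DimensionError
from .spectra import SpectraSet, Spectrum

__all__ = ["BaselineConfig", "iterative_polyfit_baseline", "batch_correct"]


@dataclass(frozen=True)
class BaselineConfig:
    """Settings of the iterative polynomial background fit.

    order
        Polynomial order; 6 suits broad LIBS continua on a 350-900 nm grid.
    max_iter, tol
        Iteration stops when the maximum change of the fitted curve,
        relative to its maximum magnitude, drops below ``tol``.
    clip_negative_residual
        Apply the non-negativity constraint to the corrected spectrum.
    """

    order: int = 6
    max_iter: int = 100
    tol: float = 1e-4
    clip_negative_residual: bool = True

    def __post_init__(self):
        if self.order < 0:
            raise ValueError("order must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


def iterative_polyfit_baseline(
    spectrum: Spectrum, cfg: BaselineConfig = BaselineConfig()
) -> tuple[np.ndarray, Spectrum]:
    """Estimate and remove the continuum background of one spectrum.

    Returns ``(baseline, corrected)``. The baseline vector spans the full
    grid (the final polynomial evaluated everywhere); the corrected
    spectrum is ``original - baseline`` on valid channels, with negative
    residuals clipped to zero when configured, and the original values on
    masked channels.
    """
    mask = spectrum.valid_mask
    n_valid = int(mask.sum())
    if n_valid < cfg.order + 1:
        raise DimensionError(
            f"{n_valid} valid channels cannot constrain an order-{cfg.order} fit"
        )
    wl = spectrum.wavelengths
    lo, hi = wl[mask][0], wl[mask][-1]
    span = hi - lo
    t_all = np.zeros_like(wl) if span == 0 else 2.0 * (wl - lo) / span - 1.0
    t = t_all[mask]

    working = spectrum.intensities[mask].astype(float).copy()
    prev_fit = None
    converged = False
    for _ in range(cfg.max_iter):
        coef = npoly.polyfit(t, working, cfg.order)
        fit = npoly.polyval(t, coef)
        if prev_fit is not None:
            scale = max(float(np.max(np.abs(fit))), np.finfo(float).tiny)
            if float(np.max(np.abs(fit - prev_fit))) / scale < cfg.tol:
                converged = True
                break
        working = np.minimum(working, fit)
        prev_fit = fit
    if not converged:
        warnings.warn(
            f"baseline fit did not converge within {cfg.max_iter} iterations; "
            "returning the last iterate",
            RuntimeWarning,
            stacklevel=2,
        )

    baseline = npoly.polyval(t_all, coef)
    corrected = spectrum.intensities - baseline
    if cfg.clip_negative_residual:
        corrected = np.clip(corrected, 0.0, None)
    corrected = np.where(mask, corrected, spectrum.intensities)
    return baseline, Spectrum(wl, corrected, mask)


def batch_correct(
    spectra: SpectraSet,
    cfg: BaselineConfig = BaselineConfig(),
    return_baselines: bool = False,
):
    """Apply :func:`iterative_polyfit_baseline` to every row of a set.

    Labels, provenance and the validity mask are preserved. Failures are
    collected and raised together with the offending row indices.
    """
    corrected = np.empty_like(spectra.intensities)
    baselines = np.empty_like(spectra.intensities)
    failures: list[int] = []
    messages: list[str] = []
    for i in range(spectra.n_spectra):
        try:
            baselines[i], row = iterative_polyfit_baseline(spectra.row(i), cfg)
            corrected[i] = row.intensities
        except Exception as exc:  # per-row failures reported together
            failures.append(i)
            messages.append(f"row {i}: {exc}")
    if failures:
        raise BatchCorrectionError(
            "baseline correction failed for rows "
            f"{failures}: {'; '.join(messages[:5])}",
            rows=failures,
        )
    out = spectra.with_intensities(corrected)
    return (out, baselines) if return_baselines else out
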