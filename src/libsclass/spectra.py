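"""Spectral data model, I/O, and the two standard preprocessing steps.

The in-memory containers are thin dataclasses around NumPy arrays: a
:class:`Spectrum` is one emission spectrum on a strictly increasing
wavelength grid (nm) with a per-channel validity mask; a
:class:`SpectraSet` is a stack of spectra sharing one grid and one mask,
with a class label (and free-text provenance) per row.

Channels flagged invalid — typically the 30 nm band around the 532 nm
excitation laser line — are excluded from every downstream computation:
normalization, baseline fitting, distances, PCA and the classifiers all
operate on valid channels only.

Preprocessing follows the usual non-gated LIBS recipe:

1. :func:`apply_notch_mask` invalidates the band around the laser line,
   where scattered excitation light swamps the plasma emission.
2. :func:`normalize_to_reference_line` divides each spectrum by the height
   of an internal-standard emission peak (default the hydrogen Balmer
   alpha line near 656.3 nm, present in every organic formulation), which
   removes shot-to-shot variation in overall ablation efficiency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, NormalizationError, SpectraFormatError

__all__ = [
    "Spectrum",
    "SpectraSet",
    "PreprocessConfig",
    "read_spectra",
    "write_spectra",
    "write_report",
    "apply_notch_mask",
    "normalize_to_reference_line",
]


def _as_float_vector(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise DimensionError(f"expected a 1-D vector, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class Spectrum:
    """One emission spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths
        Channel centers in nm, strictly increasing.
    intensities
        Intensities in arbitrary units, same length as ``wavelengths``.
    valid_mask
        Boolean per-channel validity; invalid channels are ignored by
        every downstream operation. Defaults to all-valid.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    valid_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        wl = _as_float_vector(self.wavelengths)
        inten = _as_float_vector(self.intensities)
        if self.valid_mask is None:
            mask = np.ones(wl.shape, dtype=bool)
        else:
            mask = np.asarray(self.valid_mask, dtype=bool)
        if not (wl.shape == inten.shape == mask.shape):
            raise DimensionError(
                f"length mismatch: wavelengths {wl.shape}, intensities "
                f"{inten.shape}, mask {mask.shape}"
            )
        if wl.size == 0:
            raise DimensionError("empty wavelength grid")
        if not np.all(np.diff(wl) > 0):
            raise DimensionError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(inten[mask])):
            raise DimensionError("non-finite intensity on a valid channel")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", inten)
        object.__setattr__(self, "valid_mask", mask)

    @property
    def n_channels(self) -> int:
        return self.wavelengths.size


@dataclass
class SpectraSet:
    """A labelled stack of spectra sharing one grid and one validity mask."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    labels: list[str]
    valid_mask: np.ndarray = None  # type: ignore[assignment]
    provenance: list[str] | None = None

    def __post_init__(self):
        wl = _as_float_vector(self.wavelengths)
        X = np.asarray(self.intensities, dtype=float)
        if X.ndim != 2:
            raise DimensionError(f"intensity matrix must be 2-D, got {X.shape}")
        if X.shape[0] < 1:
            raise DimensionError("a SpectraSet needs at least one spectrum")
        if X.shape[1] != wl.size:
            raise DimensionError(
                f"{X.shape[1]} intensity columns vs {wl.size} wavelengths"
            )
        if not np.all(np.diff(wl) > 0):
            raise DimensionError("wavelengths must be strictly increasing")
        if self.valid_mask is None:
            mask = np.ones(wl.shape, dtype=bool)
        else:
            mask = np.asarray(self.valid_mask, dtype=bool)
        if mask.shape != wl.shape:
            raise DimensionError("valid_mask length does not match the grid")
        labels = [str(l) for l in self.labels]
        if len(labels) != X.shape[0]:
            raise DimensionError(f"{len(labels)} labels for {X.shape[0]} rows")
        if not np.all(np.isfinite(X[:, mask])):
            raise DimensionError("non-finite intensity on a valid channel")
        if self.provenance is not None and len(self.provenance) != X.shape[0]:
            raise DimensionError("provenance length does not match rows")
        self.wavelengths = wl
        self.intensities = X
        self.valid_mask = mask
        self.labels = labels

    # -- bookkeeping ---------------------------------------------------

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    @property
    def classes(self) -> list[str]:
        """Class names in first-appearance order (stable across the pipeline)."""
        seen: dict[str, None] = {}
        for l in self.labels:
            seen.setdefault(l, None)
        return list(seen)

    def class_indices(self, name: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels, dtype=object) == name)

    def valid_matrix(self) -> np.ndarray:
        """Intensity matrix restricted to valid channels (view copy)."""
        return self.intensities[:, self.valid_mask]

    def row(self, i: int) -> Spectrum:
        return Spectrum(self.wavelengths, self.intensities[i], self.valid_mask)

    def select(self, indices) -> "SpectraSet":
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            self.wavelengths.copy(),
            self.intensities[idx].copy(),
            [self.labels[i] for i in idx],
            self.valid_mask.copy(),
            [self.provenance[i] for i in idx] if self.provenance else None,
        )

    def with_intensities(self, X: np.ndarray) -> "SpectraSet":
        return SpectraSet(
            self.wavelengths.copy(),
            np.asarray(X, dtype=float),
            list(self.labels),
            self.valid_mask.copy(),
            list(self.provenance) if self.provenance else None,
        )

    def same_grid(self, other: "SpectraSet") -> bool:
        return (
            self.n_channels == other.n_channels
            and np.allclose(self.wavelengths, other.wavelengths)
            and np.array_equal(self.valid_mask, other.valid_mask)
        )


@dataclass(frozen=True)
class PreprocessConfig:
    """Laser-notch and reference-line settings.

    ``notch_width`` is the full width of the excluded band (30 nm total
    means +/- 15 nm around the center). ``reference_window`` is the
    half-width of the peak-search window around the reference line, which
    absorbs small wavelength-calibration offsets of the H-alpha peak.
    """

    notch_center: float = 532.0
    notch_width: float = 30.0
    reference_line: float = 656.3
    reference_window: float = 2.0

    def __post_init__(self):
        if self.notch_width <= 0 or self.reference_window <= 0:
            raise ValueError("widths must be positive")
        half = self.notch_width / 2.0
        if abs(self.reference_line - self.notch_center) <= half:
            raise ValueError("reference line lies inside the notch band")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_LABEL_COLUMN = "class"
_PROVENANCE_COLUMN = "provenance"


def _infer_format(path: Path, format_hint: str | None) -> str:
    if format_hint:
        return format_hint.lower()
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xls"):
        return "xlsx"
    return "csv"


def read_spectra(
    path,
    format_hint: str | None = None,
    label_column: str = _LABEL_COLUMN,
    sheet: int | str = 0,
    orientation: str = "rows",
) -> SpectraSet:
    """Read a wide-format spectral table (CSV or XLSX) into a SpectraSet.

    The expected layout has one spectrum per row, a header row of numeric
    wavelengths (nm), one ``label_column`` with the class name, and an
    optional ``provenance`` column. ``orientation="columns"`` transposes
    a table stored with one spectrum per column (wavelengths down the
    first column, class names in the header row). Columns that are
    entirely empty are read back as masked (invalid) channels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format_hint)
    if fmt == "csv":
        header = pd.read_csv(path, header=None, nrows=1).iloc[0].astype(str)
        df = pd.read_csv(path)
    elif fmt in ("xlsx", "xls"):
        header = pd.read_excel(path, sheet_name=sheet, header=None, nrows=1).iloc[0].astype(str)
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        raise SpectraFormatError(f"unknown format {fmt!r}")
    # pandas mangles duplicate headers ("400", "400.1"); check the raw row
    if orientation == "rows" and header.duplicated().any():
        dupes = sorted(set(header[header.duplicated()]))
        raise SpectraFormatError(f"duplicate wavelength columns: {dupes}")

    if orientation == "columns":
        df = _transpose_wide(df, label_column)
    elif orientation != "rows":
        raise SpectraFormatError(f"unknown orientation {orientation!r}")

    if label_column not in df.columns:
        raise SpectraFormatError(f"label column {label_column!r} not found")
    labels = [str(v) for v in df[label_column]]
    provenance = None
    if _PROVENANCE_COLUMN in df.columns:
        provenance = [str(v) for v in df[_PROVENANCE_COLUMN]]

    wl_cols = [c for c in df.columns if c not in (label_column, _PROVENANCE_COLUMN)]
    wavelengths = []
    for c in wl_cols:
        try:
            wavelengths.append(float(c))
        except (TypeError, ValueError):
            raise SpectraFormatError(
                f"column header {c!r} is not a numeric wavelength"
            ) from None
    wl = np.asarray(wavelengths, dtype=float)
    if np.unique(wl).size != wl.size:
        raise SpectraFormatError("duplicate wavelength columns")

    order = np.argsort(wl)
    wl = wl[order]
    X = df[wl_cols].to_numpy(dtype=float)[:, order]

    # all-NaN columns encode masked channels (write_spectra leaves them blank)
    all_nan = np.all(np.isnan(X), axis=0)
    mask = ~all_nan
    X = X.copy()
    X[:, all_nan] = 0.0
    if np.any(np.isnan(X[:, mask])):
        raise DimensionError("ragged table: missing intensity values on valid channels")
    return SpectraSet(wl, X, labels, mask, provenance)


def _transpose_wide(df: pd.DataFrame, label_column: str) -> pd.DataFrame:
    first = df.columns[0]
    wl = df[first].to_numpy()
    out = pd.DataFrame(
        df.drop(columns=[first]).to_numpy().T,
        columns=[str(w) for w in wl],
    )
    out[label_column] = [str(c) for c in df.columns[1:]]
    return out


def write_spectra(spectra: SpectraSet, path, format_hint: str | None = None) -> None:
    """Write a SpectraSet as a lossless wide-format table (CSV or XLSX).

    Masked channels are written as empty cells so the validity mask
    round-trips through :func:`read_spectra`.
    """
    if spectra.n_spectra < 1:
        raise DimensionError("refusing to write an empty SpectraSet")
    path = Path(path)
    fmt = _infer_format(path, format_hint)
    X = spectra.intensities.astype(object).copy()
    X[:, ~spectra.valid_mask] = np.nan
    df = pd.DataFrame(X, columns=[f"{w:.10g}" for w in spectra.wavelengths])
    df[_LABEL_COLUMN] = spectra.labels
    if spectra.provenance is not None:
        df[_PROVENANCE_COLUMN] = spectra.provenance
    try:
        if fmt == "csv":
            df.to_csv(path, index=False)
        elif fmt in ("xlsx", "xls"):
            df.to_excel(path, index=False)
        else:
            raise SpectraFormatError(f"unknown format {fmt!r}")
    except OSError as exc:
        raise OSError(f"failed writing {path}: {exc}") from exc


def write_report(report, path) -> None:
    """Serialize a report object (anything with ``to_dict``) or dict as JSON."""
    path = Path(path)
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    try:
        path.write_text(json.dumps(payload, indent=2, sort_keys=False))
    except OSError as exc:
        raise OSError(f"failed writing {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def apply_notch_mask(spectra: SpectraSet, cfg: PreprocessConfig = PreprocessConfig()) -> SpectraSet:
    """Invalidate channels in the closed band around the laser line.

    Channels with wavelength in ``[center - width/2, center + width/2]``
    get ``valid_mask = False``; their intensities are disregarded by all
    downstream analysis. Masking a grid that does not cover the band is a
    no-op, and the operation is idempotent.
    """
    half = cfg.notch_width / 2.0
    in_band = (spectra.wavelengths >= cfg.notch_center - half) & (
        spectra.wavelengths <= cfg.notch_center + half
    )
    out = spectra.select(np.arange(spectra.n_spectra))
    out.valid_mask = spectra.valid_mask & ~in_band
    return out


def normalize_to_reference_line(
    spectra: SpectraSet, cfg: PreprocessConfig = PreprocessConfig()
) -> SpectraSet:
    """Divide each spectrum by its peak height near the reference line.

    The divisor is the maximum valid intensity within
    ``reference_line +/- reference_window``; after normalization that
    maximum is exactly 1.0. The operation is idempotent and invariant to
    positive rescaling of the input.
    """
    window = (
        (np.abs(spectra.wavelengths - cfg.reference_line) <= cfg.reference_window)
        & spectra.valid_mask
    )
    if not np.any(window):
        raise NormalizationError(
            f"reference window {cfg.reference_line}+/-{cfg.reference_window} nm "
            "contains no valid channel",
            rows=range(spectra.n_spectra),
        )
    peak = spectra.intensities[:, window].max(axis=1)
    bad = np.flatnonzero(~(peak > 0))
    if bad.size:
        raise NormalizationError(
            f"non-positive reference peak in rows {bad.tolist()}", rows=bad.tolist()
        )
    return spectra.with_intensities(spectra.intensities / peak[:, None])
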