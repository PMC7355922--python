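"""Raw-spectrum preprocessing.

Transforms detector counts into the normalized fingerprint spectra the
classifier consumes. Stages, applied in order by :func:`preprocess_dataset`:

1. dark-spectrum subtraction (optional),
2. cosmic-ray removal (running median + MAD outlier test, linear repair),
3. Savitzky–Golay smoothing,
4. tissue-fluorescence removal by an iterative modified fifth-order
   polynomial fit (the Lieber iteration: refit after clipping the spectrum
   to the current fit, so peaks are progressively excluded),
5. intensity-response correction (optional),
6. crop to the 800–1790 cm⁻¹ fingerprint region,
7. scaling the area under the curve to one.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter

from .dataset_io import SpectraDataset, SpectrumRecord, Stage
from .errors import (
    CalibrationError,
    ConfigError,
    NormalizationError,
    PreprocessError,
    RangeError,
    ShapeError,
)

__all__ = [
    "PreprocessConfig",
    "SpectrumFlags",
    "subtract_dark",
    "remove_cosmic_rays",
    "smooth_spectrum",
    "modpoly_baseline",
    "correct_intensity_response",
    "crop_spectrum",
    "normalize_area",
    "preprocess_dataset",
]


@dataclass
class PreprocessConfig:
    """Tunable preprocessing parameters.

    ``cosmic_floor`` is a relative amplitude floor: a point is only flagged
    as a cosmic ray if its median-filter residual also exceeds this fraction
    of the spectrum's intensity range, which keeps the MAD test from firing
    on the curvature of noiseless smooth spectra.
    """

    dark_spectrum: np.ndarray | None = None
    cosmic_window: int = 5
    cosmic_k: float = 8.0
    cosmic_floor: float = 0.05
    cosmic_max_fraction: float = 0.05
    smooth_window: int = 11
    smooth_polyorder: int = 3
    baseline_order: int = 5
    baseline_max_iter: int = 100
    baseline_tol: float = 1e-4
    response_curve: np.ndarray | None = None
    crop: tuple[float, float] = (800.0, 1790.0)

    def validate(self) -> None:
        if self.cosmic_window % 2 == 0 or self.cosmic_window < 3:
            raise ConfigError(f"cosmic_window must be odd and ≥ 3, got {self.cosmic_window}")
        if self.smooth_window != 1 and self.smooth_window % 2 == 0:
            raise ConfigError(f"smooth_window must be odd, got {self.smooth_window}")
        if self.smooth_window != 1 and self.smooth_polyorder >= self.smooth_window:
            raise ConfigError("smooth_polyorder must be smaller than smooth_window")
        if self.baseline_order < 1:
            raise ConfigError("baseline_order must be ≥ 1")
        if self.crop[0] >= self.crop[1]:
            raise ConfigError(f"crop range {self.crop} must be increasing")


@dataclass
class SpectrumFlags:
    """Per-measurement QC flags collected during preprocessing."""

    measurement_id: str
    n_cosmic_flagged: int = 0
    cosmic_warning: bool = False
    baseline_converged: bool = True
    baseline_iterations: int = 0
    area_before: float = 0.0


def subtract_dark(spec: SpectrumRecord, dark: np.ndarray) -> SpectrumRecord:
    """Subtract the detector dark spectrum; negatives are permitted."""
    dark = np.asarray(dark, dtype=float)
    if dark.shape != spec.intensities.shape:
        raise ShapeError(
            f"{spec.measurement_id}: dark spectrum length {dark.size} != "
            f"spectrum length {spec.intensities.size}"
        )
    return spec.with_intensities(spec.intensities - dark)


def _flag_cosmic(y: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    # reflect (not nearest) padding: an edge spike must not pad itself
    # into its own window, or it becomes its own running median
    med = median_filter(y, size=cfg.cosmic_window, mode="reflect")
    resid = y - med
    mad = np.median(np.abs(resid - np.median(resid)))
    sigma = 1.4826 * mad
    span = float(y.max() - y.min())
    floor = cfg.cosmic_floor * span
    if sigma <= 0:
        return np.abs(resid) > floor if span > 0 else np.zeros_like(y, bool)
    return (np.abs(resid) > cfg.cosmic_k * sigma) & (np.abs(resid) > floor)


def remove_cosmic_rays(
    spec: SpectrumRecord, cfg: PreprocessConfig | None = None
) -> tuple[SpectrumRecord, SpectrumFlags]:
    """Detect and repair cosmic-ray spikes.

    Points whose deviation from a running median exceeds ``cosmic_k`` robust
    standard deviations (MAD-based) *and* the relative amplitude floor are
    replaced by linear interpolation between the nearest unflagged
    neighbours (edge spikes take the nearest unflagged value). If more than
    ``cosmic_max_fraction`` of points would be flagged the spectrum is
    returned unchanged with a warning flag — a spectrum that dissimilar to
    its running median is not spike-corrupted but structurally odd.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    y = spec.intensities
    if y.size <= cfg.cosmic_window:
        raise ConfigError(
            f"{spec.measurement_id}: spectrum shorter than cosmic_window"
        )
    flags = SpectrumFlags(spec.measurement_id)
    bad = _flag_cosmic(y, cfg)
    n_bad = int(bad.sum())
    flags.n_cosmic_flagged = n_bad
    if n_bad == 0:
        return spec, flags
    if n_bad > cfg.cosmic_max_fraction * y.size:
        flags.cosmic_warning = True
        return spec, flags
    idx = np.arange(y.size)
    repaired = y.copy()
    # np.interp extends with the nearest good value beyond the ends
    repaired[bad] = np.interp(idx[bad], idx[~bad], y[~bad])
    return spec.with_intensities(repaired), flags


def smooth_spectrum(spec: SpectrumRecord, cfg: PreprocessConfig | None = None) -> SpectrumRecord:
    """Savitzky–Golay smoothing; ``smooth_window=1`` disables the filter.

    Endpoints are handled by fitting the polynomial to the truncated window
    (scipy's ``interp`` mode), so polynomials up to ``smooth_polyorder`` are
    reproduced exactly everywhere.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    if cfg.smooth_window == 1:
        return spec
    if cfg.smooth_window > spec.intensities.size:
        raise ConfigError(
            f"{spec.measurement_id}: smooth_window {cfg.smooth_window} exceeds "
            f"spectrum length {spec.intensities.size}"
        )
    smoothed = savgol_filter(
        spec.intensities, cfg.smooth_window, cfg.smooth_polyorder, mode="interp"
    )
    return spec.with_intensities(smoothed)


def modpoly_baseline(
    spec: SpectrumRecord, cfg: PreprocessConfig | None = None
) -> tuple[np.ndarray, SpectrumFlags]:
    """Iterative modified-polynomial fluorescence baseline.

    Fits an order-``baseline_order`` least-squares polynomial, clips the
    working spectrum to the fit wherever it lies above it (removing peak
    contributions), and refits, stopping when the maximum relative change of
    the fit drops below ``baseline_tol`` or after ``baseline_max_iter``
    iterations. Returns the baseline evaluated on the grid plus convergence
    flags; non-convergence is flagged, never raised.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    y = spec.intensities.astype(float)
    if y.size <= cfg.baseline_order + 1:
        raise ConfigError(
            f"{spec.measurement_id}: need more than {cfg.baseline_order + 1} points"
        )
    # rescale the abscissa to [-1, 1] for numeric conditioning
    w = spec.wavenumbers
    x = 2.0 * (w - w[0]) / (w[-1] - w[0]) - 1.0
    vander = np.polynomial.polynomial.polyvander(x, cfg.baseline_order)
    # the design never changes across iterations: prefactor once
    q, r = np.linalg.qr(vander)

    flags = SpectrumFlags(spec.measurement_id)
    fit = q @ (q.T @ y)
    converged = False
    iteration = 0
    for iteration in range(1, cfg.baseline_max_iter + 1):
        # clip the original spectrum against the current fit: intensities
        # above the fit (peaks) are replaced by the fit value before refitting
        work = np.minimum(y, fit)
        new_fit = q @ (q.T @ work)
        scale = max(float(np.max(np.abs(new_fit))), np.finfo(float).tiny)
        delta = float(np.max(np.abs(new_fit - fit))) / scale
        fit = new_fit
        if delta < cfg.baseline_tol:
            converged = True
            break
    flags.baseline_converged = converged
    flags.baseline_iterations = iteration
    return fit, flags


def correct_intensity_response(spec: SpectrumRecord, response: np.ndarray) -> SpectrumRecord:
    """Divide by the spectrometer's relative intensity response.

    The response is normalized to unit mean first, so its overall scale is
    irrelevant (only its shape matters — a calibrated-lamp measurement is
    known up to a constant).
    """
    response = np.asarray(response, dtype=float)
    if response.shape != spec.intensities.shape:
        raise ShapeError(
            f"{spec.measurement_id}: response length {response.size} != "
            f"spectrum length {spec.intensities.size}"
        )
    if np.any(response <= 0):
        raise CalibrationError(
            f"{spec.measurement_id}: response curve must be strictly positive"
        )
    return spec.with_intensities(spec.intensities / (response / response.mean()))


def crop_spectrum(spec: SpectrumRecord, lo: float, hi: float) -> SpectrumRecord:
    """Retain exactly the grid points with lo ≤ w ≤ hi (inclusive)."""
    if lo >= hi:
        raise RangeError(f"crop range [{lo}, {hi}] must be increasing")
    keep = (spec.wavenumbers >= lo) & (spec.wavenumbers <= hi)
    if keep.sum() < 2:
        raise RangeError(
            f"{spec.measurement_id}: fewer than 2 grid points inside [{lo}, {hi}]"
        )
    return dataclasses.replace(
        spec, wavenumbers=spec.wavenumbers[keep], intensities=spec.intensities[keep]
    )


def normalize_area(spec: SpectrumRecord) -> SpectrumRecord:
    """Scale so the trapezoid area under the curve equals one; marks the
    spectrum preprocessed."""
    area = spec.area()
    if area <= 0:
        raise NormalizationError(
            f"{spec.measurement_id}: non-positive area {area:.3e}, cannot normalize"
        )
    return spec.with_intensities(spec.intensities / area, stage=Stage.PREPROCESSED)


def preprocess_dataset(
    ds: SpectraDataset, cfg: PreprocessConfig | None = None
) -> tuple[SpectraDataset, list[SpectrumFlags]]:
    """Run the full chain on every spectrum of a raw dataset.

    Returns a new dataset (the input is untouched) plus per-measurement QC
    flags. Any stage failure is re-raised as a PreprocessError naming the
    offending measurement.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    for s in ds.spectra:
        if s.stage is not Stage.RAW:
            raise PreprocessError(
                f"measurement {s.measurement_id} is already preprocessed"
            )
    out: list[SpectrumRecord] = []
    all_flags: list[SpectrumFlags] = []
    for spec in ds.spectra:
        try:
            if cfg.dark_spectrum is not None:
                spec = subtract_dark(spec, cfg.dark_spectrum)
            spec, flags = remove_cosmic_rays(spec, cfg)
            spec = smooth_spectrum(spec, cfg)
            baseline, bflags = modpoly_baseline(spec, cfg)
            spec = spec.with_intensities(spec.intensities - baseline)
            flags.baseline_converged = bflags.baseline_converged
            flags.baseline_iterations = bflags.baseline_iterations
            if cfg.response_curve is not None:
                spec = correct_intensity_response(spec, cfg.response_curve)
            spec = crop_spectrum(spec, *cfg.crop)
            flags.area_before = spec.area()
            spec = normalize_area(spec)
        except PreprocessError:
            raise
        except Exception as exc:
            raise PreprocessError(f"measurement {spec.measurement_id}: {exc}") from exc
        out.append(spec)
        all_flags.append(flags)
    return SpectraDataset(spectra=out, lesions=list(ds.lesions)), all_flags
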