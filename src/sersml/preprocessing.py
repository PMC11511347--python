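"""Spectrum conditioning: crop, baseline correction, smoothing, standardization.

The pipeline applied to every spectrum, in order:

1. crop to the fingerprint region (200-1700 cm^-1 by default),
2. subtract an iteratively fitted quintic polynomial baseline,
3. Savitzky-Golay smoothing (window 5, degree 2),
4. z-standardization of the whole spectrum,
       I_std = (I_j - mean(I)) / sd(I)
   with the sample standard deviation, so every conditioned spectrum has
   mean 0 and sd 1 regardless of measurement-to-measurement intensity scale.

Each step is exposed as a plain function on arrays; :class:`RamanPreprocessor`
wraps the chain as a scikit-learn transformer operating row-wise on an
``(n_spectra, n_shifts)`` matrix.  Preprocessing of one spectrum never looks
at any other spectrum.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numpy.polynomial import Polynomial
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import SpectrumSet


@dataclasses.dataclass
class PreprocessConfig:
    crop_lo: float = 200.0
    crop_hi: float = 1700.0
    baseline_degree: int = 5
    sg_window: int = 5
    sg_degree: int = 2
    baseline_max_iter: int = 100
    baseline_tol: float = 1e-4
    apply_baseline: bool = True
    apply_smooth: bool = True

    def __post_init__(self) -> None:
        if self.crop_lo >= self.crop_hi:
            raise ValueError("crop_lo must be < crop_hi")
        if self.baseline_degree < 0:
            raise ValueError("baseline_degree must be >= 0")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_degree:
            raise ValueError(
                f"sg_window must be odd and > sg_degree "
                f"(got window={self.sg_window}, degree={self.sg_degree})"
            )


def crop(shifts: np.ndarray, intensities: np.ndarray, lo: float, hi: float):
    """Restrict to the closed shift interval [lo, hi].

    ``intensities`` may be 1-D (one spectrum) or 2-D (rows are spectra).
    Raises if no grid point falls inside the window.
    """
    shifts = np.asarray(shifts, float)
    intensities = np.asarray(intensities, float)
    mask = (shifts >= lo) & (shifts <= hi)
    if not mask.any():
        raise ValueError(
            f"crop window [{lo}, {hi}] cm^-1 contains no grid points "
            f"(grid spans [{shifts.min()}, {shifts.max()}])"
        )
    return shifts[mask], intensities[..., mask]


def fit_baseline(
    shifts: np.ndarray,
    intensities: np.ndarray,
    degree: int = 5,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> np.ndarray:
    """Iterative peak-suppressed polynomial baseline (ModPoly-style).

    Repeatedly least-squares fits a degree-``degree`` polynomial and clips
    the working signal at the fit wherever it lies above it, so peaks stop
    pulling the fit upward; stops when the maximum relative coefficient
    change drops below ``tol`` or after ``max_iter`` passes.  Deterministic.
    """
    shifts = np.asarray(shifts, float)
    y = np.asarray(intensities, float)
    if y.size < degree + 1:
        raise ValueError(
            f"baseline fit needs at least {degree + 1} points, got {y.size}"
        )
    work = y.copy()
    prev_coef = None
    baseline = work
    for _ in range(max_iter):
        poly = Polynomial.fit(shifts, work, degree)
        baseline = poly(shifts)
        coef = poly.coef  # coefficients in the scaled window basis
        if prev_coef is not None:
            scale = max(np.max(np.abs(prev_coef)), np.finfo(float).tiny)
            if np.max(np.abs(coef - prev_coef)) / scale < tol:
                break
        prev_coef = coef
        work = np.minimum(work, baseline)
    return baseline


def correct_baseline(
    shifts: np.ndarray,
    intensities: np.ndarray,
    config: PreprocessConfig | None = None,
) -> np.ndarray:
    """Subtract the fitted polynomial baseline from one spectrum."""
    config = config or PreprocessConfig()
    baseline = fit_baseline(
        shifts,
        intensities,
        degree=config.baseline_degree,
        max_iter=config.baseline_max_iter,
        tol=config.baseline_tol,
    )
    return np.asarray(intensities, float) - baseline


def smooth_sg(intensities: np.ndarray, window: int = 5, degree: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing; output length equals input length.

    Edges are handled by evaluating the edge-window polynomial fit, so
    polynomials up to ``degree`` pass through unchanged everywhere.
    """
    if window % 2 == 0 or window <= degree:
        raise ValueError(f"window must be odd and > degree (got {window}, {degree})")
    y = np.asarray(intensities, float)
    if y.shape[-1] < window:
        raise ValueError(f"spectrum length {y.shape[-1]} < window {window}")
    return savgol_filter(y, window_length=window, polyorder=degree, mode="interp")


def standardize(intensities: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Whole-spectrum z-score with sample sd; returns (standardized, mean, sd)."""
    y = np.asarray(intensities, float)
    if y.size < 2:
        raise ValueError("standardization needs at least 2 points")
    mean = float(y.mean())
    sd = float(y.std(ddof=1))
    # relative threshold: a numerically constant spectrum (e.g. the exact
    # residual of baseline-correcting a flat trace) is also degenerate
    if sd <= 1e-12 * max(1.0, abs(mean)):
        raise ValueError("zero-variance spectrum cannot be standardized")
    return (y - mean) / sd, mean, sd


def preprocess_spectrum(
    shifts: np.ndarray,
    intensities: np.ndarray,
    config: PreprocessConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """crop -> baseline -> smooth -> standardize for a single spectrum."""
    config = config or PreprocessConfig()
    s, y = crop(shifts, intensities, config.crop_lo, config.crop_hi)
    if config.apply_baseline:
        y = correct_baseline(s, y, config)
    if config.apply_smooth:
        y = smooth_sg(y, config.sg_window, config.sg_degree)
    y, _, _ = standardize(y)
    return s, y


def preprocess_set(sset: SpectrumSet, config: PreprocessConfig | None = None) -> SpectrumSet:
    """Apply the conditioning chain to every spectrum of a set.

    Labels and spectrum order are preserved; failures are re-raised with the
    offending spectrum's id.
    """
    config = config or PreprocessConfig()
    if sset.n_spectra == 0:
        s, _ = crop(sset.shifts, np.zeros_like(sset.shifts), config.crop_lo, config.crop_hi)
        return sset.with_intensities(np.empty((0, s.size)), shifts=s)
    out_rows = []
    out_shifts = None
    for i in range(sset.n_spectra):
        sid = sset.labels["spectrum_id"].iloc[i]
        try:
            s, y = preprocess_spectrum(sset.shifts, sset.intensities[i], config)
        except ValueError as exc:
            raise ValueError(f"preprocessing failed for spectrum {sid!r}: {exc}") from exc
        out_shifts = s
        out_rows.append(y)
    return sset.with_intensities(np.vstack(out_rows), shifts=out_shifts)


class RamanPreprocessor(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer view of the conditioning chain.

    Operates row-wise on an ``(n_spectra, n_shifts)`` matrix; the shift grid
    is passed at construction because it is column metadata, not data.
    Stateless across samples: ``fit`` only resolves the crop mask.
    """

    def __init__(
        self,
        shifts=None,
        crop_lo: float = 200.0,
        crop_hi: float = 1700.0,
        baseline_degree: int = 5,
        sg_window: int = 5,
        sg_degree: int = 2,
        baseline_max_iter: int = 100,
        baseline_tol: float = 1e-4,
        apply_baseline: bool = True,
        apply_smooth: bool = True,
    ):
        self.shifts = shifts
        self.crop_lo = crop_lo
        self.crop_hi = crop_hi
        self.baseline_degree = baseline_degree
        self.sg_window = sg_window
        self.sg_degree = sg_degree
        self.baseline_max_iter = baseline_max_iter
        self.baseline_tol = baseline_tol
        self.apply_baseline = apply_baseline
        self.apply_smooth = apply_smooth

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            crop_lo=self.crop_lo,
            crop_hi=self.crop_hi,
            baseline_degree=self.baseline_degree,
            sg_window=self.sg_window,
            sg_degree=self.sg_degree,
            baseline_max_iter=self.baseline_max_iter,
            baseline_tol=self.baseline_tol,
            apply_baseline=self.apply_baseline,
            apply_smooth=self.apply_smooth,
        )

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, float))
        if self.shifts is None:
            raise ValueError("RamanPreprocessor requires the shift grid (shifts=...)")
        shifts = np.asarray(self.shifts, float)
        if shifts.shape[0] != X.shape[1]:
            raise ValueError(
                f"shift grid length {shifts.shape[0]} does not match n_features {X.shape[1]}"
            )
        cfg = self._config()  # validates parameters
        self.shifts_out_, _ = crop(shifts, np.zeros_like(shifts), cfg.crop_lo, cfg.crop_hi)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "shifts_out_")
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; transformer was fitted with {self.n_features_in_}"
            )
        cfg = self._config()
        shifts = np.asarray(self.shifts, float)
        return np.vstack(
            [preprocess_spectrum(shifts, row, cfg)[1] for row in X]
        )
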