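"""Pre-processing: pressure-axis resampling, vectorization, standardization.

Raw surfaces arrive on irregular pressure axes (artefact rejection and probe
fit make device sweeps unevenly sampled). Each frequency row is moved onto
the canonical 51-point pressure grid with a monotone-preserving piecewise
cubic Hermite interpolant (PCHIP), then surfaces are flattened to
length-5457 feature vectors (frequency-major) and standardized.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .grids import N_FREQ, N_POINTS, N_PRESS, PressureGrid, make_canonical_grids
from .surface import Cohort, WaiSurface

logger = logging.getLogger(__name__)

MIN_PRESSURE_SAMPLES = 4


def resample_pressure(surface: WaiSurface, target: PressureGrid | None = None) -> WaiSurface:
    """Resample one surface onto the canonical pressure grid.

    Each frequency row is interpolated independently with PCHIP, which
    preserves monotonicity and does not overshoot, evaluated at the 51
    canonical pressures. Beyond the measured pressure range the boundary
    value is held constant (no cubic extrapolation). Output is clipped to
    [0, 1].

    Raises ``ValueError`` for surfaces with fewer than 4 distinct pressure
    samples (incomplete sweep; the record should be rejected).
    """
    if target is None:
        _, target = make_canonical_grids()
    raw_p = surface.press_grid.values
    if np.unique(raw_p).size < MIN_PRESSURE_SAMPLES:
        raise ValueError(
            f"ear {surface.meta.ear_id}: only {np.unique(raw_p).size} distinct pressure "
            f"samples (< {MIN_PRESSURE_SAMPLES}); incomplete sweep"
        )
    interpolant = PchipInterpolator(raw_p, surface.absorbance, axis=1, extrapolate=True)
    # clamp evaluation points into the measured range -> constant boundary values
    eval_p = np.clip(target.values, raw_p[0], raw_p[-1])
    values = np.clip(interpolant(eval_p), 0.0, 1.0)
    return WaiSurface(values, surface.freq_grid, target, surface.meta)


def preprocess_cohort(cohort: Cohort) -> tuple[Cohort, list[str]]:
    """Resample every surface onto the canonical grids.

    Returns the canonical cohort and a rejection log (one line per record
    dropped for an incomplete pressure sweep).
    """
    surfaces = []
    rejections: list[str] = []
    for surface in cohort:
        try:
            surfaces.append(resample_pressure(surface))
        except ValueError as exc:
            rejections.append(str(exc))
            logger.warning("rejecting record: %s", exc)
    return Cohort(surfaces), rejections


@dataclass(frozen=True)
class ScalerState:
    """Per-feature standardization state (mean, sd) fit on training data."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must have the same shape")


def vectorize(surface: WaiSurface) -> np.ndarray:
    """Flatten a canonical surface to a length-5457 vector.

    Frequency-major order: ``vector[f_idx * 51 + p_idx]``, so forest
    importances map back to grid coordinates deterministically.
    """
    if not surface.is_canonical:
        raise ValueError(f"ear {surface.meta.ear_id} is not on the canonical grids")
    return surface.absorbance.reshape(N_POINTS).copy()


def devectorize(vector: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize`, returning the 107 x 51 matrix."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (N_POINTS,):
        raise ValueError(f"expected a length-{N_POINTS} vector, got shape {vector.shape}")
    return vector.reshape(N_FREQ, N_PRESS)


def vectorize_cohort(cohort: Cohort) -> np.ndarray:
    """Stack a canonical cohort into an (n_ears, 5457) design matrix."""
    return cohort.stack().reshape(len(cohort), N_POINTS)


def fit_scaler(train_vectors: np.ndarray) -> ScalerState:
    """Fit zero-mean/unit-variance standardization on training vectors only.

    Features with sd < 1e-12 are centred but not scaled (their transformed
    training values are exactly 0).
    """
    train_vectors = np.asarray(train_vectors, dtype=float)
    if train_vectors.ndim != 2 or train_vectors.shape[0] < 2:
        raise ValueError("need at least 2 training vectors to fit a scaler")
    mean = train_vectors.mean(axis=0)
    sd = train_vectors.std(axis=0)
    degenerate = sd < 1e-12
    # centre degenerate features on their (constant) value so they map to 0
    mean = np.where(degenerate, train_vectors[0], mean)
    sd = np.where(degenerate, 1.0, sd)
    return ScalerState(mean=mean, sd=sd)


def apply_scaler(vectors: np.ndarray, state: ScalerState) -> np.ndarray:
    vectors = np.asarray(vectors, dtype=float)
    return (vectors - state.mean) / state.sd
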