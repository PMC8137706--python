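"""Canonical frequency and pressure grids for WAI frequency-pressure images.

The measurement surface is discretised on 107 frequency bins spanning
226-8000 Hz (geometric spacing) and 51 ear-canal pressures from -300 to
+200 daPa in 10-daPa steps, i.e. 5457 grid points per ear.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_FREQ = 107
N_PRESS = 51
N_POINTS = N_FREQ * N_PRESS  # 5457

FREQ_MIN_HZ = 226.0
FREQ_MAX_HZ = 8000.0
PRESS_MIN_DAPA = -300.0
PRESS_MAX_DAPA = 200.0
PRESS_STEP_DAPA = 10.0


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing probe frequencies in Hz.

    The canonical grid is geometric: constant ratio between consecutive
    centres, 226 Hz up to 8000 Hz over 107 bins.
    """

    centres: np.ndarray

    def __post_init__(self) -> None:
        centres = np.asarray(self.centres, dtype=float)
        if centres.ndim != 1 or centres.size < 2:
            raise ValueError("frequency grid must be a 1-D array with >= 2 centres")
        if not np.all(np.diff(centres) > 0):
            raise ValueError("frequency centres must be strictly increasing")
        object.__setattr__(self, "centres", centres)

    def __len__(self) -> int:
        return self.centres.size

    def nearest_index(self, freq_hz: float) -> int:
        """Index of the bin closest to ``freq_hz`` in log-frequency."""
        return int(np.argmin(np.abs(np.log2(self.centres) - np.log2(freq_hz))))


@dataclass(frozen=True)
class PressureGrid:
    """Strictly increasing ear-canal pressures in daPa."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("pressure grid must be a non-empty 1-D array")
        if values.size > 1 and not np.all(np.diff(values) > 0):
            raise ValueError("pressure values must be strictly increasing")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    def nearest_index(self, press_dapa: float) -> int:
        return int(np.argmin(np.abs(self.values - press_dapa)))


def make_canonical_grids() -> tuple[FrequencyGrid, PressureGrid]:
    """Return the canonical (107-frequency, 51-pressure) grid pair.

    Frequencies are geometrically spaced from 226 to 8000 Hz; pressures run
    -300..+200 daPa in 10-daPa steps. 107 x 51 = 5457 points.
    """
    k = np.arange(N_FREQ)
    freqs = FREQ_MIN_HZ * (FREQ_MAX_HZ / FREQ_MIN_HZ) ** (k / (N_FREQ - 1))
    # pin the endpoints exactly
    freqs[0] = FREQ_MIN_HZ
    freqs[-1] = FREQ_MAX_HZ
    pressures = np.arange(PRESS_MIN_DAPA, PRESS_MAX_DAPA + PRESS_STEP_DAPA, PRESS_STEP_DAPA)
    return FrequencyGrid(freqs), PressureGrid(pressures)


def is_canonical(freq_grid: FrequencyGrid, press_grid: PressureGrid, *, atol: float = 1e-9) -> bool:
    ref_f, ref_p = make_canonical_grids()
    if len(freq_grid) != N_FREQ or len(press_grid) != N_PRESS:
        return False
    return bool(
        np.allclose(freq_grid.centres, ref_f.centres, rtol=0, atol=atol * FREQ_MAX_HZ)
        and np.allclose(press_grid.values, ref_p.values, rtol=0, atol=atol)
    )
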