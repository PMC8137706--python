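"""Per-ear absorbance surfaces and labelled cohorts."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .grids import FrequencyGrid, PressureGrid, is_canonical

LABELS = ("normal", "ome", "unknown")
SIDES = ("L", "R")


@dataclass(frozen=True)
class EarMeta:
    """Manifest metadata for one measured ear."""

    ear_id: str
    participant_id: str
    side: str
    age: float
    label: str

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass(frozen=True)
class WaiSurface:
    """One ear's absorbance matrix, indexed [frequency, pressure].

    Absorbance is the fraction of incident acoustic energy absorbed by the
    middle ear, so every entry lies in [0, 1]. ``absorbance[i, j]`` is the
    value at ``freq_grid.centres[i]`` Hz and ``press_grid.values[j]`` daPa.
    """

    absorbance: np.ndarray
    freq_grid: FrequencyGrid
    press_grid: PressureGrid
    meta: EarMeta

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        expected = (len(self.freq_grid), len(self.press_grid))
        if a.shape != expected:
            raise ValueError(f"absorbance shape {a.shape} != grid shape {expected}")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"non-finite absorbance in ear {self.meta.ear_id}")
        if a.min() < -1e-6 or a.max() > 1 + 1e-6:
            raise ValueError(
                f"absorbance outside [0, 1] in ear {self.meta.ear_id}: "
                f"range [{a.min():.4g}, {a.max():.4g}]"
            )
        object.__setattr__(self, "absorbance", np.clip(a, 0.0, 1.0))

    @property
    def is_canonical(self) -> bool:
        return is_canonical(self.freq_grid, self.press_grid)


@dataclass
class Cohort:
    """A labelled collection of per-ear surfaces."""

    surfaces: list[WaiSurface]

    def __post_init__(self) -> None:
        ids = [s.meta.ear_id for s in self.surfaces]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ear_id in cohort")

    def __len__(self) -> int:
        return len(self.surfaces)

    def __iter__(self) -> Iterator[WaiSurface]:
        return iter(self.surfaces)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {"normal": 0, "ome": 0, "unknown": 0}
        for s in self.surfaces:
            counts[s.meta.label] += 1
        return {k: v for k, v in counts.items() if v or k in ("normal", "ome")}

    @property
    def labels(self) -> np.ndarray:
        """Binary labels: normal -> 0, OME -> 1 (errors on unknown)."""
        out = np.empty(len(self.surfaces), dtype=int)
        for i, s in enumerate(self.surfaces):
            if s.meta.label == "normal":
                out[i] = 0
            elif s.meta.label == "ome":
                out[i] = 1
            else:
                raise ValueError(f"ear {s.meta.ear_id} has label 'unknown'")
        return out

    def subset(self, label: str) -> "Cohort":
        return Cohort([s for s in self.surfaces if s.meta.label == label])

    def stack(self) -> np.ndarray:
        """Stack canonical surfaces into an (n_ears, n_freq, n_press) array."""
        if not self.surfaces:
            raise ValueError("empty cohort")
        if not all(s.is_canonical for s in self.surfaces):
            raise ValueError("all surfaces must be on the canonical grids; run preprocessing")
        return np.stack([s.absorbance for s in self.surfaces])
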