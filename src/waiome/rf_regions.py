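"""Random-forest importance maps for discriminative-region extraction.

Ten forests of increasing size (10..500 trees) are fit on the full
vectorized cohort; their normalized impurity-decrease feature importances
are averaged and reshaped onto the 107 x 51 grid. The averaged map is
overlaid with the top-5%/10% p-value regions from the rank-sum map, the
point of the comparison being that two unrelated procedures select nearly
the same frequency-pressure regions.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .grids import N_FREQ, N_POINTS, N_PRESS
from .preprocess import vectorize_cohort
from .statmap import RegionMask, StatMap, top_k_mask_from_scores, top_k_region
from .surface import Cohort

DEFAULT_TREE_COUNTS = (10, 20, 30, 40, 50, 100, 200, 300, 400, 500)


@dataclass(frozen=True)
class ImportanceMap:
    """Averaged per-grid-point forest importances (non-negative, sums to 1)."""

    imp: np.ndarray
    tree_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.imp.shape != (N_FREQ, N_PRESS):
            raise ValueError("importance map must be 107 x 51")
        if self.imp.min() < 0:
            raise ValueError("importances must be non-negative")


def importance_map(
    cohort: Cohort,
    tree_counts: Sequence[int] = DEFAULT_TREE_COUNTS,
    seed: int = 0,
    importance: str = "impurity",
) -> ImportanceMap:
    """Average normalized feature importances over forests of varying size.

    Each forest is fit on the full vectorized two-class cohort (feature
    selection usage, not cross-validated). ``importance="impurity"`` uses
    normalized mean-impurity-decrease (the forest default);
    ``importance="permutation"`` is available as a slower alternative.
    Deterministic given (cohort, tree_counts, seed).
    """
    y = cohort.labels
    if len(np.unique(y)) < 2:
        raise ValueError("importance_map needs both classes present")
    X = vectorize_cohort(cohort)
    rng = np.random.default_rng(seed)
    maps = []
    for n_trees in tree_counts:
        forest = RandomForestClassifier(
            n_estimators=int(n_trees),
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(X, y)
        if importance == "impurity":
            imp = forest.feature_importances_
        elif importance == "permutation":
            result = permutation_importance(
                forest, X, y, n_repeats=5, random_state=int(rng.integers(2**31 - 1)), n_jobs=1
            )
            imp = np.maximum(result.importances_mean, 0.0)
        else:
            raise ValueError(f"unknown importance kind {importance!r}")
        total = imp.sum()
        if total > 0:
            imp = imp / total
        maps.append(imp.reshape(N_FREQ, N_PRESS))
    return ImportanceMap(imp=np.mean(maps, axis=0), tree_counts=tuple(int(t) for t in tree_counts))


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


@dataclass(frozen=True)
class OverlaySummary:
    """Importance-based and p-value-based masks and their agreement."""

    p_masks: dict[float, RegionMask]
    imp_masks: dict[float, RegionMask]
    jaccard: dict[float, float]


def overlay_regions(
    imp_map: ImportanceMap,
    statmap: StatMap,
    fractions: Sequence[float] = (0.05, 0.10),
) -> OverlaySummary:
    """Compare top-importance and lowest-p regions at the given fractions."""
    p_masks: dict[float, RegionMask] = {}
    imp_masks: dict[float, RegionMask] = {}
    overlaps: dict[float, float] = {}
    for fraction in fractions:
        pm = top_k_region(statmap, fraction)
        im = top_k_mask_from_scores(imp_map.imp, fraction)
        p_masks[fraction] = pm
        imp_masks[fraction] = im
        overlaps[fraction] = jaccard(pm.mask, im.mask)
    return OverlaySummary(p_masks=p_masks, imp_masks=imp_masks, jaccard=overlaps)
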