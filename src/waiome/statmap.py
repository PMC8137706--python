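"""Pointwise two-sample rank-sum maps and top-k% region extraction.

Every one of the 5457 frequency-pressure grid points gets an independent
two-sided Wilcoxon rank-sum test between the normal and OME groups, with
mid-ranks for ties, tie-corrected variance and a continuity correction; for
tiny samples (total N <= 12) the exact permutation distribution of the rank
sum is enumerated instead of the normal approximation. No multiplicity
adjustment is applied by default (the map is descriptive); an optional
Benjamini-Hochberg adjustment is available for sensitivity analysis.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import ndtr
from scipy.stats import rankdata

from .grids import N_FREQ, N_POINTS, N_PRESS
from .surface import Cohort

EXACT_MAX_N = 12


def _tie_term(values: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups."""
    _, counts = np.unique(values, return_counts=True)
    counts = counts[counts > 1]
    return float(np.sum(counts**3 - counts))


def _normal_zp(w: float, n0: int, n1: int, tie_term: float) -> tuple[float, float]:
    n = n0 + n1
    mean_w = n0 * (n + 1) / 2.0
    var_w = n0 * n1 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:  # all observations identical
        return 0.0, 1.0
    diff = w - mean_w
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var_w)
    p = float(min(1.0, 2.0 * ndtr(-abs(z))))
    return float(z), p


def _exact_p(ranks: np.ndarray, n0: int) -> float:
    """Two-sided exact permutation p-value of the rank sum of group 0.

    Enumerates all C(N, n0) assignments of the (mid-)ranks to group 0;
    p = min(1, 2 * min(P(W <= w_obs), P(W >= w_obs))).
    """
    n = ranks.size
    w_obs = float(np.sum(ranks[:n0]))
    sums = np.array([sum(c) for c in combinations(ranks, n0)])
    eps = 1e-9
    p_le = np.mean(sums <= w_obs + eps)
    p_ge = np.mean(sums >= w_obs - eps)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def rank_sum_test(x: np.ndarray, y: np.ndarray, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(z, p)`` where ``z`` is the standardized rank-sum statistic of
    ``x`` (continuity-corrected, tie-corrected variance) and ``p`` the
    two-sided p-value. ``method`` is ``"auto"`` (exact permutation
    distribution when len(x)+len(y) <= 12, normal approximation otherwise),
    ``"exact"`` or ``"normal"``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise ValueError("rank_sum_test needs at least 2 observations per sample")
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)  # mid-ranks for ties
    w = float(np.sum(ranks[: x.size]))
    z, p = _normal_zp(w, x.size, y.size, _tie_term(combined))
    use_exact = method == "exact" or (method == "auto" and combined.size <= EXACT_MAX_N)
    if use_exact:
        p = _exact_p(ranks, x.size)
    return z, p


@dataclass(frozen=True)
class StatMap:
    """Per-grid-point standardized statistics and two-sided p-values."""

    z: np.ndarray  # 107 x 51
    p: np.ndarray  # 107 x 51
    n0: int  # normal group size
    n1: int  # OME group size

    def __post_init__(self) -> None:
        if self.z.shape != (N_FREQ, N_PRESS) or self.p.shape != (N_FREQ, N_PRESS):
            raise ValueError("stat map fields must be 107 x 51")
        if self.p.min() < 0 or self.p.max() > 1:
            raise ValueError("p-values must lie in [0, 1]")

    def significant_fraction(self, alpha: float = 0.05) -> float:
        return float(np.mean(self.p < alpha))

    def significant_count(self, alpha: float = 0.05) -> int:
        return int(np.sum(self.p < alpha))


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    flat = p.ravel()
    m = flat.size
    order = np.argsort(flat, kind="stable")
    adjusted = np.empty(m)
    adjusted[order] = flat[order] * m / np.arange(1, m + 1)
    adjusted[order] = np.minimum.accumulate(adjusted[order][::-1])[::-1]
    return np.minimum(adjusted, 1.0).reshape(p.shape)


def significance_map(cohort: Cohort, adjust: str | None = None) -> StatMap:
    """Rank-sum test at every canonical grid point, normal vs OME.

    ``adjust=None`` (default) reports raw per-point p-values; ``adjust="bh"``
    applies a Benjamini-Hochberg adjustment across the 5457 points.
    """
    normal = cohort.subset("normal")
    ome = cohort.subset("ome")
    if len(normal) < 2 or len(ome) < 2:
        raise ValueError("significance_map needs >= 2 ears in each class")
    x = normal.stack().reshape(len(normal), N_POINTS)  # (n0, 5457)
    y = ome.stack().reshape(len(ome), N_POINTS)
    n0, n1 = x.shape[0], y.shape[0]
    n = n0 + n1
    combined = np.vstack([x, y])
    if n <= EXACT_MAX_N:
        z = np.empty(N_POINTS)
        p = np.empty(N_POINTS)
        for j in range(N_POINTS):
            z[j], p[j] = rank_sum_test(x[:, j], y[:, j])
    else:
        ranks = rankdata(combined, axis=0)
        w = ranks[:n0].sum(axis=0)
        mean_w = n0 * (n + 1) / 2.0
        tie_terms = np.fromiter(
            (_tie_term(combined[:, j]) for j in range(N_POINTS)), float, count=N_POINTS
        )
        var_w = n0 * n1 / 12.0 * ((n + 1) - tie_terms / (n * (n - 1)))
        diff = w - mean_w
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(var_w > 0, (diff - 0.5 * np.sign(diff)) / np.sqrt(var_w), 0.0)
        p = np.minimum(1.0, 2.0 * ndtr(-np.abs(z)))
    p = p.reshape(N_FREQ, N_PRESS)
    z = z.reshape(N_FREQ, N_PRESS)
    if adjust == "bh":
        p = _benjamini_hochberg(p)
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return StatMap(z=z, p=p, n0=n0, n1=n1)


@dataclass(frozen=True)
class RegionMask:
    """Boolean top-k% selection over the canonical grid."""

    mask: np.ndarray
    fraction: float
    k: int

    def __post_init__(self) -> None:
        if self.mask.shape != (N_FREQ, N_PRESS):
            raise ValueError("mask must be 107 x 51")
        if int(self.mask.sum()) != self.k:
            raise ValueError("mask cardinality does not match k")


def round_half_away(x: float) -> int:
    """round() with halves away from zero, so 0.10 * 5457 = 545.7 -> 546."""
    return int(math.floor(abs(x) + 0.5) * math.copysign(1, x))


def top_k_region(statmap: StatMap, fraction: float) -> RegionMask:
    """Select the k = round(fraction * 5457) points with the smallest p-values.

    Deterministic tie-break: smaller p first, then larger |z|, then
    frequency index, then pressure index.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    k = round_half_away(fraction * N_POINTS)
    p = statmap.p.ravel()
    z = statmap.z.ravel()
    f_idx, p_idx = np.divmod(np.arange(N_POINTS), N_PRESS)
    # np.lexsort sorts by the last key first
    order = np.lexsort((p_idx, f_idx, -np.abs(z), p))
    mask = np.zeros(N_POINTS, dtype=bool)
    mask[order[:k]] = True
    return RegionMask(mask=mask.reshape(N_FREQ, N_PRESS), fraction=fraction, k=k)


def top_k_mask_from_scores(scores: np.ndarray, fraction: float) -> RegionMask:
    """Top-k mask of the *largest* scores (e.g. forest importances)."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    k = round_half_away(fraction * N_POINTS)
    flat = np.asarray(scores, dtype=float).ravel()
    if flat.size != N_POINTS:
        raise ValueError("score map must cover the canonical grid")
    f_idx, p_idx = np.divmod(np.arange(N_POINTS), N_PRESS)
    order = np.lexsort((p_idx, f_idx, -flat))
    mask = np.zeros(N_POINTS, dtype=bool)
    mask[order[:k]] = True
    return RegionMask(mask=mask.reshape(N_FREQ, N_PRESS), fraction=fraction, k=k)


def region_class_means(cohort: Cohort, mask: RegionMask) -> tuple[float, float]:
    """Mean absorbance over (selected points x ears), per class.

    Returns ``(mean_normal, mean_ome)``.
    """
    if mask.mask.sum() == 0:
        raise ValueError("empty region mask")
    out = []
    for label in ("normal", "ome"):
        stack = cohort.subset(label).stack()
        out.append(float(stack[:, mask.mask].mean()))
    return out[0], out[1]
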