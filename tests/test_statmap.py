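from itertools import combinations

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, rankdata

from waiome import (
    make_canonical_grids,
    null_cohort,
    rank_sum_test,
    region_class_means,
    significance_map,
    top_k_region,
)
from waiome.statmap import StatMap, round_half_away, top_k_mask_from_scores
from waiome.surface import Cohort, EarMeta, WaiSurface
from waiome.synthetic import ClassTemplate, GeneratorConfig, sample_cohort

FREQ, PRESS = make_canonical_grids()


def permutation_oracle(x, y):
    """Independent two-sided exact p: enumerate all group-0 index subsets.

    Written against the definition (probability, under random relabelling,
    of a rank sum at least as extreme as observed, doubled and capped).
    """
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n0, n = len(x), len(pooled)
    w_obs = ranks[:n0].sum()
    sums = np.array([ranks[list(idx)].sum() for idx in combinations(range(n), n0)])
    p_le = np.mean(sums <= w_obs + 1e-9)
    p_ge = np.mean(sums >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestRankSum:
    def test_identical_multisets_give_null_result(self):
        z, p = rank_sum_test([1, 2, 2, 5], [5, 2, 1, 2])
        assert z == 0.0
        assert p == 1.0

    def test_textbook_exact_case(self):
        """x={1,2}, y={3,4}: W=3 is the most extreme of C(4,2)=6 outcomes."""
        _, p = rank_sum_test([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_exact_mode_matches_permutation_oracle_with_ties(self, rng):
        for _ in range(30):
            x = rng.integers(0, 4, size=6).astype(float)
            y = rng.integers(0, 4, size=6).astype(float)
            _, p = rank_sum_test(x, y)  # N=12 -> exact branch
            assert p == pytest.approx(permutation_oracle(x, y), abs=1e-12)

    def test_normal_approximation_close_to_exact_for_moderate_n(self, rng):
        for _ in range(5):
            x = rng.normal(0, 1, 10)
            y = rng.normal(0.4, 1, 10)
            _, p_normal = rank_sum_test(x, y, method="normal")
            _, p_exact = rank_sum_test(x, y, method="exact")
            assert abs(p_normal - p_exact) < 0.01

    def test_normal_path_agrees_with_scipy(self, rng):
        """Tie-corrected continuity-corrected approximation vs mannwhitneyu."""
        for _ in range(20):
            x = np.round(rng.normal(0, 1, 15), 1)
            y = np.round(rng.normal(0.5, 1, 12), 1)
            _, p = rank_sum_test(x, y, method="normal")
            ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            assert p == pytest.approx(float(ref), abs=1e-10)

    def test_symmetry_in_sample_order(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(1, 1, 9)
        zx, px = rank_sum_test(x, y)
        zy, py = rank_sum_test(y, x)
        assert px == pytest.approx(py, abs=1e-12)
        assert zx == pytest.approx(-zy, abs=1e-12)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([1.0], [2.0, 3.0])


def _two_class_cohort(effect, n_per_class, seed, sigma=0.08):
    flat_a = ClassTemplate(0.5, (), sigma**2, ())
    flat_b = ClassTemplate(0.5 + effect, (), sigma**2, ())
    cfg = GeneratorConfig(
        templates={"normal": flat_a, "ome": flat_b},
        n_normal=n_per_class, n_ome=n_per_class,
        pressure_dropout=0.0, pressure_jitter=0.0,
    )
    return sample_cohort(cfg, seed=seed)


class TestSignificanceMap:
    def test_shape_and_sizes(self):
        smap = significance_map(null_cohort(5, 6, 0))
        assert smap.z.shape == (107, 51)
        assert smap.p.shape == (107, 51)
        assert (smap.n0, smap.n1) == (5, 6)

    def test_single_class_cohort_rejected(self):
        cohort = null_cohort(5, 5, 0)
        with pytest.raises(ValueError):
            significance_map(cohort.subset("normal"))

    def test_small_cohort_uses_exact_branch(self):
        """N<=12 per point: map p equals the pointwise exact test."""
        cohort = null_cohort(3, 3, 4)
        smap = significance_map(cohort)
        x = cohort.subset("normal").stack()[:, 0, 0]
        y = cohort.subset("ome").stack()[:, 0, 0]
        assert smap.p[0, 0] == pytest.approx(rank_sum_test(x, y, method="exact")[1], abs=1e-12)

    def test_effect_monotonicity(self):
        """Scaling up the class difference never shrinks the significant fraction."""
        fractions = [
            significance_map(_two_class_cohort(effect, 30, seed=5)).significant_fraction()
            for effect in (0.01, 0.02, 0.04)
        ]
        assert fractions == sorted(fractions)

    def test_bh_adjustment_is_conservative(self):
        smap_raw = significance_map(null_cohort(20, 20, 3))
        smap_bh = significance_map(null_cohort(20, 20, 3), adjust="bh")
        assert np.all(smap_bh.p >= smap_raw.p - 1e-12)


class TestTopKRegion:
    @pytest.mark.parametrize("fraction,k", [(0.10, 546), (0.05, 273), (1.0, 5457)])
    def test_mask_cardinality(self, fraction, k):
        smap = significance_map(null_cohort(5, 5, 1))
        assert top_k_region(smap, fraction).k == k

    def test_round_half_away_from_zero(self):
        assert round_half_away(545.7) == 546
        assert round_half_away(272.85) == 273
        assert round_half_away(2.5) == 3

    def test_tie_break_is_lexicographic_on_grid_indices(self):
        p = np.full((107, 51), 0.5)
        z = np.zeros((107, 51))
        smap = StatMap(z=z, p=p, n0=5, n1=5)
        mask = top_k_region(smap, 0.01)  # k=55: first row + 4 points of the next
        assert mask.k == 55
        assert mask.mask[0].all()
        assert mask.mask[1, :4].all() and not mask.mask[1, 4:].any()
        assert not mask.mask[2:].any()

    def test_selects_smallest_p_points(self, rng):
        p = rng.uniform(0.1, 1, (107, 51))
        p[40:45, 10:15] = rng.uniform(0, 1e-4, (5, 5))
        smap = StatMap(z=np.zeros_like(p), p=p, n0=5, n1=5)
        mask = top_k_region(smap, 25 / 5457)
        assert mask.mask[40:45, 10:15].all()

    def test_invalid_fraction(self):
        smap = significance_map(null_cohort(5, 5, 1))
        with pytest.raises(ValueError):
            top_k_region(smap, 0.0)


class TestRegionMeans:
    def _constant_cohort(self, value=0.4):
        surfaces = []
        for i, label in enumerate(["normal", "normal", "ome", "ome"]):
            meta = EarMeta(f"e{i}", f"p{i}", "L", 2.0, label)
            surfaces.append(WaiSurface(np.full((107, 51), value), FREQ, PRESS, meta))
        return Cohort(surfaces)

    def test_constant_cohort_full_mask(self):
        smap = significance_map(null_cohort(5, 5, 1))
        mask = top_k_region(smap, 1.0)
        mean_n, mean_o = region_class_means(self._constant_cohort(), mask)
        assert mean_n == pytest.approx(0.4, abs=1e-12)
        assert mean_o == pytest.approx(0.4, abs=1e-12)

    def test_single_point_mask_reduces_to_pointwise_means(self):
        cohort = null_cohort(4, 4, 2)
        scores = np.zeros((107, 51))
        scores[10, 20] = 1.0
        mask = top_k_mask_from_scores(scores, 1 / 5457)
        assert mask.k == 1
        mean_n, mean_o = region_class_means(cohort, mask)
        assert mean_n == pytest.approx(cohort.subset("normal").stack()[:, 10, 20].mean())
        assert mean_o == pytest.approx(cohort.subset("ome").stack()[:, 10, 20].mean())

    def test_empty_mask_rejected(self):
        mask = top_k_mask_from_scores(np.zeros((107, 51)), 1 / 5457)
        object.__setattr__(mask, "mask", np.zeros((107, 51), dtype=bool))
        with pytest.raises(ValueError):
            region_class_means(self._constant_cohort(), mask)
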