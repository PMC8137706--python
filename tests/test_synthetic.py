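import numpy as np
import pytest

from waiome import (
    default_generator_config,
    expected_mean_surface,
    expected_variance_surface,
    make_canonical_grids,
    mean_surface,
    null_cohort,
    sample_cohort,
    variance_surface,
)
from waiome.synthetic import ClassTemplate, GeneratorConfig

PRINTED_PEAKS = {
    "normal": [(820.0, 0.0, 0.39), (1335.0, 20.0, 0.50), (3270.0, 65.0, 0.76)],
    "ome": [(5000.0, -30.0, 0.50)],
}


class TestTemplates:
    @pytest.mark.parametrize("label", ["normal", "ome"])
    def test_template_attains_printed_peak_values_at_centres(self, default_config, label):
        """Amplitude calibration solves overlap so each peak value is exact."""
        template = default_config.templates[label]
        for freq, press, value in PRINTED_PEAKS[label]:
            got = template.mean(np.array([freq]), np.array([press]))[0, 0]
            assert got == pytest.approx(value, abs=1e-9)

    def test_normal_template_maximum_location_and_value(self, grids):
        freq, press = grids
        surface = mean_surface("normal")
        i, j = np.unravel_index(np.argmax(surface.absorbance), surface.absorbance.shape)
        assert i == freq.nearest_index(3270.0)
        assert j == press.nearest_index(65.0)
        # on-grid maximum sits just off the exact centre, hence slightly below 0.76
        assert surface.absorbance[i, j] == pytest.approx(0.76, abs=0.01)

    def test_ome_template_maximum_location_and_value(self, grids):
        freq, press = grids
        surface = mean_surface("ome")
        i, j = np.unravel_index(np.argmax(surface.absorbance), surface.absorbance.shape)
        assert i == freq.nearest_index(5000.0)
        assert j == press.nearest_index(-30.0)
        assert surface.absorbance[i, j] == pytest.approx(0.50, abs=0.01)

    def test_zero_bump_config_gives_constant_surface(self):
        flat = ClassTemplate(0.2, (), 0.0, ())
        cfg = GeneratorConfig(templates={"normal": flat, "ome": flat}, n_normal=2, n_ome=2)
        surface = mean_surface("normal", cfg)
        assert np.all(surface.absorbance == 0.2)

    def test_unknown_label_rejected(self, default_config):
        with pytest.raises(ValueError, match="unknown class label"):
            mean_surface("cholesteatoma", default_config)

    def test_variance_hotspot_levels(self, default_config, grids):
        """Peak variance 0.07 (normal) and ~0.11 (OME) at the hotspot centres."""
        freq, press = grids
        var_n = variance_surface("normal", default_config)
        var_o = variance_surface("ome", default_config)
        assert var_n[freq.nearest_index(2085), press.nearest_index(-205)] == pytest.approx(0.07, abs=0.005)
        assert var_o[freq.nearest_index(4511), press.nearest_index(120)] == pytest.approx(0.11, abs=0.005)


class TestSampling:
    def test_default_cohort_counts(self):
        cfg = default_generator_config()
        assert (cfg.n_normal, cfg.n_ome) == (423, 249)
        cohort = sample_cohort(cfg, seed=3)
        assert len(cohort) == 672
        assert cohort.class_counts == {"normal": 423, "ome": 249}

    def test_seed_determinism_and_sensitivity(self):
        cfg = default_generator_config(n_normal=5, n_ome=4)
        a = sample_cohort(cfg, seed=9)
        b = sample_cohort(cfg, seed=9)
        c = sample_cohort(cfg, seed=10)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.absorbance, sb.absorbance)
            assert np.array_equal(sa.press_grid.values, sb.press_grid.values)
            assert sa.meta == sb.meta
        assert not np.array_equal(a.surfaces[0].absorbance, c.surfaces[0].absorbance)

    def test_all_samples_within_unit_interval(self):
        cfg = default_generator_config(n_normal=10, n_ome=10)
        for surface in sample_cohort(cfg, seed=5):
            assert surface.absorbance.min() >= 0.0
            assert surface.absorbance.max() <= 1.0

    def test_raw_pressure_axes_are_irregular_but_valid(self):
        cfg = default_generator_config(n_normal=10, n_ome=5)
        cohort = sample_cohort(cfg, seed=2)
        lengths = {len(s.press_grid) for s in cohort}
        assert any(l < 51 for l in lengths)  # dropout thins the axis
        for surface in cohort:
            p = surface.press_grid.values
            assert np.all(np.diff(p) > 0)
            assert p[0] >= -300 and p[-1] <= 200

    def test_participant_structure(self):
        cohort = sample_cohort(default_generator_config(n_normal=100, n_ome=60), seed=4)
        normal_pids = {s.meta.participant_id for s in cohort if s.meta.label == "normal"}
        # ears-per-participant ratio emulates 423/242
        assert len(normal_pids) == round(100 / (423 / 242))
        per_pid: dict[str, int] = {}
        for s in cohort:
            per_pid[s.meta.participant_id] = per_pid.get(s.meta.participant_id, 0) + 1
        assert set(per_pid.values()) <= {1, 2}


class TestMoments:
    def test_cohort_mean_converges_to_clipped_expectation(self):
        """CLT bound: max |sample mean - E[clipped sample]| <= 4 sigma_max / sqrt(n)."""
        n = 200
        cfg = default_generator_config(
            n_normal=n, n_ome=2, pressure_dropout=0.0, pressure_jitter=0.0
        )
        cohort = sample_cohort(cfg, seed=1).subset("normal")
        sample_mean = cohort.stack().mean(axis=0)
        expected = expected_mean_surface("normal", cfg)
        sigma_max = float(np.sqrt(expected_variance_surface("normal", cfg)).max())
        assert np.max(np.abs(sample_mean - expected)) <= 4 * sigma_max / np.sqrt(n)

    def test_variance_recovery_at_hotspots(self, grids):
        """Sample variance at n=1000 within 25% of the clipped-Gaussian variance."""
        freq, press = grids
        cfg = default_generator_config(
            n_normal=1000, n_ome=2, pressure_dropout=0.0, pressure_jitter=0.0
        )
        stack = sample_cohort(cfg, seed=6).subset("normal").stack()
        sample_var = stack.var(axis=0)
        expected = expected_variance_surface("normal", cfg)
        for f_hz, p_dapa in [(2085, -205), (5339, -10)]:
            i, j = freq.nearest_index(f_hz), press.nearest_index(p_dapa)
            assert sample_var[i, j] == pytest.approx(expected[i, j], rel=0.25)

    def test_variance_recovery_matches_configured_when_clipping_negligible(self, grids):
        """Where the template is far from [0,1], realized variance == configured."""
        freq, press = grids
        flat = ClassTemplate(0.5, (), 0.04**2, ())
        cfg = GeneratorConfig(
            templates={"normal": flat, "ome": flat},
            n_normal=1000, n_ome=2, pressure_dropout=0.0, pressure_jitter=0.0,
        )
        stack = sample_cohort(cfg, seed=6).subset("normal").stack()
        i, j = freq.nearest_index(1000), press.nearest_index(0)
        assert stack.var(axis=0)[i, j] == pytest.approx(0.04**2, rel=0.25)

    def test_clipping_shrinks_variance_below_configured_at_low_mean_hotspot(self, default_config, grids):
        """The [0,1] clip makes realized variance < configured where mean ~ 0.1."""
        freq, press = grids
        i, j = freq.nearest_index(2085), press.nearest_index(-205)
        configured = variance_surface("normal", default_config)[i, j]
        clipped = expected_variance_surface("normal", default_config)[i, j]
        assert clipped < 0.75 * configured


class TestNullCohort:
    def test_counts_and_labels(self):
        cohort = null_cohort(50, 50, 7)
        assert len(cohort) == 100
        assert cohort.class_counts == {"normal": 50, "ome": 50}

    def test_seed_sensitivity(self):
        a = null_cohort(3, 3, 1)
        b = null_cohort(3, 3, 2)
        assert not np.array_equal(a.surfaces[0].absorbance, b.surfaces[0].absorbance)

    def test_minimum_sizes(self):
        with pytest.raises(ValueError):
            null_cohort(1, 5, 0)
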