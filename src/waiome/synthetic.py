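"""Synthetic WAI cohort generator.

The clinical cohort this package analyses is not publicly deposited, so the
generator emulates its statistical structure: per-class mean absorbance
surfaces built from separable Gaussian bumps in (log2 frequency, pressure),
heteroscedastic pointwise Gaussian noise with configured variance hotspots,
clipping to the physical [0, 1] absorbance range, and raw pressure axes
thinned and jittered to mimic uneven device sampling.

Calibration of the default configuration:

* normal-ear mean surface peaks: 0.39 at (820 Hz, 0 daPa), 0.50 at
  (1335 Hz, +20 daPa), and the global maximum 0.76 at (3270 Hz, +65 daPa);
* OME mean surface: a single broad peak of 0.50 at (5000 Hz, -30 daPa);
* variance hotspots: 0.07 for normal ears (1834-2370 Hz at strongly
  negative pressures, and near 5.3 kHz around 0 daPa), 0.11 for OME ears
  (3.7-5.5 kHz at positive pressures);
* class sizes 423 normal / 249 OME ears.

Because samples are clipped to [0, 1], the realised per-point mean and
variance differ from the raw template wherever template +/- sigma crosses a
bound; :func:`expected_mean_surface` and :func:`expected_variance_surface`
give the exact clipped-Gaussian moments used as oracles in tests.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter
from scipy.special import ndtr
from scipy.stats import norm

from .grids import (
    PRESS_MAX_DAPA,
    PRESS_MIN_DAPA,
    FrequencyGrid,
    PressureGrid,
    make_canonical_grids,
)
from .surface import Cohort, EarMeta, WaiSurface

# ears-per-participant ratios of the emulated cohort (423/242 and 249/163)
_EARS_PER_PARTICIPANT = {"normal": 423 / 242, "ome": 249 / 163}
_AGE_RANGE = {"normal": (1.0, 68.0), "ome": (1.0, 73.0)}


@dataclass(frozen=True)
class BumpSpec:
    """A separable Gaussian bump in (log2 frequency, pressure).

    ``amplitude`` is in absorbance units for mean-surface bumps and in
    absorbance-squared units for variance hotspots.
    """

    centre_freq: float  # Hz
    centre_press: float  # daPa
    width_logf: float  # sigma in octaves (log2 frequency)
    width_press: float  # sigma in daPa
    amplitude: float

    def __post_init__(self) -> None:
        if self.width_logf <= 0 or self.width_press <= 0:
            raise ValueError("bump widths must be positive")

    def __call__(self, freq_hz: np.ndarray, press_dapa: np.ndarray) -> np.ndarray:
        """Evaluate on the outer grid of ``freq_hz`` x ``press_dapa``."""
        df = (np.log2(np.asarray(freq_hz, float) / self.centre_freq) / self.width_logf) ** 2
        dp = ((np.asarray(press_dapa, float) - self.centre_press) / self.width_press) ** 2
        return self.amplitude * np.exp(-0.5 * (df[:, None] + dp[None, :]))


@dataclass(frozen=True)
class ClassTemplate:
    """Mean-surface and variance-field description for one class."""

    baseline: float
    bumps: tuple[BumpSpec, ...]
    variance_baseline: float
    variance_bumps: tuple[BumpSpec, ...]

    def mean(self, freq_hz: np.ndarray, press_dapa: np.ndarray) -> np.ndarray:
        """Raw (pre-clip) template mean on the given axes."""
        out = np.full((len(freq_hz), len(press_dapa)), self.baseline, dtype=float)
        for bump in self.bumps:
            out += bump(freq_hz, press_dapa)
        return out

    def variance(self, freq_hz: np.ndarray, press_dapa: np.ndarray) -> np.ndarray:
        out = np.full((len(freq_hz), len(press_dapa)), self.variance_baseline, dtype=float)
        for bump in self.variance_bumps:
            out += bump(freq_hz, press_dapa)
        if out.min() < 0:
            raise ValueError("variance field must be non-negative everywhere")
        return out


@dataclass(frozen=True)
class GeneratorConfig:
    templates: dict[str, ClassTemplate]
    n_normal: int = 423
    n_ome: int = 249
    pressure_dropout: float = 0.15
    pressure_jitter: float = 3.0  # daPa
    noise_blur_sigma: float = 0.0  # grid cells; >0 spatially correlates noise
    seed: int = 20210520

    def __post_init__(self) -> None:
        if self.n_normal < 1 or self.n_ome < 1:
            raise ValueError("class counts must be >= 1")
        if not (0 <= self.pressure_dropout < 1):
            raise ValueError("pressure_dropout must be in [0, 1)")
        if self.pressure_jitter < 0:
            raise ValueError("pressure_jitter must be >= 0")


def calibrate_bumps(
    baseline: float,
    peaks: list[dict],
) -> tuple[BumpSpec, ...]:
    """Solve bump amplitudes so the summed template hits each target peak.

    Each entry of ``peaks`` gives a centre, widths and the absorbance
    ``value`` the template must attain there; overlapping tails are handled
    by solving the small linear system template(centre_i) == value_i.
    """
    unit = [
        BumpSpec(p["freq_hz"], p["press_dapa"], p["width_logf"], p["width_press"], 1.0)
        for p in peaks
    ]
    targets = np.array([p["value"] for p in peaks], dtype=float) - baseline
    gram = np.array(
        [
            [
                float(bj(np.array([bi.centre_freq]), np.array([bi.centre_press]))[0, 0])
                for bj in unit
            ]
            for bi in unit
        ]
    )
    amplitudes = np.linalg.solve(gram, targets)
    if np.any(amplitudes <= 0):
        raise ValueError("peak calibration produced a non-positive amplitude")
    return tuple(replace(b, amplitude=float(a)) for b, a in zip(unit, amplitudes))


def _template_from_dict(spec: dict) -> ClassTemplate:
    var = spec["variance"]
    return ClassTemplate(
        baseline=float(spec["baseline"]),
        bumps=calibrate_bumps(float(spec["baseline"]), spec["peaks"]),
        variance_baseline=float(var["baseline"]),
        variance_bumps=tuple(
            BumpSpec(h["freq_hz"], h["press_dapa"], h["width_logf"], h["width_press"], h["level"])
            for h in var.get("hotspots", [])
        ),
    )


def config_from_dict(raw: dict) -> GeneratorConfig:
    return GeneratorConfig(
        templates={label: _template_from_dict(raw[label]) for label in ("normal", "ome")},
        n_normal=int(raw.get("n_normal", 423)),
        n_ome=int(raw.get("n_ome", 249)),
        pressure_dropout=float(raw.get("pressure_dropout", 0.15)),
        pressure_jitter=float(raw.get("pressure_jitter", 3.0)),
        noise_blur_sigma=float(raw.get("noise_blur_sigma", 0.0)),
        seed=int(raw.get("seed", 20210520)),
    )


def load_config(path: Path | str) -> GeneratorConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def default_generator_config(**overrides) -> GeneratorConfig:
    """The versioned default calibration shipped with the package."""
    ref = importlib.resources.files("waiome.configs") / "default_generator.yaml"
    cfg = config_from_dict(yaml.safe_load(ref.read_text()))
    return replace(cfg, **overrides) if overrides else cfg


def _template(class_label: str, config: GeneratorConfig | None) -> ClassTemplate:
    config = config if config is not None else default_generator_config()
    if class_label not in config.templates:
        raise ValueError(f"unknown class label {class_label!r}; expected one of "
                         f"{sorted(config.templates)}")
    return config.templates[class_label]


def mean_surface(class_label: str, config: GeneratorConfig | None = None) -> WaiSurface:
    """Deterministic class template on the canonical grids, clipped to [0, 1]."""
    freq_grid, press_grid = make_canonical_grids()
    template = _template(class_label, config)
    values = np.clip(template.mean(freq_grid.centres, press_grid.values), 0.0, 1.0)
    meta = EarMeta(f"template-{class_label}", f"template-{class_label}", "L", 0.0, class_label)
    return WaiSurface(values, freq_grid, press_grid, meta)


def variance_surface(class_label: str, config: GeneratorConfig | None = None) -> np.ndarray:
    """Configured (pre-clip) noise variance field on the canonical grids."""
    freq_grid, press_grid = make_canonical_grids()
    return _template(class_label, config).variance(freq_grid.centres, press_grid.values)


def _clipped_moments(mu: np.ndarray, sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of clip(N(mu, sigma^2), 0, 1), elementwise."""
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    out_mean = np.clip(mu, 0.0, 1.0)
    out_var = np.zeros_like(mu)
    pos = sigma > 0
    if np.any(pos):
        m, s = mu[pos], sigma[pos]
        a = (0.0 - m) / s
        b = (1.0 - m) / s
        z = ndtr(b) - ndtr(a)
        pa, pb = norm.pdf(a), norm.pdf(b)
        ey = (1.0 - ndtr(b)) + m * z + s * (pa - pb)
        ey2 = (1.0 - ndtr(b)) + (m * m + s * s) * z + 2 * m * s * (pa - pb) + s * s * (a * pa - b * pb)
        out_mean[pos] = ey
        out_var[pos] = np.maximum(ey2 - ey * ey, 0.0)
    return out_mean, out_var


def expected_mean_surface(class_label: str, config: GeneratorConfig | None = None) -> np.ndarray:
    """Exact expectation of a sampled surface (template + noise, clipped)."""
    template = _template(class_label, config)
    freq_grid, press_grid = make_canonical_grids()
    mu = template.mean(freq_grid.centres, press_grid.values)
    sigma = np.sqrt(template.variance(freq_grid.centres, press_grid.values))
    return _clipped_moments(mu, sigma)[0]


def expected_variance_surface(class_label: str, config: GeneratorConfig | None = None) -> np.ndarray:
    """Exact pointwise variance of a sampled surface after clipping."""
    template = _template(class_label, config)
    freq_grid, press_grid = make_canonical_grids()
    mu = template.mean(freq_grid.centres, press_grid.values)
    sigma = np.sqrt(template.variance(freq_grid.centres, press_grid.values))
    return _clipped_moments(mu, sigma)[1]


def _raw_pressure_axis(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Thin and jitter the canonical pressure axis to emulate uneven sampling."""
    _, press_grid = make_canonical_grids()
    p = press_grid.values
    if config.pressure_dropout > 0:
        keep = rng.random(p.size) >= config.pressure_dropout
        if keep.sum() < 4:  # completeness floor; vanishingly rare at default dropout
            keep[rng.choice(p.size, size=4, replace=False)] = True
        p = p[keep]
    if config.pressure_jitter > 0:
        p = p + rng.normal(0.0, config.pressure_jitter, size=p.size)
        p = np.clip(p, PRESS_MIN_DAPA, PRESS_MAX_DAPA)
    p = np.unique(p)  # sorted, strictly increasing
    return p


def _sample_surface(
    class_label: str,
    template: ClassTemplate,
    config: GeneratorConfig,
    meta: EarMeta,
    rng: np.random.Generator,
) -> WaiSurface:
    freq_grid, _ = make_canonical_grids()
    pressures = _raw_pressure_axis(config, rng)
    mu = template.mean(freq_grid.centres, pressures)
    sigma = np.sqrt(template.variance(freq_grid.centres, pressures))
    noise = rng.standard_normal(mu.shape)
    if config.noise_blur_sigma > 0:
        noise = gaussian_filter(noise, config.noise_blur_sigma)
        noise /= max(noise.std(), 1e-12)  # restore unit pointwise scale
    values = np.clip(mu + sigma * noise, 0.0, 1.0)
    return WaiSurface(values, freq_grid, PressureGrid(pressures), meta)


def _make_metas(class_label: str, n: int, rng: np.random.Generator) -> list[EarMeta]:
    """Assign ears to participants with the emulated bilateral/unilateral mix."""
    ratio = _EARS_PER_PARTICIPANT[class_label]
    n_participants = max(1, min(n, round(n / ratio)))
    n_bilateral = n - n_participants
    lo, hi = _AGE_RANGE[class_label]
    tag = class_label[0].upper()
    metas: list[EarMeta] = []
    ear = 0
    for j in range(n_participants):
        pid = f"P{tag}{j:04d}"
        age = float(np.round(rng.uniform(lo, hi), 1))
        sides = ("L", "R") if j < n_bilateral else (rng.choice(["L", "R"]),)
        for side in sides:
            metas.append(EarMeta(f"{tag}{ear:04d}", pid, str(side), age, class_label))
            ear += 1
    return metas


def sample_cohort(config: GeneratorConfig | None = None, seed: int | None = None) -> Cohort:
    """Draw a full labelled cohort; identical (config, seed) -> identical cohort.

    Surfaces are returned on their raw (possibly irregular) pressure axes;
    run the preprocessing stage to move them onto the canonical grids.
    """
    config = config if config is not None else default_generator_config()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    surfaces: list[WaiSurface] = []
    for label, n in (("normal", config.n_normal), ("ome", config.n_ome)):
        template = config.templates[label]
        for meta in _make_metas(label, n, rng):
            surfaces.append(_sample_surface(label, template, config, meta, rng))
    return Cohort(surfaces)


def null_cohort(n_a: int, n_b: int, seed: int) -> Cohort:
    """Two arbitrarily labelled groups drawn from one flat template.

    Used as a type-I-error harness: any pointwise test on this cohort is
    testing a true null at every grid point. The flat level 0.5 with sigma
    0.08 keeps clipping negligible, so samples are effectively Gaussian.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("null cohort needs at least 2 ears per group")
    flat = ClassTemplate(0.5, (), 0.08**2, ())
    config = GeneratorConfig(
        templates={"normal": flat, "ome": flat},
        n_normal=n_a,
        n_ome=n_b,
        pressure_dropout=0.0,
        pressure_jitter=0.0,
        seed=seed,
    )
    return sample_cohort(config)
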