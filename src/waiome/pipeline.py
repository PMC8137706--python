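"""End-to-end pipeline: simulate -> preprocess -> statmap -> regions -> classify.

Every stage writes machine-readable artifacts under the output root and
contributes a block to ``summary.json``. Identical (config, seed) pairs
produce identical summaries (no timestamps in the summary itself).
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classify import ModelSpec, benchmark_zoo, cross_validate, metrics_table
from .io import read_cohort, write_cohort
from .preprocess import preprocess_cohort
from .rf_regions import DEFAULT_TREE_COUNTS, importance_map, overlay_regions
from .statmap import region_class_means, significance_map, top_k_region
from .synthetic import GeneratorConfig, default_generator_config, sample_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "statmap", "regions", "classify")


@dataclass
class PipelineConfig:
    generator_config: GeneratorConfig | None = None  # None -> packaged default
    manifest: Path | None = None  # read a cohort instead of simulating
    alpha: float = 0.05
    fractions: tuple[float, ...] = (0.05, 0.10)
    models: list[ModelSpec] | None = None  # None -> the full benchmark zoo
    ome_weight: float = 1.0
    folds: int = 10
    restarts: int | None = None
    tree_counts: tuple[int, ...] = DEFAULT_TREE_COUNTS
    seed: int = 0
    out: Path = Path("results/pipeline")

    def __post_init__(self) -> None:
        if not all(0 < f <= 1 for f in self.fractions):
            raise ValueError("region fractions must be in (0, 1]")


def _config_hash(config: PipelineConfig) -> str:
    def default(obj):
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if hasattr(obj, "__dict__"):
            return vars(obj)
        return repr(obj)

    payload = asdict(config)
    payload.pop("out", None)  # output location does not define the analysis
    blob = json.dumps(payload, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_matrix(values: np.ndarray, path: Path) -> None:
    np.savetxt(path, values, delimiter=",", fmt="%.8g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns (and writes) the summary dictionary.

    A failure in any stage aborts with a stage-named error; artifacts of
    completed stages are preserved under the output root.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "schema_version": 1,
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
    }
    stage = "simulate"
    try:
        if config.manifest is not None:
            raw = read_cohort(config.manifest)
            summary[stage] = {"source": str(config.manifest), "n_ears": len(raw)}
        else:
            gen = config.generator_config or default_generator_config()
            raw = sample_cohort(gen, seed=config.seed)
            write_cohort(raw, out / "cohort")
            summary[stage] = {
                "source": "synthetic",
                "n_ears": len(raw),
                "class_counts": raw.class_counts,
            }

        stage = "preprocess"
        cohort, rejections = preprocess_cohort(raw)
        (out / "rejections.log").write_text("\n".join(rejections) + ("\n" if rejections else ""))
        summary[stage] = {"n_ears": len(cohort), "n_rejected": len(rejections)}

        stage = "statmap"
        smap = significance_map(cohort)
        _write_matrix(smap.z, out / "statmap_z.csv")
        _write_matrix(smap.p, out / "statmap_p.csv")
        block = {
            "alpha": config.alpha,
            "significant_fraction": smap.significant_fraction(config.alpha),
            "significant_count": smap.significant_count(config.alpha),
            "regions": {},
        }
        for fraction in config.fractions:
            mask = top_k_region(smap, fraction)
            _write_matrix(mask.mask.astype(int), out / f"pmask_{int(round(fraction * 100))}.csv")
            mean_normal, mean_ome = region_class_means(cohort, mask)
            block["regions"][f"{fraction:g}"] = {
                "k": mask.k,
                "mean_normal": mean_normal,
                "mean_ome": mean_ome,
            }
        summary[stage] = block

        stage = "regions"
        imp = importance_map(cohort, tree_counts=config.tree_counts, seed=config.seed)
        _write_matrix(imp.imp, out / "importance_map.csv")
        overlay = overlay_regions(imp, smap, fractions=config.fractions)
        summary[stage] = {
            "tree_counts": list(imp.tree_counts),
            "jaccard": {f"{k:g}": v for k, v in overlay.jaccard.items()},
        }
        try:
            from .plots import plot_overlay, plot_statmap

            plot_overlay(imp, overlay.p_masks, out / "overlay.png")
            plot_statmap(smap, out / "statmap.png")
        except Exception as exc:  # plotting must never kill the pipeline
            logger.warning("figure generation failed: %s", exc)

        stage = "classify"
        models = config.models if config.models is not None else benchmark_zoo(config.ome_weight)
        results = [
            cross_validate(cohort, spec, folds=config.folds, restarts=config.restarts,
                           seed=config.seed)
            for spec in models
        ]
        table = metrics_table(results)
        table.to_csv(out / "metrics.csv", index=False)
        summary[stage] = {
            "folds": config.folds,
            "models": {res.spec.name: res.metrics.as_dict() for res in results},
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
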