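"""Cohort file I/O.

Formats:
  * per-ear matrix: CSV with a header row of pressures (daPa), first column
    of frequencies (Hz), body = absorbance values;
  * manifest: tab-separated table with columns
    ear_id, participant_id, side, age, label, file.

Both are plain text, human-inspectable, and round-trip losslessly.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import FrequencyGrid, PressureGrid
from .surface import Cohort, EarMeta, WaiSurface

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["ear_id", "participant_id", "side", "age", "label", "file"]
ABSORBANCE_TOL = 1e-6


def write_surface(surface: WaiSurface, path: Path) -> None:
    df = pd.DataFrame(
        surface.absorbance,
        index=surface.freq_grid.centres,
        columns=surface.press_grid.values,
    )
    df.index.name = "freq_hz"
    df.to_csv(path, float_format="%.17g")


def read_surface(path: Path, meta: EarMeta) -> WaiSurface:
    df = pd.read_csv(path, index_col=0)
    freqs = df.index.to_numpy(dtype=float)
    pressures = df.columns.to_numpy(dtype=float)
    values = df.to_numpy(dtype=float)
    if values.min() < -ABSORBANCE_TOL or values.max() > 1 + ABSORBANCE_TOL:
        raise ValueError(
            f"absorbance outside [0, 1] beyond tolerance in ear {meta.ear_id}: "
            f"range [{values.min():.4g}, {values.max():.4g}]"
        )
    return WaiSurface(
        absorbance=np.clip(values, 0.0, 1.0),
        freq_grid=FrequencyGrid(freqs),
        press_grid=PressureGrid(pressures),
        meta=meta,
    )


def write_cohort(cohort: Cohort, out_dir: Path | str) -> Path:
    """Write a cohort (manifest + per-ear CSVs); returns the manifest path.

    Round-trips exactly: ``read_cohort(write_cohort(c))`` reproduces all
    matrices to machine precision and all metadata exactly.
    """
    if len(cohort) == 0:
        raise ValueError("refusing to write an empty cohort")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for surface in cohort:
        fname = f"{surface.meta.ear_id}.csv"
        write_surface(surface, out_dir / fname)
        m = surface.meta
        rows.append([m.ear_id, m.participant_id, m.side, m.age, m.label, fname])
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest_path = out_dir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


def read_cohort(manifest_path: Path | str, data_dir: Path | str | None = None) -> Cohort:
    """Load a cohort from a manifest TSV.

    A referenced file that does not exist is a hard error naming the ear.
    A record whose absorbance leaves [0, 1] by more than 1e-6 is excluded
    with a logged warning (poor-quality measurement); values within the
    tolerance are clipped.
    """
    manifest_path = Path(manifest_path)
    data_dir = Path(data_dir) if data_dir is not None else manifest_path.parent
    manifest = pd.read_csv(manifest_path, sep="\t", dtype={"ear_id": str, "participant_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")

    surfaces: list[WaiSurface] = []
    n_excluded = 0
    for row in manifest.itertuples(index=False):
        meta = EarMeta(
            ear_id=str(row.ear_id),
            participant_id=str(row.participant_id),
            side=str(row.side),
            age=float(row.age),
            label=str(row.label),
        )
        path = data_dir / str(row.file)
        if not path.exists():
            raise FileNotFoundError(f"data file for ear {meta.ear_id} not found: {path}")
        try:
            surfaces.append(read_surface(path, meta))
        except ValueError as exc:
            n_excluded += 1
            logger.warning("excluding ear %s: %s", meta.ear_id, exc)
    if n_excluded:
        logger.warning("excluded %d poor-quality record(s) while reading %s", n_excluded, manifest_path)
    return Cohort(surfaces)
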