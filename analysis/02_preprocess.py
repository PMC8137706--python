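#!/usr/bin/env python
"""Move the raw cohort onto the canonical 107 x 51 grid.

Each ear's irregular pressure axis is resampled to -300..+200 daPa in
10-daPa steps with monotone cubic (PCHIP) interpolation; sweeps with fewer
than 4 distinct pressures are rejected as incomplete.
"""
import json
from pathlib import Path

from waiome import read_cohort, write_cohort
from waiome.preprocess import preprocess_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    raw = read_cohort(ROOT / "scratch" / "cohort" / "manifest.tsv")
    cohort, rejections = preprocess_cohort(raw)
    manifest = write_cohort(cohort, ROOT / "scratch" / "cohort_canonical")
    summary = {
        "n_in": len(raw),
        "n_kept": len(cohort),
        "n_rejected": len(rejections),
        "manifest": str(manifest),
    }
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "preprocess_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
    print(f"kept {summary['n_kept']}/{summary['n_in']} ears on the canonical grid "
          f"({summary['n_rejected']} rejected)")


if __name__ == "__main__":
    main()
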