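#!/usr/bin/env python
"""Simulate the study cohort.

Draws the default calibrated synthetic cohort — 423 normal ears and 249
ears with otitis media with effusion (OME), raw pressure axes thinned and
jittered as a tympanometric sweep would be — and writes it in the package's
cohort format. The cohort files are large, so they go under scratch/; the
small summary table goes under results/.
"""
import json
from pathlib import Path

from waiome import default_generator_config, sample_cohort, write_cohort

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    config = default_generator_config()
    cohort = sample_cohort(config, seed=SEED)
    manifest = write_cohort(cohort, ROOT / "scratch" / "cohort")
    participants = {s.meta.participant_id for s in cohort}
    summary = {
        "seed": SEED,
        "n_ears": len(cohort),
        "class_counts": cohort.class_counts,
        "n_participants": len(participants),
        "manifest": str(manifest),
    }
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    (out / "cohort_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"simulated {summary['n_ears']} ears {summary['class_counts']} "
          f"from {summary['n_participants']} participants -> {manifest}")


if __name__ == "__main__":
    main()
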