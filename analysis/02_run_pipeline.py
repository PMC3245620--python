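#!/usr/bin/env python
"""Run the full analysis pipeline on the generated study bundle.

Reads scratch/study_bundle (see 01_simulate_study.py), validates it, and
writes normalized-signal metagene profiles, the expression-decile table,
decile-stratified profiles, intron/exon statistics and a run report
under results/pipeline/.
"""

import argparse
import json
from pathlib import Path

from intronchip.pipeline import RunConfig, run_pipeline, validate_inputs

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bundle", type=Path, default=ROOT / "scratch" / "study_bundle")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "pipeline")
    ap.add_argument("--figures", action="store_true")
    args = ap.parse_args()

    config = RunConfig.from_bundle(args.bundle, args.out, make_figures=args.figures)
    validation = validate_inputs(config)
    if validation["errors"]:
        raise SystemExit("validation failed:\n" + "\n".join(validation["errors"]))
    for w in validation["warnings"]:
        print(f"warning: {w}")

    report = run_pipeline(config)
    print(f"pipeline finished: {report['status']}")
    print(json.dumps(report["stages"], indent=1, default=str))
    print(f"outputs under {args.out}")


if __name__ == "__main__":
    main()
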