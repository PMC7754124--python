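#!/usr/bin/env python
"""Patient-grouped cross-validated classification of all task/algorithm cells.

Runs SVM and RF on the three tasks (HCC vs non-tumour, MFCCC vs
non-tumour, 3-class) with patient-grouped K-fold CV, then aggregates
fragment predictions into majority-vote sample verdicts.  Writes the
full report JSON and a human-readable summary.
"""

import argparse
import json
from pathlib import Path

from pesiml.io import read_feature_matrix, read_manifest
from pesiml.model import PipelineConfig
from pesiml.pipeline import evaluate_tasks, summarize_report

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=ROOT / "scratch" / "cohort")
    ap.add_argument("--k", type=int, default=10)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    fm = read_feature_matrix(args.indir / "features.tsv")
    manifest = read_manifest(args.indir / "manifest.csv")
    cfg = PipelineConfig(seed=args.seed, k_folds=args.k)
    out = evaluate_tasks(fm, manifest, cfg)

    (ROOT / "results").mkdir(exist_ok=True)
    with open(ROOT / "results" / "crossval_report.json", "w") as fh:
        json.dump(out["report"], fh, indent=2, sort_keys=True)
    summary = summarize_report(out["report"])
    (ROOT / "results" / "crossval_summary.txt").write_text(summary + "\n")
    print(summary)


if __name__ == "__main__":
    main()
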