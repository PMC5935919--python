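#!/usr/bin/env python
"""Validate the frozen model on the independent (synthetic) cohort.

No refitting, no re-standardization, no cutoff re-selection: the stored
model scores the new subjects and the stored probability cutoff makes the
calls, exactly as the model would be deployed.
"""

import argparse
import json
from pathlib import Path

from breathvoc import DiagnosticModel, read_cohort
from breathvoc.pipeline import run_validate

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--model", type=Path, default=ROOT / "results" / "fit" / "model.json")
    ap.add_argument("--validation", type=Path,
                    default=ROOT / "results" / "data" / "validation.csv")
    ap.add_argument("--out-dir", type=Path, default=ROOT / "results" / "validation")
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    model = DiagnosticModel.from_json(args.model)
    samples = read_cohort(args.validation)
    report, frame = run_validate(model, samples)
    frame.to_csv(args.out_dir / "validation_scores.csv", index=False)
    (args.out_dir / "validation_confusion.json").write_text(
        json.dumps(report.to_dict(), indent=2) + "\n"
    )
    d = report.to_dict()
    print(f"validation cohort: {report.n_cases} cases / {report.n_controls} controls")
    print(f"cutoff {model.cutoff:.6f} (frozen from training)")
    print(f"confusion: TP={d['tp']} FN={d['fn']} TN={d['tn']} FP={d['fp']}")
    print(f"sensitivity {d['sensitivity_pct']}%  specificity {d['specificity_pct']}%")
    print(f"artifacts -> {args.out_dir}")


if __name__ == "__main__":
    main()
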