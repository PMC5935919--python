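#!/usr/bin/env python
"""Draw the synthetic study cohorts.

Emits a 219-subject training cohort with the study's age-exclusion structure
(one case under 40, 41 controls under 40, one control over 75, nine cases
over 75) and a 50-subject validation cohort (26 controls / 24 cases, ages
40-75), each subject carrying a paired room-air sample.  Concentrations are
log-normal, calibrated to the printed per-group summary statistics.
"""

import argparse
from pathlib import Path

from breathvoc import generate_published_like_run, write_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=ROOT / "results" / "data")
    args = ap.parse_args()

    training, validation = generate_published_like_run(args.seed)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    t_path = write_cohort(training, args.out_dir / "training.csv")
    v_path = write_cohort(validation, args.out_dir / "validation.csv")

    t_alv = [s for s in training if s.sample_type == "alveolar"]
    print(f"seed {args.seed}")
    print(f"training cohort: {len(t_alv)} subjects "
          f"({sum(s.group == 'control' for s in t_alv)} controls, "
          f"{sum(s.group == 'case' for s in t_alv)} cases), "
          f"{len(training)} samples incl. room air -> {t_path}")
    v_alv = [s for s in validation if s.sample_type == "alveolar"]
    print(f"validation cohort: {len(v_alv)} subjects "
          f"({sum(s.group == 'control' for s in v_alv)} controls, "
          f"{sum(s.group == 'case' for s in v_alv)} cases) -> {v_path}")


if __name__ == "__main__":
    main()
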