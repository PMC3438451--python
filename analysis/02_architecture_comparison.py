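#!/usr/bin/env python
"""Stage 1: which extrinsic architecture explains the grand averages?

Inverts each of the six candidate architectures (no condition effects)
on the grand-average response for every contrast level separately and
pools log evidences over levels — a fixed-effects comparison.  Expects
the study written by 01_simulate_study.py (simulates it if missing).
"""

from pathlib import Path

from gaindcm.io import load_dataset
from gaindcm.pipeline import run_stage1

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    study = OUT / "study.h5"
    if not study.exists():
        print("study.h5 not found; run analysis/01_simulate_study.py first")
        raise SystemExit(1)
    ds = load_dataset(study)
    res = run_stage1(ds)
    print(res.comparison.report())
    truth = ds.config.architecture_id
    verdict = "matches" if res.winner_id == truth else "MISSES"
    print(f"\nwinner {verdict} the generating architecture ({truth}: "
          "serial hierarchy with diagonal interhemispheric connections)")
    res.comparison.to_frame().to_csv(OUT / "stage1_architectures.csv", index=False)
    print(f"wrote {OUT/'stage1_architectures.csv'}")


if __name__ == "__main__":
    main()
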