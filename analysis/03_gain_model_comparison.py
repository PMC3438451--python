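#!/usr/bin/env python
"""Stage 2: where does contrast act — superficial or deep gain, or not at all?

Takes the stage-1 winning architecture and, for every subject, inverts
three condition-effect hypotheses on the subject-specific averages:
no modulation (null), contrast-dependent superficial-pyramidal
self-inhibition (sp) and contrast-dependent deep-pyramidal
self-inhibition (dp).  Log evidences are pooled over subjects; the
winning model's per-area MAP modulations form the beta table for
stage 3.
"""

import json
from pathlib import Path

import numpy as np

from gaindcm.io import load_dataset
from gaindcm.model_space import build_architecture
from gaindcm.pipeline import run_stage2

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    study = OUT / "study.h5"
    if not study.exists():
        print("study.h5 not found; run analysis/01_simulate_study.py first")
        raise SystemExit(1)
    stage1 = OUT / "stage1_architectures.csv"
    if stage1.exists():
        import pandas as pd

        frame = pd.read_csv(stage1)
        winner = int(
            frame.loc[frame["pooled_log_evidence_nats"].idxmax(), "model"]
        )
    else:
        winner = 5
        print("stage-1 table not found; using architecture 5")
    ds = load_dataset(study)
    res = run_stage2(ds, build_architecture(winner))
    print(res.comparison.report())
    print(f"\nlog Bayes factor sp vs dp: "
          f"{res.comparison.log_bayes_factor('sp', 'dp'):.1f} nats")
    print(f"log Bayes factor sp vs null: "
          f"{res.comparison.log_bayes_factor('sp', 'null'):.1f} nats")
    res.comparison.to_frame().to_csv(OUT / "stage2_effect_models.csv", index=False)
    res.beta_table.to_csv(OUT / "beta_table.csv", index=False)
    print(f"wrote {OUT/'stage2_effect_models.csv'} and {OUT/'beta_table.csv'}")


if __name__ == "__main__":
    main()
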