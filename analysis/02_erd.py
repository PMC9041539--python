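#!/usr/bin/env python
"""Quantify event-related desynchronisation across a synthetic cohort.

Runs the ERD stage on a down-scaled cohort (8 subjects, 10 trials per hand
per condition) and tests contralateral-vs-ipsilateral alpha suppression per
condition and hand with a paired Wilcoxon signed-rank test (FDR-corrected).
With the default planted attenuation (amplitude x 0.5 on the contralateral
motor channel) the contralateral ERD sits near -75% and every contrast is
strongly lateralized.
"""
import argparse
from pathlib import Path

from miconn.pipeline import ExperimentConfig, run_experiment
from miconn.synth import SynthConfig


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--subjects", type=int, default=8)
    args = ap.parse_args()

    cfg = ExperimentConfig(
        synth=SynthConfig(n_trials_per_hand=10),
        n_subjects=args.subjects,
        stages=("erd",),
        seed=args.seed,
    )
    result = run_experiment(cfg, outdir=args.outdir)
    mean_erd = (
        result.erd[result.erd.channel.isin(["C3", "C4"])]
        .groupby(["condition", "hand", "channel"])["erd_percent"]
        .mean()
        .unstack()
        .round(1)
    )
    print("mean ERD% over the 0-5 s MI window (C3/C4):")
    print(mean_erd.to_string())
    print("\nlateralization tests (contralateral vs ipsilateral alpha ERD):")
    print(result.lateralization.round(4).to_string(index=False))
    print(f"\ntables -> {args.outdir}/erd_summary.csv, {args.outdir}/lateralization.csv")


if __name__ == "__main__":
    main()
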