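#!/usr/bin/env python
"""Condition contrasts of relative TE with FDR-corrected group statistics.

Runs the full chain — cohort generation, preprocessing, per-subject relative
TE, per-pair Wilcoxon signed-rank across subjects, Benjamini-Hochberg
correction over the 72-pair family — for one planted replicate (beta-band
Pz->Cz and P3->F4 couplings in bcMI only, 14 subjects) and one null
replicate, and reports which edges survive.
"""
import argparse
from pathlib import Path

from miconn.pipeline import planted_contrast_study


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    planted = planted_contrast_study(seed=args.seed)
    table = planted["contrast"].table
    table.to_csv(args.outdir / "contrast_planted.csv", index=False, float_format="%.6g")
    print(f"planted replicate (bcMI vs tMI, right hand, beta band):")
    print(f"  planted edges : {sorted(planted['planted'])}")
    print(f"  retained edges: {sorted(planted['retained'])}")
    print(f"  recall = {planted['recall']:.2f}, "
          f"retained fraction = {planted['retained_fraction']:.3f}")

    null = planted_contrast_study(seed=args.seed + 1, couplings=())
    null["contrast"].table.to_csv(args.outdir / "contrast_null.csv", index=False,
                                  float_format="%.6g")
    print(f"null replicate: retained fraction = {null['retained_fraction']:.3f} "
          f"(family-wise FDR target 0.05)")
    print(f"tables -> {args.outdir}/contrast_planted.csv, {args.outdir}/contrast_null.csv")


if __name__ == "__main__":
    main()
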