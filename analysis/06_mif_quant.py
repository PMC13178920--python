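#!/usr/bin/env python
"""Multiplex-IF quantification and the MVI+ vs MVI- group contrast.

Synthesizes MIF fields for both groups at the planted triple-positive
rates (0.30 vs 0.05), runs the full single-cell pipeline on each
(rolling-ball subtraction, mean+3SD thresholds, DAPI segmentation with
3 um expansion, 25-200 um^2 filter), and compares per-image triple
ratios with a Student t test.
"""

import argparse
from pathlib import Path

import pandas as pd

from smvk.pipeline import mif_group_contrast


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--images-per-group", type=int, default=3)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ratios, t_stat, p = mif_group_contrast(args.seed,
                                           n_per_group=args.images_per_group)
    rows = [{"group": g, "image": i, "triple_ratio_pct": r}
            for g, rs in ratios.items() for i, r in enumerate(rs)]
    df = pd.DataFrame(rows)
    df.to_csv(args.out / "mif_triple_ratios.csv", index=False)
    print(df.to_string(index=False))
    mp = sum(ratios["MVI_POS"]) / len(ratios["MVI_POS"])
    mn = sum(ratios["MVI_NEG"]) / len(ratios["MVI_NEG"])
    print(f"\nMean triple-positive ratio: MVI+ {mp:.1f}% vs MVI- {mn:.1f}% "
          f"(planted 30% vs 5%); Student t = {t_stat:.2f}, p = {p:.2e}")


if __name__ == "__main__":
    main()
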