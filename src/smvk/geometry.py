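"""Hexagonal-lattice geometry: tumor boundary spots and boundary distances.

On the Visium lattice every interior spot has six neighbors. A spot of a
region is a *boundary* spot when at least one of its six lattice
neighbor positions is missing from the section or carries a different
region label; otherwise it is a *core* spot. For spots outside the
region, the distance to the boundary is the minimum Euclidean distance
(in um, from spot centroids) to any boundary spot.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy import stats

from .types import REGIONS, SpotSample

__all__ = [
    "HEX_OFFSETS",
    "hex_neighbors",
    "BoundaryResult",
    "classify_boundary",
    "DistanceField",
    "distance_to_boundary",
    "assign_regions",
    "score_distance_gradient",
]

# (d_row, d_col) offsets of the six hex neighbors in array coordinates
HEX_OFFSETS = ((0, 2), (0, -2), (-1, 1), (-1, -1), (1, 1), (1, -1))


def hex_neighbors(spot, existing: Optional[set] = None):
    """Six lattice-neighbor positions of ``spot`` = (array_row, array_col).

    With ``existing`` given, only positions present in that set are
    returned (tissue-edge spots then have fewer than six).
    """
    r, c = int(spot[0]), int(spot[1])
    if existing is not None:
        parities = {(rr + cc) % 2 for rr, cc in existing}
        if parities and ((r + c) % 2) not in parities:
            raise ValueError(f"coordinate {(r, c)} violates lattice parity")
    out = [(r + dr, c + dc) for dr, dc in HEX_OFFSETS]
    if existing is not None:
        out = [p for p in out if p in existing]
    return out


@dataclass
class BoundaryResult:
    target_region: str
    core_spots: set      # barcodes
    boundary_spots: set  # barcodes


def classify_boundary(sample: SpotSample, target_region: str) -> BoundaryResult:
    """Split the spots of ``target_region`` into core and boundary spots."""
    in_region = sample.region_label == target_region
    if not np.any(in_region):
        raise ValueError(f"region {target_region!r} absent from sample {sample.sample_id}")
    coord_region = {
        tuple(rc): lab for rc, lab in zip(sample.array_coords, sample.region_label)
    }
    core, boundary = set(), set()
    for bc, rc, lab in zip(sample.barcodes, sample.array_coords, sample.region_label):
        if lab != target_region:
            continue
        r, c = int(rc[0]), int(rc[1])
        is_boundary = False
        for dr, dc in HEX_OFFSETS:
            nb = coord_region.get((r + dr, c + dc))
            if nb is None or nb != target_region:
                is_boundary = True
                break
        (boundary if is_boundary else core).add(bc)
    return BoundaryResult(target_region=target_region, core_spots=core, boundary_spots=boundary)


@dataclass
class DistanceField:
    distance_um: pd.Series        # indexed by query barcode
    nearest_boundary_spot: pd.Series


def distance_to_boundary(sample: SpotSample, boundary: BoundaryResult,
                         query_spots: Iterable[str]) -> DistanceField:
    """Shortest Euclidean um distance from each query spot to the boundary.

    Query spots must lie outside the target region. Distance ties go to
    the lexicographically smallest boundary barcode.
    """
    if not boundary.boundary_spots:
        raise ValueError("boundary set is empty")
    idx = sample.barcode_index()
    region_of = dict(zip(sample.barcodes, sample.region_label))
    query = list(query_spots)
    for q in query:
        if q not in idx:
            raise ValueError(f"unknown query barcode {q!r}")
        if region_of[q] == boundary.target_region:
            raise ValueError(f"query spot {q!r} lies inside the target region")
    bnd = sorted(boundary.boundary_spots)  # lexicographic order for tie-breaks
    bxy = sample.xy_um[[idx[b] for b in bnd]]
    tree = cKDTree(bxy)
    qxy = sample.xy_um[[idx[q] for q in query]]
    dists, _ = tree.query(qxy)
    nearest = []
    for (x, y), d in zip(qxy, dists):
        hits = tree.query_ball_point((x, y), d + 1e-9)
        nearest.append(bnd[min(hits)])  # bnd is sorted, so min index = lexicographic min
    return DistanceField(
        distance_um=pd.Series(dists, index=query, name="distance_um"),
        nearest_boundary_spot=pd.Series(nearest, index=query, name="nearest_boundary_spot"),
    )


def assign_regions(sample: SpotSample, cluster_to_region: Mapping[str, str],
                   overrides: Optional[Mapping[str, Mapping[str, str]]] = None) -> SpotSample:
    """Map spot clusters to regions, with optional per-sample overrides.

    ``overrides[sample_id][cluster]`` beats the global map (used when a
    cluster that is paratumoral elsewhere sits inside the lesion of one
    patient). TR-mapped spots are flagged excluded from differential
    expression.
    """
    overrides = overrides or {}
    local = dict(cluster_to_region)
    local.update(overrides.get(sample.sample_id, {}))
    unmapped = sorted(set(sample.cluster_label) - set(local))
    if unmapped:
        raise ValueError(f"clusters without region mapping: {unmapped}")
    region = np.array([local[c] for c in sample.cluster_label], dtype=object)
    bad = set(region) - set(REGIONS)
    if bad:
        raise ValueError(f"mapped to unknown regions: {sorted(bad)}")
    return replace(sample, region_label=region, de_excluded=region == "TR")


def score_distance_gradient(scores: pd.Series, dist: DistanceField,
                            method: str = "spearman"):
    """Correlate per-spot scores with distance to the tumor boundary.

    Returns (rho, two-sided p) over the spots present in both inputs.
    """
    common = scores.index.intersection(dist.distance_um.index)
    x = scores.loc[common].to_numpy(float)
    y = dist.distance_um.loc[common].to_numpy(float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in scores or distances")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be pearson|spearman")
    return float(res.statistic), float(res.pvalue)
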