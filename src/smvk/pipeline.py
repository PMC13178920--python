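"""End-to-end orchestration over a synthetic cohort.

These are the computations the numbered analysis drivers and the
reproduction script share: boundary fields, panel selection, signature
gradients, raster segmentation and enrichment, cross-modal correlation
and the MIF group contrast — each built from the module-level
operations so any stage can also be run in isolation.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .config import rng_stream
from .crossmodal import (metabolite_cell_correlation, pixels_to_spots,
                         pooled_correlation)
from .geometry import classify_boundary, distance_to_boundary, score_distance_gradient
from .markers import compute_marker_stats, module_score, select_panel
from .mif import group_compare, quantify_image
from .msi import ssc_cluster
from .synthetic import (GLYCEROLIPID_IONS, Cohort, MifImageParams,
                        generate_disk_raster, generate_mif_image)

__all__ = [
    "boundary_field",
    "panel_from_sample",
    "signature_gradient",
    "taurine_icaf_correlations",
    "glycerolipid_ratio",
    "ssc_recovery_ari",
    "mif_group_contrast",
]


def boundary_field(sample, target_region: str = "T"):
    """Boundary split of a region plus distances for all outside spots."""
    boundary = classify_boundary(sample, target_region)
    outside = [b for b, r in zip(sample.barcodes, sample.region_label)
               if r != target_region]
    dist = distance_to_boundary(sample, boundary, outside)
    return boundary, dist


def panel_from_sample(sample, reference_bulk, positive_cluster: str = "C6",
                      apriori_gene: str = "GPC3", **kw):
    """Marker stats for the positive cluster vs the rest, then selection."""
    pos = np.flatnonzero(sample.cluster_label == positive_cluster)
    neg = np.flatnonzero(sample.cluster_label != positive_cluster)
    stats_df = compute_marker_stats(sample.counts, sample.gene_ids, pos, neg)
    return select_panel(stats_df, reference_bulk, apriori_gene, **kw), stats_df


def signature_gradient(sample, gene_set, seed: int, region: str = "TC",
                       method: str = "spearman"):
    """Signature score vs distance-to-boundary correlation within a region."""
    scores = module_score(sample.counts, sample.gene_ids, gene_set,
                          rng_stream(seed, f"score-{sample.sample_id}"))
    boundary, dist = boundary_field(sample, "T")
    keep = [b for b, r in zip(sample.barcodes, sample.region_label) if r == region]
    series = pd.Series(scores, index=sample.barcodes.astype(str)).loc[keep]
    sub = dist.distance_um.loc[keep]
    from .geometry import DistanceField
    return score_distance_gradient(series, DistanceField(sub, dist.nearest_boundary_spot.loc[keep]),
                                   method=method)


def taurine_icaf_correlations(cohort: Cohort, ion: str = "taurine",
                              cell_type: str = "iCAF") -> pd.DataFrame:
    """Per-tumor-sample Pearson r between an ion and a cell type, pooled."""
    rows = []
    for sample, raster, truth in cohort.samples:
        if sample.group == "NORMAL" or sample.proportions is None:
            continue
        tf = truth.registration_transform.inverse()
        spotmet = pixels_to_spots(raster, sample, tf)
        corr = metabolite_cell_correlation(spotmet, sample.proportions, ions=[ion])
        row = corr[corr["cell_type"] == cell_type].iloc[0].to_dict()
        row["sample_id"] = sample.sample_id
        rows.append(row)
    per_sample = pd.DataFrame(rows)
    pooled = pooled_correlation(per_sample, by=["ion", "cell_type"])
    return per_sample, pooled


def glycerolipid_ratio(cohort: Cohort) -> float:
    """Mean MVI+/MVI- ratio of tumor-pixel glycerolipid ion intensity."""
    means = {"MVI_POS": [], "MVI_NEG": []}
    for sample, raster, truth in cohort.samples:
        if sample.group not in means:
            continue
        t_px = truth.raster_region == "T"
        means[sample.group].append(
            raster.intensities[np.ix_(t_px, list(GLYCEROLIPID_IONS))].mean(axis=0))
    pos = np.mean(means["MVI_POS"], axis=0)
    neg = np.mean(means["MVI_NEG"], axis=0)
    return float(np.mean(pos / neg))


def ssc_recovery_ari(seed: int = 5, **ssc_kw) -> float:
    """Adjusted Rand index of SSC segmentation vs the planted disk regions."""
    raster, labels = generate_disk_raster(rng=rng_stream(seed, "disk"))
    kw = dict(r=1, k_init=15, s=3.0)
    kw.update(ssc_kw)
    model = ssc_cluster(raster, rng=rng_stream(seed, "ssc"), **kw)
    return float(adjusted_rand_score(labels, model.assignments))


def mif_group_contrast(seed: int, n_per_group: int = 3,
                       rate_pos: float = 0.30, rate_neg: float = 0.05,
                       params: Optional[MifImageParams] = None):
    """Full-image MIF quantification of two groups plus the t contrast."""
    base = params or MifImageParams()
    ratios = {"MVI_POS": [], "MVI_NEG": []}
    for group, rate in (("MVI_POS", rate_pos), ("MVI_NEG", rate_neg)):
        for i in range(n_per_group):
            p = MifImageParams(**{**base.__dict__, "mode": "planted_triple",
                                  "triple_rate": rate})
            img, _, _ = generate_mif_image(
                p, rng_stream(seed, f"mif-{group}-{i}"),
                sample_id=f"{group}-{i}", group=group)
            _, report, _ = quantify_image(img)
            ratios[group].append(report.triple_ratio_pct)
    t, pval = group_compare(ratios["MVI_POS"], ratios["MVI_NEG"], "student_t")
    return ratios, t, pval
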