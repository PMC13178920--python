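"""Spatial metabolite analysis: SSC segmentation and class enrichment.

Segmentation follows the spatially-aware shrunken-centroid scheme:
each pixel's TIC-normalized spectrum is smoothed over its
(2r+1) x (2r+1) grid neighborhood with Gaussian weights (sigma = r/2);
the structurally-adaptive variant additionally down-weights neighbors
whose spectra differ from the center. Pixels are then assigned by a
nearest-shrunken-centroid rule: per-ion cluster statistics

    t[k, j] = (centroid[k, j] - global_mean[j]) / (m_k * (s_j + s0))

are soft-thresholded by the sparsity parameter s (|t| -> max(|t| - s, 0),
sign kept), the shrunken centroids are rebuilt from the thresholded
statistics, and each pixel goes to the cluster with the smallest
standardized squared distance to the shrunken centroid. Iterating
assignment and shrinkage to a fixed point both segments the image and
selects the ions that distinguish each segment. Here s_j is the global
per-ion standard deviation of the smoothed matrix and s0 its median,
held fixed across iterations, so that with s = 0 and r = 0 the
iteration is exactly Lloyd's k-means on the standardized matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import MsiRaster

__all__ = [
    "tic_normalize",
    "SscModel",
    "ssc_cluster",
    "cluster_marker_ions",
    "class_enrichment",
    "differential_metabolites",
]

_EPS = 1e-9


def tic_normalize(intensities: np.ndarray) -> np.ndarray:
    """Scale every pixel spectrum to the global median total ion current."""
    intensities = np.asarray(intensities, dtype=float)
    tic = intensities.sum(axis=1)
    pos = tic > 0
    if not np.any(pos):
        return intensities.copy()
    med = np.median(tic[pos])
    scale = np.ones_like(tic)
    scale[pos] = med / tic[pos]
    return intensities * scale[:, None]


def _grid_layout(pixel_xy: np.ndarray):
    """Map pixels onto integer grid indices (iy, ix) plus grid shape."""
    out = []
    for axis in (0, 1):
        vals = np.unique(pixel_xy[:, axis])
        step = np.min(np.diff(vals)) if len(vals) > 1 else 1.0
        out.append(np.round((pixel_xy[:, axis] - vals[0]) / step).astype(int))
    ix, iy = out
    return iy, ix, iy.max() + 1, ix.max() + 1


def spatial_smooth(raster_xy: np.ndarray, X: np.ndarray, r: int,
                   weights: str = "SA") -> np.ndarray:
    """Gaussian neighborhood smoothing of pixel spectra on the grid.

    ``weights='SASA'`` multiplies the spatial kernel by a spectral
    similarity weight exp(-||x_j - x_i||^2 / (2 sigma_a^2)) with sigma_a
    the median neighbor spectral distance over the whole image.
    """
    if r == 0:
        return np.asarray(X, dtype=float).copy()
    iy, ix, ny, nx = _grid_layout(raster_xy)
    p, n_ions = X.shape
    grid = np.zeros((ny, nx, n_ions))
    valid = np.zeros((ny, nx), dtype=bool)
    grid[iy, ix] = X
    valid[iy, ix] = True
    sigma = r / 2.0
    offsets = [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1)]

    sigma_a = None
    if weights == "SASA":
        dists = []
        for dy, dx in offsets:
            if dy == 0 and dx == 0:
                continue
            src_y = slice(max(0, -dy), ny - max(0, dy))
            src_x = slice(max(0, -dx), nx - max(0, dx))
            dst_y = slice(max(0, dy), ny - max(0, -dy))
            dst_x = slice(max(0, dx), nx - max(0, -dx))
            both = valid[dst_y, dst_x] & valid[src_y, src_x]
            d = np.linalg.norm(grid[dst_y, dst_x] - grid[src_y, src_x], axis=-1)
            dists.append(d[both])
        pooled = np.concatenate(dists) if dists else np.array([1.0])
        sigma_a = float(np.median(pooled))
        if sigma_a == 0:
            sigma_a = 1.0
    elif weights != "SA":
        raise ValueError("weights must be SA|SASA")

    acc = np.zeros_like(grid)
    wsum = np.zeros((ny, nx))
    for dy, dx in offsets:
        w0 = np.exp(-(dy * dy + dx * dx) / (2 * sigma * sigma))
        src_y = slice(max(0, -dy), ny - max(0, dy))
        src_x = slice(max(0, -dx), nx - max(0, dx))
        dst_y = slice(max(0, dy), ny - max(0, -dy))
        dst_x = slice(max(0, dx), nx - max(0, -dx))
        both = valid[dst_y, dst_x] & valid[src_y, src_x]
        w = np.where(both, w0, 0.0)
        if weights == "SASA":
            d2 = np.sum((grid[dst_y, dst_x] - grid[src_y, src_x]) ** 2, axis=-1)
            w = w * np.exp(-d2 / (2 * sigma_a * sigma_a))
            w = np.where(both, w, 0.0)
        acc[dst_y, dst_x] += w[..., None] * grid[src_y, src_x]
        wsum[dst_y, dst_x] += w
    wsum[wsum == 0] = 1.0
    smoothed = acc / wsum[..., None]
    return smoothed[iy, ix]


@dataclass
class SscModel:
    r: int
    k_init: int
    s: float
    weights: str
    assignments: np.ndarray       # (pixels,) cluster ids 0..K-1 (relabelled)
    centroids: np.ndarray         # (K, ions) shrunken centroids
    tstat: np.ndarray             # (K, ions) soft-thresholded statistics
    global_mean: np.ndarray       # (ions,)
    n_iter: int
    init_indices: np.ndarray      # pixel indices used as k-means++ seeds
    objective: list               # per-iteration sum of discriminant scores

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]


def _kmeanspp(Z: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Standard k-means++ seeding; returns chosen pixel indices."""
    n = Z.shape[0]
    idx = [int(rng.integers(n))]
    d2 = np.sum((Z - Z[idx[0]]) ** 2, axis=1)
    for _ in range(1, k):
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        nxt = int(rng.choice(n, p=probs))
        idx.append(nxt)
        d2 = np.minimum(d2, np.sum((Z - Z[nxt]) ** 2, axis=1))
    return np.asarray(idx)


def ssc_cluster(raster: MsiRaster, r: int = 1, k_init: int = 15, s: float = 3.0,
                weights: str = "SA", rng: Optional[np.random.Generator] = None,
                *, use_priors: bool = False, max_iter: int = 100) -> SscModel:
    """Spatially-aware shrunken-centroid segmentation of an MSI raster."""
    if r < 0:
        raise ValueError("r must be >= 0")
    if k_init < 1:
        raise ValueError("k_init must be >= 1")
    if s < 0:
        raise ValueError("s must be >= 0")
    if not np.all(np.isfinite(raster.intensities)):
        raise ValueError("intensities must be finite")
    rng = rng if rng is not None else np.random.default_rng(0)

    X = tic_normalize(raster.intensities)
    Xs = spatial_smooth(raster.pixel_xy_um, X, r=r, weights=weights)
    n, p = Xs.shape
    sj = Xs.std(axis=0, ddof=0)
    s0 = float(np.median(sj))
    sc = sj + s0
    sc[sc == 0] = 1.0
    gmean = Xs.mean(axis=0)
    Z = Xs / sc

    init_idx = _kmeanspp(Z, min(k_init, n), rng)
    centers_z = Z[init_idx]
    assign = np.argmin(
        ((Z[:, None, :] - centers_z[None, :, :]) ** 2).sum(-1), axis=1
    )

    objective = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        labels = np.unique(assign)
        nk = np.array([(assign == k).sum() for k in labels], dtype=float)
        centroids = np.stack([Xs[assign == k].mean(axis=0) for k in labels])
        mk = np.sqrt(1.0 / nk + 1.0 / n)
        t = (centroids - gmean) / (mk[:, None] * sc[None, :])
        tshr = np.sign(t) * np.maximum(np.abs(t) - s, 0.0)
        cshr = gmean + mk[:, None] * sc[None, :] * tshr
        scores = ((Z[:, None, :] - (cshr / sc)[None, :, :]) ** 2).sum(-1)
        if use_priors:
            scores = scores - 2.0 * np.log(nk / n)[None, :]
        new_assign_local = np.argmin(scores, axis=1)
        objective.append(float(scores[np.arange(n), new_assign_local].sum()))
        new_assign = labels[new_assign_local]
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign

    labels = np.unique(assign)
    relabel = {k: i for i, k in enumerate(labels)}
    final = np.array([relabel[a] for a in assign])
    nk = np.array([(final == k).sum() for k in range(len(labels))], dtype=float)
    centroids = np.stack([Xs[final == k].mean(axis=0) for k in range(len(labels))])
    mk = np.sqrt(1.0 / nk + 1.0 / n)
    t = (centroids - gmean) / (mk[:, None] * sc[None, :])
    tshr = np.sign(t) * np.maximum(np.abs(t) - s, 0.0)
    cshr = gmean + mk[:, None] * sc[None, :] * tshr
    return SscModel(r=r, k_init=k_init, s=s, weights=weights, assignments=final,
                    centroids=cshr, tstat=tshr, global_mean=gmean,
                    n_iter=n_iter, init_indices=init_idx, objective=objective)


def cluster_marker_ions(model: SscModel, top_n: int = 10) -> dict:
    """Top ions per cluster ranked by descending shrunken statistic.

    Only ions with a positive (enriched) statistic qualify; ties break
    by ascending ion index so the ordering is deterministic. A fully
    shrunk cluster yields an empty list.
    """
    out = {}
    for k in range(model.n_clusters):
        t = model.tstat[k]
        ions = [j for j in range(len(t)) if t[j] > 0]
        ions.sort(key=lambda j: (-t[j], j))
        out[k] = ions[:top_n]
    return out


def _corrected(a, b, c, d):
    if min(a, b, c, d) == 0:
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(a), float(b), float(c), float(d)


def class_enrichment(marker_ions: Sequence[int], raster: MsiRaster,
                     level: str = "super_class") -> pd.DataFrame:
    """Fisher-exact enrichment of metabolite classes among marker ions.

    For each class at the chosen annotation level, a 2x2 table is built
    over *annotated* ions only: (marker in class, marker out of class,
    non-marker in class, non-marker out of class). The odds ratio uses
    a Haldane 0.5 correction only when a zero cell occurs; the 95% CI is
    the log-OR normal approximation on the (corrected) table. Raw
    two-sided Fisher p values are reported alongside BH-adjusted q.
    """
    if raster.annotations is None:
        raise ValueError("raster has no ion annotations")
    if level not in ("super_class", "class_", "sub_class"):
        raise ValueError("level must be super_class|class_|sub_class")
    marker_ions = set(int(i) for i in marker_ions)
    if not marker_ions:
        raise ValueError("empty marker ion set")
    labels = raster.annotations[level].to_numpy(dtype=object)
    annotated = np.array([isinstance(l, str) and l != "" for l in labels])
    ann_idx = np.flatnonzero(annotated)
    markers = marker_ions & set(ann_idx.tolist())
    classes = sorted({labels[i] for i in ann_idx})
    rows = []
    for cls in classes:
        in_cls = {int(i) for i in ann_idx if labels[i] == cls}
        a = len(markers & in_cls)
        b = len(markers - in_cls)
        c = len(in_cls - markers)
        d = len(ann_idx) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        ca, cb, cc, cd = _corrected(a, b, c, d)
        orr = (ca * cd) / (cb * cc)
        se = np.sqrt(1 / ca + 1 / cb + 1 / cc + 1 / cd)
        rows.append({"class_name": cls, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": orr,
                     "ci_low": float(np.exp(np.log(orr) - 1.959963984540054 * se)),
                     "ci_high": float(np.exp(np.log(orr) + 1.959963984540054 * se)),
                     "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def differential_metabolites(raster: MsiRaster, region_mask_a, region_mask_b,
                             lfc_min: float = 1.0, q_max: float = 0.05) -> pd.DataFrame:
    """Ions differing between two pixel masks (A vs B).

    log2FC compares mean TIC-normalized intensity (1e-9 floor), p is a
    two-sided Wilcoxon rank-sum over pixels, q is BH. Returns the ions
    passing both |log2FC| and q thresholds with their direction.
    """
    a = np.asarray(region_mask_a, dtype=int)
    b = np.asarray(region_mask_b, dtype=int)
    if len(set(a.tolist()) & set(b.tolist())):
        raise ValueError("pixel masks overlap")
    if len(a) < 10 or len(b) < 10:
        raise ValueError("each mask needs at least 10 pixels")
    X = tic_normalize(raster.intensities)
    A, B = X[a], X[b]
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    log2fc = np.log2((mean_a + _EPS) / (mean_b + _EPS))
    res = stats.mannwhitneyu(A, B, axis=0, alternative="two-sided", method="auto")
    p = np.atleast_1d(res.pvalue).astype(float)
    q = multipletests(p, method="fdr_bh")[1]
    df = pd.DataFrame({
        "ion": np.arange(raster.n_ions), "mz": raster.mz,
        "log2fc": log2fc, "p": p, "q": q,
    })
    if raster.annotations is not None:
        df["name"] = raster.annotations["name"].to_numpy(dtype=object)
    keep = (np.abs(df["log2fc"]) > lfc_min) & (df["q"] < q_max)
    out = df[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out.reset_index(drop=True)
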