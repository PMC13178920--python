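"""Registration of the metabolite raster onto the spot lattice and
spatial correlation of metabolite intensities with cell proportions,
signature scores and boundary distances.

Serial sections differ mainly by scale, rotation and shift, so a
4-degree-of-freedom similarity transform fitted to matched landmarks
(least-squares / Umeyama) carries MSI pixel coordinates into the spot
frame; each pixel is then assigned to its nearest spot center within a
cutoff radius (half the spot pitch by default) and per-spot ion values
are pixel means, so they are independent of the pixel pitch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from skimage import transform as sktransform

from .geometry import DistanceField
from .types import MsiRaster, SpotSample

__all__ = [
    "SimilarityTransform",
    "fit_similarity",
    "SpotMetabolite",
    "pixels_to_spots",
    "metabolite_cell_correlation",
    "pooled_correlation",
    "metabolite_distance_correlation",
]


@dataclass
class SimilarityTransform:
    """x' = scale * R(rotation) x + translation (um)."""

    scale: float
    rotation: float
    translation: tuple
    rmse: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return xy @ self.matrix().T + np.asarray(self.translation)

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        inv_rot = -self.rotation
        c, s = np.cos(inv_rot), np.sin(inv_rot)
        R = inv_scale * np.array([[c, -s], [s, c]])
        t = -R @ np.asarray(self.translation)
        return SimilarityTransform(scale=inv_scale, rotation=inv_rot,
                                   translation=(float(t[0]), float(t[1])))


def fit_similarity(landmarks_src, landmarks_dst) -> SimilarityTransform:
    """Least-squares similarity transform mapping src landmarks to dst."""
    src = np.asarray(landmarks_src, dtype=float)
    dst = np.asarray(landmarks_dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[0] < 2:
        raise ValueError("need >= 2 matched landmark pairs")
    if np.allclose(np.ptp(src, axis=0), 0):
        raise ValueError("source landmarks are coincident")
    if hasattr(sktransform.SimilarityTransform, "from_estimate"):
        tf = sktransform.SimilarityTransform.from_estimate(src, dst)
        if not tf:
            raise ValueError("similarity estimation failed")
    else:
        tf = sktransform.SimilarityTransform()
        if not tf.estimate(src, dst):
            raise ValueError("similarity estimation failed")
    resid = tf(src) - dst
    rmse = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return SimilarityTransform(scale=float(tf.scale), rotation=float(tf.rotation),
                               translation=(float(tf.translation[0]),
                                            float(tf.translation[1])),
                               rmse=rmse)


@dataclass
class SpotMetabolite:
    """Per-spot aggregated ion intensities; uncovered spots are missing (NaN)."""

    intensity: pd.DataFrame   # spots x ions (NaN where n_pixels == 0)
    n_pixels: pd.Series       # per spot

    def covered(self) -> pd.Index:
        return self.n_pixels.index[self.n_pixels > 0]


def pixels_to_spots(raster: MsiRaster, sample: SpotSample,
                    transform: SimilarityTransform,
                    radius_um: Optional[float] = None) -> SpotMetabolite:
    """Map raster pixels into the spot frame and aggregate per spot.

    ``transform`` carries pixel coordinates into the spot frame. Each
    pixel joins the nearest spot center if within ``radius_um`` (default:
    half the lattice pitch); per-spot values are means over its pixels.
    """
    mapped = transform.apply(raster.pixel_xy_um)
    if radius_um is None:
        tree_sp = cKDTree(sample.xy_um)
        d, _ = tree_sp.query(sample.xy_um, k=2)
        radius_um = float(np.median(d[:, 1])) / 2.0
    tree = cKDTree(sample.xy_um)
    dist, nearest = tree.query(mapped)
    # resolve exact distance ties toward the lexicographically smaller barcode
    order = np.argsort(sample.barcodes.astype(str), kind="mergesort")
    assigned = np.full(len(mapped), -1, dtype=int)
    for i, (pt, d0) in enumerate(zip(mapped, dist)):
        if d0 > radius_um:
            continue
        hits = tree.query_ball_point(pt, d0 + 1e-9)
        if len(hits) == 1:
            assigned[i] = hits[0]
        else:
            hitset = set(hits)
            assigned[i] = next(j for j in order if j in hitset)
    if np.all(assigned < 0):
        raise ValueError("registration failed: no pixel maps to any spot")
    n = sample.n_spots
    sums = np.zeros((n, raster.n_ions))
    counts = np.zeros(n, dtype=int)
    for i, j in enumerate(assigned):
        if j >= 0:
            sums[j] += raster.intensities[i]
            counts[j] += 1
    vals = np.full((n, raster.n_ions), np.nan)
    nz = counts > 0
    vals[nz] = sums[nz] / counts[nz, None]
    cols = [raster.annotations["name"][j] or repr(raster.mz[j])
            for j in range(raster.n_ions)] if raster.annotations is not None \
        else [repr(m) for m in raster.mz]
    return SpotMetabolite(
        intensity=pd.DataFrame(vals, index=sample.barcodes.astype(str), columns=cols),
        n_pixels=pd.Series(counts, index=sample.barcodes.astype(str)),
    )


def _pairwise_corr(x: np.ndarray, y: np.ndarray, method: str = "pearson"):
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 10:
        raise ValueError("need >= 10 paired spots")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan, len(x)
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be pearson|spearman")
    return float(res.statistic), float(res.pvalue), len(x)


def metabolite_cell_correlation(spotmet: SpotMetabolite, proportions: pd.DataFrame,
                                ions: Optional[Sequence[str]] = None,
                                method: str = "pearson") -> pd.DataFrame:
    """Per (ion, cell type) correlation of spot intensity vs proportion.

    Spots without raster coverage drop out pairwise; zero-variance ions
    report a missing (NaN) coefficient rather than 0.
    """
    ions = list(ions) if ions is not None else list(spotmet.intensity.columns)
    common = spotmet.covered().intersection(proportions.index)
    rows = []
    for ion in ions:
        x = spotmet.intensity.loc[common, ion].to_numpy(float)
        for ct in proportions.columns:
            y = proportions.loc[common, ct].to_numpy(float)
            rho, p, n = _pairwise_corr(x, y, method)
            rows.append({"ion": ion, "cell_type": ct, "rho": rho, "p": p, "n": n})
    return pd.DataFrame(rows)


def pooled_correlation(per_sample_rho: pd.DataFrame,
                       by=("ion", "cell_type")) -> pd.DataFrame:
    """Unweighted mean correlation across samples for each (ion, target).

    Missing per-sample estimates are dropped; the number of contributing
    samples is reported per pair.
    """
    by = list(by)
    grp = per_sample_rho.dropna(subset=["rho"]).groupby(by)["rho"]
    out = grp.agg(["mean", "count"]).reset_index()
    return out.rename(columns={"mean": "mean_rho", "count": "n_samples"})


def metabolite_distance_correlation(spotmet: SpotMetabolite, dist: DistanceField,
                                    ion: str, method: str = "pearson"):
    """Correlate one ion's spot intensity with distance to the boundary."""
    common = spotmet.covered().intersection(dist.distance_um.index)
    x = spotmet.intensity.loc[common, ion].to_numpy(float)
    y = dist.distance_um.loc[common].to_numpy(float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in intensity or distance")
    res = stats.pearsonr(x, y) if method == "pearson" else stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
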