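"""Multiplex-immunofluorescence single-cell quantification.

The workflow mirrors a HALO-style analysis: rolling-ball background
subtraction (radius 15 px), per-channel positivity thresholds set at
the background mean plus three standard deviations, DAPI nuclear
segmentation with a 3 um cytoplasmic expansion, a 25-200 um^2 nuclear
object filter, and co-localization ratios over GPC3+ cells:

    triple ratio (%) = 100 * |STMN1+ HMGN2+ GPC3+| / |GPC3+|

with the analogous STMN1+GPC3+ and HMGN2+GPC3+ double ratios. Group
comparisons of per-image ratios use a two-sided t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import measure, morphology, restoration, segmentation
from skimage.filters import threshold_otsu

from .types import MifImage

__all__ = [
    "rolling_ball_subtract",
    "channel_threshold",
    "MifParams",
    "Segmentation",
    "segment_cells",
    "call_positivity",
    "RatioReport",
    "colocalization_ratios",
    "group_compare",
    "quantify_image",
]

MARKERS = ("STMN1", "HMGN2", "GPC3")


def rolling_ball_subtract(channel: np.ndarray, radius_px: int = 15) -> np.ndarray:
    """Subtract the rolling-ball background estimate, clipping at zero."""
    if radius_px <= 0:
        raise ValueError("radius must be > 0")
    channel = np.asarray(channel, dtype=float)
    background = restoration.rolling_ball(channel, radius=radius_px)
    return np.clip(channel - background, 0.0, None)


def channel_threshold(channel: np.ndarray, background_mask: np.ndarray) -> float:
    """Positivity cutoff: background mean + 3 * population SD."""
    mask = np.asarray(background_mask, dtype=bool)
    if not mask.any():
        raise ValueError("background mask is empty")
    vals = np.asarray(channel, dtype=float)[mask]
    if vals.size == 1:
        warnings.warn("background mask has a single pixel; SD is zero")
    return float(vals.mean() + 3.0 * vals.std(ddof=0))


@dataclass
class MifParams:
    dapi_threshold: object = "otsu"   # "otsu" or a fixed float
    expansion_um: float = 3.0
    area_min_um2: float = 25.0
    area_max_um2: float = 200.0
    rolling_ball_radius: int = 15
    background_dilation_um: float = 10.0
    positivity_stat: str = "mean"     # mean over cell region | nucleus_mean


@dataclass
class Segmentation:
    cells: pd.DataFrame          # id, x_um, y_um, nucleus_area_um2, cell_area_um2
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    pixel_size_um: float

    def background_mask(self, dilation_um: float = 10.0) -> np.ndarray:
        """Pixels beyond a dilation of all nuclei; HALO-style control region."""
        radius = max(1, int(round(dilation_um / self.pixel_size_um)))
        dilated = ndimage.binary_dilation(self.nucleus_labels > 0,
                                          structure=morphology.disk(radius))
        return ~dilated


def segment_cells(image: MifImage, params: Optional[MifParams] = None) -> Segmentation:
    """DAPI nuclear segmentation with cytoplasmic expansion.

    Nuclei are connected components of the thresholded, rolling-ball
    subtracted DAPI channel; components outside the area window are
    dropped; survivors expand by ``expansion_um`` with contested pixels
    going to the nearest nucleus (distance-transform label expansion).
    """
    params = params or MifParams()
    px = image.pixel_size_um
    dapi = rolling_ball_subtract(image.channels["DAPI"], params.rolling_ball_radius)
    if params.dapi_threshold == "otsu":
        thr = threshold_otsu(dapi)
    else:
        thr = float(params.dapi_threshold)
    mask = dapi > thr
    labels, _ = ndimage.label(mask)
    props = measure.regionprops(labels)
    px_area = px * px
    keep = [p for p in props
            if params.area_min_um2 <= p.area * px_area <= params.area_max_um2]
    if not keep:
        raise ValueError("no cells: no nucleus passes the area filter")
    nucleus_labels = np.zeros_like(labels)
    rows = []
    for new_id, p in enumerate(sorted(keep, key=lambda p: p.label), start=1):
        nucleus_labels[labels == p.label] = new_id
        cy, cx = p.centroid
        rows.append({"id": new_id, "x_um": cx * px, "y_um": cy * px,
                     "nucleus_area_um2": p.area * px_area})
    cell_labels = segmentation.expand_labels(nucleus_labels,
                                             distance=params.expansion_um / px)
    areas = np.bincount(cell_labels.ravel(), minlength=len(rows) + 1)
    cells = pd.DataFrame(rows)
    cells["cell_area_um2"] = areas[cells["id"].to_numpy()] * px_area
    return Segmentation(cells=cells, nucleus_labels=nucleus_labels,
                        cell_labels=cell_labels, pixel_size_um=px)


def call_positivity(seg: Segmentation, image: MifImage,
                    thresholds: Mapping[str, float],
                    *, subtracted_channels: Optional[Mapping[str, np.ndarray]] = None,
                    stat: str = "mean") -> pd.DataFrame:
    """Per-cell marker means and positivity calls (mean >= threshold).

    ``subtracted_channels`` lets the caller pass background-subtracted
    channels so means and thresholds refer to the same images. With
    ``stat='nucleus_mean'`` the statistic is restricted to the nucleus.
    """
    region = seg.nucleus_labels if stat == "nucleus_mean" else seg.cell_labels
    cells = seg.cells.copy()
    ids = cells["id"].to_numpy()
    for ch in ("DAPI",) + MARKERS:
        img = (subtracted_channels or {}).get(ch, image.channels[ch])
        means = ndimage.mean(img, labels=region, index=ids)
        cells[f"mean_{ch}"] = means
        if ch in thresholds:
            # >= so a cell sitting exactly at the cutoff counts positive;
            # a cell with no signal at all never does (degenerate dark
            # channels would otherwise pass a zero threshold)
            cells[f"pos_{ch}"] = (means >= thresholds[ch]) & (means > 0)
    if all(f"pos_{m}" in cells for m in MARKERS):
        cells["triple"] = cells[[f"pos_{m}" for m in MARKERS]].all(axis=1)
    return cells


@dataclass
class RatioReport:
    triple_ratio_pct: float
    stmn1_gpc3_pct: float
    hmgn2_gpc3_pct: float
    n_gpc3_pos: int
    n_cells: int


def colocalization_ratios(cells: pd.DataFrame) -> RatioReport:
    """Co-localization ratios over the GPC3+ denominator."""
    gpc3 = cells["pos_GPC3"].to_numpy(bool)
    n_gpc3 = int(gpc3.sum())
    if n_gpc3 == 0:
        raise ValueError("ratio undefined: zero GPC3+ cells")
    stmn1 = cells["pos_STMN1"].to_numpy(bool)
    hmgn2 = cells["pos_HMGN2"].to_numpy(bool)
    triple = int((stmn1 & hmgn2 & gpc3).sum())
    sg = int((stmn1 & gpc3).sum())
    hg = int((hmgn2 & gpc3).sum())
    return RatioReport(
        triple_ratio_pct=100.0 * triple / n_gpc3,
        stmn1_gpc3_pct=100.0 * sg / n_gpc3,
        hmgn2_gpc3_pct=100.0 * hg / n_gpc3,
        n_gpc3_pos=n_gpc3,
        n_cells=len(cells),
    )


def group_compare(ratios_a, ratios_b, test: str = "welch_t"):
    """Two-sided t test of per-image ratios between groups."""
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 images")
    if test == "welch_t":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "student_t":
        res = stats.ttest_ind(a, b, equal_var=True)
    else:
        raise ValueError("test must be welch_t|student_t")
    return float(res.statistic), float(res.pvalue)


def quantify_image(image: MifImage, params: Optional[MifParams] = None,
                   background_masks: Optional[Mapping[str, np.ndarray]] = None):
    """Full single-image pipeline: subtract, segment, threshold, call, ratio.

    Returns (cells table, RatioReport, thresholds). Without explicit
    background masks, the control region is everything beyond a 10 um
    dilation of the nuclei.
    """
    params = params or MifParams()
    seg = segment_cells(image, params)
    sub = {m: rolling_ball_subtract(image.channels[m], params.rolling_ball_radius)
           for m in MARKERS}
    auto_mask = seg.background_mask(params.background_dilation_um)
    thresholds = {}
    for m in MARKERS:
        mask = background_masks[m] if background_masks and m in background_masks else auto_mask
        thresholds[m] = channel_threshold(sub[m], mask)
    cells = call_positivity(seg, image, thresholds, subtracted_channels=sub,
                            stat=params.positivity_stat)
    return cells, colocalization_ratios(cells), thresholds
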