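"""Shared domain containers for the spatial MVI pipeline.

A :class:`SpotSample` is one Visium-style tissue section: a hexagonal
lattice of capture spots with raw counts, cluster/region labels and
(optionally) per-spot cell-type proportions from upstream deconvolution.
A :class:`MsiRaster` is the matched mass-spectrometry-imaging section: a
regular pixel grid of per-ion intensities with an m/z annotation table.
A :class:`MifImage` is a multi-channel immunofluorescence field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "REGIONS",
    "GROUPS",
    "MIF_CHANNELS",
    "SpotSample",
    "MsiRaster",
    "MifImage",
]

REGIONS = ("T", "TC", "PT", "TR", "NA")
GROUPS = ("MVI_POS", "MVI_NEG", "NORMAL")
MIF_CHANNELS = ("DAPI", "STMN1", "HMGN2", "GPC3")


@dataclass
class SpotSample:
    """One tissue section on a hexagonal spot lattice.

    ``array_coords`` follow the 10x convention: integer (row, col) with
    row + col of constant parity; physical distances always come from
    ``xy_um``, never from array indices.
    """

    sample_id: str
    group: str
    barcodes: np.ndarray          # (n,) str
    array_coords: np.ndarray      # (n, 2) int: array_row, array_col
    xy_um: np.ndarray             # (n, 2) float
    counts: np.ndarray            # (genes, n) int
    gene_ids: np.ndarray          # (genes,) str
    cluster_label: np.ndarray     # (n,) str
    region_label: np.ndarray      # (n,) str in REGIONS
    proportions: Optional[pd.DataFrame] = None  # n x cell types, rows sum to 1
    de_excluded: Optional[np.ndarray] = None    # (n,) bool; TR spots dropped from DE

    def __post_init__(self) -> None:
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.array_coords = np.asarray(self.array_coords, dtype=int)
        self.xy_um = np.asarray(self.xy_um, dtype=float)
        self.counts = np.asarray(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cluster_label = np.asarray(self.cluster_label, dtype=object)
        self.region_label = np.asarray(self.region_label, dtype=object)
        n = len(self.barcodes)
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if len(set(self.barcodes)) != n:
            raise ValueError("barcodes are not unique")
        if self.array_coords.shape != (n, 2) or self.xy_um.shape != (n, 2):
            raise ValueError("coordinate table shape mismatch")
        if self.counts.shape[1] != n:
            raise ValueError("counts columns do not match number of spots")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        parity = (self.array_coords[:, 0] + self.array_coords[:, 1]) % 2
        if n > 0 and len(np.unique(parity)) != 1:
            raise ValueError("array_row + array_col parity is not constant")
        bad = set(self.region_label) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown region labels: {sorted(bad)}")
        if self.proportions is not None:
            if len(self.proportions) != n:
                raise ValueError("proportions rows do not match spots")
            sums = self.proportions.to_numpy(dtype=float).sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                raise ValueError("proportions rows must sum to 1")
        if self.de_excluded is None:
            self.de_excluded = self.region_label == "TR"

    @property
    def n_spots(self) -> int:
        return len(self.barcodes)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    def barcode_index(self) -> dict:
        return {b: i for i, b in enumerate(self.barcodes)}


@dataclass
class MsiRaster:
    """Regular-grid MSI section: pixels x ions intensity matrix."""

    sample_id: str
    pixel_xy_um: np.ndarray       # (p, 2) float, regular grid
    intensities: np.ndarray       # (p, ions) float >= 0
    mz: np.ndarray                # (ions,) float > 0
    annotations: Optional[pd.DataFrame] = None  # per-ion name/super_class/class_/sub_class
    polarity: str = "positive"

    def __post_init__(self) -> None:
        self.pixel_xy_um = np.asarray(self.pixel_xy_um, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mz = np.asarray(self.mz, dtype=float)
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be positive|negative")
        if np.any(self.mz <= 0):
            raise ValueError("m/z values must be strictly positive")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.intensities.shape != (len(self.pixel_xy_um), len(self.mz)):
            raise ValueError("intensity matrix shape mismatch")
        if self.annotations is not None and len(self.annotations) != len(self.mz):
            raise ValueError("annotation rows must match ions")

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_xy_um)

    @property
    def n_ions(self) -> int:
        return len(self.mz)


@dataclass
class MifImage:
    """Multiplex immunofluorescence field: DAPI plus three marker channels."""

    channels: dict                # name -> 2D float array
    pixel_size_um: float
    sample_id: str = ""
    group: str = "MVI_NEG"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        missing = [c for c in MIF_CHANNELS if c not in self.channels]
        if missing:
            raise ValueError(f"missing channels: {missing}")
        shapes = {self.channels[c].shape for c in self.channels}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        if any(np.any(v < 0) for v in self.channels.values()):
            raise ValueError("channel intensities must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.channels["DAPI"].shape
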