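"""Readers and writers for the plain-text exchange formats.

Spot samples travel as a 10x-style ``positions.csv`` (barcode, array_row,
array_col, x_um, y_um, in_tissue) plus a counts matrix in MatrixMarket
(with ``features.tsv``/``barcodes.tsv`` sidecars) or as a dense CSV, and
an optional labels CSV. MSI rasters travel as a wide pixel CSV
(x_um, y_um, one column per observed m/z) plus a reference annotation
CSV matched at a ppm tolerance. MIF images are multi-channel TIFFs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import tifffile
from scipy.io import mmread, mmwrite
from scipy import sparse

from .types import MifImage, MsiRaster, SpotSample

__all__ = [
    "read_spot_sample",
    "write_spot_sample",
    "read_msi_raster",
    "write_msi_raster",
    "annotate_mz",
    "read_mif_image",
    "write_mif_image",
]

POSITION_COLS = ["barcode", "array_row", "array_col", "x_um", "y_um", "in_tissue"]


def _read_counts(counts_path: Path):
    """Counts as (genes x barcodes) plus gene and barcode id arrays."""
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        mat = mmread(counts_path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        genes = pd.read_csv(counts_path.parent / "features.tsv", sep="\t", header=None)[0].to_numpy(dtype=object)
        bcs = pd.read_csv(counts_path.parent / "barcodes.tsv", sep="\t", header=None)[0].to_numpy(dtype=object)
        return np.asarray(mat), genes, bcs
    df = pd.read_csv(counts_path, index_col=0)
    return df.to_numpy(), df.index.to_numpy(dtype=object), df.columns.to_numpy(dtype=object)


def read_spot_sample(
    positions_csv,
    counts_path,
    labels_csv=None,
    *,
    sample_id: str = "",
    group: str = "NORMAL",
    proportions_csv=None,
) -> SpotSample:
    """Load a spot sample, keeping only in-tissue spots.

    The barcode order of the returned counts matrix follows the positions
    file. Missing labels default to region ``NA``.
    """
    pos = pd.read_csv(positions_csv)
    missing_cols = [c for c in POSITION_COLS if c not in pos.columns]
    if missing_cols:
        raise ValueError(f"positions file lacks columns {missing_cols}")
    pos = pos[pos["in_tissue"].astype(int) == 1].reset_index(drop=True)

    counts, gene_ids, count_bcs = _read_counts(counts_path)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    bc_to_col = {b: j for j, b in enumerate(count_bcs)}
    for b in pos["barcode"]:
        if b not in bc_to_col:
            raise ValueError(f"barcode {b!r} present in positions but missing from counts")
    extra = set(count_bcs) - set(pos["barcode"])
    if extra:
        raise ValueError(f"barcode {sorted(extra)[0]!r} present in counts but missing from positions")
    order = [bc_to_col[b] for b in pos["barcode"]]
    counts = counts[:, order]

    n = len(pos)
    cluster = np.array(["NA"] * n, dtype=object)
    region = np.array(["NA"] * n, dtype=object)
    if labels_csv is not None:
        lab = pd.read_csv(labels_csv).set_index("barcode")
        for i, b in enumerate(pos["barcode"]):
            if b in lab.index:
                if "cluster" in lab.columns:
                    cluster[i] = str(lab.loc[b, "cluster"])
                if "region" in lab.columns:
                    region[i] = str(lab.loc[b, "region"])

    props = None
    if proportions_csv is not None:
        props = pd.read_csv(proportions_csv, index_col=0).loc[pos["barcode"].to_list()]

    return SpotSample(
        sample_id=sample_id or Path(positions_csv).stem,
        group=group,
        barcodes=pos["barcode"].to_numpy(dtype=object),
        array_coords=pos[["array_row", "array_col"]].to_numpy(int),
        xy_um=pos[["x_um", "y_um"]].to_numpy(float),
        counts=counts,
        gene_ids=gene_ids,
        cluster_label=cluster,
        region_label=region,
        proportions=props,
    )


def write_spot_sample(sample: SpotSample, out_dir, *, fmt: str = "mtx") -> Path:
    """Write a sample in the exchange layout read by :func:`read_spot_sample`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "barcode": sample.barcodes,
            "array_row": sample.array_coords[:, 0],
            "array_col": sample.array_coords[:, 1],
            "x_um": sample.xy_um[:, 0],
            "y_um": sample.xy_um[:, 1],
            "in_tissue": 1,
        }
    ).to_csv(out_dir / "positions.csv", index=False)
    if fmt == "mtx":
        mmwrite(out_dir / "counts.mtx", sparse.csr_matrix(sample.counts.astype(int)))
        pd.Series(sample.gene_ids).to_csv(out_dir / "features.tsv", sep="\t", index=False, header=False)
        pd.Series(sample.barcodes).to_csv(out_dir / "barcodes.tsv", sep="\t", index=False, header=False)
    else:
        pd.DataFrame(sample.counts, index=sample.gene_ids, columns=sample.barcodes).to_csv(out_dir / "counts.csv")
    pd.DataFrame(
        {"barcode": sample.barcodes, "cluster": sample.cluster_label, "region": sample.region_label}
    ).to_csv(out_dir / "labels.csv", index=False)
    if sample.proportions is not None:
        sample.proportions.to_csv(out_dir / "proportions.csv")
    meta = {"sample_id": sample.sample_id, "group": sample.group}
    (out_dir / "sample.json").write_text(json.dumps(meta))
    return out_dir


def read_sample_dir(sample_dir) -> SpotSample:
    """Convenience reader for a directory written by :func:`write_spot_sample`."""
    sample_dir = Path(sample_dir)
    meta = json.loads((sample_dir / "sample.json").read_text())
    counts = sample_dir / "counts.mtx"
    if not counts.exists():
        counts = sample_dir / "counts.csv"
    props = sample_dir / "proportions.csv"
    return read_spot_sample(
        sample_dir / "positions.csv",
        counts,
        sample_dir / "labels.csv",
        sample_id=meta["sample_id"],
        group=meta["group"],
        proportions_csv=props if props.exists() else None,
    )


def annotate_mz(observed_mz, reference: pd.DataFrame, ppm_tol: float = 5.0) -> pd.DataFrame:
    """Match observed ion m/z values against a reference table.

    Each ion takes the reference record minimising |delta m/z| provided the
    relative error is within ``ppm_tol`` parts per million; ties break by
    smaller absolute error, then lexicographic name. Unmatched ions get
    empty annotation fields. Matching is independent of reference row
    order by construction.
    """
    observed_mz = np.asarray(observed_mz, dtype=float)
    ref = reference.sort_values(["theoretical_mz", "name"]).reset_index(drop=True)
    cols = {"name": "", "super_class": "", "class_": "", "sub_class": ""}
    out = {k: np.array([v] * len(observed_mz), dtype=object) for k, v in cols.items()}
    out["theoretical_mz"] = np.full(len(observed_mz), np.nan)
    ref_mz = ref["theoretical_mz"].to_numpy(dtype=float)
    for i, m in enumerate(observed_mz):
        err = np.abs(ref_mz - m)
        best = err.min() if len(err) else np.inf
        if best / m <= ppm_tol * 1e-6:
            cand = ref[np.abs(err - best) <= 1e-12].sort_values("name")
            row = cand.iloc[0]
            out["name"][i] = row["name"]
            out["super_class"][i] = row.get("super_class", "")
            out["class_"][i] = row.get("class", row.get("class_", ""))
            out["sub_class"][i] = row.get("sub_class", "")
            out["theoretical_mz"][i] = row["theoretical_mz"]
    return pd.DataFrame(out)


def _check_grid(coords: np.ndarray, axis_name: str) -> None:
    vals = np.unique(coords)
    if len(vals) > 2:
        steps = np.diff(vals)
        if np.any(np.abs(steps - steps.mean()) > 0.01 * steps.mean()):
            raise ValueError(f"non-uniform pixel grid spacing along {axis_name}")


def read_msi_raster(pixels_csv, annotation_csv=None, ppm_tol: float = 5.0,
                    *, sample_id: str = "", polarity: str = "positive") -> MsiRaster:
    """Load a wide-format MSI pixel table and annotate ions at ppm tolerance."""
    df = pd.read_csv(pixels_csv)
    if "x_um" not in df.columns or "y_um" not in df.columns:
        raise ValueError("pixel table needs x_um and y_um columns")
    ion_cols = [c for c in df.columns if c not in ("x_um", "y_um")]
    mz = np.array([float(c) for c in ion_cols])
    xy = df[["x_um", "y_um"]].to_numpy(float)
    _check_grid(xy[:, 0], "x")
    _check_grid(xy[:, 1], "y")
    ann = None
    if annotation_csv is not None:
        ref = pd.read_csv(annotation_csv)
        ann = annotate_mz(mz, ref, ppm_tol=ppm_tol)
    return MsiRaster(
        sample_id=sample_id or Path(pixels_csv).stem,
        pixel_xy_um=xy,
        intensities=df[ion_cols].to_numpy(float),
        mz=mz,
        annotations=ann,
        polarity=polarity,
    )


def write_msi_raster(raster: MsiRaster, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(raster.intensities,
                      columns=[repr(float(m)) for m in raster.mz])
    df.insert(0, "y_um", raster.pixel_xy_um[:, 1])
    df.insert(0, "x_um", raster.pixel_xy_um[:, 0])
    df.to_csv(out_dir / "pixels.csv", index=False, float_format="%.17g")
    if raster.annotations is not None:
        raster.annotations.to_csv(out_dir / "ion_annotations.csv", index=False)
    return out_dir


def read_mif_image(tiff_path, channel_map: Mapping[str, int], pixel_size_um: float,
                   *, sample_id: str = "", group: str = "MVI_NEG") -> MifImage:
    """Load a multi-channel TIFF; ``channel_map`` names the page/plane of
    each required channel (DAPI, STMN1, HMGN2, GPC3)."""
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    arr = tifffile.imread(tiff_path)
    if arr.ndim == 2:
        arr = arr[None]
    for name in ("DAPI", "STMN1", "HMGN2", "GPC3"):
        if name not in channel_map:
            raise ValueError(f"channel_map lacks {name!r}")
    channels = {name: arr[idx].astype(float) for name, idx in channel_map.items()}
    return MifImage(channels=channels, pixel_size_um=pixel_size_um,
                    sample_id=sample_id or Path(tiff_path).stem, group=group)


def write_mif_image(image: MifImage, tiff_path) -> Path:
    """Write channels as TIFF pages in canonical order (DAPI, STMN1, HMGN2, GPC3)."""
    order = ["DAPI", "STMN1", "HMGN2", "GPC3"]
    stack = np.stack([image.channels[c] for c in order]).astype(np.float32)
    tifffile.imwrite(tiff_path, stack, photometric="minisblack")
    return Path(tiff_path)
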