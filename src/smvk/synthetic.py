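"""Synthetic MVI+/MVI- cohort with known planted truth.

The generator emulates the structure of a tumor-boundary section: a hex
lattice of spots with a central tumor disk (T), a closed capsule
annulus (TC) and surrounding paratumor (PT); negative-binomial counts
with a planted triple-positive malignant subpopulation enriched in
MVI+ samples; Dirichlet cell-type proportions with an iCAF fraction
rising with distance from the tumor boundary inside the capsule; a
matched metabolite raster whose glycerolipid ions are shifted in MVI+
tumor pixels and whose taurine channel is an affine function of the
covering spot's iCAF proportion plus noise calibrated to a target
Pearson correlation; and immunofluorescence fields of disk nuclei with
known per-cell marker positivity.

Every planted effect is recorded in a :class:`PlantedTruth` so that
downstream stages can be tested for recovery without any external data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import rng_stream
from .crossmodal import SimilarityTransform
from .types import MifImage, MsiRaster, SpotSample

__all__ = [
    "CELL_TYPES",
    "ION_DEFS",
    "CohortParams",
    "MifImageParams",
    "PlantedTruth",
    "GenePool",
    "make_gene_pool",
    "make_reference_bulk",
    "generate_spot_sample",
    "generate_msi_raster",
    "generate_mif_image",
    "generate_disk_raster",
    "generate_cohort",
    "truth_landmarks",
    "ion_annotation_table",
]

CELL_TYPES = ("malignant", "hepatocyte", "iCAF", "mCAF", "vCAF",
              "endothelial", "immune")

# (name, observed m/z, super class, class, sub class); positive mode stand-ins
ION_DEFS = [
    ("taurine", 126.0219, "Organic acids and derivatives", "Organic sulfonic acids", "Aminosulfonic acids"),
    ("creatine", 132.0768, "Organic acids and derivatives", "Carboxylic acids", "Amino acids"),
    ("glutamine", 147.0764, "Organic acids and derivatives", "Carboxylic acids", "Amino acids"),
    ("arginine", 175.1190, "Organic acids and derivatives", "Carboxylic acids", "Amino acids"),
    ("carnitine", 162.1125, "Organic acids and derivatives", "Carboxylic acids", "Amino acids"),
    ("TG(52:2)", 876.8014, "Lipids and lipid-like molecules", "Glycerolipids", "Triradylcglycerols"),
    ("TG(54:3)", 902.8171, "Lipids and lipid-like molecules", "Glycerolipids", "Triradylcglycerols"),
    ("DG(36:2)", 638.5718, "Lipids and lipid-like molecules", "Glycerolipids", "Diradylglycerols"),
    ("DG(34:1)", 614.5719, "Lipids and lipid-like molecules", "Glycerolipids", "Diradylglycerols"),
    ("MG(18:1)", 357.3363, "Lipids and lipid-like molecules", "Glycerolipids", "Monoradylglycerols"),
    ("PC(34:1)", 760.5851, "Lipids and lipid-like molecules", "Glycerophospholipids", "Glycerophosphocholines"),
    ("PC(36:2)", 786.6007, "Lipids and lipid-like molecules", "Glycerophospholipids", "Glycerophosphocholines"),
    ("PE(38:4)", 768.5538, "Lipids and lipid-like molecules", "Glycerophospholipids", "Glycerophosphoethanolamines"),
    ("SM(d34:1)", 703.5749, "Lipids and lipid-like molecules", "Sphingolipids", "Phosphosphingolipids"),
    ("cholesterol", 369.3516, "Lipids and lipid-like molecules", "Steroids and steroid derivatives", "Cholestane steroids"),
    ("glucose", 203.0526, "Organic oxygen compounds", "Organooxygen compounds", "Carbohydrates"),
    ("lactate", 91.0390, "Organic oxygen compounds", "Organooxygen compounds", "Alpha hydroxy acids"),
    ("choline", 104.1070, "Organic nitrogen compounds", "Organonitrogen compounds", "Cholines"),
    ("spermidine", 146.1652, "Organic nitrogen compounds", "Organonitrogen compounds", "Amines"),
    ("adenosine", 268.1040, "Nucleosides, nucleotides, and analogues", "Purine nucleosides", "Purine ribonucleosides"),
    ("inosine", 269.0880, "Nucleosides, nucleotides, and analogues", "Purine nucleosides", "Purine ribonucleosides"),
    ("uridine", 245.0768, "Nucleosides, nucleotides, and analogues", "Pyrimidine nucleosides", "Pyrimidine ribonucleosides"),
    ("hypoxanthine", 137.0458, "Organoheterocyclic compounds", "Imidazopyrimidines", "Purines"),
    ("bilirubin", 585.2708, "Organoheterocyclic compounds", "Tetrapyrroles and derivatives", "Bilirubins"),
]

GLYCEROLIPID_IONS = tuple(i for i, d in enumerate(ION_DEFS) if d[3] == "Glycerolipids")
TAURINE_ION = 0

PANEL_GENES = ("STMN1", "HMGN2", "GPC3")
# baseline means chosen so the boosted subpopulation clears the pct.1 > 0.8
# filter while the seed marker keeps a clear pct.1 - pct.2 margin
_PANEL_BASE_MEAN = {"STMN1": 1.0, "HMGN2": 2.0, "GPC3": 2.4}


def ion_annotation_table() -> pd.DataFrame:
    """Per-ion annotation frame aligned with :data:`ION_DEFS`."""
    return pd.DataFrame(
        [{"name": n, "theoretical_mz": m, "super_class": sc, "class_": c,
          "sub_class": sub} for n, m, sc, c, sub in ION_DEFS]
    )


@dataclass
class CohortParams:
    n_rows: int = 40
    n_cols: int = 40                  # usable spots per row
    pitch_um: float = 100.0
    tumor_radius_um: float = 1100.0
    capsule_width_um: float = 350.0
    n_genes: int = 500
    nb_dispersion: float = 0.5        # var = mu + phi mu^2
    panel_log2fc: float = 2.0         # subpopulation boost of the panel genes
    triple_prevalence: dict = field(default_factory=lambda: {"MVI_POS": 0.30,
                                                             "MVI_NEG": 0.05,
                                                             "NORMAL": 0.0})
    icaf_gradient: float = 3.0        # capsule iCAF alpha scaling with distance
    taurine_icaf_rho: float = 0.6
    taurine_intercept: float = 200.0
    taurine_slope: float = 400.0
    glycerolipid_logfc: float = -1.0  # MVI+ vs MVI- in T-region pixels
    raster_sigma: float = 0.3         # lognormal noise of base intensities
    registration: SimilarityTransform = field(
        default_factory=lambda: SimilarityTransform(scale=1.0, rotation=0.01,
                                                    translation=(30.0, -20.0)))
    n_reference_samples: int = 50


@dataclass
class MifImageParams:
    size_px: int = 512
    pixel_size_um: float = 0.5
    n_cells: int = 300
    nucleus_radius_um: tuple = (3.0, 4.0)
    halo_um: float = 3.0
    bg_mean: float = 100.0
    bg_sd: float = 10.0
    contrast_k: float = 8.0           # foreground = bg_mean + k * bg_sd
    gpc3_rate: float = 1.0
    stmn1_rate: float = 0.5
    hmgn2_rate: float = 0.5
    mode: str = "independent"         # or "planted_triple"
    triple_rate: float = 0.30         # used by planted_triple


@dataclass
class PlantedTruth:
    """Ground truth of one synthetic sample (plus cohort-level effects)."""

    region_mask: np.ndarray                 # per-spot true region
    triple_mask: np.ndarray                 # per-spot subpopulation membership
    true_panel: tuple = PANEL_GENES
    triple_prevalence: float = 0.0
    taurine_icaf_rho: float = 0.6
    glycerolipid_logfc: float = -1.0
    registration_transform: Optional[SimilarityTransform] = None
    raster_region: Optional[np.ndarray] = None   # per-pixel region ("BG" off tissue)
    raster_spot_index: Optional[np.ndarray] = None  # covering spot per pixel (-1 = none)
    mif_true_rates: Optional[dict] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.triple_prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if abs(self.taurine_icaf_rho) > 1:
            raise ValueError("|taurine_icaf_rho| must be <= 1")
        if self.registration_transform is not None and self.registration_transform.scale <= 0:
            raise ValueError("registration scale must be > 0")

    def to_json(self) -> dict:
        out = {
            "true_panel": list(self.true_panel),
            "triple_prevalence": self.triple_prevalence,
            "taurine_icaf_rho": self.taurine_icaf_rho,
            "glycerolipid_logfc": self.glycerolipid_logfc,
            "region_counts": pd.Series(self.region_mask).value_counts().to_dict(),
            "n_triple_spots": int(np.sum(self.triple_mask)),
        }
        if self.registration_transform is not None:
            t = self.registration_transform
            out["registration_transform"] = {"scale": t.scale, "rotation": t.rotation,
                                             "translation": list(t.translation)}
        if self.mif_true_rates is not None:
            out["mif_true_rates"] = self.mif_true_rates
        return out


@dataclass
class GenePool:
    """Cohort-level gene model shared by every sample."""

    gene_ids: np.ndarray
    base_mean: np.ndarray            # per-gene baseline NB mean
    region_log2: pd.DataFrame        # genes x (T, TC, PT) log2 region effects


def make_gene_pool(params: CohortParams, rng: np.random.Generator) -> GenePool:
    g = params.n_genes
    ids = np.array(list(PANEL_GENES) + [f"G{i:04d}" for i in range(g - 3)],
                   dtype=object)
    base = np.exp(rng.normal(np.log(0.8), 1.0, size=g))
    for gene, m in _PANEL_BASE_MEAN.items():
        base[list(ids).index(gene)] = m
    eff = np.zeros((g, 3))
    hit = rng.random(g) < 0.3
    eff[hit] = rng.normal(0.0, 0.4, size=(int(hit.sum()), 3))
    eff[:3] = 0.0  # panel genes carry only the subpopulation boost
    return GenePool(gene_ids=ids, base_mean=base,
                    region_log2=pd.DataFrame(eff, index=ids, columns=["T", "TC", "PT"]))


def make_reference_bulk(genes: GenePool, rng: np.random.Generator,
                        n_samples: int = 50) -> pd.DataFrame:
    """Bulk reference (genes x samples) with a latent proliferation factor
    loading strongly on STMN1 and HMGN2, used by the companion-gene step."""
    g = len(genes.gene_ids)
    z = rng.normal(size=n_samples)
    loadings = rng.normal(0.0, 0.1, size=g)
    name_to_i = {n: i for i, n in enumerate(genes.gene_ids)}
    loadings[name_to_i["STMN1"]] = 1.0
    loadings[name_to_i["HMGN2"]] = 0.9
    loadings[name_to_i["GPC3"]] = 0.35
    expr = (np.log1p(genes.base_mean)[:, None]
            + loadings[:, None] * z[None, :]
            + rng.normal(0.0, 0.3, size=(g, n_samples)))
    return pd.DataFrame(expr, index=genes.gene_ids, columns=[f"B{i:02d}" for i in range(n_samples)])


def _hex_lattice(params: CohortParams):
    rows, cols = [], []
    for r in range(params.n_rows):
        for j in range(params.n_cols):
            rows.append(r)
            cols.append(2 * j + (r % 2))
    coords = np.column_stack([rows, cols])
    x = coords[:, 1] * params.pitch_um / 2.0
    y = coords[:, 0] * params.pitch_um * np.sqrt(3) / 2.0
    return coords, np.column_stack([x, y])


def generate_spot_sample(params: CohortParams, genes: GenePool, group: str,
                         sample_id: str, rng: np.random.Generator):
    """One synthetic section: hex lattice, regions, proportions, counts."""
    row_pitch = params.pitch_um * np.sqrt(3) / 2.0
    if group != "NORMAL" and params.capsule_width_um < row_pitch:
        raise ValueError("capsule annulus thinner than one spot row")
    coords, xy = _hex_lattice(params)
    n = len(coords)
    center = xy.mean(axis=0)
    d_center = np.linalg.norm(xy - center, axis=1)
    if group == "NORMAL":
        region = np.array(["PT"] * n, dtype=object)
    else:
        region = np.where(
            d_center <= params.tumor_radius_um, "T",
            np.where(d_center <= params.tumor_radius_um + params.capsule_width_um,
                     "TC", "PT")).astype(object)

    prevalence = params.triple_prevalence.get(group, 0.0)
    triple = np.zeros(n, dtype=bool)
    t_idx = np.flatnonzero(region == "T")
    if prevalence > 0 and len(t_idx):
        triple[t_idx] = rng.random(len(t_idx)) < prevalence

    cluster = np.where(triple, "C6",
                       np.where(region == "T", "C1",
                                np.where(region == "TC", "C3", "C4"))).astype(object)

    # cell-type proportions; capsule iCAF alpha grows with boundary distance
    alphas = {
        "T": np.array([12.0, 2.0, 0.5, 1.0, 1.0, 1.5, 2.0]),
        "TC": np.array([2.0, 1.0, 2.0, 4.0, 3.0, 2.0, 2.0]),
        "PT": np.array([1.0, 12.0, 1.0, 1.0, 1.0, 1.5, 2.5]),
    }
    icaf_col = CELL_TYPES.index("iCAF")
    props = np.empty((n, len(CELL_TYPES)))
    for i in range(n):
        a = alphas[region[i]].copy()
        if region[i] == "TC":
            depth = np.clip((d_center[i] - params.tumor_radius_um)
                            / params.capsule_width_um, 0.0, 1.0)
            a[icaf_col] *= 1.0 + params.icaf_gradient * depth
        props[i] = rng.dirichlet(a)

    # negative-binomial counts
    mu = genes.base_mean[:, None] * np.ones((1, n))
    reg_eff = genes.region_log2.to_numpy()
    reg_idx = {"T": 0, "TC": 1, "PT": 2}
    for rname, ri in reg_idx.items():
        cols_mask = region == rname
        if cols_mask.any():
            mu[:, cols_mask] *= 2.0 ** reg_eff[:, ri][:, None]
    panel_rows = [list(genes.gene_ids).index(g) for g in PANEL_GENES]
    if triple.any():
        mu[np.ix_(panel_rows, np.flatnonzero(triple))] *= 2.0 ** params.panel_log2fc
    lib = np.exp(rng.normal(0.0, 0.15, size=n))
    mu = mu * lib[None, :]
    theta = 1.0 / params.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu))

    barcodes = np.array([f"{sample_id}-{i:04d}" for i in range(n)], dtype=object)
    sample = SpotSample(
        sample_id=sample_id, group=group, barcodes=barcodes,
        array_coords=coords, xy_um=xy, counts=counts, gene_ids=genes.gene_ids,
        cluster_label=cluster, region_label=region.copy(),
        proportions=pd.DataFrame(props, index=barcodes.astype(str),
                                 columns=list(CELL_TYPES)),
    )
    truth = PlantedTruth(
        region_mask=region.copy(), triple_mask=triple,
        triple_prevalence=prevalence,
        taurine_icaf_rho=params.taurine_icaf_rho,
        glycerolipid_logfc=params.glycerolipid_logfc,
        registration_transform=params.registration,
    )
    return sample, truth


def generate_msi_raster(sample: SpotSample, truth: PlantedTruth,
                        params: CohortParams, rng: np.random.Generator,
                        ion_region_log2: Optional[pd.DataFrame] = None) -> MsiRaster:
    """Matched metabolite raster on a 100 um grid offset by the planted
    registration transform; see module docstring for the planted effects."""
    names = [d[0] for d in ION_DEFS]
    mz = np.array([d[1] for d in ION_DEFS])
    n_ions = len(names)
    if ion_region_log2 is None:
        ion_region_log2 = default_ion_region_effects(rng_stream(0, "ion-effects"))

    # the raster lives on its own axis-aligned scan grid; the planted
    # similarity transform maps raster coordinates into the spot frame,
    # so pixels are laid out over the image of the tissue bounding box
    pitch = params.pitch_um
    lo = sample.xy_um.min(axis=0) - pitch / 2
    hi = sample.xy_um.max(axis=0) + pitch / 2
    tf = truth.registration_transform or SimilarityTransform(1.0, 0.0, (0.0, 0.0))
    corners = np.array([[lo[0], lo[1]], [hi[0], lo[1]],
                        [hi[0], hi[1]], [lo[0], hi[1]]])
    sm_lo = tf.apply(corners).min(axis=0)
    sm_hi = tf.apply(corners).max(axis=0)
    xs = np.arange(sm_lo[0], sm_hi[0] + pitch / 2, pitch)
    ys = np.arange(sm_lo[1], sm_hi[1] + pitch / 2, pitch)
    gx, gy = np.meshgrid(xs, ys)
    sm_xy = np.column_stack([gx.ravel(), gy.ravel()])
    st_xy = tf.inverse().apply(sm_xy)
    extent = hi - lo
    if np.any(sm_hi - sm_lo > 2.0 * extent.max()):
        raise ValueError(
            "transform maps pixels outside twice the tissue extent: "
            "the raster would cover more than double the section")

    from scipy.spatial import cKDTree

    tree = cKDTree(sample.xy_um)
    dist, nearest = tree.query(st_xy)
    covered = dist <= pitch / 2
    spot_idx = np.where(covered, nearest, -1)
    region = np.array(["BG"] * len(st_xy), dtype=object)
    region[covered] = sample.region_label[nearest[covered]]

    base_level = np.exp(rng_stream(0, "ion-base").normal(np.log(500.0), 0.5, size=n_ions))
    reg_map = {"T": 0, "TC": 1, "PT": 2, "BG": 3}
    reg_idx = np.array([reg_map[r] for r in region])
    eff = np.column_stack([ion_region_log2.to_numpy(), np.full(n_ions, -2.0)])
    mu = base_level[None, :] * 2.0 ** eff[:, reg_idx].T
    if sample.group == "MVI_POS":
        t_px = region == "T"
        for j in GLYCEROLIPID_IONS:
            mu[t_px, j] *= 2.0 ** params.glycerolipid_logfc
    intensities = mu * np.exp(rng.normal(0.0, params.raster_sigma, size=mu.shape))

    # taurine: affine in the covering spot's iCAF proportion, noise calibrated
    # so the sample Pearson correlation matches the planted rho
    icaf = sample.proportions["iCAF"].to_numpy(float)
    tau = np.full(len(st_xy), params.taurine_intercept * 0.25)
    tau[covered] = (params.taurine_intercept
                    + params.taurine_slope * icaf[spot_idx[covered]])
    rho = params.taurine_icaf_rho
    if abs(rho) < 1.0 and rho != 0.0:
        signal_sd = params.taurine_slope * np.std(icaf[spot_idx[covered]])
        noise_sd = signal_sd * np.sqrt(1.0 / rho ** 2 - 1.0)
        tau = tau + rng.normal(0.0, noise_sd, size=len(tau))
    intensities[:, TAURINE_ION] = np.clip(tau, 0.0, None)

    ann = ion_annotation_table().rename(columns={"theoretical_mz": "theoretical_mz"})
    raster = MsiRaster(sample_id=sample.sample_id, pixel_xy_um=sm_xy,
                       intensities=np.clip(intensities, 0.0, None), mz=mz,
                       annotations=ann, polarity="positive")
    truth.raster_region = region
    truth.raster_spot_index = spot_idx
    return raster


def default_ion_region_effects(rng: np.random.Generator) -> pd.DataFrame:
    """Fixed per-ion region multipliers (log2 over T, TC, PT), shared by
    every sample of a cohort so group contrasts stay clean."""
    names = [d[0] for d in ION_DEFS]
    eff = rng.normal(0.0, 0.6, size=(len(names), 3))
    return pd.DataFrame(eff, index=names, columns=["T", "TC", "PT"])


def generate_mif_image(params: MifImageParams, rng: np.random.Generator,
                       *, sample_id: str = "mif", group: str = "MVI_NEG"):
    """Synthetic MIF field of non-touching disk nuclei with known positivity.

    Cells sit on a jittered grid so the non-overlap guarantee is exact;
    marker channels paint each positive cell's nucleus plus a halo at
    foreground level (background mean + k * SD).
    """
    px = params.pixel_size_um
    size = params.size_px
    rmin_px = params.nucleus_radius_um[0] / px
    rmax_px = params.nucleus_radius_um[1] / px
    g = int(np.ceil(np.sqrt(params.n_cells)))
    spacing = size / g
    jitter = spacing / 2.0 - rmax_px - 2.0
    if jitter < 0 or g * g < params.n_cells:
        raise ValueError("cannot place n_cells without overlap")
    sites = [(i, j) for i in range(g) for j in range(g)]
    chosen = rng.choice(len(sites), size=params.n_cells, replace=False)
    margin = rmax_px + params.halo_um / px + 2.0
    centers, radii = [], []
    for s in chosen:
        i, j = sites[s]
        cy = (i + 0.5) * spacing + rng.uniform(-jitter, jitter)
        cx = (j + 0.5) * spacing + rng.uniform(-jitter, jitter)
        cy = float(np.clip(cy, margin, size - margin))
        cx = float(np.clip(cx, margin, size - margin))
        centers.append((cy, cx))
        radii.append(float(rng.uniform(rmin_px, rmax_px)))

    if params.contrast_k <= 0:
        warnings.warn("zero foreground contrast: downstream recovery will fail")
    fg = params.bg_mean + params.contrast_k * params.bg_sd

    if params.mode == "independent":
        pos = np.column_stack([
            rng.random(params.n_cells) < params.stmn1_rate,
            rng.random(params.n_cells) < params.hmgn2_rate,
            rng.random(params.n_cells) < params.gpc3_rate,
        ])
    elif params.mode == "planted_triple":
        is_triple = rng.random(params.n_cells) < params.triple_rate
        pos = np.zeros((params.n_cells, 3), dtype=bool)
        pos[:, 2] = rng.random(params.n_cells) < params.gpc3_rate
        pos[is_triple] = True
        for i in np.flatnonzero(~is_triple):
            while True:
                s = rng.random() < params.stmn1_rate
                h = rng.random() < params.hmgn2_rate
                if not (s and h and pos[i, 2]):
                    break
            pos[i, 0], pos[i, 1] = s, h
    else:
        raise ValueError("mode must be independent|planted_triple")

    yy, xx = np.mgrid[0:size, 0:size]
    channels = {c: np.clip(rng.normal(params.bg_mean, params.bg_sd, (size, size)),
                           0.0, None)
                for c in ("DAPI", "STMN1", "HMGN2", "GPC3")}
    halo_px = params.halo_um / px
    rows = []
    for cid, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        nucleus = d2 <= r * r
        cell = d2 <= (r + halo_px) ** 2
        channels["DAPI"][nucleus] = fg
        for k, ch in enumerate(("STMN1", "HMGN2", "GPC3")):
            if pos[cid - 1, k]:
                channels[ch][cell] = fg
        rows.append({"id": cid, "x_um": cx * px, "y_um": cy * px,
                     "nucleus_area_um2": float(nucleus.sum()) * px * px,
                     "pos_STMN1": bool(pos[cid - 1, 0]),
                     "pos_HMGN2": bool(pos[cid - 1, 1]),
                     "pos_GPC3": bool(pos[cid - 1, 2]),
                     "triple": bool(pos[cid - 1].all())})
    cells = pd.DataFrame(rows)
    image = MifImage(channels=channels, pixel_size_um=px,
                     sample_id=sample_id, group=group)
    gpc3 = cells["pos_GPC3"]
    denom = max(int(gpc3.sum()), 1)
    rates = {
        "triple": float((cells["triple"] & gpc3).sum() / denom),
        "stmn1_gpc3": float((cells["pos_STMN1"] & gpc3).sum() / denom),
        "hmgn2_gpc3": float((cells["pos_HMGN2"] & gpc3).sum() / denom),
    }
    return image, cells, rates


def generate_disk_raster(n_side: int = 40, pitch_um: float = 100.0,
                         contrast_log2: float = 1.6, sigma: float = 0.25,
                         rng: Optional[np.random.Generator] = None):
    """Two-region fixture: disk vs background with distinct ion profiles.

    Returns (MsiRaster, per-pixel labels) for segmentation-recovery tests.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    xs = np.arange(n_side) * pitch_um
    gx, gy = np.meshgrid(xs, xs)
    xy = np.column_stack([gx.ravel(), gy.ravel()])
    center = xy.mean(axis=0)
    radius = n_side * pitch_um * 0.3
    inside = np.linalg.norm(xy - center, axis=1) <= radius
    n_ions = len(ION_DEFS)
    base = np.exp(rng.normal(np.log(500.0), 0.4, size=n_ions))
    eff = np.where(np.arange(n_ions) % 2 == 0, contrast_log2, -contrast_log2)
    mu = base[None, :] * 2.0 ** (eff[None, :] * inside[:, None])
    intensities = mu * np.exp(rng.normal(0.0, sigma, size=mu.shape))
    raster = MsiRaster(sample_id="disk", pixel_xy_um=xy, intensities=intensities,
                       mz=np.array([d[1] for d in ION_DEFS]),
                       annotations=ion_annotation_table())
    labels = np.where(inside, "disk", "bg")
    return raster, labels


def truth_landmarks(sample: SpotSample, transform: SimilarityTransform,
                    n: int = 4):
    """Matched landmark pairs (spot frame, raster frame) from the planted
    transform; corners of the tissue bounding box plus the centroid."""
    lo = sample.xy_um.min(axis=0)
    hi = sample.xy_um.max(axis=0)
    pts = np.array([[lo[0], lo[1]], [hi[0], lo[1]], [hi[0], hi[1]],
                    [lo[0], hi[1]], [(lo[0] + hi[0]) / 2, (lo[1] + hi[1]) / 2]])
    pts = pts[:max(n, 2)]
    return pts, transform.apply(pts)


@dataclass
class Cohort:
    samples: list            # of (SpotSample, MsiRaster, PlantedTruth)
    genes: GenePool
    reference_bulk: pd.DataFrame
    params: CohortParams


def generate_cohort(seed: int, params: Optional[CohortParams] = None,
                    groups=("MVI_POS", "MVI_POS", "MVI_NEG", "MVI_NEG",
                            "NORMAL", "NORMAL")) -> Cohort:
    """Full synthetic cohort: sections, matched rasters and shared truth.

    All randomness descends from ``seed`` through named streams, one per
    sample and stage, so the cohort is bit-reproducible.
    """
    params = params or CohortParams()
    genes = make_gene_pool(params, rng_stream(seed, "gene-pool"))
    bulk = make_reference_bulk(genes, rng_stream(seed, "reference-bulk"),
                               params.n_reference_samples)
    ion_eff = default_ion_region_effects(rng_stream(seed, "ion-effects"))
    samples = []
    for g in groups:
        sid = f"{'P' if g != 'NORMAL' else 'N'}{len(samples) + 1}_{g.lower()}"
        sample, truth = generate_spot_sample(
            params, genes, g, sid, rng_stream(seed, f"sample-{sid}"))
        raster = generate_msi_raster(
            sample, truth, params, rng_stream(seed, f"raster-{sid}"), ion_eff)
        samples.append((sample, raster, truth))
    return Cohort(samples=samples, genes=genes, reference_bulk=bulk, params=params)


def write_truth(cohort: Cohort, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {s.sample_id: t.to_json() for s, _, t in cohort.samples}
    path = out_dir / "truth.json"
    path.write_text(json.dumps(payload, indent=2))
    return path
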