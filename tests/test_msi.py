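"""TIC normalization, SSC segmentation, marker ions, enrichment, DMs."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from smvk.config import rng_stream
from smvk.msi import (class_enrichment, cluster_marker_ions,
                      differential_metabolites, spatial_smooth, ssc_cluster,
                      tic_normalize, SscModel)
from smvk.synthetic import generate_disk_raster, ion_annotation_table
from smvk.types import MsiRaster


def test_tic_normalization_invariant(disk_raster):
    raster, _ = disk_raster
    X = tic_normalize(raster.intensities)
    tic = X.sum(axis=1)
    med = np.median(raster.intensities.sum(axis=1))
    assert np.allclose(tic, med, atol=1e-9)


def test_smoothing_preserves_constant_field():
    xy = np.array([[x * 100.0, y * 100.0] for y in range(5) for x in range(5)])
    X = np.full((25, 3), 7.0)
    for w in ("SA", "SASA"):
        sm = spatial_smooth(xy, X, r=1, weights=w)
        assert np.allclose(sm, 7.0)


def test_ssc_unshrunk_limit_equals_kmeans(disk_raster):
    """s=0, r=0 fixed point = Lloyd's k-means on the standardized matrix."""
    raster, _ = disk_raster
    model = ssc_cluster(raster, r=0, k_init=5, s=0.0,
                        rng=rng_stream(5, "ssc-km"))
    X = tic_normalize(raster.intensities)
    sc = X.std(axis=0) + np.median(X.std(axis=0))
    Z = X / sc
    km = KMeans(n_clusters=5, init=Z[model.init_indices], n_init=1,
                max_iter=300, tol=0.0).fit(Z)
    assert adjusted_rand_score(km.labels_, model.assignments) == 1.0


def test_ssc_full_shrinkage_collapses(disk_raster):
    raster, _ = disk_raster
    model = ssc_cluster(raster, r=0, k_init=15, s=1e6,
                        rng=rng_stream(5, "ssc-big"))
    assert model.n_clusters == 1
    assert np.all(model.tstat == 0.0)


@pytest.mark.parametrize("weights", ["SA", "SASA"])
def test_ssc_recovers_planted_disk(disk_raster, weights):
    raster, labels = disk_raster
    model = ssc_cluster(raster, r=1, k_init=15, s=3.0, weights=weights,
                        rng=rng_stream(5, "ssc"))
    assert adjusted_rand_score(labels, model.assignments) >= 0.9


def test_ssc_invariant_to_ion_order(disk_raster):
    raster, _ = disk_raster
    m1 = ssc_cluster(raster, r=1, k_init=6, s=2.0, rng=rng_stream(5, "o"))
    perm = np.random.default_rng(1).permutation(raster.n_ions)
    r2 = MsiRaster(sample_id="p", pixel_xy_um=raster.pixel_xy_um,
                   intensities=raster.intensities[:, perm], mz=raster.mz[perm])
    m2 = ssc_cluster(r2, r=1, k_init=6, s=2.0, rng=rng_stream(5, "o"))
    assert adjusted_rand_score(m1.assignments, m2.assignments) == 1.0


def test_ssc_objective_monotone_unshrunk(disk_raster):
    raster, _ = disk_raster
    model = ssc_cluster(raster, r=0, k_init=8, s=0.0, rng=rng_stream(2, "m"))
    assert all(np.diff(model.objective) <= 1e-9)


def test_ssc_argument_errors(disk_raster):
    raster, _ = disk_raster
    with pytest.raises(ValueError):
        ssc_cluster(raster, r=-1)
    with pytest.raises(ValueError):
        ssc_cluster(raster, k_init=0)


def test_marker_ions_hand_built():
    model = SscModel(r=0, k_init=2, s=0.0, weights="SA",
                     assignments=np.array([0, 1]),
                     centroids=np.zeros((2, 3)),
                     tstat=np.array([[3.0, 1.0, 0.0], [0.0, 2.0, 5.0]]),
                     global_mean=np.zeros(3), n_iter=1,
                     init_indices=np.array([0, 1]), objective=[])
    top = cluster_marker_ions(model, top_n=2)
    assert top[0] == [0, 1] and top[1] == [2, 1]
    assert cluster_marker_ions(model, top_n=10)[0] == [0, 1]
    model.tstat = np.zeros((2, 3))
    assert cluster_marker_ions(model)[0] == []


def _raster_with_classes(class_of):
    n = len(class_of)
    ann = pd.DataFrame({"name": [f"i{j}" for j in range(n)],
                        "super_class": class_of,
                        "class_": class_of, "sub_class": class_of})
    return MsiRaster(sample_id="t", pixel_xy_um=np.zeros((2, 2)),
                     intensities=np.ones((2, n)),
                     mz=np.linspace(100, 200, n), annotations=ann)


def test_enrichment_exact_table():
    """Single-class marker set: corrected OR and the exact Fisher p."""
    raster = _raster_with_classes(["A"] * 5 + ["B"] * 20)
    rows = class_enrichment(range(5), raster, "super_class")
    a_row = rows[rows["class_name"] == "A"].iloc[0]
    assert (a_row["a"], a_row["b"], a_row["c"], a_row["d"]) == (5, 0, 0, 20)
    assert np.isclose(a_row["odds_ratio"], (5.5 * 20.5) / (0.5 * 0.5))
    assert np.isclose(a_row["odds_ratio"], 451.0)
    assert np.isclose(a_row["p"], 1.0 / 53130, rtol=1e-6)  # 1 / C(25,5)


def test_enrichment_fisher_matches_hypergeometric_oracle(rng):
    """Two-sided Fisher p equals exhaustive hypergeometric summation."""
    def oracle(a, b, c, d):
        N, K, n1 = a + b + c + d, a + b, a + c
        ks = range(max(0, K + n1 - N), min(K, n1) + 1)
        pmf = {k: hypergeom.pmf(k, N, K, n1) for k in ks}
        return sum(p for p in pmf.values() if p <= pmf[a] * (1 + 1e-9))

    for _ in range(30):
        na = int(rng.integers(2, 12))
        nb = int(rng.integers(2, 18))
        if na + nb > 30:
            continue
        classes = ["A"] * na + ["B"] * nb
        raster = _raster_with_classes(classes)
        k = int(rng.integers(1, na + nb))
        markers = rng.choice(na + nb, size=k, replace=False)
        rows = class_enrichment(markers, raster, "super_class")
        for _, row in rows.iterrows():
            assert abs(row["p"] - oracle(row["a"], row["b"], row["c"], row["d"])) < 1e-10


def test_enrichment_null_or_near_one(rng):
    raster = _raster_with_classes(["A"] * 10 + ["B"] * 10)
    log_ors = []
    for _ in range(200):
        markers = rng.choice(20, size=6, replace=False)
        rows = class_enrichment(markers, raster, "super_class")
        log_ors.append(np.log(rows["odds_ratio"].to_numpy()))
    assert abs(np.mean(log_ors)) < 0.25


def test_enrichment_excludes_unannotated_and_empty_error():
    ann = pd.DataFrame({"name": ["i0", "i1", ""],
                        "super_class": ["A", "B", ""],
                        "class_": ["A", "B", ""], "sub_class": ["A", "B", ""]})
    raster = MsiRaster(sample_id="t", pixel_xy_um=np.zeros((2, 2)),
                       intensities=np.ones((2, 3)),
                       mz=np.array([1.0, 2.0, 3.0]), annotations=ann)
    rows = class_enrichment([0], raster, "super_class")
    assert rows["a"].sum() + rows["c"].sum() + rows["b"].sum() + rows["d"].sum() \
        == 2 * len(rows)  # only the two annotated ions enter each table
    with pytest.raises(ValueError):
        class_enrichment([], raster, "super_class")


def test_differential_symmetry_and_arithmetic():
    rng = np.random.default_rng(4)
    xy = np.array([[x * 100.0, 0.0] for x in range(40)])
    base = rng.lognormal(5, 0.1, size=(40, 1))
    other = rng.lognormal(5, 0.2, size=(40, 3))
    intens = np.hstack([base, other])
    # ion 0 doubled in mask A against an otherwise identical background
    intens[:20, 0] *= 2.0
    # identical masks: nothing passes
    raster = MsiRaster(sample_id="t", pixel_xy_um=xy, intensities=intens,
                       mz=np.array([1.0, 2.0, 3.0, 4.0]))
    with pytest.raises(ValueError):
        differential_metabolites(raster, range(20), range(10, 30))
    out = differential_metabolites(raster, range(20), range(20, 40),
                                   lfc_min=0.5, q_max=0.5)
    assert 0 in set(out["ion"])


def test_differential_exact_doubling_zero_noise():
    xy = np.array([[x * 100.0, 0.0] for x in range(40)])
    intens = np.ones((40, 2))
    intens[:20, 0] = 2.0
    # keep TIC variation out: add a balancing ion so row sums are equal
    intens[:20, 1] = 1.0
    intens[20:, 1] = 2.0
    raster = MsiRaster(sample_id="t", pixel_xy_um=xy, intensities=intens,
                       mz=np.array([1.0, 2.0]))
    out = differential_metabolites(raster, range(20), range(20, 40),
                                   lfc_min=0.5, q_max=0.5)
    row = out[out["ion"] == 0].iloc[0]
    assert np.isclose(row["log2fc"], 1.0, atol=1e-6)
    assert row["direction"] == "up"
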