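"""Similarity registration, pixel->spot aggregation, spatial correlations."""

import numpy as np
import pandas as pd
import pytest

from smvk.config import rng_stream
from smvk.crossmodal import (SimilarityTransform, fit_similarity,
                             metabolite_cell_correlation,
                             metabolite_distance_correlation, pixels_to_spots,
                             pooled_correlation)
from smvk.geometry import DistanceField
from smvk.pipeline import boundary_field
from smvk.synthetic import truth_landmarks


def test_identity_fit():
    pts = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
    tf = fit_similarity(pts, pts)
    assert np.isclose(tf.scale, 1.0) and abs(tf.rotation) < 1e-12
    assert np.allclose(tf.translation, 0.0) and tf.rmse < 1e-12


def test_known_transform_recovered_exactly():
    true = SimilarityTransform(scale=1.1, rotation=0.2, translation=(50.0, -30.0))
    src = np.array([[0.0, 0.0], [500.0, 100.0], [-200.0, 300.0]])
    tf = fit_similarity(src, true.apply(src))
    assert abs(tf.scale - 1.1) < 1e-9
    assert abs(tf.rotation - 0.2) < 1e-9
    assert np.allclose(tf.translation, (50.0, -30.0), atol=1e-9)
    assert tf.rmse < 1e-9


def test_noisy_landmarks_fit():
    rng = np.random.default_rng(11)
    true = SimilarityTransform(scale=1.05, rotation=-0.1, translation=(20.0, 40.0))
    src = rng.uniform(0, 3000, size=(10, 2))
    dst = true.apply(src) + rng.normal(0, 5.0, size=(10, 2))
    tf = fit_similarity(src, dst)
    assert tf.rmse <= 15.0                      # <= 3 sigma
    assert abs(tf.scale - true.scale) / true.scale < 0.05
    assert abs(tf.rotation - true.rotation) < 0.05


def test_degenerate_landmarks_error():
    with pytest.raises(ValueError):
        fit_similarity(np.zeros((3, 2)), np.ones((3, 2)))
    with pytest.raises(ValueError):
        fit_similarity(np.zeros((1, 2)), np.zeros((1, 2)))


def test_inverse_round_trip():
    tf = SimilarityTransform(scale=0.9, rotation=0.7, translation=(12.0, -3.0))
    pts = np.random.default_rng(0).uniform(-100, 100, size=(50, 2))
    back = tf.inverse().apply(tf.apply(pts))
    assert np.allclose(back, pts, atol=1e-9)


def test_refit_on_aligned_landmarks_is_identity(mvi_pos):
    sample, _, truth = mvi_pos
    st_pts, sm_pts = truth_landmarks(sample, truth.registration_transform, 5)
    tf = fit_similarity(st_pts, sm_pts)
    aligned = tf.inverse().apply(sm_pts)
    tf2 = fit_similarity(st_pts, aligned)
    assert abs(tf2.scale - 1.0) < 1e-9 and abs(tf2.rotation) < 1e-9
    assert np.allclose(tf2.translation, 0.0, atol=1e-6)


def test_pixels_to_spots_contract(mvi_pos):
    sample, raster, truth = mvi_pos
    tf = truth.registration_transform.inverse()
    sm = pixels_to_spots(raster, sample, tf)
    # pixel conservation: assigned + unassigned = total
    assert sm.n_pixels.sum() <= raster.n_pixels
    # brute-force nearest-center oracle on a pixel subsample
    mapped = tf.apply(raster.pixel_xy_um)
    rng = np.random.default_rng(0)
    sub = rng.choice(raster.n_pixels, size=1000, replace=False)
    pitch_half = 50.0
    recon = np.zeros(sample.n_spots, dtype=int)
    for i in sub:
        d = np.hypot(*(sample.xy_um - mapped[i]).T)
        j = int(np.argmin(d))
        if d[j] <= pitch_half + 1e-12:
            recon[j] += 1
    # rebuild the same subsample assignment through the public path
    import smvk.types as t
    sub_raster = t.MsiRaster(sample_id="sub",
                             pixel_xy_um=raster.pixel_xy_um[sub],
                             intensities=raster.intensities[sub],
                             mz=raster.mz, annotations=raster.annotations)
    sm_sub = pixels_to_spots(sub_raster, sample, tf, radius_um=pitch_half)
    np.testing.assert_array_equal(sm_sub.n_pixels.to_numpy(), recon)


def test_pixel_cutoff_and_exact_center(mvi_pos):
    sample, raster, truth = mvi_pos
    import smvk.types as t
    one = t.MsiRaster(sample_id="one",
                      pixel_xy_um=np.array([sample.xy_um[10],
                                            sample.xy_um[10] + [0.0, 60.0]]),
                      intensities=np.ones((2, raster.n_ions)), mz=raster.mz)
    ident = SimilarityTransform(1.0, 0.0, (0.0, 0.0))
    sm = pixels_to_spots(one, sample, ident, radius_um=50.0)
    assert sm.n_pixels.iloc[10] >= 1
    # pixel at 60 um from every center with 50 um cutoff stays unassigned
    assert sm.n_pixels.sum() == 1 + (
        1 if np.min(np.hypot(*(sample.xy_um - (sample.xy_um[10] + [0, 60])).T)) <= 50 else 0)


def test_no_pixel_maps_error(mvi_pos):
    sample, raster, truth = mvi_pos
    far = SimilarityTransform(1.0, 0.0, (1e7, 1e7))
    with pytest.raises(ValueError, match="registration failed"):
        pixels_to_spots(raster, sample, far)


def test_duplicated_proportion_as_pseudo_ion(mvi_pos):
    sample, raster, truth = mvi_pos
    tf = truth.registration_transform.inverse()
    sm = pixels_to_spots(raster, sample, tf)
    covered = sm.covered()
    pseudo = sm.intensity.copy()
    pseudo["pseudo"] = np.nan
    pseudo.loc[covered, "pseudo"] = sample.proportions.loc[covered, "iCAF"]
    from smvk.crossmodal import SpotMetabolite
    sm2 = SpotMetabolite(intensity=pseudo, n_pixels=sm.n_pixels)
    corr = metabolite_cell_correlation(sm2, sample.proportions, ions=["pseudo"])
    row = corr[corr["cell_type"] == "iCAF"].iloc[0]
    assert np.isclose(row["rho"], 1.0)


def test_planted_taurine_icaf_rho(mvi_pos):
    sample, raster, truth = mvi_pos
    tf = truth.registration_transform.inverse()
    sm = pixels_to_spots(raster, sample, tf)
    corr = metabolite_cell_correlation(sm, sample.proportions, ions=["taurine"])
    rho = corr[corr["cell_type"] == "iCAF"]["rho"].iloc[0]
    assert corr["n"].iloc[0] >= 500
    assert abs(rho - truth.taurine_icaf_rho) <= 0.1


def test_shuffled_proportions_null(mvi_pos):
    sample, raster, truth = mvi_pos
    tf = truth.registration_transform.inverse()
    sm = pixels_to_spots(raster, sample, tf)
    rng = np.random.default_rng(2)
    shuffled = sample.proportions.copy()
    shuffled[:] = shuffled.to_numpy()[rng.permutation(len(shuffled))]
    corr = metabolite_cell_correlation(sm, shuffled, ions=["taurine"])
    assert abs(corr[corr["cell_type"] == "iCAF"]["rho"].iloc[0]) < 0.15


def test_zero_variance_ion_reported_missing(mvi_pos):
    sample, raster, truth = mvi_pos
    tf = truth.registration_transform.inverse()
    sm = pixels_to_spots(raster, sample, tf)
    flat = sm.intensity.copy()
    flat.loc[sm.covered(), "taurine"] = 1.0
    from smvk.crossmodal import SpotMetabolite
    corr = metabolite_cell_correlation(SpotMetabolite(flat, sm.n_pixels),
                                       sample.proportions, ions=["taurine"])
    assert corr["rho"].isna().all()


def test_pooled_correlation_arithmetic():
    df = pd.DataFrame({"ion": ["t", "t"], "cell_type": ["iCAF", "iCAF"],
                       "rho": [0.5, 0.7], "p": [0.01, 0.01], "n": [100, 100]})
    pooled = pooled_correlation(df)
    assert np.isclose(pooled["mean_rho"].iloc[0], 0.6)
    one = pooled_correlation(df.iloc[[0]])
    assert one["mean_rho"].iloc[0] == 0.5
    with_missing = pd.concat([df, pd.DataFrame(
        {"ion": ["t"], "cell_type": ["iCAF"], "rho": [np.nan],
         "p": [np.nan], "n": [0]})])
    pooled2 = pooled_correlation(with_missing)
    assert pooled2["n_samples"].iloc[0] == 2


def test_metabolite_distance_correlation(mvi_pos):
    sample, raster, truth = mvi_pos
    tf = truth.registration_transform.inverse()
    sm = pixels_to_spots(raster, sample, tf)
    boundary, dist = boundary_field(sample, "T")
    tc = [b for b, r in zip(sample.barcodes, sample.region_label) if r == "TC"]
    sub = DistanceField(dist.distance_um.loc[tc],
                        dist.nearest_boundary_spot.loc[tc])
    rho, p = metabolite_distance_correlation(sm, sub, "taurine")
    assert rho > 0  # taurine tracks the distal iCAF gradient
    # intensity = distance exactly
    fake = sm.intensity.copy()
    common = fake.index.intersection(sub.distance_um.index)
    fake.loc[common, "taurine"] = sub.distance_um.loc[common]
    from smvk.crossmodal import SpotMetabolite
    rho1, _ = metabolite_distance_correlation(
        SpotMetabolite(fake, sm.n_pixels), sub, "taurine")
    assert np.isclose(rho1, 1.0)
    flat = sm.intensity.copy()
    flat.loc[:, "taurine"] = 3.0
    with pytest.raises(ValueError):
        metabolite_distance_correlation(SpotMetabolite(flat, sm.n_pixels),
                                        sub, "taurine")
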