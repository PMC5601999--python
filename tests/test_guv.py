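"""GUV quantification: geometry, radial profiles, ratios, classification
and population statistics."""

import numpy as np
import pytest

from memfluo.guv import (
    GuvGeometry,
    GuvRecord,
    RingDetectionError,
    classify_guv,
    estimate_camera_offset,
    find_guv_geometry,
    lumen_exterior_ratio,
    population_stats,
    radial_profile,
)
from memfluo.synth.images import GuvSceneConfig, synth_guv_image


def _scene(gfp_ratio, tracer_ratio, seed=7, **kw):
    cfg = GuvSceneConfig(
        channels={
            "membrane": (800.0, 0.0, 0.0),
            "gfp": (300.0, gfp_ratio, 100.0),
            "tracer": (0.0, tracer_ratio, 150.0),
        },
        seed=seed,
        **kw,
    )
    return synth_guv_image(cfg)


def test_geometry_recovery_within_half_pixel():
    imgs, truth = _scene(2.0, 1.0, center=(64.0, 64.0))
    geom = find_guv_geometry(imgs["membrane"])
    assert abs(geom.center[0] - 64.0) < 0.5
    assert abs(geom.center[1] - 64.0) < 0.5
    assert geom.radius == pytest.approx(truth["radius"], abs=1.0)
    assert geom.inside_image


def test_uniform_image_is_a_detection_error(rng):
    with pytest.raises(RingDetectionError):
        find_guv_geometry(rng.poisson(100.0, size=(64, 64)).astype(float))


def test_ring_near_border_flagged():
    imgs, _ = _scene(1.0, 1.0, center=(40.0, 40.0), image_size=128, radius=30.0)
    # crop so the ring touches the border
    crop = imgs["membrane"][:66, :66]
    geom = find_guv_geometry(crop, approx_center=(40.0, 40.0))
    assert not geom.inside_image


def test_radial_profile_flat_image():
    geom = GuvGeometry(center=(32.0, 32.0), radius=12.0)
    prof = radial_profile(np.full((64, 64), 7.0), geom)
    assert np.allclose(prof.values, 7.0)
    assert np.allclose(prof.normalized, 1.0)


def test_radial_profile_peak_at_ring():
    imgs, truth = _scene(1.0, 1.0)
    geom = GuvGeometry(center=truth["center"], radius=truth["radius"])
    prof = radial_profile(imgs["membrane"], geom)
    peak_r = prof.radii[np.argmax(prof.values)]
    assert peak_r == pytest.approx(truth["radius"], abs=1.0)


def test_radial_profile_truncation_flag():
    geom = GuvGeometry(center=(32.0, 32.0), radius=10.0)
    prof = radial_profile(np.ones((64, 64)), geom, r_max=100.0)
    assert prof.truncated


def test_lumen_plateau_ratio_recovery():
    imgs, truth = _scene(5.0, 1.0, seed=3)
    geom = find_guv_geometry(imgs["membrane"])
    r = lumen_exterior_ratio(imgs["gfp"], geom, truth["camera_offset"])
    assert r == pytest.approx(5.0, rel=0.02)


@pytest.mark.parametrize(
    "gfp,tracer,tol_gfp,tol_tracer",
    [(4.93, 0.96, 0.05 * 4.93, 0.05), (1.33, 0.05, 0.05 * 1.33, 0.02)],
)
def test_exemplar_ratio_recovery(gfp, tracer, tol_gfp, tol_tracer):
    imgs, truth = _scene(gfp, tracer, seed=5)
    geom = find_guv_geometry(imgs["membrane"])
    rg = lumen_exterior_ratio(imgs["gfp"], geom, truth["camera_offset"])
    rt = lumen_exterior_ratio(imgs["tracer"], geom, truth["camera_offset"])
    assert abs(rg - gfp) <= tol_gfp
    assert abs(rt - tracer) <= tol_tracer


def test_flat_field_ratio_any_geometry():
    img = np.full((96, 96), 250.0)
    for center, radius in [((48.0, 48.0), 20.0), ((40.0, 55.0), 15.0)]:
        geom = GuvGeometry(center=center, radius=radius)
        assert lumen_exterior_ratio(img, geom) == pytest.approx(1.0, abs=0.02)


def test_ratio_scale_invariance():
    imgs, truth = _scene(3.0, 0.5, seed=9)
    geom = find_guv_geometry(imgs["membrane"])
    r1 = lumen_exterior_ratio(imgs["gfp"], geom, truth["camera_offset"])
    r2 = lumen_exterior_ratio(3.0 * imgs["gfp"], geom, 3.0 * truth["camera_offset"])
    assert r2 == pytest.approx(r1, rel=1e-9)


def test_exterior_annulus_required():
    geom = GuvGeometry(center=(32.0, 32.0), radius=28.0)  # 1.4R outside image
    with pytest.raises(ValueError, match="exterior"):
        lumen_exterior_ratio(np.ones((64, 64)), geom)


def test_camera_offset_estimate_uses_darkest_corner():
    img = np.full((64, 64), 500.0)
    img[:8, :8] = 100.0
    assert estimate_camera_offset(img, patch=8) == pytest.approx(100.0)


# ------------------------------------------------------------ classifier


def test_classification_boundaries_count_as_positive():
    assert classify_guv(0.6, 1.6) == (True, True)
    assert classify_guv(0.5999, 1.5999) == (False, False)


@pytest.mark.parametrize(
    "tracer,gfp,expected",
    [
        (0.96, 6.44, (True, True)),   # long-chain heparin exemplar
        (0.05, 0.84, (False, False)),  # cholesterol-free exemplar
    ],
)
def test_classification_exemplars(tracer, gfp, expected):
    assert classify_guv(tracer, gfp) == expected


def test_threshold_monotonicity(rng):
    ratios = rng.uniform(0.0, 3.0, size=200)
    pct = [
        np.mean([classify_guv(0.0, g, thresholds=(0.6, thr))[1] for g in ratios])
        for thr in (1.2, 1.6, 2.0)
    ]
    assert pct[0] >= pct[1] >= pct[2]


def test_nonfinite_ratio_rejected():
    with pytest.raises(ValueError):
        classify_guv(np.nan, 1.0)


# ------------------------------------------------------- population stats


def _record(cond, rep, pore, trans):
    geom = GuvGeometry(center=(10.0, 10.0), radius=6.0)
    return GuvRecord(geometry=geom, ratio_tracer=1.0, ratio_gfp=1.0,
                     pore=pore, translocation=trans,
                     condition_label=cond, replicate=rep)


def test_population_stats_all_positive():
    recs = [_record("a", 0, True, True) for _ in range(5)]
    (s,) = population_stats(recs)
    assert s.pct_pore == 100.0 and s.sd_pore == 0.0
    assert s.n_guvs == 5


def test_population_stats_hand_computed_replicates():
    recs = [_record("c", 0, False, i < 2) for i in range(10)]
    recs += [_record("c", 1, False, i < 4) for i in range(10)]
    (s,) = population_stats(recs)
    assert s.pct_translocation == pytest.approx(30.0)
    assert s.sd_translocation == pytest.approx(np.std([20.0, 40.0], ddof=1))
    assert s.n_guvs == 20


def test_population_stats_binomial_recovery(rng):
    recs = []
    p = 0.4
    for rep in range(3):
        for _ in range(40):
            recs.append(_record("sim", rep, bool(rng.random() < p), False))
    (s,) = population_stats(recs)
    se = 100 * np.sqrt(p * (1 - p) / 120)
    assert abs(s.pct_pore - 40.0) < 3 * se
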