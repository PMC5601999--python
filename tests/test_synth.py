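"""Synthetic-data generators: determinism, closed-form conservation laws
and physical consistency of the Brownian-dynamics oracle."""

import numpy as np
import pytest

from memfluo.fcs.correlate import correlate_trace
from memfluo.fcs.fitting import fit_acf
from memfluo.fcs.zscan import InstrumentConfig, analyze_zscan
from memfluo.synth.curves import synth_frap, synth_titration
from memfluo.synth.images import GuvSceneConfig, synth_guv_image, synth_spot_image
from memfluo.synth.trace import (
    SimConfig,
    SimConfigError,
    expected_mean_intensity,
    simulate_membrane_trace,
)
from memfluo.synth.zscan import simulate_zscan_series


def test_trace_determinism_bit_identical():
    cfg = SimConfig(n_species=((2, 30.0, 1.5),), duration=2.0, bin_width=5e-4,
                    seed=99)
    c1, t1 = simulate_membrane_trace(cfg)
    c2, t2 = simulate_membrane_trace(cfg)
    assert np.array_equal(c1, c2)
    assert t1["species"] == t2["species"]


def test_zero_particles_is_poisson_background(rng):
    cfg = SimConfig(n_species=((1, 0.0, 2.5),), duration=4.0, bin_width=2e-4,
                    background=5000.0, seed=5)
    counts, _ = simulate_membrane_trace(cfg)
    lam = 5000.0 * 2e-4
    assert counts.mean() == pytest.approx(lam, rel=0.05)
    assert counts.var() == pytest.approx(lam, rel=0.1)  # Poisson: var = mean
    cur = correlate_trace(counts, 2e-4)
    assert np.max(np.abs(cur.values - 1.0)) < 0.05


def test_mean_intensity_conservation():
    """Simulated trace mean matches the closed-form detection integral
    within 2%."""
    cfg = SimConfig(n_species=((1, 80.0, 2.5), (4, 10.0, 1.0)),
                    duration=20.0, bin_width=2e-4, background=300.0, seed=8)
    counts, truth = simulate_membrane_trace(cfg)
    expected = expected_mean_intensity(cfg)
    assert truth["expected_mean_intensity"] == expected
    assert counts.mean() / cfg.bin_width == pytest.approx(expected, rel=0.02)


def test_triplet_bright_fraction_scales_mean_rate():
    # dense, fast membrane: many particles and short τ2D keep the
    # time-averaged occupancy noise well below the tolerance (2D
    # diffusion is recurrent, so sparse slow traces wander for seconds)
    base = dict(n_species=((1, 100.0, 10.0),), duration=1.0, bin_width=1e-5,
                background=0.0, seed=13)
    cfg0 = SimConfig(**base)
    cfgt = SimConfig(**base, triplet=(0.3, 1e-4))
    c0, _ = simulate_membrane_trace(cfg0)
    ct, _ = simulate_membrane_trace(cfgt)
    assert c0.mean() / cfg0.bin_width == pytest.approx(
        expected_mean_intensity(cfg0), rel=0.1
    )
    assert ct.mean() / cfgt.bin_width == pytest.approx(
        expected_mean_intensity(cfgt), rel=0.1
    )
    assert expected_mean_intensity(cfgt) == pytest.approx(
        0.7 * expected_mean_intensity(cfg0)
    )


def test_triplet_blinking_correlation_on_static_emitters():
    """With diffusion frozen, blinking is the only fluctuation source:
    G(τ) − 1 must be a single exponential with the triplet lifetime and
    no long-lag plateau."""
    tau_t = 1e-4
    cfg = SimConfig(n_species=((1, 10.0, 1e-6),), duration=2.0, bin_width=1e-5,
                    brightness_per_monomer=2e4, background=0.0, seed=21,
                    triplet=(0.3, tau_t))
    counts, _ = simulate_membrane_trace(cfg)
    cur = correlate_trace(counts, cfg.bin_width)
    # decays to baseline beyond a few lifetimes
    plateau = cur.values[(cur.lags >= 5 * tau_t) & (cur.lags <= 5e-3)]
    assert np.max(np.abs(plateau - 1.0)) < 0.03
    # positive fast component
    fast = cur.lags <= 0.3 * tau_t
    assert cur.values[fast].mean() - 1.0 > 0.02
    # exponential lifetime: log-linear slope over the decay
    band = (cur.lags >= 2e-5) & (cur.lags <= 2.5e-4) & (cur.values > 1.005)
    slope = np.polyfit(cur.lags[band], np.log(cur.values[band] - 1.0), 1)[0]
    assert -1.0 / slope == pytest.approx(tau_t, rel=0.3)


def test_triplet_too_coarse_binning_rejected():
    with pytest.raises(SimConfigError):
        SimConfig(n_species=((1, 10.0, 2.5),), bin_width=0.1, duration=10.0,
                  triplet=(0.2, 1e-6))


def test_oracle_chain_recovers_particle_number_and_diffusion():
    """simulate → correlate → fit recovers (N, τD) within 10%."""
    w0, d = 0.25, 2.5
    tau_d = w0**2 / (4 * d)
    cfg = SimConfig(n_species=((1, 10.0 / (np.pi * w0**2), d),), w0=w0,
                    bin_width=2e-4, duration=30.0, background=0.0, seed=55)
    counts, truth = simulate_membrane_trace(cfg)
    cur = correlate_trace(counts, cfg.bin_width)
    fit = fit_acf(cur.restrict(tau_max=1.0),
                  fixed=("tau3d", "sp", "tau_t", "t_frac"))
    assert fit.converged
    assert fit.params.pn2d == pytest.approx(truth["species"][0]["pn2d"], rel=0.1)
    assert fit.params.tau2d == pytest.approx(tau_d, rel=0.1)


def test_brightness_squared_weighting_of_mixtures():
    """For an equal-count monomer/8-mer mixture the apparent state
    I/(PN·ϕ_monomer) equals Σcn²/Σcn = 65/9 ≈ 7.2 (brightness-squared
    particle weighting of FCS), between the two pure states."""
    w0, d, q = 0.25, 2.5, 3000.0
    c_each = 20.0
    cfg = SimConfig(n_species=((1, c_each, d), (8, c_each, d)), w0=w0, bin_width=2e-4,
                    duration=30.0, background=0.0, brightness_per_monomer=q, seed=66)
    counts, _ = simulate_membrane_trace(cfg)
    cur = correlate_trace(counts, cfg.bin_width)
    fit = fit_acf(cur.restrict(tau_max=1.0),
                  fixed=("tau3d", "sp", "tau_t", "t_frac"))
    phi_cluster = cur.mean_intensity / fit.params.pn2d
    state = phi_cluster / (q / 2.0)
    assert 1.0 < state < 8.0
    assert state == pytest.approx(65.0 / 9.0, rel=0.2)


def test_bulk_species_contributes_3d_component():
    cfg = SimConfig(n_species=((1, 0.0, 2.5),), bulk=(50.0, 50.0),
                    duration=5.0, bin_width=5e-5, background=0.0, seed=44)
    counts, _ = simulate_membrane_trace(cfg)
    assert counts.mean() / cfg.bin_width == pytest.approx(
        expected_mean_intensity(cfg), rel=0.05
    )
    cur = correlate_trace(counts, cfg.bin_width)
    assert cur.values[cur.lags < 5e-4].mean() > 1.005  # correlated signal present


# ------------------------------------------------------------- z-scan fast mode


def test_zscan_fast_mode_parabola_is_exact_without_noise(instrument):
    cfg = SimConfig(n_species=((1, 40.0, 2.5),), seed=1)
    series, truth = simulate_zscan_series(cfg, instrument, membrane_z=-0.075,
                                          noise_scale=0.0, intensity_noise=0.0)
    pn = np.array([fit_acf(c, fixed=("tau3d", "sp", "tau_t", "t_frac")).params.pn2d
                   for c in series.curves])
    w2 = instrument.beam_radius_sq(series.z_positions - (-0.075))
    assert pn == pytest.approx(cfg.n_species[0][1] * np.pi * w2, rel=1e-3)


def test_zscan_dimensional_consistency():
    """Scaling w0 by k rescales the recovered τ2D minimum by k²."""
    results = {}
    for k, w0 in ((1, 0.25), (2, 0.5)):
        inst = InstrumentConfig(w0=w0)
        cfg = SimConfig(n_species=((1, 40.0, 2.5),), w0=w0, seed=3)
        series, _ = simulate_zscan_series(cfg, inst, noise_scale=0.0,
                                          intensity_noise=0.0)
        res = analyze_zscan(series, inst, background=cfg.background)
        results[k] = res.min_tau2d
    assert results[2] / results[1] == pytest.approx(4.0, rel=0.01)


def test_zscan_generator_determinism(instrument):
    cfg = SimConfig(n_species=((1, 40.0, 2.5),), seed=17)
    s1, _ = simulate_zscan_series(cfg, instrument)
    s2, _ = simulate_zscan_series(cfg, instrument)
    assert all(np.array_equal(a.values, b.values)
               for a, b in zip(s1.curves, s2.curves))
    assert np.array_equal(s1.intensities, s2.intensities)


# ---------------------------------------------------------------- images


def test_spot_image_empty_truth_is_background_only():
    img, table = synth_spot_image([], background=50.0, read_noise=0.0, seed=2,
                                  poisson=False)
    assert table == []
    assert np.all(img == 50.0)


def test_spot_image_determinism():
    truth = [(20.0, 30.0, 3), (60.0, 70.0, 6)]
    i1, _ = synth_spot_image(truth, seed=4)
    i2, _ = synth_spot_image(truth, seed=4)
    assert np.array_equal(i1, i2)


def test_guv_image_determinism_and_truth():
    cfg = GuvSceneConfig(seed=12)
    i1, t1 = synth_guv_image(cfg)
    i2, _ = synth_guv_image(cfg)
    assert all(np.array_equal(i1[k], i2[k]) for k in i1)
    assert t1["ratios"]["gfp"] == pytest.approx(1.0)


def test_guv_scene_must_fit_in_image():
    with pytest.raises(ValueError, match="margin"):
        GuvSceneConfig(image_size=64, radius=30.0, center=(32.0, 32.0))


# ---------------------------------------------------------------- curves


def test_titration_noise_free_exact_recovery():
    from memfluo.binding import fit_titration

    series = synth_titration(16.0, {"A": 0.2}, noise=0.0, seed=0)
    fit = fit_titration(series)
    assert fit.mean_kd == pytest.approx(16.0, rel=1e-3)


def test_frap_generator_edge_cases():
    t, y, _ = synth_frap(0.4, 1.0, noise=0.0, seed=0)
    assert y[-1] == pytest.approx(1.0, rel=1e-2)  # full recovery
    t, y0, _ = synth_frap(0.4, 0.0, noise=0.0, seed=0)
    assert np.allclose(y0, y0[0])  # immobile: flat post-bleach curve
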