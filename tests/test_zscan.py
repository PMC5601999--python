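"""z-scan analysis chain: recovery on the generator, units, QC and
degenerate geometries."""

import numpy as np
import pytest

from memfluo.fcs.curve import CorrelationCurve
from memfluo.fcs.model import AcfParams, InvalidParameterError, acf_model
from memfluo.fcs.zscan import (
    InstrumentConfig,
    MonomerReference,
    ZScanSeries,
    analyze_zscan,
    diffusion_coefficient,
    monomer_reference_from_results,
    oligomeric_state,
    surface_concentration_fcs,
    surface_concentration_intensity,
)
from memfluo.synth.trace import SimConfig
from memfluo.synth.zscan import simulate_zscan_series
from memfluo.units import AVOGADRO


@pytest.fixture(scope="module")
def monomer_ref():
    inst = InstrumentConfig()
    results = []
    for i in range(5):
        cfg = SimConfig(n_species=((1, 60.0, 2.5),), seed=9000 + i)
        series, _ = simulate_zscan_series(cfg, inst)
        results.append(analyze_zscan(series, inst, background=cfg.background))
    return monomer_reference_from_results(results)


def test_monomer_zscan_recovery(instrument, monomer_ref):
    cfg = SimConfig(n_species=((1, 40.0, 2.5),), seed=21)
    series, truth = simulate_zscan_series(cfg, instrument, with_lipid_channel=True)
    res = analyze_zscan(series, instrument, monomer=monomer_ref,
                        background=cfg.background)
    assert res.qc_pass
    assert res.oligomeric_state == pytest.approx(1.0, abs=0.1)
    assert res.diffusion_coeff == pytest.approx(2.5, rel=0.15)
    true_conc = 40.0 * 1e21 / AVOGADRO  # molecules/µm² -> nmol/m²
    assert res.surface_conc == pytest.approx(true_conc, rel=0.15)


def test_hexamer_zscan_recovery(instrument, monomer_ref):
    cfg = SimConfig(n_species=((6, 10.0, 2.5),), seed=22)
    series, _ = simulate_zscan_series(cfg, instrument)
    res = analyze_zscan(series, instrument, monomer=monomer_ref,
                        background=cfg.background)
    assert res.oligomeric_state == pytest.approx(6.0, abs=0.6)


def test_missing_monomer_reference_gives_no_state(instrument):
    cfg = SimConfig(n_species=((1, 40.0, 2.5),), seed=23)
    series, _ = simulate_zscan_series(cfg, instrument)
    res = analyze_zscan(series, instrument, background=cfg.background)
    assert res.oligomeric_state is None
    assert res.surface_conc is None
    assert res.diffusion_coeff > 0


def test_vertex_at_symmetry_center(instrument):
    """A z-symmetric scan yields the vertex at the center within half a
    z-step (noise-free)."""
    cfg = SimConfig(n_species=((1, 40.0, 2.5),), seed=24)
    series, _ = simulate_zscan_series(
        cfg, instrument, membrane_z=-0.075, z_start=-1.5, noise_scale=0.0,
        intensity_noise=0.0,
    )
    res = analyze_zscan(series, instrument, background=cfg.background)
    assert abs(res.vertex_z - (-0.075)) <= instrument.z_step / 2


def test_flat_pn_profile_falls_back_and_fails_qc(instrument):
    """No membrane: constant PN2D(z) and τ2D(z) — fall-back + qc failure."""
    lags = np.geomspace(4e-6, 10.0, 128)
    p = AcfParams(pn2d=10.0, tau2d=5e-3)
    g = acf_model(lags, p)
    z = -1.5 + 0.15 * np.arange(20)
    curves = [CorrelationCurve(lags=lags, values=g) for _ in z]
    series = ZScanSeries(z_positions=z, curves=curves,
                         intensities=np.full(20, 1e4))
    res = analyze_zscan(series, instrument)
    assert res.pn_parabola.fallback and res.tau_parabola.fallback
    assert not res.qc_pass


def test_implausible_lipid_diffusion_fails_qc(instrument):
    cfg = SimConfig(n_species=((1, 40.0, 2.5),), seed=25)
    series, _ = simulate_zscan_series(cfg, instrument, with_lipid_channel=True,
                                      lipid_d=50.0)  # outside [0.5, 20] µm²/s
    res = analyze_zscan(series, instrument, background=cfg.background)
    assert not res.qc_pass
    assert any("lipid" in n for n in res.notes)


def test_oracle_and_fast_modes_agree(instrument):
    """The Brownian-dynamics z-scan and the analytic fast mode give the
    same analysis results within 15%."""
    inst = InstrumentConfig(n_steps=9, z_step=0.15)
    cfg = SimConfig(n_species=((1, 30.0, 2.5),), bin_width=2e-4, seed=42,
                    background=100.0)
    s_orc, _ = simulate_zscan_series(cfg, inst, mode="oracle", z_start=-0.6,
                                     curve_duration=8.0)
    r_orc = analyze_zscan(s_orc, inst, background=100.0)
    s_fast, _ = simulate_zscan_series(cfg, inst, mode="fast", z_start=-0.6,
                                      curve_duration=8.0)
    r_fast = analyze_zscan(s_fast, inst, background=100.0)
    assert r_orc.min_pn2d == pytest.approx(r_fast.min_pn2d, rel=0.15)
    assert r_orc.diffusion_coeff == pytest.approx(r_fast.diffusion_coeff, rel=0.15)
    assert r_orc.phi_cluster == pytest.approx(r_fast.phi_cluster, rel=0.15)


# ----------------------------------------------------- scalar operations


def test_oligomeric_state_values():
    assert oligomeric_state(100.0, 100.0) == 1.0
    assert oligomeric_state(9.23 * 840.0, 840.0) == pytest.approx(9.23)
    with pytest.raises(InvalidParameterError):
        oligomeric_state(100.0, 0.0)


def test_diffusion_coefficient_values():
    assert diffusion_coefficient(1.0, 2.0) == 1.0  # w0² = 4·τ
    assert diffusion_coefficient(4.0e-3, 0.2) == pytest.approx(2.5)
    with pytest.raises(InvalidParameterError):
        diffusion_coefficient(-1.0, 0.2)


def test_surface_concentration_unit_conversion():
    # state=1, PN2D=π, w0=1 µm → 1 molecule/µm² exactly
    expected = 1e21 / AVOGADRO  # nmol/m²
    assert surface_concentration_fcs(1.0, np.pi, 1.0) == pytest.approx(expected,
                                                                       rel=1e-12)
    small = surface_concentration_fcs(1.0, 1e-9, 1.0)
    assert 0 < small < 1e-9  # PN→0 limit: concentration → 0


def test_surface_concentration_intensity_linearity():
    assert surface_concentration_intensity(0.0, 2.0) == 0.0
    c1 = surface_concentration_intensity(500.0, 2.0)
    assert surface_concentration_intensity(1000.0, 2.0) == pytest.approx(2 * c1)
    with pytest.raises(InvalidParameterError):
        surface_concentration_intensity(500.0, None)


def test_both_concentration_methods_agree_on_generator(instrument, monomer_ref):
    """FCS-based and intensity-based surface concentrations within 20%."""
    # calibrate counts-per-concentration on one scan of known density
    cal_density = 50.0
    cfg = SimConfig(n_species=((1, cal_density, 2.5),), seed=31)
    series, _ = simulate_zscan_series(cfg, instrument)
    res = analyze_zscan(series, instrument, background=cfg.background)
    cal_conc = cal_density * 1e21 / AVOGADRO
    calibration = (res.intensity_at_min - cfg.background) / cal_conc

    cfg2 = SimConfig(n_species=((1, 25.0, 2.5),), seed=32)
    series2, _ = simulate_zscan_series(cfg2, instrument)
    res2 = analyze_zscan(series2, instrument, monomer=monomer_ref,
                         background=cfg2.background)
    c_int = surface_concentration_intensity(
        res2.intensity_at_min - cfg2.background, calibration
    )
    assert c_int == pytest.approx(res2.surface_conc, rel=0.2)


def test_monomer_reference_requires_positive_brightness():
    with pytest.raises(InvalidParameterError):
        MonomerReference(phi_monomer=-1.0)
    ref = monomer_reference_from_results(
        [type("R", (), {"phi_cluster": v})() for v in (10.0, 11.0, 9.5)]
    )
    assert ref.n_measurements == 3
    assert ref.phi_monomer == pytest.approx(10.1666, rel=1e-3)
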