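"""Parameter-recovery validation studies.

Each function runs one self-contained simulation study — generate
synthetic data with known ground truth, push it through the analysis
chain, and measure recovery — and returns a flat dict of metrics.
These studies back both the validation test suite and the
``scripts/acceptance.py`` report; all randomness derives from the
single ``seed`` argument.

Problem sizes are chosen for desk-scale runs: the Brownian-dynamics
oracle study uses four replicate 60-s traces per condition (the
curve-to-curve scatter of single 60-s membrane ACFs is a few percent
of the amplitude, so replicate averaging is required for a stable
deviation measure); the other studies run in seconds.
"""

from __future__ import annotations

import numpy as np

from .binding import CompetitionTable, fit_titration, normalize_competition
from .fcs.correlate import correlate_trace
from .fcs.zscan import (
    InstrumentConfig,
    analyze_zscan,
    monomer_reference_from_results,
)
from .frap import fit_frap
from .guv import (
    classify_guv,
    find_guv_geometry,
    lumen_exterior_ratio,
    radial_profile,
)
from .spots import mixture_decompose
from .synth.curves import synth_frap, synth_titration
from .synth.images import GuvSceneConfig, synth_guv_image
from .synth.trace import SimConfig, simulate_membrane_trace
from .synth.zscan import simulate_zscan_series

W0 = 0.25  # µm, package default beam waist
D_REF = 2.5  # µm²/s


def _subseed(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + k * 7919) % (2**31 - 1))


# ---------------------------------------------------------------- FCS oracle


def fcs_oracle_equivalence(
    seed: int,
    n_values: tuple = (5, 20),
    replicates: int = 4,
    duration: float = 60.0,
    d_coeff: float = D_REF,
) -> dict:
    """Brownian-dynamics traces vs the closed-form 2D ACF.

    For each mean particle number N, ``replicates`` independent 60-s
    monomer traces are simulated, correlated and averaged; the mean
    absolute relative deviation of G(τ)−1 from 1+(1/N)(1+τ/τD)⁻¹−1 is
    evaluated over τ ∈ [0.1τD, 10τD].  Background is zero because the
    reference form carries no uncorrelated-background dilution.
    """
    tau_d = W0**2 / (4.0 * d_coeff)
    out = {}
    for n in n_values:
        dens = n / (np.pi * W0**2)
        curves = []
        pn_eff = None
        for r in range(replicates):
            cfg = SimConfig(
                n_species=((1, dens, d_coeff),),
                w0=W0,
                bin_width=2.0e-4,
                duration=duration,
                background=0.0,
                seed=_subseed(seed, 100 * n + r),
            )
            counts, truth = simulate_membrane_trace(cfg)
            curves.append(correlate_trace(counts, cfg.bin_width))
            pn_eff = truth["species"][0]["pn2d"]
        lags = curves[0].lags
        g_avg = np.mean([c.values for c in curves], axis=0)
        band = (lags >= 0.1 * tau_d) & (lags <= 10.0 * tau_d)
        g_model = (1.0 / pn_eff) / (1.0 + lags[band] / tau_d)
        dev = np.abs((g_avg[band] - 1.0) - g_model) / g_model
        out[f"mard_pct_n{n}"] = float(100.0 * np.mean(dev))
        out[f"n_lags_n{n}"] = int(band.sum())
    return out


# ------------------------------------------------------- z-scan recovery


def _monomer_reference(seed: int, instrument: InstrumentConfig, n_scans: int = 5):
    results = []
    for i in range(n_scans):
        cfg = SimConfig(n_species=((1, 60.0, D_REF),), w0=instrument.w0,
                        seed=_subseed(seed, 9000 + i))
        series, _ = simulate_zscan_series(cfg, instrument)
        results.append(analyze_zscan(series, instrument, background=cfg.background))
    return monomer_reference_from_results(results)


def oligomer_recovery(
    seed: int,
    n_values: tuple = (1, 2, 4, 8, 12),
    replicates: int = 10,
    cluster_density: float = 20.0,
) -> dict:
    """Pure n-mer z-scans through the full pipeline against a monomer
    reference built by the identical pipeline."""
    inst = InstrumentConfig(w0=W0)
    ref = _monomer_reference(seed, inst)
    out = {"phi_monomer": ref.phi_monomer}
    for n in n_values:
        states = []
        for r in range(replicates):
            cfg = SimConfig(n_species=((n, cluster_density, D_REF),), w0=W0,
                            seed=_subseed(seed, 100 * n + r))
            series, _ = simulate_zscan_series(cfg, inst)
            res = analyze_zscan(series, inst, monomer=ref, background=cfg.background)
            states.append(res.oligomeric_state)
        states = np.asarray(states)
        out[f"state_n{n}_mean"] = float(states.mean())
        out[f"state_n{n}_min"] = float(states.min())
        out[f"state_n{n}_max"] = float(states.max())
    return out


def d_recovery(
    seed: int,
    d_values: tuple = (0.4, 1.7, 2.5, 4.8),
    replicates: int = 10,
) -> dict:
    """Diffusion-constant recovery from the τ2D(z) parabola minimum,
    plus the monomer-control oligomeric state."""
    inst = InstrumentConfig(w0=W0)
    out = {}
    worst = 0.0
    for d in d_values:
        ests = []
        for r in range(replicates):
            cfg = SimConfig(n_species=((1, 40.0, d),), w0=W0,
                            seed=_subseed(seed, int(d * 1000) + r))
            series, _ = simulate_zscan_series(cfg, inst)
            res = analyze_zscan(series, inst, background=cfg.background)
            ests.append(res.diffusion_coeff)
        ests = np.asarray(ests)
        rel = np.abs(ests - d) / d
        out[f"d{d}_mean"] = float(ests.mean())
        out[f"d{d}_max_rel_err_pct"] = float(100.0 * rel.max())
        worst = max(worst, float(rel.max()))
    out["max_rel_err_pct"] = 100.0 * worst

    ref = _monomer_reference(seed, inst)
    states = []
    for r in range(replicates):
        cfg = SimConfig(n_species=((1, 20.0, D_REF),), w0=W0,
                        seed=_subseed(seed, 777000 + r))
        series, _ = simulate_zscan_series(cfg, inst)
        states.append(
            analyze_zscan(series, inst, monomer=ref, background=cfg.background)
            .oligomeric_state
        )
    out["monomer_state_mean"] = float(np.mean(states))
    return out


# ------------------------------------------------------------- mixtures


MIXTURE_MEANS = (3.0, 6.0, 11.0, 17.0)
MIXTURE_WEIGHTS = (0.35, 0.35, 0.2, 0.1)


def mixture_benchmark(seed: int, n_runs: int = 20, n_clusters: int = 1200) -> dict:
    """Four-component subunit-count benchmark (means 3/6/11/17).

    Cluster counts are drawn from the mixture with per-component sd of
    15% of the mean; BIC-selected k and the worst relative error of the
    recovered means (when k = 4) are reported over seeded runs.
    """
    means = np.asarray(MIXTURE_MEANS)
    hits = 0
    worst = []
    for run in range(n_runs):
        s = _subseed(seed, 5000 + run)
        rng = np.random.default_rng(s)
        comp = rng.choice(4, size=n_clusters, p=MIXTURE_WEIGHTS)
        counts = np.clip(rng.normal(means[comp], 0.15 * means[comp]), 0.3, None)
        dist = mixture_decompose(counts, k_max=8, seed=s)
        if dist.n_components == 4:
            hits += 1
            m = np.array([c[0] for c in dist.components])
            worst.append(float(np.max(np.abs(m - means) / means)))
    return {
        "k4_rate_pct": 100.0 * hits / n_runs,
        "max_mean_rel_err_pct": 100.0 * max(worst) if worst else float("nan"),
        "n_runs": n_runs,
    }


# ------------------------------------------------------------------ GUVs


def _measure_scene(gfp_ratio: float, tracer_ratio: float, seed: int) -> tuple:
    cfg = GuvSceneConfig(
        channels={
            "membrane": (800.0, 0.0, 0.0),
            "gfp": (300.0, gfp_ratio, 100.0),
            "tracer": (0.0, tracer_ratio, 150.0),
        },
        seed=seed,
    )
    images, truth = synth_guv_image(cfg)
    geom = find_guv_geometry(images["membrane"])
    off = truth["camera_offset"]
    rg = lumen_exterior_ratio(images["gfp"], geom, off)
    rt = lumen_exterior_ratio(images["tracer"], geom, off)
    return rg, rt


def guv_classifier_exactness(seed: int, n_guvs: int = 200, margin: float = 0.05) -> dict:
    """Cohort with true ratios at least ``margin`` away from the 0.6/1.6
    thresholds: measured classification must match truth exactly."""
    rng = np.random.default_rng(_subseed(seed, 31))

    def draw(lo, hi, thr):
        while True:
            v = rng.uniform(lo, hi)
            if abs(v - thr) >= margin:
                return v

    correct = 0
    for i in range(n_guvs):
        tr = draw(0.02, 1.4, 0.6)
        gf = draw(0.2, 3.0, 1.6)
        rg, rt = _measure_scene(gf, tr, _subseed(seed, 40000 + i))
        if classify_guv(rt, rg) == classify_guv(tr, gf):
            correct += 1

    # flat-field property: uniform image at an arbitrary geometry
    flat = np.full((96, 96), 400.0)
    from .guv import GuvGeometry

    geom = GuvGeometry(center=(43.0, 51.0), radius=20.0)
    flat_ratio = lumen_exterior_ratio(flat, geom, camera_offset=0.0)
    prof = radial_profile(flat, geom)
    return {
        "accuracy_pct": 100.0 * correct / n_guvs,
        "flat_field_ratio": float(flat_ratio),
        "flat_profile_cv": float(prof.values.std() / prof.values.mean()),
        "n_guvs": n_guvs,
    }


GUV_EXEMPLARS = {
    # label: (gfp lumen/exterior, tracer lumen/exterior)
    "long_chain_heparin": (6.44, 0.96),
    "luminal_heparin": (4.93, 0.96),
    "no_luminal_heparin": (1.33, 0.05),
    "cholesterol_free": (0.84, 0.05),
}


def guv_exemplar_recovery(seed: int) -> dict:
    """Worked-exemplar ratio recovery and classification."""
    out = {}
    for i, (label, (gf, tr)) in enumerate(GUV_EXEMPLARS.items()):
        rg, rt = _measure_scene(gf, tr, _subseed(seed, 600 + i))
        pore, trans = classify_guv(rt, rg)
        out[f"{label}_gfp_measured"] = float(rg)
        out[f"{label}_gfp_true"] = gf
        out[f"{label}_tracer_measured"] = float(rt)
        out[f"{label}_tracer_true"] = tr
        out[f"{label}_pore"] = bool(pore)
        out[f"{label}_translocation"] = bool(trans)
    return out


# ---------------------------------------------------------------- binding


KD_GRID = (1.0, 5.0, 16.0, 50.0, 100.0)


def kd_recovery(seed: int, replicates: int = 10, noise: float = 0.05) -> dict:
    """Quadratic-model K_D recovery at P = 80 µM, 8 residues, 5% noise.

    Reports the median relative error pooled over the K_D grid and
    replicate datasets, plus the hyperbolic/quadratic agreement in the
    depletion-free limit (P = K_D/200, noise-free).
    """
    ddmax = {f"R{i}": 0.08 + 0.03 * i for i in range(8)}
    errs = []
    per_kd = {}
    for kd in KD_GRID:
        kd_errs = []
        for r in range(replicates):
            series = synth_titration(
                kd, ddmax, protein_conc=80.0, noise=noise,
                seed=_subseed(seed, int(kd * 37) + r),
            )
            fit = fit_titration(series, model="quadratic")
            kd_errs.append(abs(fit.mean_kd - kd) / kd)
        per_kd[f"kd{kd:g}_median_rel_err_pct"] = float(100.0 * np.median(kd_errs))
        errs.extend(kd_errs)

    # depletion-free limit: both models on the same noise-free data
    series = synth_titration(100.0, {"A": 0.2, "B": 0.15}, protein_conc=0.5,
                             noise=0.0, seed=_subseed(seed, 12))
    kq = fit_titration(series, model="quadratic").mean_kd
    kh = fit_titration(series, model="hyperbolic").mean_kd
    out = {
        "pooled_median_rel_err_pct": float(100.0 * np.median(errs)),
        "model_agreement_pct": float(100.0 * abs(kq - kh) / kq),
    }
    out.update(per_kd)
    return out


def frap_and_competition(seed: int) -> dict:
    """Mobile-fraction recovery and competition half-max interpolation."""
    out = {}
    worst = 0.0
    for i, mf in enumerate((0.0, 0.5, 0.98, 1.0)):
        t, y, _ = synth_frap(0.4, mf, roi_side=2.0, noise=0.01,
                             seed=_subseed(seed, 70 + i))
        fit = fit_frap(t, y, roi_side=2.0)
        err = abs(fit.mobile_fraction - mf)
        out[f"mf_{mf:g}_est"] = float(fit.mobile_fraction)
        worst = max(worst, err)
    out["mf_max_abs_err"] = float(worst)

    # competition series constructed with a 5 µM half-max
    conc = np.array([0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0])
    true_half = 5.0
    pct_true = 100.0 / (1.0 + conc / true_half)
    table = CompetitionTable(
        competitor_conc=conc,
        signal_bound=10.0 + 90.0 * pct_true / 100.0,  # linear densitometry scale
        control_bound=100.0,
        background=10.0,
    )
    _, half = normalize_competition(table)
    out["half_max_um"] = float(half)
    out["half_max_rel_err_pct"] = float(100.0 * abs(half - true_half) / true_half)
    return out


# ------------------------------------------------------------ determinism


def determinism(seed: int) -> dict:
    """Bit-identical regeneration under a repeated seed."""
    cfg = SimConfig(n_species=((1, 50.0, D_REF),), duration=2.0,
                    bin_width=1e-3, seed=_subseed(seed, 1))
    c1, _ = simulate_membrane_trace(cfg)
    c2, _ = simulate_membrane_trace(cfg)
    trace_ok = bool(np.array_equal(c1, c2))

    gcfg = GuvSceneConfig(seed=_subseed(seed, 2))
    i1, _ = synth_guv_image(gcfg)
    i2, _ = synth_guv_image(gcfg)
    guv_ok = all(np.array_equal(i1[k], i2[k]) for k in i1)

    scfg = SimConfig(n_species=((1, 40.0, D_REF),), seed=_subseed(seed, 3))
    s1, _ = simulate_zscan_series(scfg)
    s2, _ = simulate_zscan_series(scfg)
    zscan_ok = all(
        np.array_equal(a.values, b.values) for a, b in zip(s1.curves, s2.curves)
    ) and np.array_equal(s1.intensities, s2.intensities)
    return {
        "trace_bit_identical": trace_ok,
        "guv_bit_identical": bool(guv_ok),
        "zscan_bit_identical": bool(zscan_ok),
        "all_identical": bool(trace_ok and guv_ok and zscan_ok),
    }
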