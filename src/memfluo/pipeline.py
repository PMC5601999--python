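"""End-to-end pipelines: z-scan oligomer-state determination and GUV
translocation scoring over a run manifest.

A run manifest is a CSV enumerating input files with their roles:

* GUV stage: columns file, condition, replicate, membrane, gfp, tracer
  (the last three are TIFF page indices for the channel map).
* z-scan stage: columns file (long-format z-scan CSV), label.

Every run writes CSV/JSON reports embedding the seed and config hash;
QC exclusions are enumerated in the QC log, never dropped silently.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .fcs.zscan import InstrumentConfig, MonomerReference, analyze_zscan
from .guv import (
    DEFAULT_THRESHOLDS,
    GuvRecord,
    RingDetectionError,
    classify_guv,
    find_guv_geometry,
    lumen_exterior_ratio,
    population_stats,
)

__all__ = ["run_guv_pipeline", "run_zscan_pipeline", "PipelineError"]

log = logging.getLogger("memfluo")


class PipelineError(RuntimeError):
    pass


def run_guv_pipeline(
    manifest_path,
    out_dir,
    thresholds: tuple = DEFAULT_THRESHOLDS,
    camera_offset: float | None = None,
    seed: int = 0,
) -> dict:
    """Score every GUV image listed in the manifest and summarize.

    Returns a dict with the per-GUV table, per-condition summaries and
    the QC log; the same content is written to ``out_dir``.
    """
    manifest = pd.read_csv(manifest_path)
    required = {"file", "condition", "replicate", "membrane", "gfp", "tracer"}
    if manifest.empty or not required.issubset(manifest.columns):
        raise PipelineError(f"manifest must be non-empty with columns {sorted(required)}")
    base = Path(manifest_path).parent
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records: list[GuvRecord] = []
    qc_log: list[dict] = []
    for row in manifest.itertuples(index=False):
        path = base / str(row.file)
        try:
            channels = mio.read_image(
                path,
                {"membrane": row.membrane, "gfp": row.gfp, "tracer": row.tracer},
            )
            offset = camera_offset
            if offset is None:
                from .guv import estimate_camera_offset

                offset = estimate_camera_offset(channels["tracer"])
            geom = find_guv_geometry(channels["membrane"].astype(float))
            if not geom.inside_image:
                qc_log.append({"file": str(row.file), "reason": "ring clipped by border"})
                continue
            rt = lumen_exterior_ratio(channels["tracer"].astype(float), geom, offset)
            rg = lumen_exterior_ratio(channels["gfp"].astype(float), geom, offset)
            pore, trans = classify_guv(rt, rg, thresholds)
            records.append(
                GuvRecord(
                    geometry=geom, ratio_tracer=rt, ratio_gfp=rg,
                    pore=pore, translocation=trans,
                    condition_label=str(row.condition), replicate=int(row.replicate),
                )
            )
        except (RingDetectionError, ValueError) as exc:
            qc_log.append({"file": str(row.file), "reason": str(exc)})
            log.warning("excluded %s: %s", row.file, exc)

    per_guv = pd.DataFrame(
        {
            "condition": [r.condition_label for r in records],
            "replicate": [r.replicate for r in records],
            "center_row": [r.geometry.center[0] for r in records],
            "center_col": [r.geometry.center[1] for r in records],
            "radius_px": [r.geometry.radius for r in records],
            "ratio_tracer": [r.ratio_tracer for r in records],
            "ratio_gfp": [r.ratio_gfp for r in records],
            "pore": [r.pore for r in records],
            "translocation": [r.translocation for r in records],
        }
    )
    summaries = population_stats(records)
    summary = pd.DataFrame(
        {
            "condition": [s.condition_label for s in summaries],
            "n_guvs": [s.n_guvs for s in summaries],
            "pct_pore": [s.pct_pore for s in summaries],
            "sd_pore": [s.sd_pore for s in summaries],
            "pct_translocation": [s.pct_translocation for s in summaries],
            "sd_translocation": [s.sd_translocation for s in summaries],
        }
    )
    per_guv.to_csv(out_dir / "guv_records.csv", index=False, float_format=mio.FLOAT_FMT)
    summary.to_csv(out_dir / "guv_summary.csv", index=False, float_format=mio.FLOAT_FMT)
    cfg = {"thresholds": list(thresholds), "camera_offset": camera_offset}
    mio.write_report(
        out_dir / "guv_report.json",
        {"n_records": len(records), "qc_excluded": qc_log},
        seed=seed,
        config=cfg,
    )
    return {"records": per_guv, "summary": summary, "qc_log": qc_log}


def run_zscan_pipeline(
    manifest_path,
    out_dir,
    instrument: InstrumentConfig | None = None,
    monomer_phi: float | None = None,
    background: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Analyze every z-scan CSV in the manifest (columns file, label)."""
    manifest = pd.read_csv(manifest_path)
    if manifest.empty or "file" not in manifest.columns:
        raise PipelineError("manifest must be non-empty with a 'file' column")
    if instrument is None:
        instrument = InstrumentConfig()
    monomer = MonomerReference(monomer_phi) if monomer_phi else None
    base = Path(manifest_path).parent
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for row in manifest.itertuples(index=False):
        series = mio.read_zscan_csv(base / str(row.file))
        res = analyze_zscan(series, instrument, monomer=monomer, background=background)
        rows.append(
            {
                "file": str(row.file),
                "label": getattr(row, "label", ""),
                "min_pn2d": res.min_pn2d,
                "min_tau2d_s": res.min_tau2d,
                "phi_cluster_cps": res.phi_cluster,
                "oligomeric_state": res.oligomeric_state,
                "diffusion_um2_s": res.diffusion_coeff,
                "surface_conc_nmol_m2": res.surface_conc,
                "qc_pass": res.qc_pass,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "zscan_results.csv", index=False, float_format=mio.FLOAT_FMT)
    mio.write_report(
        out_dir / "zscan_report.json",
        {"n_scans": len(rows), "n_qc_fail": int((~df["qc_pass"]).sum())},
        seed=seed,
        config={"w0_um": instrument.w0, "background_cps": background,
                "monomer_phi": monomer_phi},
    )
    return df
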