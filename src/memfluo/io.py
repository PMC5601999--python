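"""File formats: CSV for curves and tables, YAML for configs, TIFF for
images, JSON for nested reports.

Writers and readers are paired round-trip tested; floats are written
with 9 significant digits.  Reports always embed the seed and a hash of
the configuration so that two runs with identical inputs are
byte-identical apart from timestamps.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .fcs.curve import CorrelationCurve
from .fcs.zscan import InstrumentConfig, ZScanSeries

__all__ = [
    "write_curve_csv",
    "read_curve_csv",
    "write_zscan_csv",
    "read_zscan_csv",
    "write_trace_csv",
    "read_trace_csv",
    "read_instrument_config",
    "write_instrument_config",
    "read_image",
    "write_report",
    "config_hash",
]

FLOAT_FMT = "%.9g"


def write_curve_csv(path, curve: CorrelationCurve) -> None:
    df = pd.DataFrame({"lag_s": curve.lags, "g": curve.values})
    if curve.se is not None:
        df["se"] = curve.se
    with open(path, "w") as fh:
        fh.write(f"# duration_s={curve.duration:.9g}\n")
        fh.write(f"# mean_intensity_cps={curve.mean_intensity:.9g}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def _read_csv_with_meta(path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = float(val)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, meta


def read_curve_csv(path) -> CorrelationCurve:
    df, meta = _read_csv_with_meta(path)
    return CorrelationCurve(
        lags=df["lag_s"].to_numpy(),
        values=df["g"].to_numpy(),
        se=df["se"].to_numpy() if "se" in df else None,
        duration=meta.get("duration_s", 0.0),
        mean_intensity=meta.get("mean_intensity_cps", 0.0),
    )


def write_zscan_csv(path, series: ZScanSeries) -> None:
    """Single long-format CSV: one row per (z, lag)."""
    rows = []
    for z, cur, inten in zip(series.z_positions, series.curves, series.intensities):
        n = len(cur)
        rows.append(
            pd.DataFrame(
                {
                    "z_um": np.full(n, z),
                    "mean_intensity_cps": np.full(n, inten),
                    "lag_s": cur.lags,
                    "g": cur.values,
                    "se": cur.se if cur.se is not None else np.full(n, np.nan),
                }
            )
        )
    pd.concat(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_zscan_csv(path) -> ZScanSeries:
    df = pd.read_csv(path)
    z_vals = np.unique(df["z_um"].to_numpy())
    curves, intens = [], []
    for z in z_vals:
        g = df[df["z_um"] == z]
        se = g["se"].to_numpy()
        curves.append(
            CorrelationCurve(
                lags=g["lag_s"].to_numpy(),
                values=g["g"].to_numpy(),
                se=None if np.all(np.isnan(se)) else se,
                mean_intensity=float(g["mean_intensity_cps"].iloc[0]),
            )
        )
        intens.append(float(g["mean_intensity_cps"].iloc[0]))
    return ZScanSeries(z_positions=z_vals, curves=curves, intensities=np.array(intens))


def write_trace_csv(path, counts: np.ndarray, bin_width: float) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bin_width_s={bin_width:.9g}\n")
        pd.DataFrame({"counts": np.asarray(counts)}).to_csv(fh, index=False)


def read_trace_csv(path) -> tuple[np.ndarray, float]:
    df, meta = _read_csv_with_meta(path)
    if "bin_width_s" not in meta:
        raise ValueError("trace file must declare bin_width_s metadata")
    return df["counts"].to_numpy(), float(meta["bin_width_s"])


def write_instrument_config(path, cfg: InstrumentConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "w0_um": cfg.w0,
                "wavelength_nm": cfg.wavelength,
                "refractive_index": cfg.refractive_index,
                "z_step_um": cfg.z_step,
                "n_steps": cfg.n_steps,
            },
            fh,
        )


def read_instrument_config(path) -> InstrumentConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return InstrumentConfig(
        w0=float(d["w0_um"]),
        wavelength=float(d.get("wavelength_nm", 488.0)),
        refractive_index=float(d.get("refractive_index", 1.33)),
        z_step=float(d.get("z_step_um", 0.15)),
        n_steps=int(d.get("n_steps", 20)),
    )


def read_image(path, channel_map: dict | None = None) -> dict:
    """Read a TIFF stack into named integer channel arrays.

    ``channel_map`` maps channel name -> page index and is mandatory
    for multi-page files: page order is never assumed to carry meaning.
    Accepted bit depths: 8, 12 (stored as 16) and 16 bit unsigned.
    """
    arr = tifffile.imread(str(path))
    if arr.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"unsupported bit depth/dtype {arr.dtype} in {path}")
    if arr.ndim == 2:
        name = "image" if not channel_map else next(iter(channel_map))
        return {name: arr}
    if arr.ndim != 3:
        raise ValueError(f"expected 2D or 3D TIFF, got shape {arr.shape}")
    if not channel_map:
        raise ValueError("multi-page TIFF requires an explicit channel map")
    out = {}
    for name, page in channel_map.items():
        if not 0 <= int(page) < arr.shape[0]:
            raise ValueError(f"channel {name!r} maps to missing page {page}")
        out[name] = arr[int(page)]
    return out


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_report(path, payload: dict, seed: int | None = None, config: dict | None = None) -> None:
    """JSON report embedding the seed and configuration hash."""
    doc = dict(payload)
    if seed is not None:
        doc["seed"] = seed
    if config is not None:
        doc["config_hash"] = config_hash(config)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
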