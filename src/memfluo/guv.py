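"""GUV confocal-image quantification.

For each vesicle: locate the membrane ring in the marker channel, build
radial intensity profiles per channel, form lumen/exterior intensity
ratios, classify pore formation (small-tracer ratio ≥ 0.6) and cargo
translocation (GFP ratio ≥ 1.6), and aggregate per-condition statistics
across replicates.

Region conventions (configurable): the lumen is sampled at r < 0.6·R
and the exterior at r > 1.4·R, both excluding the membrane peak and its
PSF skirt; annuli are 1 px wide.  Ratios are computed on camera-offset-
subtracted raw means, not on the peak-normalized display profile, so
they do not couple to membrane brightness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GuvGeometry",
    "RadialProfile",
    "GuvRecord",
    "ConditionSummary",
    "find_guv_geometry",
    "radial_profile",
    "lumen_exterior_ratio",
    "classify_guv",
    "population_stats",
    "estimate_camera_offset",
    "RingDetectionError",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (0.6, 1.6)  # tracer (pore), GFP (translocation)
LUMEN_FRACTION = 0.6
EXTERIOR_FRACTION = 1.4


class RingDetectionError(ValueError):
    """No membrane ring could be located."""


@dataclass
class GuvGeometry:
    center: tuple  # (row, col), pixels
    radius: float  # px
    pixel_size: float = 1.0  # µm/px
    inside_image: bool = True

    def __post_init__(self) -> None:
        if self.radius <= 5:
            raise RingDetectionError(f"ring radius {self.radius} px too small")


@dataclass
class RadialProfile:
    radii: np.ndarray  # px, increasing annulus centers
    values: np.ndarray  # mean intensity per annulus (raw counts)
    normalized: np.ndarray  # values / max(values)
    truncated: bool = False

    def __post_init__(self) -> None:
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be increasing")
        if self.radii.shape != self.values.shape:
            raise ValueError("length mismatch")


@dataclass
class GuvRecord:
    geometry: GuvGeometry
    ratio_tracer: float
    ratio_gfp: float
    pore: bool
    translocation: bool
    condition_label: str = ""
    replicate: int = 0


@dataclass
class ConditionSummary:
    condition_label: str
    n_guvs: int
    pct_pore: float
    pct_translocation: float
    per_experiment_pore: list = field(default_factory=list)
    per_experiment_translocation: list = field(default_factory=list)
    sd_pore: float = 0.0
    sd_translocation: float = 0.0


def _radial_distances(shape: tuple, center: tuple) -> np.ndarray:
    yy, xx = np.indices(shape)
    return np.hypot(yy - center[0], xx - center[1])


def estimate_camera_offset(image: np.ndarray, patch: int = 8) -> float:
    """Camera offset estimate from the darkest of the four corner patches.

    Only valid when at least one corner is free of fluorescent signal;
    prefer passing a measured offset when one is available.
    """
    image = np.asarray(image, dtype=float)
    p = patch
    corners = [
        image[:p, :p], image[:p, -p:], image[-p:, :p], image[-p:, -p:],
    ]
    return float(min(c.mean() for c in corners))


def radial_profile(
    image: np.ndarray,
    geometry: GuvGeometry,
    r_max: float | None = None,
    bin_width: float = 1.0,
    allow_partial_annuli: bool = False,
) -> RadialProfile:
    """Mean intensity over concentric 1-px annuli around the GUV center.

    ``r_max`` beyond the nearest image border truncates the profile and
    sets the ``truncated`` flag, unless ``allow_partial_annuli`` is set,
    in which case annuli are averaged over the pixels that exist (used
    for ring detection near borders).
    """
    image = np.asarray(image, dtype=float)
    r = _radial_distances(image.shape, geometry.center)
    cy, cx = geometry.center
    border = min(cy, cx, image.shape[0] - 1 - cy, image.shape[1] - 1 - cx)
    truncated = False
    if allow_partial_annuli:
        corner = float(r.max())
        r_max = corner if r_max is None else min(r_max, corner)
    elif r_max is None:
        r_max = border
    elif r_max > border:
        r_max = border
        truncated = True
    nbins = int(r_max / bin_width)
    if nbins < 3:
        raise ValueError("profile would have fewer than 3 annuli")
    idx = (r / bin_width).astype(int)
    mask = idx < nbins
    sums = np.bincount(idx[mask], weights=image[mask], minlength=nbins)
    cnts = np.bincount(idx[mask], minlength=nbins)
    vals = sums / np.maximum(cnts, 1)
    radii = (np.arange(nbins) + 0.5) * bin_width
    vmax = vals.max()
    return RadialProfile(
        radii=radii, values=vals,
        normalized=vals / vmax if vmax > 0 else vals,
        truncated=truncated,
    )


def find_guv_geometry(
    image: np.ndarray,
    approx_center: tuple | None = None,
    pixel_size: float = 1.0,
    n_iter: int = 5,
) -> GuvGeometry:
    """Locate the membrane ring in the marker channel.

    Starting from ``approx_center`` (default: intensity-weighted
    centroid of the above-background pixels), alternate between taking
    the radius as the argmax of the radial profile and re-centering on
    the intensity-weighted centroid of the ring annulus.  Rings cut by
    the image border are flagged via ``inside_image=False``.
    """
    image = np.asarray(image, dtype=float)
    bg = np.median(image)
    peak = image.max()
    if peak <= bg or (peak - bg) < 5 * (np.percentile(image, 75) - np.percentile(image, 25) + 1e-12):
        raise RingDetectionError("no ring-like structure above background")

    if approx_center is None:
        w = np.clip(image - bg, 0, None)
        yy, xx = np.indices(image.shape)
        approx_center = (float((w * yy).sum() / w.sum()), float((w * xx).sum() / w.sum()))
    center = approx_center
    radius = None
    for _ in range(n_iter):
        r = _radial_distances(image.shape, center)
        geom = GuvGeometry(center=center, radius=max(6.0, 1.0), pixel_size=pixel_size)
        prof = radial_profile(image, geom, allow_partial_annuli=True)
        new_radius = float(prof.radii[int(np.argmax(prof.values))])
        if radius is not None and new_radius < 0.7 * radius:
            # re-centering collapsed (partial arc near a border):
            # keep the previous stable estimate
            break
        radius = new_radius
        ring = np.abs(r - radius) < 3.0
        w = np.clip(image - bg, 0, None) * ring
        if w.sum() <= 0:
            raise RingDetectionError("empty ring annulus")
        yy, xx = np.indices(image.shape)
        new_center = (float((w * yy).sum() / w.sum()), float((w * xx).sum() / w.sum()))
        if max(abs(new_center[0] - center[0]), abs(new_center[1] - center[1])) > 0.3 * radius:
            break  # unstable centroid (clipped ring); keep last estimate
        center = new_center
    cy, cx = center
    border = min(cy, cx, image.shape[0] - 1 - cy, image.shape[1] - 1 - cx)
    inside = radius is not None and radius < border
    return GuvGeometry(center=center, radius=float(radius), pixel_size=pixel_size,
                       inside_image=bool(inside))


def lumen_exterior_ratio(
    image: np.ndarray,
    geometry: GuvGeometry,
    camera_offset: float = 0.0,
    lumen_fraction: float = LUMEN_FRACTION,
    exterior_fraction: float = EXTERIOR_FRACTION,
) -> float:
    """Background-subtracted lumen/exterior mean-intensity ratio.

    Lumen: r < lumen_fraction·R; exterior: r > exterior_fraction·R up to
    the nearest border.  Raises when the exterior annulus is empty.
    """
    image = np.asarray(image, dtype=float)
    r = _radial_distances(image.shape, geometry.center)
    lum = r < lumen_fraction * geometry.radius
    cy, cx = geometry.center
    border = min(cy, cx, image.shape[0] - 1 - cy, image.shape[1] - 1 - cx)
    ext = (r > exterior_fraction * geometry.radius) & (r < border)
    if not np.any(ext):
        raise ValueError("exterior annulus is empty — profile must extend beyond 1.4R")
    if not np.any(lum):
        raise ValueError("lumen region is empty")
    lumen_mean = image[lum].mean() - camera_offset
    ext_mean = image[ext].mean() - camera_offset
    if ext_mean <= 0:
        raise ValueError("non-positive exterior intensity after offset subtraction")
    return float(lumen_mean / ext_mean)


def classify_guv(
    ratio_tracer: float,
    ratio_gfp: float,
    thresholds: tuple = DEFAULT_THRESHOLDS,
) -> tuple[bool, bool]:
    """Pore / translocation calls; boundary values count as positive."""
    if not (np.isfinite(ratio_tracer) and np.isfinite(ratio_gfp)):
        raise ValueError("ratios must be finite")
    pore = ratio_tracer >= thresholds[0]
    translocation = ratio_gfp >= thresholds[1]
    return bool(pore), bool(translocation)


def population_stats(records: list) -> list:
    """Per-condition percentages of pore-positive and translocation-positive
    GUVs, with cross-replicate mean and standard deviation.

    Empty conditions are excluded (they contribute no rows by
    construction); counts are preserved in ``n_guvs``.
    """
    if not records:
        return []
    df = pd.DataFrame(
        {
            "condition": [r.condition_label for r in records],
            "replicate": [r.replicate for r in records],
            "pore": [r.pore for r in records],
            "translocation": [r.translocation for r in records],
        }
    )
    out = []
    for cond, g in df.groupby("condition", sort=False):
        rep = g.groupby("replicate").agg(
            pore_pct=("pore", lambda s: 100.0 * s.mean()),
            trans_pct=("translocation", lambda s: 100.0 * s.mean()),
            n=("pore", "size"),
        )
        pore_pcts = rep["pore_pct"].to_list()
        trans_pcts = rep["trans_pct"].to_list()
        out.append(
            ConditionSummary(
                condition_label=str(cond),
                n_guvs=int(rep["n"].sum()),
                pct_pore=float(np.mean(pore_pcts)),
                pct_translocation=float(np.mean(trans_pcts)),
                per_experiment_pore=pore_pcts,
                per_experiment_translocation=trans_pcts,
                sd_pore=float(np.std(pore_pcts, ddof=1)) if len(pore_pcts) > 1 else 0.0,
                sd_translocation=float(np.std(trans_pcts, ddof=1)) if len(trans_pcts) > 1 else 0.0,
            )
        )
    return out
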