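"""Single-molecule spot-brightness analysis on supported bilayers.

Workflow: detect diffraction-limited spots as local maxima, fit each
with a 2D Gaussian to extract its peak brightness, normalize the peak
brightness to that of a monomeric reference fluorophore to obtain a
monomer count per cluster, and deconvolve the count distribution into
Gaussian sub-populations selected by the Bayesian information
criterion.

Pixel convention: 0-based indices, coordinates at pixel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from sklearn.mixture import GaussianMixture

__all__ = [
    "SpotDetection",
    "OligomerDistribution",
    "detect_spots",
    "fit_spot_gaussian",
    "monomer_normalize",
    "mixture_decompose",
    "BorderSpotError",
    "InsufficientDataError",
]

# accepted fitted-σ range relative to the nominal PSF σ
SIGMA_ACCEPT = (0.7, 1.9)


class BorderSpotError(ValueError):
    """Fit window clipped by the image border; the spot is skipped."""


class InsufficientDataError(ValueError):
    pass


@dataclass
class SpotDetection:
    """A localized diffraction-limited spot."""

    x: float  # pixel coordinates, 0-based, pixel-center convention
    y: float
    peak: float  # background-subtracted peak amplitude, counts
    sigma: float  # PSF standard deviation, pixels
    offset: float  # local background, counts
    fit_ok: bool


@dataclass
class OligomerDistribution:
    """Gaussian-mixture decomposition of per-cluster monomer counts."""

    monomer_counts: np.ndarray
    components: list  # (mean, sd, weight), sorted by mean
    n_components: int
    selection_score: float  # BIC of the selected model
    scores: dict = field(default_factory=dict)  # k -> BIC
    flagged: bool = False


def detect_spots(
    image: np.ndarray,
    min_separation: float = 3.0,
    threshold: float = 0.0,
) -> np.ndarray:
    """Local-maxima candidate detection.

    Returns an (n, 2) array of (row, col) integer candidate positions
    above ``threshold`` counts over the image median; maxima closer
    than ``min_separation`` are merged to the brighter one.  A flat
    image yields an empty result.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 15:
        raise ValueError("image must be 2D and at least 15x15 pixels")
    bg = float(np.median(image))
    size = max(3, int(round(min_separation)))
    footprint = np.ones((size, size), dtype=bool)
    local_max = image == ndimage.maximum_filter(image, footprint=footprint)
    candidates = np.argwhere(local_max & (image > bg + threshold))
    if candidates.size == 0:
        return candidates.reshape(0, 2)
    # greedy merge: keep brighter of any pair closer than min_separation
    order = np.argsort(image[candidates[:, 0], candidates[:, 1]])[::-1]
    kept: list[np.ndarray] = []
    for idx in order:
        c = candidates[idx]
        if all(np.hypot(*(c - k)) >= min_separation for k in kept):
            kept.append(c)
    return np.array(kept, dtype=int)


def _gauss2d(params: np.ndarray, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    amp, x0, y0, sigma, off = params
    return amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma**2)) + off


def fit_spot_gaussian(
    image: np.ndarray,
    candidate: tuple,
    window: int = 7,
    psf_sigma: float = 1.3,
) -> SpotDetection:
    """Least-squares 2D Gaussian fit of one spot in a square window.

    ``candidate`` is (row, col).  ``fit_ok`` is False when the fitted σ
    falls outside 0.7–1.9× the nominal PSF σ or the optimizer diverges.
    Raises BorderSpotError when the window does not fit in the image.
    """
    image = np.asarray(image, dtype=float)
    r, c = int(candidate[0]), int(candidate[1])
    half = window // 2
    if r - half < 0 or c - half < 0 or r + half >= image.shape[0] or c + half >= image.shape[1]:
        raise BorderSpotError(f"window around ({r}, {c}) clipped by border")
    patch = image[r - half : r + half + 1, c - half : c + half + 1]
    yy, xx = np.mgrid[r - half : r + half + 1, c - half : c + half + 1]

    off0 = float(patch.min())
    amp0 = float(patch.max() - off0)
    x0 = np.array([max(amp0, 1e-6), c, r, psf_sigma, off0])
    lo = [0.0, c - half, r - half, 0.3 * psf_sigma, -np.inf]
    hi = [np.inf, c + half, r + half, 3.0 * psf_sigma, np.inf]

    try:
        sol = least_squares(
            lambda p: (_gauss2d(p, yy, xx) - patch).ravel(), x0,
            bounds=(lo, hi), method="trf", max_nfev=500,
        )
        amp, xc, yc, sigma, off = sol.x
        ok = (
            sol.status > 0
            and amp > 0
            and SIGMA_ACCEPT[0] * psf_sigma <= sigma <= SIGMA_ACCEPT[1] * psf_sigma
        )
    except Exception:
        amp, xc, yc, sigma, off, ok = 0.0, float(c), float(r), psf_sigma, off0, False
    return SpotDetection(
        x=float(xc), y=float(yc), peak=float(max(amp, 0.0)),
        sigma=float(sigma), offset=float(off), fit_ok=bool(ok),
    )


def monomer_normalize(
    peaks: np.ndarray,
    phi_monomer: float,
    dol: float = 0.9,
    correct_labeling: bool = False,
) -> np.ndarray:
    """Convert peak brightness to monomer counts per cluster.

    count = peak / ϕ_monomer; when ``correct_labeling`` is requested the
    counts are additionally divided by the degree of labeling (off by
    default — brightness distributions are customarily reported without
    the correction, with the DOL quoted as metadata).
    """
    if phi_monomer <= 0:
        raise ValueError("phi_monomer must be > 0")
    if not 0 < dol <= 1:
        raise ValueError("dol must be in (0, 1]")
    counts = np.asarray(peaks, dtype=float) / phi_monomer
    if correct_labeling:
        counts = counts / dol
    return counts


def mixture_decompose(
    counts: np.ndarray,
    k_max: int = 8,
    seed: int = 0,
    n_init: int = 10,
    variance_floor: float = 1.0e-2,
    min_counts: int = 50,
) -> OligomerDistribution:
    """1D Gaussian-mixture deconvolution of monomer-count distributions.

    Mixtures with k = 1..k_max components (free variances with a floor)
    are fitted by seeded expectation-maximization with ``n_init``
    restarts each; k is chosen by BIC.  Components are reported sorted
    by mean.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < min_counts:
        raise InsufficientDataError(f"need >= {min_counts} counts, got {counts.size}")
    if np.any(counts <= 0):
        raise ValueError("monomer counts must be > 0")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")

    x = counts.reshape(-1, 1)
    scores: dict[int, float] = {}
    models: dict[int, GaussianMixture] = {}
    flagged = False
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k, covariance_type="full", n_init=n_init,
            reg_covar=variance_floor, random_state=seed, max_iter=500,
        )
        try:
            gm.fit(x)
        except Exception:
            flagged = True
            continue
        if not gm.converged_:
            flagged = True
        scores[k] = float(gm.bic(x))
        models[k] = gm
    if not models:
        raise RuntimeError("no mixture fit succeeded")

    k_best = min(scores, key=scores.get)
    gm = models[k_best]
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    components = [
        (float(means[i]), float(sds[i]), float(weights[i])) for i in order
    ]
    return OligomerDistribution(
        monomer_counts=counts,
        components=components,
        n_components=k_best,
        selection_score=scores[k_best],
        scores=scores,
        flagged=flagged,
    )


def analyze_image(
    image: np.ndarray,
    psf_sigma: float = 1.3,
    min_separation: float = 3.0,
    threshold: float = 0.0,
    window: int = 7,
) -> list[SpotDetection]:
    """Detect-and-fit convenience wrapper; border spots are skipped."""
    out = []
    for cand in detect_spots(image, min_separation=min_separation, threshold=threshold):
        try:
            out.append(fit_spot_gaussian(image, cand, window=window, psf_sigma=psf_sigma))
        except BorderSpotError:
            continue
    return out


def monomer_brightness(detections: list) -> float:
    """Monomer brightness standard from a monomer-control image set.

    Single-component Gaussian fit (the mode) of the accepted peak
    distribution, mirroring how the cluster pipeline itself is run.
    """
    peaks = np.array([d.peak for d in detections if d.fit_ok], dtype=float)
    if peaks.size < 5:
        raise InsufficientDataError("need >= 5 accepted monomer spots")
    gm = GaussianMixture(n_components=1, random_state=0).fit(peaks.reshape(-1, 1))
    return float(gm.means_.ravel()[0])
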