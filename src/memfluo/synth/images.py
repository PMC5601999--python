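"""Synthetic image generators: diffraction-limited spot fields and
multi-channel GUV scenes.

Spot images place 2D Gaussian spots of amplitude n·monomer_brightness
on a constant background, then apply Poisson shot noise and Gaussian
read noise.  GUV scenes build a membrane ring with a Gaussian
cross-section over lumen/exterior intensity plateaus per channel,
apply a Gaussian PSF blur, a camera offset and noise; the ground-truth
ratios are recorded alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["synth_spot_image", "GuvSceneConfig", "synth_guv_image"]


def synth_spot_image(
    truth: list,
    shape: tuple = (128, 128),
    psf_sigma: float = 1.3,
    monomer_brightness: float = 100.0,
    background: float = 20.0,
    read_noise: float = 2.0,
    seed: int = 0,
    poisson: bool = True,
) -> tuple[np.ndarray, list]:
    """Render spots given truth = [(x, y, n_monomers), ...].

    Returns the image and a truth table [(x, y, n, peak), ...] with the
    noise-free peak amplitude of each spot.
    """
    rng = np.random.default_rng(seed)
    img = np.full(shape, float(background))
    yy, xx = np.indices(shape)
    table = []
    for x, y, n in truth:
        peak = n * monomer_brightness
        img += peak * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * psf_sigma**2))
        table.append((float(x), float(y), int(n), float(peak)))
    if poisson:
        img = rng.poisson(img).astype(float)
    if read_noise > 0:
        img = img + read_noise * rng.standard_normal(shape)
    return img, table


@dataclass(frozen=True)
class GuvSceneConfig:
    """One synthetic GUV scene.

    ``channels`` maps channel name -> (membrane_amplitude, lumen_ratio,
    exterior_intensity); the lumen plateau is lumen_ratio×exterior.
    """

    image_size: int = 128
    pixel_size: float = 0.1  # µm/px
    center: tuple = (64.0, 64.0)
    radius: float = 30.0  # px
    channels: dict = field(
        default_factory=lambda: {
            "membrane": (800.0, 0.0, 0.0),
            "gfp": (300.0, 1.0, 100.0),
            "tracer": (0.0, 1.0, 150.0),
        }
    )
    ring_sigma: float = 1.2  # px, membrane cross-section
    psf_sigma: float = 1.0  # px
    camera_offset: float = 100.0
    read_noise: float = 2.0
    seed: int = 0
    noise: bool = True

    def __post_init__(self) -> None:
        margin = self.radius + 4 * (self.ring_sigma + self.psf_sigma)
        cy, cx = self.center
        n = self.image_size
        if min(cy, cx, n - 1 - cy, n - 1 - cx) < margin:
            raise ValueError("ring plus PSF margin must fit inside the image")


def synth_guv_image(config: GuvSceneConfig) -> tuple[dict, dict]:
    """Render a multi-channel GUV scene.

    Returns (channel name -> image) and a truth record with the exact
    lumen/exterior ratios per channel, the geometry and the offset.
    """
    rng = np.random.default_rng(config.seed)
    n = config.image_size
    yy, xx = np.indices((n, n))
    r = np.hypot(yy - config.center[0], xx - config.center[1])
    images = {}
    truth = {
        "center": config.center,
        "radius": config.radius,
        "camera_offset": config.camera_offset,
        "seed": config.seed,
        "ratios": {},
    }
    lumen_mask = r < config.radius
    for name, (ring_amp, lumen_ratio, exterior) in config.channels.items():
        lumen = lumen_ratio * exterior
        img = np.where(lumen_mask, lumen, float(exterior))
        img = img + ring_amp * np.exp(-((r - config.radius) ** 2) / (2 * config.ring_sigma**2))
        if config.psf_sigma > 0:
            img = ndimage.gaussian_filter(img, config.psf_sigma)
        img = img + config.camera_offset
        if config.noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
            if config.read_noise > 0:
                img = img + config.read_noise * rng.standard_normal((n, n))
        images[name] = img
        truth["ratios"][name] = (lumen / exterior) if exterior > 0 else np.nan
    return images, truth
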