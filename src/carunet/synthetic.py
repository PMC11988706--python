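"""Deterministic lung-like phantom generator.

Real chest radiographs show two bright, vertically elongated lung fields on
a darker mediastinum/background.  The phantoms emulate exactly that bimodal
structure — two filled, slightly inward-rotated ellipses with jittered
centres, sizes and axis ratios, optional low-amplitude sinusoidal "rib"
bands, and additive Gaussian noise — so every downstream stage (pipeline,
model, trainer, metrics) is testable without downloading any dataset.  No
claim of anatomical realism is made: there are no opacities, devices,
clavicles or cardiac silhouettes.

Determinism contract: each phantom is a pure function of ``(seed, index)``
via a counter-based random stream, so datasets are order-independent and
reproducible bit for bit.

The requested lung-area fraction is hit to well under one pixel row: each
ellipse is rasterized by ranking pixels on the ellipse quadratic form and
keeping exactly the target pixel count, which keeps the region an ellipse
level set while making the area error O(ties) pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import ImagePair, write_pairs
from .errors import ConfigurationError

__all__ = ["PhantomConfig", "generate_phantom", "generate_dataset", "write_dataset"]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the phantom family.

    ``lung_area_range`` is the closed interval from which the total lung
    fraction of the image area is drawn; ``background_level`` and
    ``lung_level`` are the two mean intensities (on [0, 1]); ``noise_sigma``
    is the standard deviation of the additive Gaussian noise.
    """

    image_size: int = 256
    lung_area_range: tuple[float, float] = (0.15, 0.35)
    noise_sigma: float = 0.05
    background_level: float = 0.20
    lung_level: float = 0.65
    rib_stripes: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ConfigurationError(f"image_size: must be >= 32, got {self.image_size}")
        lo, hi = self.lung_area_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigurationError(
                f"lung_area_range: need 0 <= lo <= hi <= 1, got ({lo}, {hi})")
        if self.noise_sigma < 0:
            raise ConfigurationError(f"noise_sigma: must be >= 0, got {self.noise_sigma}")
        for name in ("background_level", "lung_level"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name}: must be in [0, 1], got {v}")
        if self.seed < 0:
            raise ConfigurationError(f"seed: must be non-negative, got {self.seed}")


def _ellipse_mask(size: int, centre_rc: tuple[float, float], a: float, b: float,
                  phi: float, n_pixels: int) -> np.ndarray:
    """Filled ellipse with semi-axes ``a`` (vertical) and ``b`` (horizontal),
    rotated by ``phi`` radians, containing exactly the ``n_pixels`` pixels
    that rank lowest on the quadratic form (plus boundary ties)."""
    rows = np.arange(size)[:, None] - centre_rc[0]
    cols = np.arange(size)[None, :] - centre_rc[1]
    u = cols * np.cos(phi) + rows * np.sin(phi)       # along horizontal axis b
    v = -cols * np.sin(phi) + rows * np.cos(phi)      # along vertical axis a
    q = (u / b) ** 2 + (v / a) ** 2
    if n_pixels <= 0:
        return np.zeros((size, size), dtype=bool)
    thresh = np.partition(q.ravel(), n_pixels - 1)[n_pixels - 1]
    return q <= thresh


def generate_phantom(config: PhantomConfig, index: int) -> ImagePair:
    """Generate phantom ``index`` of the stream defined by ``config.seed``."""
    if not isinstance(config, PhantomConfig):
        config = PhantomConfig(**config)
    if index < 0:
        raise ConfigurationError(f"index: must be >= 0, got {index}")
    rng = np.random.default_rng([config.seed, index])
    s = config.image_size
    lo, hi = config.lung_area_range
    fraction = rng.uniform(lo, hi)
    left_share = rng.uniform(0.46, 0.54)

    mask = np.zeros((s, s), dtype=np.uint8)
    for side, share in (("left", left_share), ("right", 1.0 - left_share)):
        target = int(round(fraction * share * s * s))
        ratio = rng.uniform(1.9, 2.5)                 # vertical elongation a/b
        b = np.sqrt(max(target, 1) / (np.pi * ratio))
        a = ratio * b
        # slight inward rotation: lung tops lean toward the midline
        phi = rng.uniform(0.04, 0.12) * (1 if side == "left" else -1)
        ext_c = np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
        ext_r = np.sqrt((b * np.sin(phi)) ** 2 + (a * np.cos(phi)) ** 2)
        row = np.clip(s * rng.uniform(0.49, 0.55), ext_r + 1, s - 2 - ext_r)
        mid = (s - 1) / 2
        if side == "left":
            col = np.clip(s * rng.uniform(0.26, 0.30), ext_c + 1, mid - 1.5 - ext_c)
        else:
            col = np.clip(s * rng.uniform(0.70, 0.74), mid + 1.5 + ext_c, s - 2 - ext_c)
        mask |= _ellipse_mask(s, (row, col), a, b, phi, target).astype(np.uint8)

    image = np.where(mask == 1,
                     np.float32(config.lung_level),
                     np.float32(config.background_level))
    if config.rib_stripes:
        period = s / rng.uniform(7.0, 10.0)
        phase = rng.uniform(0, 2 * np.pi)
        bands = 0.03 * np.sin(2 * np.pi * np.arange(s) / period + phase)
        image = image + bands[:, None].astype(np.float32)
    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, (s, s)).astype(np.float32)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return ImagePair(image=image, mask=mask, id=f"phantom_{index:05d}")


def generate_dataset(n: int, config: PhantomConfig) -> list[ImagePair]:
    """Generate phantoms 0..n-1; element ``i`` equals
    ``generate_phantom(config, i)``."""
    if n < 0:
        raise ConfigurationError(f"n: must be >= 0, got {n}")
    return [generate_phantom(config, i) for i in range(n)]


def write_dataset(n: int, config: PhantomConfig, out_dir,
                  manifest: dict[str, str] | None = None) -> list[ImagePair]:
    """Generate and write ``n`` phantom pairs as PNG files; optionally write
    a ``manifest.csv`` with a split column."""
    pairs = generate_dataset(n, config)
    write_pairs(pairs, out_dir)
    if manifest is not None:
        from .data import write_manifest
        write_manifest(manifest, Path(out_dir) / "manifest.csv")
    return pairs
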