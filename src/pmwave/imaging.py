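"""Image I/O, synthetic phantoms and quality metrics.

The phantom generator provides seeded stand-ins for the kinds of images the
denoiser targets: sharp-contoured shapes (brain-like, probing Gibbs/edge
behaviour), fine parallel low-contrast ridges (tissue-microgroove-like,
probing block-seam behaviour), a step edge and a smooth sine field.  Clean
intensities are kept inside [0.15, 0.85] so additive Gaussian noise at the
default level is essentially never clipped.

Images are read from 8- or 16-bit grayscale PNG/TIFF/PGM and rescaled to
[0, 1]; writing rescales back to the requested bit depth with half-to-even
rounding, so read-write-read is idempotent at the stored depth.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "read_image",
    "write_image",
    "psnr",
]

SCENES = ("disks", "step_edge", "microgrooves", "sine")


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Synthetic test image: scene geometry plus seeded Gaussian noise."""

    size: tuple = (128, 128)
    scene: str = "disks"
    contrast: float = 0.5
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.scene not in SCENES:
            raise ValueError(f"scene must be one of {SCENES}")
        if not (0 < self.contrast <= 1):
            raise ValueError("contrast must be in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if min(self.size) < 8:
            raise ValueError("phantom must be at least 8x8")


def _clean_scene(spec: PhantomSpec) -> np.ndarray:
    rows, cols = spec.size
    y, x = np.meshgrid(np.linspace(0, 1, rows), np.linspace(0, 1, cols),
                       indexing="ij")
    lo = 0.5 - 0.35 * spec.contrast
    hi = 0.5 + 0.35 * spec.contrast
    if spec.scene == "disks":
        img = np.full(spec.size, lo)
        for (cy, cx, r, val) in [(0.40, 0.42, 0.30, hi),
                                 (0.68, 0.70, 0.14, 0.5),
                                 (0.28, 0.72, 0.10, lo + 0.25 * (hi - lo))]:
            img[(y - cy) ** 2 + (x - cx) ** 2 <= r * r] = val
        return img
    if spec.scene == "step_edge":
        return np.where(x < 0.5, lo, hi)
    if spec.scene == "microgrooves":
        # fine parallel ridges: duty-cycled stripes of low contrast
        period_px = 8
        phase = (np.arange(cols) // (period_px // 2)) % 2
        return lo + (hi - lo) * np.broadcast_to(phase, spec.size).astype(float)
    return 0.5 + 0.35 * spec.contrast * np.sin(2 * np.pi * x) * np.sin(2 * np.pi * y)


def generate_phantom(spec: PhantomSpec):
    """(clean, noisy) pair; noisy = clip(clean + N(0, sigma^2), 0, 1), seeded."""
    clean = _clean_scene(spec)
    rng = np.random.default_rng(spec.seed)
    noisy = clean + spec.noise_sigma * rng.standard_normal(spec.size)
    return clean, np.clip(noisy, 0.0, 1.0)


def read_image(path) -> np.ndarray:
    """Grayscale 8/16-bit PNG/TIFF/PGM to float values in [0, 1]."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError(f"multi-channel image ({arr.shape[2]} channels); "
                             "grayscale input required")
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    else:
        raise ValueError(f"unsupported pixel type {arr.dtype}; 8/16-bit required")
    return arr.astype(float) / scale


def write_image(values, path, bit_depth: int = 8) -> None:
    """Write [0, 1] values at the requested bit depth (rounding half-to-even)."""
    if bit_depth == 8:
        dtype, scale = np.uint8, 255.0
    elif bit_depth == 16:
        dtype, scale = np.uint16, 65535.0
    else:
        raise ValueError("bit_depth must be 8 or 16")
    v = np.asarray(getattr(values, "values", values), dtype=float)
    arr = np.rint(np.clip(v, 0.0, 1.0) * scale).astype(dtype)
    iio.imwrite(Path(path), arr)


def psnr(reference, test) -> float:
    """Peak signal-to-noise ratio in dB on the [0, 1] intensity scale."""
    ref = np.asarray(getattr(reference, "values", reference), dtype=float)
    tst = np.asarray(getattr(test, "values", test), dtype=float)
    if ref.shape != tst.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((ref - tst) ** 2))
    if mse == 0.0:
        return float("inf")
    return -10.0 * np.log10(mse)
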