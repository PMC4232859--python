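"""Phase-scrambled control stimuli.

Scrambled controls are produced by replacing the Fourier phases of a greyscale
image with the phases of a white-noise image of the same size, which preserves
the 2D amplitude spectrum while destroying all spatial structure.  A shared
affine intensity normalization — parameterized by the scrambled image's
intensity range and applied identically to both members of a pair — then
matches the mean and standard deviation of each image to its control.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["GreyImage", "phase_scramble", "normalize_pair", "load_image", "save_image", "spectrum_mismatch"]


@dataclass
class GreyImage:
    """Greyscale image with real-valued intensities (nominally in [0, 1])."""

    pixels: np.ndarray  # (height, width)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("image must be a non-empty 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite intensities")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _self_conjugate_mask(shape: tuple[int, int]) -> np.ndarray:
    """Bins that are their own Fourier conjugate (DC and Nyquist combinations).

    At these bins the spectrum of a real image is real, so their phases must be
    kept at 0 or pi for the output to remain real; we keep the input's phases
    there, which also preserves the mean intensity (DC bin).
    """
    h, w = shape
    rows = [0] + ([h // 2] if h % 2 == 0 else [])
    cols = [0] + ([w // 2] if w % 2 == 0 else [])
    mask = np.zeros(shape, dtype=bool)
    for r in rows:
        for c in cols:
            mask[r, c] = True
    return mask


def phase_scramble(image: GreyImage, seed: int) -> GreyImage:
    """Replace the Fourier phases of ``image`` with white-noise phases.

    The replacement phases are taken from the 2D FFT of a seeded uniform
    white-noise image of equal size; because that image is real, its phase
    field is Hermitian-symmetric and the inverse transform is real to within
    rounding.  Self-conjugate bins (DC, Nyquist) keep the original phases so
    the result is exactly real-compatible and mean-preserving.

    The output is NOT range-normalized; see :func:`normalize_pair`.
    """
    if not isinstance(image, GreyImage):
        image = GreyImage(np.asarray(image))
    rng = np.random.default_rng(seed)
    noise = rng.uniform(0.0, 1.0, size=image.pixels.shape)
    spectrum = np.fft.fft2(image.pixels)
    noise_phase = np.angle(np.fft.fft2(noise))
    phase = noise_phase.copy()
    keep = _self_conjugate_mask(image.pixels.shape)
    phase[keep] = np.angle(spectrum[keep])
    scrambled = np.fft.ifft2(np.abs(spectrum) * np.exp(1j * phase))
    return GreyImage(scrambled.real)


def normalize_pair(
    original: GreyImage,
    scrambled: GreyImage,
    mode: str = "as_printed",
) -> tuple[GreyImage, GreyImage]:
    """Apply one shared affine intensity map to an original/scrambled pair.

    The map parameters are the minimum and maximum intensity of the
    *scrambled* image, so the two images stay matched in mean and standard
    deviation after mapping.  Two forms are available:

    ``as_printed``
        p -> (p - min) / (min + max), the published normalization.
    ``minmax``
        p -> (p - min) / (max - min), the conventional range normalization.
    """
    if mode not in ("as_printed", "minmax"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    lo = float(scrambled.pixels.min())
    hi = float(scrambled.pixels.max())
    denom = lo + hi if mode == "as_printed" else hi - lo
    if denom == 0.0:
        raise ZeroDivisionError(
            f"normalization denominator is zero (min={lo}, max={hi}, mode={mode})"
        )
    out_orig = GreyImage((original.pixels - lo) / denom)
    out_scr = GreyImage((scrambled.pixels - lo) / denom)
    return out_orig, out_scr


def spectrum_mismatch(a: GreyImage, b: GreyImage) -> float:
    """Max relative deviation between the amplitude spectra of two images."""
    fa = np.abs(np.fft.fft2(a.pixels))
    fb = np.abs(np.fft.fft2(b.pixels))
    scale = np.abs(fa).max()
    if scale == 0.0:
        return 0.0
    return float(np.abs(fa - fb).max() / scale)


def load_image(path: str | Path) -> GreyImage:
    """Read a PNG/TIFF image as 8-bit greyscale scaled to [0, 1]."""
    from PIL import Image

    with Image.open(path) as im:
        grey = im.convert("L")
        arr = np.asarray(grey, dtype=float) / 255.0
    return GreyImage(arr)


def save_image(image: GreyImage, path: str | Path) -> None:
    """Write an image as 8-bit greyscale PNG/TIFF, clipping to [0, 1]."""
    from PIL import Image

    arr = np.clip(image.pixels, 0.0, 1.0)
    Image.fromarray(np.round(arr * 255.0).astype(np.uint8), mode="L").save(path)
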