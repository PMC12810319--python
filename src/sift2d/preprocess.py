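"""Map square class-average images onto the fixed 210x210 model canvas.

Large images are Fourier-cropped (only the central low-frequency block of
the centered 2D spectrum is kept), small images are zero-padded in real
space after standardization, so native features reach the scorer at their
native scale.  The minimum accepted input side is 31 pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CANVAS_SIDE", "MIN_INPUT_SIDE", "CanvasImage", "fourier_crop", "standardize", "resample_to_canvas"]

#: Fixed side of the model input canvas, in pixels.
CANVAS_SIDE = 210
#: Smallest accepted input side, in pixels.
MIN_INPUT_SIDE = 31


@dataclass(frozen=True)
class CanvasImage:
    """A 210x210 standardized image plus provenance of how it got there."""

    pixels: np.ndarray
    origin_side: int
    method: str  # identity | fourier_downsample | zero_pad

    def __post_init__(self) -> None:
        if self.pixels.shape != (CANVAS_SIDE, CANVAS_SIDE):
            raise ValueError(f"canvas must be {CANVAS_SIDE}x{CANVAS_SIDE}; got {self.pixels.shape}")


def _check_input(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError(f"image must be square 2D; got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains NaN or Inf pixels")
    return image


def standardize(image: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-SD standardization; constant images become all zeros."""
    image = np.asarray(image, dtype=np.float64)
    centered = image - image.mean()
    sd = image.std()
    if sd == 0:
        return centered
    return centered / sd


def fourier_crop(image: np.ndarray, out_side: int) -> np.ndarray:
    """Down-sample by keeping the central ``out_side`` x ``out_side`` block
    of the centered 2D spectrum.

    The result is rescaled so its real-space mean equals the input mean
    (the DC coefficient is untouched by the crop, so this is exact up to
    floating point).  The imaginary residue of the inverse transform must be
    negligible and is discarded.
    """
    image = _check_input(image)
    s = image.shape[0]
    if out_side > s:
        raise ValueError(f"fourier_crop cannot enlarge: {s} -> {out_side}")
    if out_side == s:
        return image.copy()
    spectrum = np.fft.fftshift(np.fft.fft2(image))
    c = s // 2
    half = out_side // 2
    lo, hi = c - half, c - half + out_side
    cropped = np.fft.ifftshift(spectrum[lo:hi, lo:hi])
    # The crop severs the conjugate partner of the band-edge (Nyquist) rows,
    # so enforce Hermitian symmetry: intact pairs are unchanged, only the
    # edge rows/columns are averaged with their mod-n mirror.  DC (and hence
    # the mean) is untouched.
    neg = (-np.arange(out_side)) % out_side
    cropped = 0.5 * (cropped + np.conj(cropped[np.ix_(neg, neg)]))
    out = np.fft.ifft2(cropped) * (out_side**2 / s**2)
    scale = np.abs(out.real).max()
    if scale > 0 and np.abs(out.imag).max() > 1e-6 * scale:
        raise AssertionError("imaginary residue of Fourier crop exceeds tolerance")
    return np.ascontiguousarray(out.real)


def _zero_pad(image: np.ndarray, out_side: int) -> np.ndarray:
    s = image.shape[0]
    pad = out_side - s
    top = pad // 2
    left = pad // 2
    out = np.zeros((out_side, out_side), dtype=np.float64)
    out[top : top + s, left : left + s] = image
    return out


def resample_to_canvas(image: np.ndarray) -> CanvasImage:
    """Map a square image of side >= 31 onto the 210x210 canvas.

    Sides above 210 are Fourier-cropped then standardized; sides below 210
    are standardized then centered in a zero field (odd remainders pad the
    extra row/column at bottom/right); side 210 is standardized in place.
    """
    image = _check_input(image)
    s = image.shape[0]
    if s < MIN_INPUT_SIDE:
        raise ValueError(f"side {s} is below minimum input size {MIN_INPUT_SIDE}x{MIN_INPUT_SIDE}")
    if s > CANVAS_SIDE:
        pixels = standardize(fourier_crop(image, CANVAS_SIDE))
        method = "fourier_downsample"
    elif s < CANVAS_SIDE:
        pixels = _zero_pad(standardize(image), CANVAS_SIDE)
        method = "zero_pad"
    else:
        pixels = standardize(image)
        method = "identity"
    return CanvasImage(pixels=pixels, origin_side=s, method=method)
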