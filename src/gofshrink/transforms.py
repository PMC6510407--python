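"""Forward/inverse DWT and cycle spinning.

The decimated 2-D DWT is delegated to PyWavelets with circular
("periodization") boundary handling, which keeps the transform exactly
orthonormal for orthogonal filter families: unit-variance white noise maps
to unit-variance detail coefficients at every scale and the Parseval
identity holds to rounding error.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt

from .pyramid import DWT_LABELS, WaveletPyramid

__all__ = ["decompose_dwt", "reconstruct_dwt", "cycle_spin", "default_shift_set"]

_MODE = "periodization"


def _check_image(image: np.ndarray, levels: int) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if min(image.shape) < 2**levels:
        raise ValueError(
            f"image of shape {image.shape} is too small for a "
            f"{levels}-level decomposition (needs >= {2**levels} per side)"
        )
    return image


def decompose_dwt(image: np.ndarray, wavelet: str = "db8", levels: int = 5) -> WaveletPyramid:
    """Decompose an image into a J-level DWT pyramid.

    Parameters
    ----------
    image : 2-D array
        Grayscale pixel grid; both sides must be at least ``2**levels``.
    wavelet : str
        PyWavelets filter name (orthogonal families expected).
    levels : int
        Decomposition depth J.
    """
    image = _check_image(image, levels)
    try:
        wav = pywt.Wavelet(wavelet)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet {wavelet!r}") from exc
    with warnings.catch_warnings():
        # pywt warns when the coarsest band is shorter than the filter; with
        # circular extension the transform stays orthonormal and invertible,
        # and J=5 on a 256-512 pixel image is the standard operating point.
        warnings.filterwarnings("ignore", message="Level value of .* is too high")
        coeffs = pywt.wavedec2(image, wav, mode=_MODE, level=levels)
    approx = {"ll": np.asarray(coeffs[0], dtype=float)}
    details = []
    # wavedec2 returns coarsest-first; pyramid stores finest-first.
    for ch, cv, cd in reversed(coeffs[1:]):
        details.append(
            {
                "horizontal": np.asarray(ch, dtype=float),
                "vertical": np.asarray(cv, dtype=float),
                "diagonal": np.asarray(cd, dtype=float),
            }
        )
    return WaveletPyramid(
        transform="dwt",
        wavelet=wavelet,
        levels=levels,
        details=details,
        approx=approx,
        shape=image.shape,
    )


def reconstruct_dwt(pyramid: WaveletPyramid) -> np.ndarray:
    """Inverse DWT of a pyramid back to the spatial domain."""
    if pyramid.transform != "dwt":
        raise ValueError(f"expected a dwt pyramid, got {pyramid.transform!r}")
    coeffs = [pyramid.approx["ll"]]
    for lv in reversed(pyramid.details):
        missing = [k for k in DWT_LABELS if k not in lv]
        if missing:
            raise ValueError(f"pyramid level missing bands {missing}")
        coeffs.append((lv["horizontal"], lv["vertical"], lv["diagonal"]))
    out = pywt.waverec2(coeffs, pywt.Wavelet(pyramid.wavelet), mode=_MODE)
    return out[: pyramid.shape[0], : pyramid.shape[1]]


def default_shift_set(grid: int = 4) -> list[tuple[int, int]]:
    """The ``grid x grid`` cycle-spinning shift lattice, containing (0, 0)."""
    if grid < 1:
        raise ValueError("shift grid must be >= 1")
    return [(r, c) for r in range(grid) for c in range(grid)]


def cycle_spin(denoiser, image: np.ndarray, shifts) -> np.ndarray:
    """Average the denoiser over circularly shifted copies of the image.

    For each shift ``(dr, dc)`` the image is rolled, denoised, un-rolled, and
    the results are averaged.  This approximates a translation-invariant
    (undecimated) version of a shift-variant denoiser.
    """
    shifts = list(shifts)
    if not shifts:
        raise ValueError("shift set must be non-empty")
    image = np.asarray(image, dtype=float)
    results = []
    for dr, dc in shifts:
        shifted = np.roll(image, (dr, dc), axis=(0, 1))
        den = np.asarray(denoiser(shifted), dtype=float)
        if den.shape != image.shape:
            raise ValueError("denoiser changed the image dimensions")
        results.append(np.roll(den, (-dr, -dc), axis=(0, 1)))
    # pairwise summation keeps the identity denoiser bit-exact for 2^k
    # equal shifts (x+x doubles exactly; sequential accumulation would not)
    while len(results) > 1:
        merged = [a + b for a, b in zip(results[::2], results[1::2])]
        if len(results) % 2:
            merged[-1] = merged[-1] + results[-1]
        results = merged
    return results[0] / len(shifts)
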