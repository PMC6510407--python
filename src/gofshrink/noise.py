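"""Noise level estimation, pyramid normalization and the reference CDF.

The noise standard deviation is estimated with the robust median absolute
deviation (MAD) rule on the finest-scale diagonal DWT band,

    sigma_hat = median(|d1|) / 0.6745,

where 0.6745 is the third quartile of the standard normal distribution, so
that the estimator is unbiased for pure Gaussian noise.  Detail bands are
then divided by ``sigma_hat * band_gain`` so that, under the noise-only
hypothesis, every band holds unit-variance Gaussian samples and the
goodness-of-fit test can use the standard normal CDF as its fixed reference.

For the orthonormal DWT every ``band_gain`` is exactly 1.  The DT-CWT is
redundant and its oriented real/imaginary parts do not carry unit noise
variance, so their gains are measured once per filter design by decomposing
white noise and caching the per-scale, per-band sample standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pywt
from scipy.special import ndtr

from .dualtree import decompose_dtcwt
from .pyramid import WaveletPyramid

__all__ = [
    "NoiseEstimate",
    "ReferenceCdf",
    "estimate_sigma",
    "estimate_sigma_from_image",
    "normalize_pyramid",
    "denormalize_pyramid",
    "standard_reference_cdf",
    "dtcwt_band_gains",
    "unit_gains",
]

MAD_SCALE = 0.6745  # Phi^-1(0.75): median(|N(0, s^2)|) = MAD_SCALE * s


@dataclass(frozen=True)
class NoiseEstimate:
    sigma: float
    source_band: str = "dwt_level1_diagonal"


@dataclass(frozen=True)
class ReferenceCdf:
    """Reference noise CDF for the GoF test (standard normal by default)."""

    mean: float
    sigma: float
    evaluator: Callable[[np.ndarray], np.ndarray]

    def __call__(self, t):
        return self.evaluator(t)


def standard_reference_cdf() -> ReferenceCdf:
    """Standard normal CDF Phi; the GoF test always runs on normalized
    coefficients, so mean 0 / sigma 1 is the only reference needed."""
    return ReferenceCdf(mean=0.0, sigma=1.0, evaluator=ndtr)


def estimate_sigma(diagonal_band: np.ndarray) -> NoiseEstimate:
    """MAD estimate of sigma from the finest-scale diagonal band."""
    band = np.asarray(diagonal_band, dtype=float)
    if band.size == 0:
        raise ValueError("empty coefficient band")
    return NoiseEstimate(sigma=float(np.median(np.abs(band)) / MAD_SCALE))


def estimate_sigma_from_image(image: np.ndarray, wavelet: str = "db8") -> NoiseEstimate:
    """Estimate sigma from a 1-level DWT of the image (diagonal band only).

    The same estimate is used by both the DWT and DT-CWT pipelines.
    """
    _, (_, _, diag) = pywt.dwt2(np.asarray(image, dtype=float), wavelet, mode="periodization")
    return estimate_sigma(diag)


def _gain(band_gains, scale: int, label: str) -> float:
    if band_gains is None:
        return 1.0
    g = band_gains[scale - 1][label]
    if not g > 0:
        raise ValueError(f"non-positive band gain for scale {scale} {label!r}")
    return g


def normalize_pyramid(
    pyramid: WaveletPyramid, estimate: NoiseEstimate, band_gains=None
) -> WaveletPyramid:
    """Divide every detail band by ``sigma * band_gain``; approximation bands
    are left untouched.  ``band_gains`` follows the pyramid layout
    (``band_gains[j-1][label]``); ``None`` means all gains are 1 (DWT)."""
    if not estimate.sigma > 0:
        raise ValueError(
            "sigma must be positive for normalization; sigma == 0 means a "
            "noise-free input and pipelines short-circuit instead"
        )
    s = estimate.sigma
    return pyramid.map_details(lambda b, j, lab: b / (s * _gain(band_gains, j, lab)))


def denormalize_pyramid(
    pyramid: WaveletPyramid, estimate: NoiseEstimate, band_gains=None
) -> WaveletPyramid:
    """Exact inverse of :func:`normalize_pyramid`."""
    if not estimate.sigma > 0:
        raise ValueError("sigma must be positive")
    s = estimate.sigma
    return pyramid.map_details(lambda b, j, lab: b * (s * _gain(band_gains, j, lab)))


_GAIN_CACHE: dict[tuple, list[dict[str, float]]] = {}


def dtcwt_band_gains(
    levels: int,
    vanishing_moments: int = 4,
    delay_order: int = 3,
    first_stage: str = "db10",
    field_size: int = 512,
    realizations: int = 4,
    seed: int = 20051,
) -> list[dict[str, float]]:
    """Per-scale, per-band noise gains of the DT-CWT.

    Decomposes ``realizations`` unit-variance white noise fields and returns
    the pooled sample standard deviation of every oriented real/imaginary
    band, indexed like pyramid details.  Results are cached per design.
    """
    key = (levels, vanishing_moments, delay_order, first_stage, field_size, realizations, seed)
    if key in _GAIN_CACHE:
        return _GAIN_CACHE[key]
    rng = np.random.default_rng(seed)
    sumsq: list[dict[str, float]] | None = None
    counts: list[dict[str, int]] | None = None
    for _ in range(realizations):
        noise = rng.standard_normal((field_size, field_size))
        pyr = decompose_dtcwt(noise, levels, vanishing_moments, delay_order, first_stage)
        if sumsq is None:
            sumsq = [{lab: 0.0 for lab in lv} for lv in pyr.details]
            counts = [{lab: 0 for lab in lv} for lv in pyr.details]
        for j, lv in enumerate(pyr.details):
            for lab, band in lv.items():
                sumsq[j][lab] += float(np.sum(band * band))
                counts[j][lab] += band.size
    gains = [
        {lab: float(np.sqrt(sumsq[j][lab] / counts[j][lab])) for lab in sumsq[j]}
        for j in range(levels)
    ]
    _GAIN_CACHE[key] = gains
    return gains


def unit_gains(pyramid: WaveletPyramid) -> list[dict[str, float]]:
    """All-ones gain table matching a pyramid's layout (orthonormal DWT)."""
    return [{lab: 1.0 for lab in lv} for lv in pyramid.details]
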