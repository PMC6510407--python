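"""Image quality metrics: MSE, PSNR (255 peak) and SSIM.

Metrics are computed on unclipped floating-point estimates against the
clean reference; clipping to [0, 255] happens only when images are written
to disk.
"""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["mse", "psnr", "ssim", "metric_report"]

PEAK = 255.0


def _pair(reference, estimate):
    a = np.asarray(reference, dtype=float)
    b = np.asarray(estimate, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mse(reference, estimate) -> float:
    """Mean squared error, in intensity^2 units."""
    a, b = _pair(reference, estimate)
    return float(np.mean((a - b) ** 2))


def psnr(reference, estimate) -> float:
    """Peak signal-to-noise ratio 10*log10(255^2 / MSE) in dB (inf for
    identical images)."""
    err = mse(reference, estimate)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(PEAK**2 / err))


def ssim(reference, estimate) -> float:
    """Structural similarity, delegated to scikit-image (reporting aid)."""
    a, b = _pair(reference, estimate)
    return float(structural_similarity(a, b, data_range=PEAK))


def metric_report(reference, estimate, with_ssim: bool = False) -> dict:
    report = {"mse": mse(reference, estimate), "psnr": psnr(reference, estimate)}
    if with_ssim:
        report["ssim"] = ssim(reference, estimate)
    return report
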