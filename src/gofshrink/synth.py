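"""Synthetic test imagery and Gaussian noise injection.

Phantom generators provide clean reference images with known structure so
the whole pipeline is exercisable without any external dataset.  Every kind
mixes smooth regions with oriented edges, so the directional selectivity of
the dual-tree transform is actually engaged.  Generation is deterministic
given (kind, size, seed).
"""

from __future__ import annotations

import numpy as np

__all__ = ["add_gaussian_noise", "make_phantom", "PHANTOM_KINDS"]

PHANTOM_KINDS = (
    "piecewise_constant_shapes",
    "smooth_gradient",
    "mri_like_ellipses",
    "multifocus_texture",
)


def add_gaussian_noise(image, sigma: float, seed: int | None = None):
    """image + i.i.d. N(0, sigma^2); unclipped, reproducible via seed."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    image = np.asarray(image, dtype=float)
    if sigma == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    return image + rng.normal(0.0, sigma, size=image.shape)


def _grid(size):
    y, x = np.mgrid[0:size, 0:size]
    return y.astype(float), x.astype(float)


def _rotated(y, x, cy, cx, angle):
    dy, dx = y - cy, x - cx
    c, s = np.cos(angle), np.sin(angle)
    return c * dy - s * dx, s * dy + c * dx


def _piecewise_constant(size, rng):
    img = np.full((size, size), 40.0)
    y, x = _grid(size)
    # axis-aligned rectangle
    r0, c0 = (rng.uniform(0.08, 0.15, 2) * size).astype(int)
    img[r0 : r0 + int(0.35 * size), c0 : c0 + int(0.25 * size)] = 200.0
    # rotated square (oriented edges)
    ry, rx = _rotated(y, x, 0.62 * size, 0.32 * size, np.pi / 4 + rng.uniform(-0.1, 0.1))
    img[(np.abs(ry) < 0.13 * size) & (np.abs(rx) < 0.13 * size)] = 120.0
    # disc
    cy, cx = 0.32 * size, 0.72 * size
    img[(y - cy) ** 2 + (x - cx) ** 2 < (0.14 * size) ** 2] = 230.0
    # oblique stripe
    sy, sx = _rotated(y, x, 0.75 * size, 0.75 * size, rng.uniform(0.4, 0.9))
    img[np.abs(sy) < 0.05 * size] = 90.0
    return img


def _smooth_gradient(size, rng):
    y, x = _grid(size)
    ang = rng.uniform(0, np.pi)
    lin = (np.cos(ang) * y + np.sin(ang) * x) / size
    cy, cx = rng.uniform(0.3, 0.7, 2) * size
    rad = np.hypot(y - cy, x - cx) / size
    img = 120.0 + 90.0 * lin - 60.0 * np.exp(-8.0 * rad**2)
    # one oblique intensity step so even the smooth phantom carries an
    # oriented edge for the directional transform to lock onto
    ry, _ = _rotated(y, x, 0.8 * size, 0.2 * size, ang + 0.6)
    img += 35.0 * (ry > 0)
    return np.clip(img, 0.0, 255.0)


def _mri_ellipses(size, rng):
    img = np.full((size, size), 12.0)
    y, x = _grid(size)
    specs = [
        (0.42, 0.34, 0.15, 150.0),
        (0.34, 0.26, 0.35, 95.0),
        (0.24, 0.17, 0.55, 170.0),
        (0.12, 0.08, 0.85, 220.0),
    ]
    cy, cx = 0.5 * size, 0.5 * size
    base = rng.uniform(-0.2, 0.2)
    for a, b, tilt, val in specs:
        ry, rx = _rotated(y, x, cy, cx, base + tilt)
        img[(ry / (a * size)) ** 2 + (rx / (b * size)) ** 2 < 1.0] = val
    # two small lateral lesions
    for off, val in ((-0.28, 60.0), (0.28, 200.0)):
        ry, rx = _rotated(y, x, cy + off * size, cx + off * size / 2, 0.3)
        img[(ry / (0.05 * size)) ** 2 + (rx / (0.03 * size)) ** 2 < 1.0] = val
    return img


def _multifocus_texture(size, rng):
    y, x = _grid(size)
    ang = rng.uniform(0.2, 1.2)
    freq = 2 * np.pi * rng.uniform(6, 10) / size
    texture = 130.0 + 70.0 * np.sin(freq * (np.cos(ang) * y + np.sin(ang) * x))
    smooth = _smooth_gradient(size, rng)
    split = _rotated(y, x, 0.5 * size, 0.5 * size, rng.uniform(0.3, 0.8))[0]
    img = np.where(split > 0, texture, smooth)
    img[np.abs(split) < 1.5] = 255.0  # sharp seam between the two regions
    return np.clip(img, 0.0, 255.0)


_GENERATORS = {
    "piecewise_constant_shapes": _piecewise_constant,
    "smooth_gradient": _smooth_gradient,
    "mri_like_ellipses": _mri_ellipses,
    "multifocus_texture": _multifocus_texture,
}


def make_phantom(kind: str = "piecewise_constant_shapes", size: int = 256, seed: int = 0):
    """Deterministic synthetic grayscale test image with values in [0, 255]."""
    if kind not in _GENERATORS:
        raise ValueError(f"unknown phantom kind {kind!r}; choose from {PHANTOM_KINDS}")
    if size < 64:
        raise ValueError("size must be >= 64")
    rng = np.random.default_rng(seed)
    return _GENERATORS[kind](size, rng)
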