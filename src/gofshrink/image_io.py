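"""Reading and writing 8-bit grayscale images (PNG/TIFF/PGM)."""

from __future__ import annotations

import logging

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image"]

log = logging.getLogger(__name__)


def read_image(path) -> np.ndarray:
    """Read a grayscale image as a float array in [0, 255].

    16-bit inputs are rescaled to the 8-bit range (with a logged warning);
    color inputs are rejected unless all channels are identical.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4) and np.all(arr[..., :3] == arr[..., :1]):
            arr = arr[..., 0]
        else:
            raise ValueError(f"{path}: expected a grayscale image, got shape {arr.shape}")
    arr = arr.astype(float)
    if arr.max() > 255.0:
        log.warning("%s: rescaling 16-bit data to the 8-bit range", path)
        arr *= 255.0 / 65535.0
    return arr


def write_image(path, image: np.ndarray) -> None:
    """Clip to [0, 255], round to uint8 and write."""
    out = np.clip(np.asarray(image, dtype=float), 0.0, 255.0)
    iio.imwrite(path, np.rint(out).astype(np.uint8))
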