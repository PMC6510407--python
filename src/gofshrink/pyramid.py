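"""Uniform multiscale container for DWT and DT-CWT coefficients.

A :class:`WaveletPyramid` stores, for each decomposition level ``j`` (1 =
finest), a dict of orientation-labelled real 2-D detail bands plus the
coarsest approximation band(s).  For the DWT the labels are ``horizontal``,
``vertical`` and ``diagonal`` and there is a single approximation band
``ll``.  For the DT-CWT there are six oriented complex bands per scale whose
real and imaginary parts are exposed as twelve separate real grids labelled
``d15_real`` ... ``d165_imag``, and the approximation consists of the four
tree lowpass residues ``aa``/``ab``/``ba``/``bb``.

Bands are stored per orientation, never flattened into a single mosaic, so
windowed statistics can never straddle band boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DWT_LABELS = ("horizontal", "vertical", "diagonal")
DTCWT_ANGLES = (15, 45, 75, 105, 135, 165)
DTCWT_LABELS = tuple(
    f"d{a}_{part}" for a in DTCWT_ANGLES for part in ("real", "imag")
)


@dataclass
class WaveletPyramid:
    """Per-scale, per-orientation detail coefficients plus approximation.

    Attributes
    ----------
    transform : {"dwt", "dtcwt"}
    wavelet : str
        Filter identifier (e.g. ``db8``, or the dual-tree design tag).
    levels : int
    details : list of dict
        ``details[j-1][label]`` is the real 2-D band at scale ``j``.
    approx : dict
        Lowpass residue(s) at the coarsest scale.
    shape : tuple of int
        Spatial shape of the image the pyramid was computed from.
    """

    transform: str
    wavelet: str
    levels: int
    details: list[dict[str, np.ndarray]]
    approx: dict[str, np.ndarray]
    shape: tuple[int, int]
    meta: dict = field(default_factory=dict)

    def copy(self) -> "WaveletPyramid":
        return WaveletPyramid(
            transform=self.transform,
            wavelet=self.wavelet,
            levels=self.levels,
            details=[{k: v.copy() for k, v in lv.items()} for lv in self.details],
            approx={k: v.copy() for k, v in self.approx.items()},
            shape=self.shape,
            meta=dict(self.meta),
        )

    def band_labels(self) -> tuple[str, ...]:
        return DWT_LABELS if self.transform == "dwt" else DTCWT_LABELS

    def map_details(self, fn) -> "WaveletPyramid":
        """Return a new pyramid with ``fn(band, scale, label)`` applied to
        every detail band; the approximation is carried over untouched."""
        out = self.copy()
        for j, lv in enumerate(out.details, start=1):
            for label in lv:
                lv[label] = fn(lv[label], j, label)
        return out

    def total_detail_energy(self) -> float:
        return float(sum(np.sum(b * b) for lv in self.details for b in lv.values()))


def save_pyramid(path, pyr: WaveletPyramid) -> None:
    """Serialize to an NPZ container (debugging aid).

    Keys: ``detail/<scale>/<label>`` and ``approx/<label>`` map to arrays;
    scalar metadata is stored under ``_transform``, ``_wavelet``, ``_levels``
    and ``_shape``.
    """
    payload = {
        "_transform": np.array(pyr.transform),
        "_wavelet": np.array(pyr.wavelet),
        "_levels": np.array(pyr.levels),
        "_shape": np.array(pyr.shape),
    }
    for j, lv in enumerate(pyr.details, start=1):
        for label, band in lv.items():
            payload[f"detail/{j}/{label}"] = band
    for label, band in pyr.approx.items():
        payload[f"approx/{label}"] = band
    np.savez(path, **payload)


def load_pyramid(path) -> WaveletPyramid:
    with np.load(path) as npz:
        levels = int(npz["_levels"])
        details: list[dict[str, np.ndarray]] = [{} for _ in range(levels)]
        approx: dict[str, np.ndarray] = {}
        for key in npz.files:
            if key.startswith("detail/"):
                _, j, label = key.split("/")
                details[int(j) - 1][label] = npz[key]
            elif key.startswith("approx/"):
                approx[key.split("/", 1)[1]] = npz[key]
        return WaveletPyramid(
            transform=str(npz["_transform"]),
            wavelet=str(npz["_wavelet"]),
            levels=levels,
            details=details,
            approx=approx,
            shape=tuple(int(v) for v in npz["_shape"]),
        )
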