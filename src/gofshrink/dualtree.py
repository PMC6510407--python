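"""2-D dual-tree complex wavelet transform (DT-CWT).

Two orthonormal wavelet trees are run in parallel; their lowpass filters
differ by half a sample of group delay (one full sample at level 1), so the
tree-B wavelet approximates the Hilbert transform of the tree-A wavelet.
Running all four row/column tree combinations on an image and forming
sum/difference pairs of the four real subbands yields six complex subbands
per scale, oriented near +/-15, +/-45 and +/-75 degrees, that are nearly
shift invariant and directionally selective.  The transform is 4:1
redundant; each constituent tree is a perfectly reconstructing orthonormal
filter bank under circular extension, so the inverse (the average of the
four tree inverses) is exact to rounding error.

Analysis/synthesis is implemented directly as periodized polyphase
filtering, which makes the per-tree operators genuinely orthogonal matrices
and lets tree B at level 1 be realized as odd-phase downsampling (an exact
one-sample offset).
"""

from __future__ import annotations

import numpy as np

from ._filters import dual_tree_filters, first_stage_filter, qmf
from .pyramid import WaveletPyramid
from .transforms import _check_image

__all__ = ["decompose_dtcwt", "reconstruct_dtcwt"]

_SQRT2 = np.sqrt(2.0)

# (subband, orientation-pair) layout: each of the three detail subbands of a
# separable 2-D transform carries two of the six orientations.
_SUBBAND_ANGLES = {"lh": (15, 165), "hh": (45, 135), "hl": (75, 105)}


# ---------------------------------------------------------------------------
# periodized 1-D polyphase filtering along an axis

def _analyze_axis(x, h0, h1, axis, offset=0):
    x = np.moveaxis(x, axis, 0)
    n = x.shape[0]
    half = n // 2
    idx = (2 * np.arange(half)[:, None] + offset + np.arange(h0.size)[None, :]) % n
    gathered = x[idx]
    lo = np.tensordot(h0, gathered, axes=(0, 1))
    hi = np.tensordot(h1, gathered, axes=(0, 1))
    return np.moveaxis(lo, 0, axis), np.moveaxis(hi, 0, axis)


def _synthesize_axis(lo, hi, h0, h1, axis, offset=0):
    lo = np.moveaxis(lo, axis, 0)
    hi = np.moveaxis(hi, axis, 0)
    half = lo.shape[0]
    n = 2 * half
    out = np.zeros((n,) + lo.shape[1:])
    base = 2 * np.arange(half)
    for k in range(h0.size):
        out[(base + offset + k) % n] += h0[k] * lo + h1[k] * hi
    return np.moveaxis(out, 0, axis)


def _level_filters(level, tree, vanishing_moments, delay_order, first_stage):
    """(h0, h1, polyphase offset) for one tree at one level (0-based)."""
    if level == 0:
        h0 = first_stage_filter(first_stage)
        return h0, qmf(h0), (0 if tree == "a" else 1)
    h_a, h_b = dual_tree_filters(vanishing_moments, delay_order)
    h0 = h_a if tree == "a" else h_b
    return h0, qmf(h0), 0


def _forward_tree(image, levels, row_tree, col_tree, design):
    lo = image
    bands = []
    for j in range(levels):
        hr0, hr1, orow = _level_filters(j, row_tree, *design)
        hc0, hc1, ocol = _level_filters(j, col_tree, *design)
        low, high = _analyze_axis(lo, hr0, hr1, 0, orow)
        ll, lh = _analyze_axis(low, hc0, hc1, 1, ocol)
        hl, hh = _analyze_axis(high, hc0, hc1, 1, ocol)
        bands.append({"lh": lh, "hl": hl, "hh": hh})
        lo = ll
    return bands, lo


def _inverse_tree(bands, lo, row_tree, col_tree, design):
    for j in reversed(range(len(bands))):
        hr0, hr1, orow = _level_filters(j, row_tree, *design)
        hc0, hc1, ocol = _level_filters(j, col_tree, *design)
        low = _synthesize_axis(lo, bands[j]["lh"], hc0, hc1, 1, ocol)
        high = _synthesize_axis(bands[j]["hl"], bands[j]["hh"], hc0, hc1, 1, ocol)
        lo = _synthesize_axis(low, high, hr0, hr1, 0, orow)
    return lo


# ---------------------------------------------------------------------------
# public API

def _pad_to_multiple(image, levels):
    m = 2**levels
    pr = (-image.shape[0]) % m
    pc = (-image.shape[1]) % m
    if pr or pc:
        image = np.pad(image, ((0, pr), (0, pc)), mode="symmetric")
    return image


def decompose_dtcwt(
    image: np.ndarray,
    levels: int = 5,
    vanishing_moments: int = 4,
    delay_order: int = 3,
    first_stage: str = "db10",
) -> WaveletPyramid:
    """Decompose an image into a J-level DT-CWT pyramid.

    Each scale holds twelve real grids: the real and imaginary parts of the
    six oriented complex subbands, labelled ``d<angle>_<part>``.  The
    approximation consists of the four tree lowpass residues.
    """
    image = _check_image(image, levels)
    orig_shape = image.shape
    image = _pad_to_multiple(image, levels)
    design = (vanishing_moments, delay_order, first_stage)

    trees = {
        rt + ct: _forward_tree(image, levels, rt, ct, design)
        for rt in "ab"
        for ct in "ab"
    }
    details = []
    for j in range(levels):
        lv = {}
        for sb, (ang1, ang2) in _SUBBAND_ANGLES.items():
            u_aa = trees["aa"][0][j][sb]
            u_ab = trees["ab"][0][j][sb]
            u_ba = trees["ba"][0][j][sb]
            u_bb = trees["bb"][0][j][sb]
            lv[f"d{ang1}_real"] = (u_aa - u_bb) / _SQRT2
            lv[f"d{ang1}_imag"] = (u_ab + u_ba) / _SQRT2
            lv[f"d{ang2}_real"] = (u_aa + u_bb) / _SQRT2
            lv[f"d{ang2}_imag"] = (u_ba - u_ab) / _SQRT2
        details.append(lv)
    approx = {key: trees[key][1] for key in ("aa", "ab", "ba", "bb")}
    return WaveletPyramid(
        transform="dtcwt",
        wavelet=f"cf{vanishing_moments}.{delay_order}+{first_stage}",
        levels=levels,
        details=details,
        approx=approx,
        shape=orig_shape,
        meta={
            "vanishing_moments": vanishing_moments,
            "delay_order": delay_order,
            "first_stage": first_stage,
            "padded_shape": image.shape,
        },
    )


def reconstruct_dtcwt(pyramid: WaveletPyramid) -> np.ndarray:
    """Inverse DT-CWT: unmix the oriented bands into the four trees, invert
    each orthonormal tree exactly, and average."""
    if pyramid.transform != "dtcwt":
        raise ValueError(f"expected a dtcwt pyramid, got {pyramid.transform!r}")
    meta = pyramid.meta
    design = (
        meta.get("vanishing_moments", 4),
        meta.get("delay_order", 3),
        meta.get("first_stage", "db10"),
    )
    tree_bands = {key: [] for key in ("aa", "ab", "ba", "bb")}
    for lv in pyramid.details:
        per_tree = {key: {} for key in tree_bands}
        for sb, (ang1, ang2) in _SUBBAND_ANGLES.items():
            try:
                re1 = lv[f"d{ang1}_real"]
                im1 = lv[f"d{ang1}_imag"]
                re2 = lv[f"d{ang2}_real"]
                im2 = lv[f"d{ang2}_imag"]
            except KeyError as exc:
                raise ValueError(f"pyramid level missing band {exc}") from exc
            per_tree["aa"][sb] = (re1 + re2) / _SQRT2
            per_tree["bb"][sb] = (re2 - re1) / _SQRT2
            per_tree["ab"][sb] = (im1 - im2) / _SQRT2
            per_tree["ba"][sb] = (im1 + im2) / _SQRT2
        for key in tree_bands:
            tree_bands[key].append(per_tree[key])

    recs = [
        _inverse_tree(tree_bands[rt + ct], pyramid.approx[rt + ct], rt, ct, design)
        for rt in "ab"
        for ct in "ab"
    ]
    out = np.mean(recs, axis=0)
    return out[: pyramid.shape[0], : pyramid.shape[1]]
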