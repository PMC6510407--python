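"""Monte-Carlo calibration of the false-alarm / threshold relationship.

The null distribution of the windowed AD statistic has no convenient closed
form at the window sizes used here (L = 25 by default), so the mapping from
a probability of false alarm Pfa to a decision threshold T is estimated
empirically: a large white Gaussian noise field is decomposed with the same
transform, normalization and sliding windows used at denoising time, the
statistic is computed for every window, and Pfa(T) is the fraction of
windows at or above T.  The resulting survival curve is tabulated on a
threshold grid, optionally modelled with a degree-8 polynomial T(Pfa), and
inverted by monotone interpolation at lookup time.

A fixed degree-8 reference polynomial is also shipped as a convenience
default.  Threshold curves depend on the exact statistic variant and window
scheme, so the self-calibrated curve is the primary path and curve files
carry their full scope; lookups refuse a curve whose scope does not match.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dualtree import decompose_dtcwt
from .gof import ad_statistic, ad_statistic_map
from .noise import dtcwt_band_gains, standard_reference_cdf
from .transforms import decompose_dwt

__all__ = [
    "REFERENCE_COEFFS",
    "reference_threshold",
    "ThresholdCurve",
    "estimate_pfa_curve",
    "fit_threshold_polynomial",
    "threshold_for_pfa",
    "get_calibrated_curve",
    "save_curve",
    "load_curve",
]

# Degree-8 reference fit of T(Pfa), highest degree first.  Fitted against a
# legacy variant of the windowed statistic, hence the very different scale
# from the self-calibrated curves; shipped for convenience and comparison.
REFERENCE_COEFFS = np.array(
    [42950.0, -193200.0, 357600.0, -351900.0, 198400.0, -64360.0, 11470.0, -1047.0, 81.76]
)


def reference_threshold(pfa: float) -> float:
    """Evaluate the reference polynomial at a false-alarm probability."""
    if not 0.0 <= pfa <= 1.0:
        raise ValueError("pfa must lie in [0, 1]")
    return float(np.polyval(REFERENCE_COEFFS, pfa))


@dataclass
class ThresholdCurve:
    """Empirical (T, Pfa) tables per scale plus fitted polynomial models.

    ``tables[key] = (thresholds ascending, pfa nonincreasing)`` where ``key``
    is ``"all"`` / ``"scale<j>"`` for the DWT and ``"scale<j>_real"`` /
    ``"scale<j>_imag"`` for the DT-CWT.  ``scope`` records transform,
    wavelet, window side and depth; lookups check it.
    """

    scope: dict
    seed: int
    tables: dict[str, tuple[np.ndarray, np.ndarray]]
    polys: dict[str, np.ndarray] = field(default_factory=dict)
    poly_domains: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_windows: dict[str, int] = field(default_factory=dict)

    def keys(self):
        return list(self.tables)

    def pfa_range(self, key: str) -> tuple[float, float]:
        pfa = self.tables[key][1]
        positive = pfa[pfa > 0]
        lo = float(positive.min()) if positive.size else float(pfa.min())
        return lo, float(pfa.max())


def _dwt_tau_samples(rng, wavelet, levels, window_side, field_size, realizations, tiled):
    ref = standard_reference_cdf()
    per_scale: dict[int, list[np.ndarray]] = {j: [] for j in range(1, levels + 1)}
    for _ in range(realizations):
        noise = rng.standard_normal((field_size, field_size))
        pyr = decompose_dwt(noise, wavelet, levels)
        for j, lv in enumerate(pyr.details, start=1):
            for band in lv.values():
                per_scale[j].append(_band_tau(band, window_side, ref, tiled))
    return {f"scale{j}": np.concatenate([a.ravel() for a in v]) for j, v in per_scale.items()}


def _dtcwt_tau_samples(rng, levels, window_side, field_size, realizations, tiled):
    ref = standard_reference_cdf()
    gains = dtcwt_band_gains(levels)
    acc: dict[str, list[np.ndarray]] = {}
    for _ in range(realizations):
        noise = rng.standard_normal((field_size, field_size))
        pyr = decompose_dtcwt(noise, levels)
        for j, lv in enumerate(pyr.details, start=1):
            for lab, band in lv.items():
                part = lab.rsplit("_", 1)[1]
                key = f"scale{j}_{part}"
                tau = _band_tau(band / gains[j - 1][lab], window_side, ref, tiled)
                acc.setdefault(key, []).append(tau)
    return {k: np.concatenate([a.ravel() for a in v]) for k, v in acc.items()}


def _band_tau(band, window_side, ref, tiled):
    if not tiled:
        return ad_statistic_map(band, window_side, ref)
    h = (band.shape[0] // window_side) * window_side
    w = (band.shape[1] // window_side) * window_side
    tiles = (
        band[:h, :w]
        .reshape(h // window_side, window_side, w // window_side, window_side)
        .transpose(0, 2, 1, 3)
        .reshape(-1, window_side * window_side)
    )
    return np.array([ad_statistic(t, ref) for t in tiles])


def estimate_pfa_curve(
    transform: str = "dwt",
    wavelet: str = "db8",
    levels: int = 5,
    window_side: int = 5,
    field_size: int = 1024,
    realizations: int = 4,
    threshold_grid: np.ndarray | None = None,
    seed: int = 20051,
    tiled: bool = False,
) -> ThresholdCurve:
    """Estimate the per-scale threshold-versus-Pfa curve on white noise.

    Windows are the same sliding, symmetrically padded windows used at
    denoising time (``tiled=True`` switches to disjoint tiles, for
    comparison only).  The DWT tables also include a pooled ``"all"`` key:
    the orthonormal DWT whitens white noise identically at every scale, so
    scales share one curve and pooling maximizes the sample.
    """
    if transform not in ("dwt", "dtcwt"):
        raise ValueError(f"unknown transform {transform!r}")
    rng = np.random.default_rng(seed)
    if transform == "dwt":
        samples = _dwt_tau_samples(rng, wavelet, levels, window_side, field_size, realizations, tiled)
        samples["all"] = np.concatenate(list(samples.values()))
    else:
        samples = _dtcwt_tau_samples(rng, levels, window_side, field_size, realizations, tiled)

    coarsest = min(v.size for v in samples.values())
    if coarsest < 10_000:
        warnings.warn(
            f"only {coarsest} windows at the coarsest scale; widen the noise "
            "field or reduce the decomposition depth for reliable small-Pfa "
            "calibration",
            stacklevel=2,
        )

    pooled = np.concatenate(list(samples.values()))
    if threshold_grid is None:
        lo, hi = np.percentile(pooled, [50.0, 99.999])
        if lo > 0:
            threshold_grid = np.geomspace(lo, hi, 200)
        else:
            threshold_grid = np.linspace(lo, hi, 200)
    grid = np.asarray(threshold_grid, dtype=float)

    tables = {}
    n_windows = {}
    for key, tau in samples.items():
        tau_sorted = np.sort(tau)
        # survival fraction tau >= T, nonincreasing in T by construction
        pfa = 1.0 - np.searchsorted(tau_sorted, grid, side="left") / tau.size
        tables[key] = (grid.copy(), pfa)
        n_windows[key] = int(tau.size)

    return ThresholdCurve(
        scope={
            "transform": transform,
            "wavelet": wavelet if transform == "dwt" else "dualtree-cf4.3+db10",
            "levels": levels,
            "window_side": window_side,
            "field_size": field_size,
            "realizations": realizations,
            "windows": "tiled" if tiled else "sliding",
        },
        seed=seed,
        tables=tables,
        n_windows=n_windows,
    )


POLY_PFA_FLOOR = 1e-3


def fit_threshold_polynomial(
    curve: ThresholdCurve,
    degree: int = 8,
    key: str | None = None,
    pfa_floor: float = POLY_PFA_FLOOR,
):
    """Least-squares polynomial model T(pfa) for one table of a curve.

    The model covers pfa in ``[max(pfa_floor, table minimum), table
    maximum]``: the empirical quantile curve steepens without bound as pfa
    shrinks, and a fixed-degree polynomial simply cannot track it over many
    decades (smaller pfa lookups go through the table interpolation
    instead).  Points are weighted by their local pfa spacing so the
    log-in-T tabulation does not bias the fit toward tiny pfa, and if the
    unconstrained fit wiggles, a monotone-decreasing refit (constrained
    least squares) replaces it.  Coefficients (highest degree first) are
    stored on the curve and returned; ``None`` is returned with a warning
    when no usable fit exists.
    """
    if key is None:
        key = "all" if "all" in curve.tables else next(iter(curve.tables))
    thresholds, pfa = curve.tables[key]
    order = np.argsort(pfa, kind="stable")
    pfa = pfa[order]
    thresholds = thresholds[order]
    lo = max(pfa_floor, float(pfa[pfa > 0].min()))
    keep = pfa >= lo
    pfa, thresholds = pfa[keep], thresholds[keep]
    distinct = np.unique(pfa).size
    if distinct < degree + 2:
        raise ValueError(
            f"need at least {degree + 2} distinct pfa values, have {distinct}"
        )
    weights = np.sqrt(np.maximum(np.gradient(pfa), 1e-300))
    with warnings.catch_warnings():
        warnings.simplefilter("error", np.exceptions.RankWarning)
        try:
            coeffs = np.polyfit(pfa, thresholds, degree, w=weights)
        except np.exceptions.RankWarning:
            warnings.warn(
                "ill-conditioned polynomial fit; curve lookups will use "
                "monotone interpolation only",
                stacklevel=2,
            )
            return None

    grid = np.linspace(lo, pfa.max(), 400)
    target = np.interp(grid, pfa, thresholds)

    def _deriv(c):
        return np.polyval(c[:-1] * np.arange(degree, 0, -1), grid)

    if np.any(np.diff(np.polyval(coeffs, grid)) > 0):
        from scipy.optimize import minimize

        res = minimize(
            lambda c: float(np.sum((np.polyval(c, grid) - target) ** 2)),
            coeffs,
            constraints=[{"type": "ineq", "fun": lambda c: -_deriv(c)}],
            method="SLSQP",
            options={"maxiter": 300},
        )
        if res.success:
            coeffs = res.x

    resid = target - np.polyval(coeffs, grid)
    span = thresholds.max() - thresholds.min()
    if span > 0 and np.sqrt(np.mean(resid**2)) > 0.05 * span:
        warnings.warn("poor polynomial fit quality; interpolation preferred", stacklevel=2)
    curve.polys[key] = np.asarray(coeffs)
    curve.poly_domains[key] = (float(lo), float(pfa.max()))
    return curve.polys[key]


def threshold_for_pfa(
    pfa: float,
    curve: ThresholdCurve | None = None,
    key: str = "all",
    scope: dict | None = None,
) -> float:
    """Threshold achieving a target false-alarm probability.

    With no curve, evaluates the shipped reference polynomial (valid for
    pfa in [0, 0.5]).  With a self-calibrated curve, inverts the empirical
    survival table by interpolating T against log(pfa); pfa outside the
    table's range raises.  ``scope`` (if given) is checked against the
    curve's scope to prevent applying a curve to the wrong transform.
    """
    if not 0.0 < pfa <= 0.5:
        if curve is None and pfa == 0.0:
            return reference_threshold(0.0)
        raise ValueError("pfa must lie in (0, 0.5]")
    if curve is None:
        return reference_threshold(pfa)
    if scope:
        for k, v in scope.items():
            if k in curve.scope and curve.scope[k] != v:
                raise ValueError(
                    f"curve scope mismatch for {k!r}: curve has "
                    f"{curve.scope[k]!r}, requested {v!r}"
                )
    if key not in curve.tables:
        raise KeyError(f"curve has no table {key!r}; available: {curve.keys()}")
    lo, hi = curve.pfa_range(key)
    if not lo <= pfa <= hi:
        raise ValueError(
            f"pfa {pfa:g} outside the calibrated range [{lo:g}, {hi:g}] of {key!r}"
        )
    thresholds, pfas = curve.tables[key]
    pos = pfas > 0
    x = np.log(pfas[pos][::-1])  # ascending log-pfa
    y = thresholds[pos][::-1]
    return float(np.interp(np.log(pfa), x, y))


_CURVE_CACHE: dict[tuple, ThresholdCurve] = {}


def get_calibrated_curve(
    transform: str,
    wavelet: str = "db8",
    levels: int = 5,
    window_side: int = 5,
    field_size: int = 1024,
    realizations: int = 4,
    seed: int = 20051,
) -> ThresholdCurve:
    """Memoized :func:`estimate_pfa_curve` (curves are expensive but depend
    only on the scope and seed, never on the image)."""
    key = (transform, wavelet, levels, window_side, field_size, realizations, seed)
    if key not in _CURVE_CACHE:
        _CURVE_CACHE[key] = estimate_pfa_curve(
            transform, wavelet, levels, window_side, field_size, realizations, seed=seed
        )
    return _CURVE_CACHE[key]


def save_curve(path, curve: ThresholdCurve) -> None:
    """Write a curve as ``<path>`` (CSV: key, threshold, pfa) plus
    ``<path>.json`` metadata (scope, seed, window counts, polynomials)."""
    path = str(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["scale", "threshold", "pfa"])
        for key, (thr, pfa) in curve.tables.items():
            for t, p in zip(thr, pfa):
                writer.writerow([key, repr(float(t)), repr(float(p))])
    meta = {
        "scope": curve.scope,
        "seed": curve.seed,
        "n_windows": curve.n_windows,
        "polys": {k: list(map(float, v)) for k, v in curve.polys.items()},
        "poly_domains": {k: list(v) for k, v in curve.poly_domains.items()},
    }
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_curve(path) -> ThresholdCurve:
    path = str(path)
    with open(path + ".json") as fh:
        meta = json.load(fh)
    rows: dict[str, list[tuple[float, float]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.setdefault(row["scale"], []).append(
                (float(row["threshold"]), float(row["pfa"]))
            )
    tables = {}
    for key, pairs in rows.items():
        arr = np.array(pairs)
        tables[key] = (arr[:, 0], arr[:, 1])
    return ThresholdCurve(
        scope=meta["scope"],
        seed=meta["seed"],
        tables=tables,
        polys={k: np.array(v) for k, v in meta.get("polys", {}).items()},
        poly_domains={
            k: (float(v[0]), float(v[1]))
            for k, v in meta.get("poly_domains", {}).items()
        },
        n_windows={k: int(v) for k, v in meta.get("n_windows", {}).items()},
    )
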