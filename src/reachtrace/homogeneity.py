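"""Trajectory-homogeneity diagnostics.

Type-based analyses thrive on heterogeneous trajectory shapes while
aggregate/temporal analyses assume homogeneity, so both the bimodality
coefficient and Hartigan's dip statistic are provided as scalar diagnostics
of an index distribution (e.g. MAD or AUC), together with line-density grids
(heatmaps) and between-condition difference grids for visual assessment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .dataset import RAW, TIMESTAMPS, XPOS, YPOS, TrackingDataset

log = logging.getLogger("reachtrace")


@dataclass
class BimodalityResult:
    """Scalar multimodality diagnostics for one sample."""

    bc: float | None = None
    dip: float | None = None
    dip_p: float | None = None
    n: int = 0


def bimodality_coefficient(values) -> float:
    """BC = (g1^2 + 1) / (g2 + 3(n-1)^2 / ((n-2)(n-3))).

    g1 is the bias-corrected sample skewness and g2 the bias-corrected excess
    kurtosis.  BC tends to 1/3 for a normal sample, 5/9 for a uniform one and
    1 for a symmetric two-point mass; values above 5/9 are conventionally
    read as evidence of bimodality, but no verdict is applied here.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 4:
        raise ValueError("bimodality coefficient requires n >= 4")
    if np.ptp(x) == 0:
        raise ValueError("bimodality coefficient undefined for zero variance")
    g1 = stats.skew(x, bias=False)
    g2 = stats.kurtosis(x, fisher=True, bias=False)
    return float((g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


# ---------------------------------------------------------------------------
# Hartigan's dip
#
# The dip is the sup-norm distance between the ECDF and the closest unimodal
# (convex-then-concave) CDF.  For a fixed mode position k the minimal
# tolerance decomposes into (a) flank terms — half the maximal gap between
# the ECDF's upper steps and the greatest convex minorant of its lower steps
# on the prefix (symmetrically, the least concave majorant on the suffix) —
# and (b) a junction term coupling the two pieces through their shared value
# at the mode, expressed by chord extrapolations.  The flank terms are exact
# for almost all samples; candidate modes are verified (and if necessary
# corrected) against the junction condition by bisection.


def _flank_devs(xs: np.ndarray, low: np.ndarray, up: np.ndarray):
    """Per-mode flank deviations, in count units.

    ``conv_dev[k]``: max over j <= k of ``up_j`` minus the greatest convex
    minorant of the lower step counts on [0..k]; ``conc_dev[k]``: the mirror
    image with the least concave majorant of the upper counts on [k..m-1].
    """
    m = len(xs)
    conv_dev = np.empty(m)
    hull: list[int] = []
    seg_max: list[float] = []
    for k in range(m):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (xs[k] - xs[a]) * (low[b] - low[a]) >= (low[k] - low[a]) * (xs[b] - xs[a]):
                hull.pop()
                seg_max.pop()
            else:
                break
        if hull:
            a = hull[-1]
            js = np.arange(a, k + 1)
            line = low[a] + (low[k] - low[a]) * (xs[js] - xs[a]) / (xs[k] - xs[a])
            seg_max.append(float(np.max(up[js] - line)))
        hull.append(k)
        conv_dev[k] = max(seg_max) if seg_max else up[0] - low[0]
    conc_dev = np.empty(m)
    hull, seg_max = [], []
    for k in range(m - 1, -1, -1):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            # pop b when it lies on or below the chord k -> a (keep the majorant)
            if (xs[a] - xs[k]) * (up[b] - up[k]) <= (up[a] - up[k]) * (xs[b] - xs[k]):
                hull.pop()
                seg_max.pop()
            else:
                break
        if hull:
            a = hull[-1]
            js = np.arange(k, a + 1)
            line = up[k] + (up[a] - up[k]) * (xs[js] - xs[k]) / (xs[a] - xs[k])
            seg_max.append(float(np.max(line - low[js])))
        hull.append(k)
        conc_dev[k] = max(seg_max) if seg_max else up[k] - low[k]
    return conv_dev, conc_dev


def _junction_gap(xs, low, up, k: int, t: float) -> tuple[float, float]:
    """Junction infeasibility gap at mode ``k`` and its slope in t.

    Pinning the fit's value v at ``xs[k]``, convexity requires v to lie above
    every chord through (x_i, upper_i) and (x_j, lower_j) with i < j < k
    extrapolated to x_k; concavity bounds v from above symmetrically.  The
    returned gap (required minus available v, in count units) is a convex,
    strictly decreasing piecewise-linear function of t; the slope of the
    active constraints enables exact Newton root-finding.
    """
    m = len(xs)
    lo_v, lo_slope = up[k] - t, -1.0
    hi_v, hi_slope = low[k] + t, 1.0
    if k >= 2:
        i = np.arange(k - 1)[:, None]
        j = np.arange(1, k)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xs[k] - xs[i]) / (xs[j] - xs[i])
            ext = (low[i] + t) + ((up[j] - t) - (low[i] + t)) * r
        ext = np.where(i < j, ext, -np.inf)
        best = np.unravel_index(int(np.nanargmax(ext)), ext.shape)
        if ext[best] > lo_v:
            lo_v = float(ext[best])
            lo_slope = float(1.0 - 2.0 * r[best[0], best[1]])
    if k <= m - 3:
        i = np.arange(k + 1, m - 1)[:, None]
        j = np.arange(k + 2, m)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xs[k] - xs[j]) / (xs[i] - xs[j])
            ext = (up[j] - t) + ((low[i] + t) - (up[j] - t)) * r
        ext = np.where(i < j, ext, np.inf)
        best = np.unravel_index(int(np.nanargmin(ext)), ext.shape)
        if ext[best] < hi_v:
            hi_v = float(ext[best])
            hi_slope = float(-1.0 + 2.0 * r[best[0], best[1]])
    return lo_v - hi_v, lo_slope - hi_slope


def _mode_tolerance(xs, low, up, k: int, t_lo: float, t_hi: float) -> float | None:
    """Exact per-mode tolerance, or None if it exceeds ``t_hi``.

    Newton iteration on the convex decreasing junction gap, started at the
    flank lower bound ``t_lo``; finite convergence on piecewise-linear gaps.
    """
    t = t_lo
    for _ in range(200):
        gap, slope = _junction_gap(xs, low, up, k, t)
        if gap <= 1e-12:
            return t
        if slope >= 0:  # cannot happen for a proper gap; bail out safely
            return None
        t = t - gap / slope
        if t > t_hi + 1e-12:
            return None
    return t


def dip_value(values) -> float:
    """Hartigan's dip statistic of a sample.

    Bounded below by 1/(2n), attained for perfectly unimodal-compatible
    samples (any two distinct points, identical values, equally spaced
    points).  Ties are genuine atoms: an atom of probability mass p forces a
    dip of at least ~p/2, because no continuous unimodal CDF can track the
    jump (a degenerate all-identical sample returns the 1/(2n) floor).
    """
    x = np.sort(np.asarray(values, dtype=float))
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 1:
        raise ValueError("empty sample")
    if n == 1 or x[0] == x[-1]:
        return 0.5 / n
    xs, start = np.unique(x, return_index=True)
    m = len(xs)
    low = start.astype(float)                      # count strictly below
    up = np.append(start[1:], n).astype(float)     # count at or below
    conv_dev, conc_dev = _flank_devs(xs, low, up)
    flank_t = np.maximum(conv_dev, conc_dev) / 2.0  # tolerance lower bound per mode

    best = np.inf
    for k in np.argsort(flank_t, kind="stable"):
        k = int(k)
        if flank_t[k] >= best:
            break
        t_k = _mode_tolerance(xs, low, up, k, float(flank_t[k]), min(best, float(n)))
        if t_k is not None:
            best = min(best, t_k)
    return max(best, 0.5) / n


def dip_statistic(values, n_boot: int = 0, seed: int | None = None) -> BimodalityResult:
    """Dip statistic with an optional bootstrap p value.

    The null calibration draws ``n_boot`` uniform(0,1) samples of the same
    size; p is the fraction of bootstrap dips at or above the observed one.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    d = dip_value(x)
    p = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.array([dip_value(rng.uniform(size=n)) for _ in range(n_boot)])
        p = float(np.mean(boots >= d - 1e-15))
    if np.ptp(x) == 0:
        p = 1.0
    return BimodalityResult(dip=d, dip_p=p, n=n)


def check_bimodality(values, n_boot: int = 0, seed: int | None = None) -> BimodalityResult:
    """Convenience wrapper returning BC and dip for one index sample."""
    res = dip_statistic(values, n_boot=n_boot, seed=seed)
    res.bc = bimodality_coefficient(values)
    return res


# ---------------------------------------------------------------------------
# density grids


@dataclass
class DensityGrid:
    """Line-density grid of trajectory coverage.

    ``intensity[iy, ix]`` counts (smoothed) resampled trajectory points per
    cell; bounds are (xmin, xmax, ymin, ymax) in px and resolution (nx, ny).
    """

    bounds: tuple[float, float, float, float]
    resolution: tuple[int, int]
    intensity: np.ndarray
    smooth_radius: float = 0.0
    n_shades: int = 0


def density_grid(
    ds: TrackingDataset,
    representation: str = RAW,
    bounds: tuple[float, float, float, float] | None = None,
    resolution: tuple[int, int] = (100, 100),
    smooth_radius: float = 0.0,
    trial_ids=None,
) -> DensityGrid:
    """Bin arc-length-uniform resampled trajectory points into a grid.

    Trajectories are densely resampled (constant arc-length step no larger
    than one cell) before binning so that line coverage, not sampling rate,
    drives intensity.  Gaussian smoothing with the given radius (in cells,
    reflected boundaries) conserves total intensity.
    """
    arr = ds.get(representation)
    xi = arr.feature_index(XPOS)
    yi = arr.feature_index(YPOS)
    keep = range(arr.n_trials) if trial_ids is None else [
        arr.trial_ids.index(t) for t in trial_ids
    ]
    trajs = []
    for i in keep:
        L = arr.valid_length[i]
        trajs.append(arr.values[i, :L, [xi, yi]].T)
    if bounds is None:
        allp = np.vstack(trajs)
        bounds = (allp[:, 0].min(), allp[:, 0].max(), allp[:, 1].min(), allp[:, 1].max())
    nx, ny = resolution
    cell = min((bounds[1] - bounds[0]) / nx, (bounds[3] - bounds[2]) / ny)
    grid = np.zeros((ny, nx))
    for p in trajs:
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        if total == 0:
            pts = p[:1]
        else:
            m = max(int(np.ceil(total / max(cell, 1e-12))) + 1, 2)
            new_s = np.linspace(0, total, m)
            pts = np.column_stack(
                [np.interp(new_s, s, p[:, 0]), np.interp(new_s, s, p[:, 1])]
            )
        ix = np.clip(((pts[:, 0] - bounds[0]) / (bounds[1] - bounds[0] + 1e-12) * nx).astype(int), 0, nx - 1)
        iy = np.clip(((pts[:, 1] - bounds[2]) / (bounds[3] - bounds[2] + 1e-12) * ny).astype(int), 0, ny - 1)
        np.add.at(grid, (iy, ix), 1.0)
    if smooth_radius > 0:
        grid = ndimage.gaussian_filter(grid, sigma=smooth_radius, mode="reflect")
    return DensityGrid(bounds, resolution, grid, smooth_radius)


def diff_grid(a: DensityGrid, b: DensityGrid, n_shades: int = 0) -> DensityGrid:
    """Normalized density difference a - b, optionally quantized.

    Each grid is normalized to unit total mass first; with ``n_shades`` > 0
    the signed difference is quantized to that many levels per sign.
    """
    if a.bounds != b.bounds or a.resolution != b.resolution:
        raise ValueError("grids must share bounds and resolution")
    ia = a.intensity / max(a.intensity.sum(), 1e-300)
    ib = b.intensity / max(b.intensity.sum(), 1e-300)
    diff = ia - ib
    if n_shades > 0:
        peak = np.abs(diff).max()
        if peak > 0:
            diff = np.round(diff / peak * n_shades) / n_shades * peak
    return DensityGrid(a.bounds, a.resolution, diff, 0.0, n_shades)
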