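"""Temporal-dynamics analysis of time-normalized trajectories.

Aggregates trajectory features (x position, movement angle, ...) per
normalized time step and group, runs per-step linear models with
subject-clustered standard errors, re-runs aggregation within response-time
strata, and computes per-type velocity/acceleration profiles.

Per-step inference deliberately uses a single-level linear model with
cluster-robust (by subject) standard errors: step-by-step mixed models are
statistically fragile under multiple testing, so full mixed-model estimation
is delegated to external tooling via tidy exports.  Consecutive significant
steps are screened by a minimum run length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .dataset import TIME_NORMALIZED, TIMESTAMPS, XPOS, YPOS, TrackingDataset
from .typing import TypeAssignment

log = logging.getLogger("reachtrace")


@dataclass
class StepTestConfig:
    """Configuration of the per-step regression scan."""

    feature: str = XPOS
    predictors: list[str] = field(default_factory=list)
    subject_id: str = "subject_id"
    alpha: float = 0.05
    min_run: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


def _feature_matrix(ds: TrackingDataset, representation: str, feature: str) -> np.ndarray:
    arr = ds.get(representation)
    if feature not in arr.feature_names:
        raise KeyError(
            f"feature {feature!r} missing from {representation!r}; "
            "add kinematic channels with derivatives()/angles() first"
        )
    if len(np.unique(arr.valid_length)) != 1:
        raise ValueError("per-step analysis needs a fixed number of steps; "
                         "time-normalize first")
    L = int(arr.valid_length[0])
    return arr.values[:, :L, arr.feature_index(feature)]


def step_aggregate(
    ds: TrackingDataset,
    representation: str = TIME_NORMALIZED,
    feature: str = XPOS,
    group_by: str | None = None,
) -> pd.DataFrame:
    """Mean, SD and count of one feature per time step (and group).

    Steps are numbered 1..n_steps.  NaN feature cells (e.g. the undefined
    first angle sample) are excluded from the per-step statistics.
    """
    mat = _feature_matrix(ds, representation, feature)
    arr = ds.get(representation)
    ids = arr.trial_ids
    groups = (
        pd.Series(["all"] * len(ids), index=ids)
        if group_by is None
        else ds.trial_table.set_index("trial_id")[group_by].reindex(ids)
    )
    rows = []
    for gval, idx in pd.Series(range(len(ids)), index=groups.values).groupby(level=0):
        sub = mat[idx.to_numpy()]
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(sub, axis=0)
            n = np.sum(np.isfinite(sub), axis=0)
            sd = np.full(sub.shape[1], np.nan)
            ok = n >= 2
            sd[ok] = np.nanstd(sub[:, ok], axis=0, ddof=1)
        for s in range(sub.shape[1]):
            rows.append({"step": s + 1, "group": gval, "mean": mean[s],
                         "sd": sd[s], "n": int(n[s])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-step tests


def _cluster_robust_scan(Y: np.ndarray, X: np.ndarray, clusters: np.ndarray):
    """OLS of every column of Y on X with CR1 cluster-robust covariance.

    Vectorized across columns (time steps): beta = pinv(X) Y, then the
    sandwich estimator with cluster sums and the (G/(G-1)) * ((N-1)/(N-K))
    small-sample factor.  Returns (beta, se) of shape (K, n_steps).
    """
    n, k = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    labels, inv = np.unique(clusters, return_inverse=True)
    G = len(labels)
    # per-cluster score sums: S_g = sum_{i in g} x_i * e_i  -> (G, K, steps)
    scores = X[:, :, None] * resid[:, None, :]
    S = np.zeros((G, k, Y.shape[1]))
    np.add.at(S, inv, scores)
    meat = np.einsum("gks,gls->kls", S, S)
    cov = np.einsum("km,mls,ln->kns", XtX_inv, meat, XtX_inv)
    factor = (G / (G - 1)) * ((n - 1) / (n - k)) if G > 1 and n > k else np.nan
    var = np.einsum("kks->ks", cov) * factor
    se = np.sqrt(np.maximum(var, 0.0))
    return beta, se, G


def significant_runs(flags: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    """Maximal runs of consecutive True flags of length >= min_run.

    Returns 1-based inclusive (start, end) step intervals.
    """
    runs = []
    start = None
    for i, f in enumerate(list(flags) + [False]):
        if f and start is None:
            start = i
        elif not f and start is not None:
            if i - start >= min_run:
                runs.append((start + 1, i))
            start = None
    return runs


def step_tests(
    ds: TrackingDataset,
    representation: str = TIME_NORMALIZED,
    config: StepTestConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, list[tuple[int, int]]]]:
    """Per-step linear models of one feature on trial-level predictors.

    For every time step, the feature is regressed on the predictors (with
    intercept); standard errors are clustered by subject and p values use
    the t distribution with G-1 degrees of freedom.  Returns the per-step
    coefficient table and, per predictor, the significant-step runs of at
    least ``min_run`` consecutive steps at level alpha.  Steps with NaN
    feature values for some trials drop those trials (singular designs give
    NaN stats with a warning).
    """
    config = config or StepTestConfig()
    if not config.predictors:
        raise ValueError("at least one predictor is required")
    mat = _feature_matrix(ds, representation, config.feature)
    meta = ds.trial_table.set_index("trial_id").reindex(ds.get(representation).trial_ids)
    X_cols = []
    for p in config.predictors:
        col = meta[p]
        if col.dtype == object or str(col.dtype) == "category":
            col = pd.factorize(col)[0].astype(float)  # two-level contrast
        X_cols.append(np.asarray(col, dtype=float))
    X = np.column_stack([np.ones(len(meta))] + X_cols)
    if np.unique(X, axis=0).shape[0] < X.shape[1]:
        raise ValueError("predictors do not vary across trials")
    clusters = meta[config.subject_id].to_numpy()

    n_steps = mat.shape[1]
    names = ["intercept"] + list(config.predictors)
    beta = np.full((X.shape[1], n_steps), np.nan)
    se = np.full_like(beta, np.nan)
    complete = np.isfinite(mat).all(axis=0)
    if complete.any():
        b, s, G = _cluster_robust_scan(mat[:, complete], X, clusters)
        beta[:, complete], se[:, complete] = b, s
    for step in np.nonzero(~complete)[0]:
        keep = np.isfinite(mat[:, step])
        if keep.sum() <= X.shape[1]:
            log.warning("step %d: too few complete trials, stats missing", step + 1)
            continue
        try:
            b, s, G = _cluster_robust_scan(
                mat[keep, step][:, None], X[keep], clusters[keep]
            )
            beta[:, step], se[:, step] = b[:, 0], s[:, 0]
        except np.linalg.LinAlgError:
            log.warning("step %d: singular design, stats missing", step + 1)
    G = len(np.unique(clusters))
    with np.errstate(invalid="ignore", divide="ignore"):
        tval = beta / se
        pval = 2 * stats.t.sf(np.abs(tval), df=max(G - 1, 1))

    rows = []
    for j, name in enumerate(names):
        for s_i in range(n_steps):
            rows.append({"step": s_i + 1, "term": name, "beta": beta[j, s_i],
                         "se": se[j, s_i], "t": tval[j, s_i], "p": pval[j, s_i]})
    coef = pd.DataFrame(rows)
    runs = {}
    for j, name in enumerate(names[1:], start=1):
        flags = pval[j] < config.alpha
        flags &= np.isfinite(pval[j])
        runs[name] = significant_runs(flags, config.min_run)
    return coef, runs


def stratified_reanalysis(
    ds: TrackingDataset,
    representation: str = TIME_NORMALIZED,
    feature: str = XPOS,
    rt_breaks: list[float] = (1500.0, 2500.0, 5000.0),
    group_by: str | None = None,
    rt_column: str = "RT",
) -> dict[str, pd.DataFrame]:
    """Per-step aggregation within response-time strata.

    Breaks must be strictly increasing; trials fall into (0, b1], (b1, b2],
    ... and trials above the last break are excluded (with their count
    logged).  Empty strata are dropped with a warning.
    """
    breaks = list(rt_breaks)
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ValueError("rt_breaks must be strictly increasing")
    meta = ds.trial_table.copy()
    if rt_column not in meta.columns:
        arr = ds.get(representation)
        ti = arr.feature_index(TIMESTAMPS)
        rts = {
            arr.trial_ids[i]: float(
                arr.values[i, arr.valid_length[i] - 1, ti] - arr.values[i, 0, ti]
            )
            for i in range(arr.n_trials)
        }
        meta[rt_column] = meta["trial_id"].map(rts)
    edges = [0.0] + breaks
    out: dict[str, pd.DataFrame] = {}
    n_excluded = int((meta[rt_column] > breaks[-1]).sum())
    if n_excluded:
        log.info("stratified_reanalysis: excluded %d trials with RT > %g ms",
                 n_excluded, breaks[-1])
    for lo, hi in zip(edges, edges[1:]):
        ids = meta.loc[(meta[rt_column] > lo) & (meta[rt_column] <= hi), "trial_id"]
        name = f"{int(lo)}-{int(hi)}ms"
        if ids.empty:
            log.warning("stratified_reanalysis: stratum %s is empty", name)
            continue
        sub = ds.select_ids(ids, "stratify", stratum=name)
        out[name] = step_aggregate(sub, representation, feature, group_by)
    if not out:
        raise ValueError("all strata are empty")
    return out


# ---------------------------------------------------------------------------
# per-type kinematic profiles


def _crop_stationary(points: np.ndarray) -> np.ndarray:
    """Drop the leading and trailing runs of zero displacement."""
    xy = points[:, 1:3]
    step = np.hypot(*(np.diff(xy, axis=0).T))
    moving = np.nonzero(step > 0)[0]
    if len(moving) == 0:
        return points[:0]
    first, last = moving[0], moving[-1] + 1
    return points[first : last + 1]


def type_kinematic_profiles(
    ds: TrackingDataset,
    assignment: TypeAssignment,
    representation: str = "trajectories",
    n_steps: int = 101,
    crop: bool = True,
    smooth_sd: float = 2.0,
) -> pd.DataFrame:
    """Per-type mean velocity and acceleration across normalized time steps.

    Initiation idle time and terminal stationary time are cropped from each
    raw trajectory (``crop=True``), velocity and acceleration are computed
    from finite differences, time-normalized to ``n_steps`` and smoothed
    with a Gaussian filter (SD in steps, reflected boundaries; SD 0 leaves
    profiles unsmoothed).  Fully stationary trials are excluded with a
    warning.
    """
    arr = ds.get(representation)
    ti = arr.feature_index(TIMESTAMPS)
    xi = arr.feature_index(XPOS)
    yi = arr.feature_index(YPOS)
    label_of = assignment.table.set_index("trial_id")["label"].to_dict()
    prof_v: dict[str, list[np.ndarray]] = {}
    prof_a: dict[str, list[np.ndarray]] = {}
    n_dropped = 0
    for i in range(arr.n_trials):
        lab = label_of.get(arr.trial_ids[i])
        if lab is None:
            continue
        L = arr.valid_length[i]
        pts = arr.values[i, :L, :][:, [ti, xi, yi]]
        if crop:
            pts = _crop_stationary(pts)
        if len(pts) < 3:
            n_dropped += 1
            continue
        t, x, y = pts[:, 0], pts[:, 1], pts[:, 2]
        d = np.hypot(np.diff(x), np.diff(y))
        dt = np.diff(t)
        v = d / dt
        a = np.diff(v) / dt[1:]
        steps = np.linspace(0.0, 1.0, n_steps)
        tv = (t[1:] - t[1]) / max(t[-1] - t[1], 1e-12)
        v_n = np.interp(steps, tv, v)
        if len(a):
            ta = (t[1:-1] - t[1]) / max(t[-2] - t[1], 1e-12)
            a_n = np.interp(steps, ta, a)
        else:
            a_n = np.zeros(n_steps)
        if smooth_sd > 0:
            v_n = ndimage.gaussian_filter1d(v_n, smooth_sd, mode="reflect")
            a_n = ndimage.gaussian_filter1d(a_n, smooth_sd, mode="reflect")
        prof_v.setdefault(lab, []).append(v_n)
        prof_a.setdefault(lab, []).append(a_n)
    if n_dropped:
        log.warning("type_kinematic_profiles: excluded %d (near-)stationary trials",
                    n_dropped)
    rows = []
    for lab in prof_v:
        v_mean = np.mean(prof_v[lab], axis=0)
        a_mean = np.mean(prof_a[lab], axis=0)
        for s in range(n_steps):
            rows.append({"label": lab, "step": s + 1,
                         "velocity": v_mean[s], "acceleration": a_mean[s],
                         "n": len(prof_v[lab])})
    return pd.DataFrame(rows)
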