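"""Spatial transformation and resampling of trajectories.

Spatial steps (remapping to a common side, start/end alignment) overwrite the
representation they operate on by default, because they are meant to affect
all downstream analyses; resampling steps store their result under a new
representation name so several resolutions can coexist.

Coordinates follow the mathematical y-up convention; importers expose a
``screen_y_down`` flag that negates y at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataset import (
    LENGTH_NORMALIZED,
    RAW,
    TIME_NORMALIZED,
    TIMESTAMPS,
    XPOS,
    YPOS,
    TrackingDataset,
    TrajectoryArray,
)

log = logging.getLogger("reachtrace")


@dataclass
class ResampleSpec:
    """How to resample a trajectory representation.

    mode
        ``time_normalized`` — ``n_steps`` temporally equidistant points
        (conventionally 101); ``length_normalized`` — ``n_points``
        arc-length-equidistant points (conventionally 20);
        ``constant_interval`` — timestamps at multiples of ``interval_ms``.
    """

    mode: str
    n_steps: int = 101
    n_points: int = 20
    interval_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in ("time_normalized", "length_normalized", "constant_interval"):
            raise ValueError(f"unknown resample mode {self.mode!r}")
        if self.n_steps < 2 or self.n_points < 2:
            raise ValueError("n_steps and n_points must be >= 2")
        if self.interval_ms <= 0:
            raise ValueError("interval_ms must be positive")


# ---------------------------------------------------------------------------
# spatial transforms


def remap_symmetric(
    ds: TrackingDataset,
    representation: str = RAW,
    target_side: str = "left",
    remap_y: bool = False,
    save_as: str | None = None,
) -> TrackingDataset:
    """Mirror trajectories so all end on a common side of their start.

    The side is decided by the x sign of the LAST point relative to the FIRST
    point; trials already on the target side are untouched, the others have
    all x values reflected about the start x.  An exact tie (end x == start x)
    is assigned to the target side without flipping (logged).  ``remap_y``
    analogously maps endpoints to above the start.
    """
    if target_side not in ("left", "right"):
        raise ValueError("target_side must be 'left' or 'right'")
    arr = ds.get(representation).copy()
    xi = arr.feature_index(XPOS)
    yi = arr.feature_index(YPOS)
    n_ties = 0
    for i in range(arr.n_trials):
        L = arr.valid_length[i]
        x = arr.values[i, :L, xi]
        dx = x[-1] - x[0]
        if dx == 0:
            n_ties += 1
        wrong = dx > 0 if target_side == "left" else dx < 0
        if wrong:
            arr.values[i, :L, xi] = 2 * x[0] - x
        if remap_y:
            y = arr.values[i, :L, yi]
            if y[-1] - y[0] < 0:
                arr.values[i, :L, yi] = 2 * y[0] - y
    if n_ties:
        log.warning("remap_symmetric: %d trials end exactly above their start", n_ties)
    return ds.with_representation(
        save_as or representation, arr, "remap_symmetric",
        representation=representation, target_side=target_side, remap_y=remap_y,
    )


def align_start(
    ds: TrackingDataset,
    representation: str = RAW,
    origin: tuple[float, float] = (0.0, 0.0),
    save_as: str | None = None,
) -> TrackingDataset:
    """Translate each trial so its first point equals ``origin``.

    A rigid translation: all pairwise point distances are preserved exactly.
    """
    arr = ds.get(representation).copy()
    xi = arr.feature_index(XPOS)
    yi = arr.feature_index(YPOS)
    for i in range(arr.n_trials):
        L = arr.valid_length[i]
        arr.values[i, :L, xi] += origin[0] - arr.values[i, 0, xi]
        arr.values[i, :L, yi] += origin[1] - arr.values[i, 0, yi]
    return ds.with_representation(
        save_as or representation, arr, "align_start",
        representation=representation, origin=origin,
    )


def align_start_end(
    ds: TrackingDataset,
    representation: str = RAW,
    start: tuple[float, float] = (0.0, 0.0),
    end: tuple[float, float] = (-1.0, 1.5),
    save_as: str | None = None,
) -> TrackingDataset:
    """Per-axis affine map sending each trial's (start, end) to fixed points.

    This stretches or compresses the axes; a trial with zero extent on an
    axis cannot be rescaled on that axis and raises an error naming it.
    """
    arr = ds.get(representation).copy()
    for ax, (s_t, e_t) in zip((XPOS, YPOS), zip(start, end)):
        fi = arr.feature_index(ax)
        for i in range(arr.n_trials):
            L = arr.valid_length[i]
            v = arr.values[i, :L, fi]
            extent = v[-1] - v[0]
            if extent == 0:
                raise ValueError(
                    f"trial {arr.trial_ids[i]!r} has zero {ax} extent; "
                    "cannot align start and end on this axis"
                )
            arr.values[i, :L, fi] = s_t + (v - v[0]) * (e_t - s_t) / extent
    return ds.with_representation(
        save_as or representation, arr, "align_start_end",
        representation=representation, start=start, end=end,
    )


# ---------------------------------------------------------------------------
# resampling


def _resample_trial(points: np.ndarray, t_idx: int, spec: ResampleSpec) -> np.ndarray:
    """Resample one ``(L, F)`` trial block according to ``spec``."""
    t = points[:, t_idx]
    if spec.mode == "time_normalized":
        new_t = np.linspace(t[0], t[-1], spec.n_steps)
        out = np.column_stack(
            [new_t if j == t_idx else np.interp(new_t, t, points[:, j])
             for j in range(points.shape[1])]
        )
        out[0], out[-1] = points[0], points[-1]  # endpoints exact
        return out
    if spec.mode == "constant_interval":
        n_full = int(np.floor((t[-1] - t[0]) / spec.interval_ms + 1e-9))
        new_t = t[0] + spec.interval_ms * np.arange(n_full + 1)
        if new_t[-1] < t[-1] - 1e-9:
            new_t = np.append(new_t, t[-1])
        out = np.column_stack(
            [new_t if j == t_idx else np.interp(new_t, t, points[:, j])
             for j in range(points.shape[1])]
        )
        out[0] = points[0]
        return out
    # length_normalized: equal arc-length spacing along the x/y polyline
    cols = [j for j in range(points.shape[1]) if j != t_idx]
    # x and y are the first two non-time columns by construction
    xy = points[:, cols[:2]]
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        log.warning("length normalization: zero-length trajectory, all points collapse")
        out = np.repeat(points[:1], spec.n_points, axis=0)
        out[:, t_idx] = np.linspace(t[0], t[-1], spec.n_points)
        return out
    new_s = np.linspace(0.0, total, spec.n_points)
    out = np.column_stack([np.interp(new_s, s, points[:, j]) for j in range(points.shape[1])])
    out[0], out[-1] = points[0], points[-1]
    return out


def resample(
    ds: TrackingDataset,
    representation: str = RAW,
    spec: ResampleSpec | None = None,
    save_as: str | None = None,
) -> TrackingDataset:
    """Resample a representation, storing the result under ``save_as``.

    The source representation is left untouched and the trial table never
    changes.  Interpolation is piecewise linear throughout; in length mode
    the timestamps are carried by linear interpolation in arc length.
    """
    spec = spec or ResampleSpec("time_normalized")
    arr = ds.get(representation)
    if np.any(arr.valid_length < 2):
        raise ValueError("resampling requires >= 2 valid points per trial")
    t_idx = arr.feature_index(TIMESTAMPS)
    trials = [_resample_trial(arr.trial_values(i), t_idx, spec) for i in range(arr.n_trials)]
    out = TrajectoryArray.from_trials(trials, arr.trial_ids, arr.feature_names)
    if save_as is None:
        save_as = {
            "time_normalized": TIME_NORMALIZED,
            "length_normalized": LENGTH_NORMALIZED,
            "constant_interval": "cn_trajectories",
        }[spec.mode]
    return ds.with_representation(
        save_as, out, "resample", representation=representation,
        mode=spec.mode, n_steps=spec.n_steps, n_points=spec.n_points,
        interval_ms=spec.interval_ms,
    )


def time_normalize(ds, representation=RAW, n_steps=101, save_as=None):
    """Shorthand for temporally equidistant resampling (default 101 steps)."""
    return resample(ds, representation, ResampleSpec("time_normalized", n_steps=n_steps), save_as)


def length_normalize(ds, representation=RAW, n_points=20, save_as=None):
    """Shorthand for arc-length equidistant resampling (default 20 points)."""
    return resample(ds, representation, ResampleSpec("length_normalized", n_points=n_points), save_as)


# ---------------------------------------------------------------------------
# prototype-distance outlier flagging


def flag_outliers_by_prototype(
    ds: TrackingDataset,
    representation: str = RAW,
    prototypes=None,
    z_threshold: float = 2.0,
    n_points: int = 20,
) -> "pd.DataFrame":
    """Flag trajectories unusually far from their closest prototype.

    Each trajectory's distance to its closest prototype is z-standardized
    within the group of trajectories mapped to that prototype; trials with
    z > ``z_threshold`` are flagged.  Groups with fewer than 3 members have
    an undefined z and are never flagged (warned).
    """
    import pandas as pd

    from .typing import map_to_prototypes, standard_prototypes

    prototypes = prototypes or standard_prototypes()
    assignment = map_to_prototypes(ds, representation, prototypes, n_points=n_points)
    out = assignment.table.copy()
    out["outlier"] = False
    for label, grp in out.groupby("label", dropna=True):
        if len(grp) < 3:
            log.warning(
                "flag_outliers_by_prototype: group %r has <3 members, z undefined", label
            )
            continue
        sd = grp["distance"].std(ddof=1)
        if sd == 0:
            continue
        z = (grp["distance"] - grp["distance"].mean()) / sd
        out.loc[grp.index, "z_distance"] = z
        out.loc[grp.index, "outlier"] = z > z_threshold
    return pd.DataFrame(
        {
            "trial_id": out["trial_id"],
            "z_distance": out["z_distance"],
            "outlier": out["outlier"],
        }
    )
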