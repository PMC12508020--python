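"""Per-point kinematic channels: distance, velocity, acceleration, angles.

Velocity is unsigned speed (px/ms).  Acceleration uses forward differences of
velocity, so the final sample's acceleration is undefined.  Movement angles
come in two flavours: ``angle_v``, the signed angle of each two-point segment
against the vertical axis (0 = straight up, positive toward negative x, i.e.
the left/chosen side after left-remapping, range (-pi, pi]); and ``angle_p``,
the interior angle at the center of three-point segments (pi for a collinear
continuation).  Undefined leading/degenerate samples are NaN.
"""

from __future__ import annotations

import numpy as np

from .dataset import RAW, TIMESTAMPS, XPOS, YPOS, TrackingDataset

DIST = "dist"
VEL = "vel"
ACC = "acc"
ANGLE_V = "angle_v"
ANGLE_P = "angle_p"


def derivatives(ds: TrackingDataset, representation: str = RAW) -> TrackingDataset:
    """Add ``dist``, ``vel`` and ``acc`` channels to a representation.

    dist_i is the Euclidean step from point i-1 to i; vel_i = dist_i / dt_i;
    acc_i = (vel_{i+1} - vel_i) / dt_{i+1}.  Repeated timestamps with nonzero
    displacement would imply infinite velocity and raise an error naming the
    trial.
    """
    arr = ds.get(representation)
    n, m = arr.n_trials, arr.max_points
    dist = np.full((n, m), np.nan)
    vel = np.full((n, m), np.nan)
    acc = np.full((n, m), np.nan)
    ti = arr.feature_index(TIMESTAMPS)
    xi = arr.feature_index(XPOS)
    yi = arr.feature_index(YPOS)
    for i in range(n):
        L = arr.valid_length[i]
        t = arr.values[i, :L, ti]
        x = arr.values[i, :L, xi]
        y = arr.values[i, :L, yi]
        d = np.hypot(np.diff(x), np.diff(y))
        dt = np.diff(t)
        if np.any((dt == 0) & (d > 0)):
            raise ValueError(
                f"trial {arr.trial_ids[i]!r}: repeated timestamp with nonzero "
                "displacement (infinite velocity)"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(dt > 0, d / np.where(dt == 0, np.nan, dt), 0.0)
        dist[i, 1:L] = d
        vel[i, 1:L] = v
        if L >= 3:
            acc[i, 1 : L - 1] = np.diff(v) / dt[1:]
    return ds.with_representation(
        representation,
        arr.with_features({DIST: dist, VEL: vel, ACC: acc}),
        "derivatives",
        representation=representation,
    )


def angles(ds: TrackingDataset, representation: str = RAW) -> TrackingDataset:
    """Add ``angle_v`` and ``angle_p`` channels to a representation.

    Zero-length segments give NaN for both channels.
    """
    arr = ds.get(representation)
    n, m = arr.n_trials, arr.max_points
    angle_v = np.full((n, m), np.nan)
    angle_p = np.full((n, m), np.nan)
    xi = arr.feature_index(XPOS)
    yi = arr.feature_index(YPOS)
    for i in range(n):
        L = arr.valid_length[i]
        dx = np.diff(arr.values[i, :L, xi])
        dy = np.diff(arr.values[i, :L, yi])
        nonzero = (dx != 0) | (dy != 0)
        # signed angle vs vertical (0,1); positive toward negative x;
        # +0.0 keeps straight-down at +pi (range (-pi, pi])
        av = np.arctan2(-dx + 0.0, dy)
        av[~nonzero] = np.nan
        angle_v[i, 1:L] = av
        if L >= 3:
            ux, uy = -dx[:-1], -dy[:-1]  # incoming segment, reversed
            vx, vy = dx[1:], dy[1:]      # outgoing segment
            dot = ux * vx + uy * vy
            norm = np.hypot(ux, uy) * np.hypot(vx, vy)
            with np.errstate(invalid="ignore", divide="ignore"):
                ap = np.arccos(np.clip(dot / norm, -1.0, 1.0))
            ap[norm == 0] = np.nan
            angle_p[i, 1 : L - 1] = ap
    return ds.with_representation(
        representation,
        arr.with_features({ANGLE_V: angle_v, ANGLE_P: angle_p}),
        "angles",
        representation=representation,
    )
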