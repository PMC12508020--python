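"""Trial-level trajectory indices: curvature, complexity, temporal.

Curvature is measured against the idealized trajectory — the straight segment
from a trial's first to last point.  Pointwise deviations are signed
perpendicular distances to that line, positive toward the nonchosen side
(the side opposite the endpoint; positive x after left-remapping).

Complexity covers x/y flips (direction changes along an axis), midline
reversals, and sample entropy.  Temporal indices decompose response time into
movement time and idle time, with initiation time the idle span before
movement onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import RAW, TIMESTAMPS, XPOS, YPOS, TrackingDataset
from .kinematics import ACC, VEL

log = logging.getLogger("reachtrace")

#: the eleven standard indices of the correlation report
CURVATURE_INDICES = ["MAD", "MD_above", "AD", "AUC"]
COMPLEXITY_INDICES = ["x_flips", "x_reversals", "sample_entropy"]
TEMPORAL_INDICES = ["RT", "initiation_time", "idle_time", "movement_time"]


def signed_deviations(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Signed perpendicular deviations of ``(L, 2)`` x/y points from the chord.

    Returns ``(dev, length)`` where positive deviation points toward the
    nonchosen side: after left-remapping the endpoint lies at negative x, and
    deviations toward positive x are positive.  ``length`` is the chord length
    (0 if start and end coincide).
    """
    start, end = points[0], points[-1]
    d = end - start
    length = float(np.hypot(*d))
    if length == 0:
        return np.full(len(points), np.nan), 0.0
    rel = points - start
    cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
    factor = 1.0 if d[0] > 0 else -1.0  # endpoint left (or straight up) -> -1
    return factor * cross / length, length


def _shoelace(points: np.ndarray) -> float:
    """Signed shoelace area of the closed polygon through ``points``."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _count_sign_changes(values: np.ndarray) -> int:
    """Sign alternations in a sequence after dropping zeros."""
    s = np.sign(values)
    s = s[s != 0]
    return int(np.sum(s[1:] != s[:-1])) if len(s) > 1 else 0


def _flips(positions: np.ndarray, threshold: float) -> int:
    """Direction changes along one axis, ignoring deltas with |d| <= threshold."""
    deltas = np.diff(positions)
    deltas = deltas[np.abs(deltas) > threshold]
    return _count_sign_changes(deltas)


def compute_measures(
    ds: TrackingDataset,
    representation: str = RAW,
    flip_threshold: float = 0.0,
    initiation_at_movement: bool = False,
    jitter_tolerance: float = 0.0,
) -> pd.DataFrame:
    """Compute the standard trial-level indices for one representation.

    Returns one row per trial with curvature (MAD, MAD_time, MD_above, AD,
    AUC), complexity (x_flips, y_flips, x_reversals) and temporal indices
    (RT, initiation_time, idle_time, movement_time, motor_pauses), plus
    vel_max/acc_max when kinematic channels are present.

    ``initiation_at_movement`` switches initiation time from the timestamp of
    the last still sample before movement onset (default) to the first moved
    sample's timestamp.  ``jitter_tolerance`` treats displacements up to that
    many px as stillness for the temporal decomposition.
    """
    arr = ds.get(representation)
    ti = arr.feature_index(TIMESTAMPS)
    xi = arr.feature_index(XPOS)
    yi = arr.feature_index(YPOS)
    has_kin = VEL in arr.feature_names
    rows = []
    for i in range(arr.n_trials):
        L = arr.valid_length[i]
        t = arr.values[i, :L, ti]
        x = arr.values[i, :L, xi]
        y = arr.values[i, :L, yi]
        pts = np.column_stack([x, y])
        row: dict = {"trial_id": arr.trial_ids[i]}

        # curvature ------------------------------------------------------
        dev, chord = signed_deviations(pts)
        if chord == 0:
            log.warning("trial %r: coincident start/end, curvature undefined",
                        arr.trial_ids[i])
            row.update(MAD=np.nan, MAD_time=np.nan, MD_above=np.nan,
                       AD=np.nan, AUC=np.nan)
        else:
            k = int(np.argmax(np.abs(dev)))  # argmax takes the earliest tie
            row["MAD"] = dev[k]
            row["MAD_time"] = t[k]
            row["MD_above"] = max(0.0, float(dev.max()))
            row["AD"] = float(dev.mean())
            factor = 1.0 if (x[-1] - x[0]) > 0 else -1.0
            row["AUC"] = -factor * _shoelace(pts)

        # complexity -----------------------------------------------------
        row["x_flips"] = _flips(x, flip_threshold)
        row["y_flips"] = _flips(y, flip_threshold)
        row["x_reversals"] = _count_sign_changes(x - x[0])

        # temporal -------------------------------------------------------
        step = np.hypot(np.diff(x), np.diff(y))
        moving = step > jitter_tolerance
        rt = float(t[-1] - t[0])
        movement_time = float(np.sum(np.diff(t)[moving]))
        idle_time = rt - movement_time
        if moving.any():
            first_move = int(np.argmax(moving))  # interval index
            # default: timestamp of the last still sample before onset
            initiation = float(t[first_move + (1 if initiation_at_movement else 0)])
        else:
            first_move = None
            initiation = rt
        row.update(
            RT=rt,
            movement_time=movement_time,
            idle_time=idle_time,
            initiation_time=initiation,
            motor_pauses=idle_time - initiation,
        )
        if has_kin:
            vel = arr.values[i, :L, arr.feature_index(VEL)]
            acc = arr.values[i, :L, arr.feature_index(ACC)]
            row["vel_max"] = np.nanmax(vel) if np.isfinite(vel).any() else np.nan
            row["acc_max"] = np.nanmax(acc) if np.isfinite(acc).any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sample entropy


@dataclass
class SampleEntropyParams:
    """Parameters of the sample-entropy estimator.

    m is the template length, r the match tolerance (default 0.2 x SD of the
    analyzed series), matching uses Chebyshev distance at lag 1, and
    self-matches are excluded.
    """

    m: int = 3
    r: float | None = None  # None -> 0.2 * SD of the series

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r is not None and self.r < 0:
            raise ValueError("r must be nonnegative")


def sample_entropy(series: np.ndarray, params: SampleEntropyParams | None = None) -> float:
    """SampEn = -ln(A/B) with template counts at lengths m+1 (A) and m (B).

    Both counts run over the same template start indices (0 .. N-m-2) so that
    a strictly periodic series yields exactly 0.  Returns NaN with a warning
    when either count is zero.
    """
    params = params or SampleEntropyParams()
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    m = params.m
    if n < m + 2:
        raise ValueError(f"series too short for sample entropy (need > {m + 1} points)")
    r = params.r if params.r is not None else 0.2 * float(np.std(x, ddof=1))
    n_templates = n - m  # start indices 0 .. n-m-1 for (m+1)-length templates
    tpl = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:n_templates]
    # Chebyshev distances between all ordered template pairs
    diff = np.abs(tpl[:, None, :] - tpl[None, :, :])
    d_m = diff[:, :, :m].max(axis=2)
    d_m1 = diff.max(axis=2)
    off = ~np.eye(n_templates, dtype=bool)
    B = int(np.sum((d_m <= r) & off))
    A = int(np.sum((d_m1 <= r) & off))
    if A == 0 or B == 0:
        log.warning("sample_entropy: no template matches (A=%d, B=%d)", A, B)
        return float("nan")
    return float(-np.log(A / B)) + 0.0  # +0.0 normalizes -0.0


def add_sample_entropy(
    ds: TrackingDataset,
    measures: pd.DataFrame,
    representation: str = "tn_trajectories",
    feature: str = XPOS,
    params: SampleEntropyParams | None = None,
) -> pd.DataFrame:
    """Append a per-trial sample-entropy column computed on one channel.

    Defaults to the x positions of the time-normalized representation.
    """
    arr = ds.get(representation)
    fi = arr.feature_index(feature)
    ent = {
        arr.trial_ids[i]: sample_entropy(
            arr.values[i, : arr.valid_length[i], fi], params
        )
        for i in range(arr.n_trials)
    }
    out = measures.copy()
    out["sample_entropy"] = out["trial_id"].map(ent)
    return out


# ---------------------------------------------------------------------------
# standardization / aggregation / correlation report


def standardize(
    table: pd.DataFrame,
    variables: list[str],
    within: str | None = None,
    suffix: str = "_z",
) -> pd.DataFrame:
    """Z-score columns, optionally within groups (e.g. per subject).

    Zero-SD groups yield NaN with a warning.  Standardizing an already
    standardized column is a no-op up to floating error.
    """
    out = table.copy()
    for v in variables:
        if within is None:
            grouped = [(None, out)]
        else:
            grouped = out.groupby(within, dropna=False)
        z = pd.Series(np.nan, index=out.index, dtype=float)
        for _, grp in grouped:
            vals = grp[v].astype(float)
            sd = vals.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                log.warning("standardize: zero or undefined SD for %r", v)
                continue
            z.loc[grp.index] = (vals - vals.mean()) / sd
        out[v + suffix] = z
    return out


def aggregate(
    table: pd.DataFrame,
    use_variables: list[str],
    group_by: list[str],
    subject_id: str | None = None,
) -> pd.DataFrame:
    """Arithmetic-mean aggregation of index columns within groups.

    When ``subject_id`` is given, values are first averaged within subject
    (per group) and then the subject means are averaged — i.e. the result is
    the unweighted mean of subject means, not the pooled trial mean.
    """
    present = [g for g in group_by if g in table.columns]
    if len(present) != len(group_by):
        raise KeyError(f"missing grouping columns: {set(group_by) - set(present)}")
    if subject_id is not None:
        per_subj = (
            table.groupby(group_by + [subject_id], dropna=False)[use_variables]
            .mean()
            .reset_index()
        )
        return per_subj.groupby(group_by, dropna=False)[use_variables].mean().reset_index()
    return table.groupby(group_by, dropna=False)[use_variables].mean().reset_index()


def index_correlation_report(
    measures: pd.DataFrame,
    indices: list[str] | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Pairwise-complete correlation matrix over the trajectory indices.

    ``method`` is ``pearson`` or ``spearman``; constant columns give NaN
    entries with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if indices is None:
        standard = CURVATURE_INDICES + COMPLEXITY_INDICES + TEMPORAL_INDICES
        indices = [c for c in standard if c in measures.columns]
    sub = measures[indices].astype(float)
    if len(sub.dropna()) < 3:
        raise ValueError("need at least 3 complete rows for a correlation report")
    constant = [c for c in indices if sub[c].nunique(dropna=True) <= 1]
    if constant:
        log.warning("index_correlation_report: constant columns %s", constant)
    return sub.corr(method=method, min_periods=3)
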