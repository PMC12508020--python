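"""Type-based trajectory analysis.

Trajectories of two-option reach tasks tend to fall into discrete movement
types — straight approaches, curved pulls toward the competing option, and
continuous or discrete changes of mind.  This module provides both routes to
a type assignment: bottom-up agglomerative clustering of a pointwise
Euclidean distance matrix, and top-down mapping onto a canonical prototype
set, plus the nominal (chi-square) and ordinal statistical exports for
comparing type frequencies between conditions.

The distance between two trajectories is the summed pointwise Euclidean
distance ``d_ij = sum_k sqrt((x_ik - x_jk)^2 + (y_ik - y_jk)^2)`` over a
common number of points, which requires a length-normalized representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .dataset import LENGTH_NORMALIZED, TIMESTAMPS, XPOS, YPOS, TrackingDataset

log = logging.getLogger("reachtrace")

#: canonical type labels ordered by the level of response competition
TYPE_ORDER = ["straight", "curved", "cCoM", "dCoM", "dCoM2"]


@dataclass
class Prototype:
    label: str
    rank: int
    polyline: np.ndarray  # (k, 2) control vertices in unit space


@dataclass
class PrototypeSet:
    """Ordered, labeled reference polylines in unit space.

    Unit space runs from the start (0, 0) to the chosen option's end
    (-1, 1.5); the nonchosen side is positive x.  Ranks form a strict total
    order by increasing response competition.
    """

    entries: list[Prototype] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [p.label for p in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("prototype labels must be unique")
        for p in self.entries:
            if not np.allclose(p.polyline[0], (0.0, 0.0)) or not np.allclose(
                p.polyline[-1], (-1.0, 1.5)
            ):
                raise ValueError(
                    f"prototype {p.label!r} must run from (0,0) to (-1,1.5)"
                )

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.entries]

    def rank_of(self, label: str) -> int:
        for p in self.entries:
            if p.label == label:
                return p.rank
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.entries:
            for i, (x, y) in enumerate(p.polyline):
                rows.append({"label": p.label, "rank": p.rank, "vertex": i,
                             "x": x, "y": y})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PrototypeSet":
        entries = []
        for label, grp in df.groupby("label", sort=False):
            grp = grp.sort_values("vertex")
            entries.append(Prototype(label, int(grp["rank"].iloc[0]),
                                     grp[["x", "y"]].to_numpy(dtype=float)))
        entries.sort(key=lambda p: p.rank)
        return cls(entries)


def _quad_bezier(p0, p1, p2, n=21):
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * np.asarray(p0) + 2 * (1 - t) * t * np.asarray(p1) \
        + t**2 * np.asarray(p2)


def _cubic_bezier(p0, p1, p2, p3, n=21):
    t = np.linspace(0.0, 1.0, n)[:, None]
    return ((1 - t) ** 3 * np.asarray(p0) + 3 * (1 - t) ** 2 * t * np.asarray(p1)
            + 3 * (1 - t) * t**2 * np.asarray(p2) + t**3 * np.asarray(p3))


def standard_prototypes() -> PrototypeSet:
    """The package's canonical five-prototype set.

    In unit space (start (0,0), chosen end (-1, 1.5), nonchosen side +x):

    - ``straight`` — direct segment to the chosen option.
    - ``curved`` — quadratic arc bulging toward the nonchosen side, passing
      (+0.25, 0.75) at its midpoint.
    - ``cCoM`` — continuous change of mind: a smooth sweep reaching
      (+0.6, 0.9) toward the nonchosen option before turning to the chosen.
    - ``dCoM`` — discrete change of mind: straight to the nonchosen corner
      (+1, 1.5), then straight across to the chosen corner.
    - ``dCoM2`` — discrete double change of mind: toward the chosen side,
      back toward the nonchosen corner, then across to the chosen corner.

    The exact vertices are this package's own canonical choice; the set is
    fully overridable wherever a PrototypeSet is accepted.
    """
    curved = _quad_bezier((0, 0), (1.0, 0.75), (-1, 1.5))
    ccom = _cubic_bezier((0, 0), (1.0, 0.55), (0.9333, 1.35), (-1, 1.5))
    entries = [
        Prototype("straight", 1, np.array([(0.0, 0.0), (-1.0, 1.5)])),
        Prototype("curved", 2, curved),
        Prototype("cCoM", 3, ccom),
        Prototype("dCoM", 4, np.array([(0.0, 0.0), (1.0, 1.5), (-1.0, 1.5)])),
        Prototype("dCoM2", 5, np.array(
            [(0.0, 0.0), (-0.5, 0.75), (0.7, 1.3), (-1.0, 1.5)])),
    ]
    return PrototypeSet(entries)


# ---------------------------------------------------------------------------
# distances and clustering


def _xy_stack(ds: TrackingDataset, representation: str) -> np.ndarray:
    """All trials' x/y points as one ``(n, points, 2)`` array (equal lengths)."""
    arr = ds.get(representation)
    if len(np.unique(arr.valid_length)) != 1:
        raise ValueError(
            "trials have unequal point counts; resample first "
            "(length normalization is the conventional choice)"
        )
    L = int(arr.valid_length[0])
    xi = arr.feature_index(XPOS)
    yi = arr.feature_index(YPOS)
    return np.stack([arr.values[:, :L, xi], arr.values[:, :L, yi]], axis=2)


def distance_matrix(ds: TrackingDataset, representation: str = LENGTH_NORMALIZED) -> pd.DataFrame:
    """Pointwise Euclidean distance matrix over all trial pairs.

    Returns a symmetric DataFrame indexed by trial_id with zero diagonal.
    """
    xy = _xy_stack(ds, representation)
    ids = ds.get(representation).trial_ids
    # sum_k ||P_ik - P_jk|| for all pairs; loop over points to bound memory
    n = xy.shape[0]
    dm = np.zeros((n, n))
    for k in range(xy.shape[1]):
        diff = xy[:, None, k, :] - xy[None, :, k, :]
        dm += np.hypot(diff[:, :, 0], diff[:, :, 1])
    np.fill_diagonal(dm, 0.0)
    return pd.DataFrame(dm, index=ids, columns=ids)


@dataclass
class TypeAssignment:
    """Per-trial type label with distances.

    ``table`` columns: trial_id, label, distance (to the assigned prototype
    or cluster mean), z_distance (standardized within label).
    """

    table: pd.DataFrame
    means: dict[str, np.ndarray] = field(default_factory=dict)

    def counts(self) -> pd.Series:
        return self.table["label"].value_counts()


def _add_z(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    table["z_distance"] = np.nan
    for label, grp in table.groupby("label", dropna=True):
        sd = grp["distance"].std(ddof=1)
        if np.isfinite(sd) and sd > 0:
            table.loc[grp.index, "z_distance"] = (
                grp["distance"] - grp["distance"].mean()
            ) / sd
    return table


def cluster_hierarchical(
    source: TrackingDataset | pd.DataFrame,
    representation: str = LENGTH_NORMALIZED,
    n_clusters: int = 5,
    ds: TrackingDataset | None = None,
) -> TypeAssignment:
    """Bottom-up typing: agglomerative clustering of the distance matrix.

    Uses Ward linkage on the pointwise-Euclidean distances (the Lance-
    Williams Ward recursion applied to the distances as given, obtained by
    handing their square roots to scipy's ward linkage).  Cluster labels are
    ``"1"``, ``"2"``, ... ordered by descending cluster size; each trial's
    distance is its pointwise distance to its cluster's mean trajectory.
    The partition depends only on the distance matrix, so permuting trial
    order permutes labels but not the grouping.
    """
    if isinstance(source, TrackingDataset):
        ds = source
        dm = distance_matrix(ds, representation)
    else:
        dm = source
        if ds is None:
            raise ValueError("pass the dataset as ds= when supplying a distance matrix")
    n = len(dm)
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if n_clusters > n:
        raise ValueError("more clusters than trials")
    condensed = squareform(dm.to_numpy(), checks=False)
    Z = linkage(np.sqrt(condensed), method="ward")
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")

    xy = _xy_stack(ds, representation)
    ids = list(dm.index)
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    relabel = {c: str(i + 1) for i, c in enumerate(order)}
    labels = [relabel[c] for c in raw]
    means = {
        lab: xy[np.array(labels) == lab].mean(axis=0) for lab in set(labels)
    }
    dist = [
        float(np.hypot(*(xy[i] - means[labels[i]]).T).sum()) for i in range(n)
    ]
    table = _add_z(pd.DataFrame({"trial_id": ids, "label": labels, "distance": dist}))
    return TypeAssignment(table, means)


def map_to_prototypes(
    ds: TrackingDataset,
    representation: str = LENGTH_NORMALIZED,
    prototypes: PrototypeSet | None = None,
    n_points: int = 20,
) -> TypeAssignment:
    """Top-down typing: assign each trial to its closest prototype.

    Each prototype is rescaled per trial by the per-axis affine map sending
    the unit-space start/end to the trial's start/end, both curves are
    length-normalized to ``n_points``, and the trial takes the label of the
    prototype with the smallest pointwise Euclidean distance (ties go to the
    lowest rank).  Trials with coincident start and end points cannot anchor
    the rescaling and stay unassigned (with a warning).
    """
    from .preprocess import _resample_trial, ResampleSpec

    prototypes = prototypes or standard_prototypes()
    arr = ds.get(representation)
    xi = arr.feature_index(XPOS)
    yi = arr.feature_index(YPOS)
    spec = ResampleSpec("length_normalized", n_points=n_points)

    rows = []
    n_unassigned = 0
    for i in range(arr.n_trials):
        L = arr.valid_length[i]
        pts = np.column_stack(
            [np.linspace(0, 1, L), arr.values[i, :L, xi], arr.values[i, :L, yi]]
        )
        traj = _resample_trial(pts, 0, spec)[:, 1:]
        start, end = traj[0], traj[-1]
        if np.allclose(start, end):
            n_unassigned += 1
            rows.append({"trial_id": arr.trial_ids[i], "label": None,
                         "distance": np.nan})
            continue
        best_label, best_dist = None, np.inf
        for p in prototypes.entries:
            # rescale the control polyline itself, then length-normalize in
            # trial space: corners survive the anisotropic scaling exactly
            scaled = np.empty_like(p.polyline)
            scaled[:, 0] = start[0] + p.polyline[:, 0] / -1.0 * (end[0] - start[0])
            scaled[:, 1] = start[1] + p.polyline[:, 1] / 1.5 * (end[1] - start[1])
            curve = _resample_trial(
                np.column_stack([np.linspace(0, 1, len(scaled)), scaled]), 0, spec
            )[:, 1:]
            d = float(np.hypot(*(traj - curve).T).sum())
            if d < best_dist - 1e-12:
                best_label, best_dist = p.label, d
        rows.append({"trial_id": arr.trial_ids[i], "label": best_label,
                     "distance": best_dist})
    if n_unassigned:
        log.warning("map_to_prototypes: %d trials with coincident start/end "
                    "left unassigned", n_unassigned)
    return TypeAssignment(_add_z(pd.DataFrame(rows)))


# ---------------------------------------------------------------------------
# frequency statistics


@dataclass
class FrequencyTestResult:
    """Chi-square test of stochastic independence on a contingency table."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    df: int
    p: float
    pearson_residuals: pd.DataFrame


def type_frequency_table(
    assignment: TypeAssignment,
    trial_table: pd.DataFrame,
    group: str,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Observed group x label count table (rows: groups, columns: labels)."""
    merged = trial_table[["trial_id", group]].merge(
        assignment.table[["trial_id", "label"]], on="trial_id"
    )
    merged = merged.dropna(subset=["label"])
    table = pd.crosstab(merged[group], merged["label"])
    if labels is not None:
        table = table.reindex(columns=[l for l in labels if l in table.columns])
    return table


def chi_square_independence(observed: pd.DataFrame) -> FrequencyTestResult:
    """Pearson chi-square test without continuity correction.

    ``E_rc = row_total * col_total / grand_total``; the statistic is
    ``sum (O - E)^2 / E`` with ``df = (R - 1)(C - 1)``, and the Pearson
    residuals ``(O - E) / sqrt(E)`` satisfy ``sum(residuals^2) == chi2``.
    """
    O = observed.astype(float)
    if O.shape[0] < 2 or O.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (O.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    row = O.sum(axis=1).to_numpy()
    col = O.sum(axis=0).to_numpy()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero row or column total")
    total = O.to_numpy().sum()
    E = np.outer(row, col) / total
    resid = (O.to_numpy() - E) / np.sqrt(E)
    chi2 = float((resid**2).sum())
    dof = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, dof))
    return FrequencyTestResult(
        observed=O,
        expected=pd.DataFrame(E, index=O.index, columns=O.columns),
        chi2=chi2,
        df=dof,
        p=p,
        pearson_residuals=pd.DataFrame(resid, index=O.index, columns=O.columns),
    )


def ordinal_export(
    assignment: TypeAssignment,
    prototypes: PrototypeSet | None = None,
    trial_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tidy table with the competition rank of each assigned trial.

    Ready for external ordinal regression: trial_id, label, rank (1 =
    straight ... 5 = dCoM2 for the standard set), plus any trial covariates.
    """
    prototypes = prototypes or standard_prototypes()
    out = assignment.table.dropna(subset=["label"])[["trial_id", "label"]].copy()
    out["rank"] = [prototypes.rank_of(l) for l in out["label"]]
    if trial_table is not None:
        out = out.merge(trial_table, on="trial_id", how="left")
    return out.reset_index(drop=True)
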