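"""Core data containers for movement-tracking datasets.

A movement-tracking dataset couples a trial-level metadata table with one or
more named trajectory-array representations (raw, time-normalized,
length-normalized, ...).  Trajectories are stored as a dense 3-D float array
``(trial, point, feature)`` padded with NaN beyond each trial's valid length,
so trials of different durations share one array.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: canonical feature names present after import
TIMESTAMPS = "timestamps"
XPOS = "xpos"
YPOS = "ypos"

#: conventional representation names
RAW = "trajectories"
TIME_NORMALIZED = "tn_trajectories"
LENGTH_NORMALIZED = "ln_trajectories"


@dataclass
class TrajectoryArray:
    """N trials x M points x F features, NaN-padded beyond ``valid_length``.

    Parameters
    ----------
    values
        ``(n_trials, max_points, n_features)`` float array.  Cells beyond a
        trial's valid length are NaN (padding is never zero: zero is a legal
        coordinate).
    trial_ids
        Ordered trial keys matching the trial table.
    feature_names
        Ordered labels for the last axis; minimally ``timestamps`` (ms),
        ``xpos`` (px) and ``ypos`` (px).
    valid_length
        Number of real (non-padding) points per trial.
    """

    values: np.ndarray
    trial_ids: list[str]
    feature_names: list[str]
    valid_length: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_length = np.asarray(self.valid_length, dtype=int)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D (trial, point, feature) array")
        n, m, f = self.values.shape
        if len(self.trial_ids) != n:
            raise ValueError("trial_ids length does not match first axis")
        if len(self.feature_names) != f:
            raise ValueError("feature_names length does not match last axis")
        if self.valid_length.shape != (n,):
            raise ValueError("valid_length must have one entry per trial")
        if np.any(self.valid_length < 0) or np.any(self.valid_length > m):
            raise ValueError("valid_length out of range")

    # -- basic queries -----------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def max_points(self) -> int:
        return self.values.shape[1]

    def feature_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise KeyError(
                f"feature {name!r} not present; available: {self.feature_names}"
            ) from None

    def feature(self, name: str) -> np.ndarray:
        """Return the ``(n_trials, max_points)`` slab for one feature."""
        return self.values[:, :, self.feature_index(name)]

    def trial(self, trial_id: str) -> pd.DataFrame:
        """Return one trial's valid points as a DataFrame (feature columns)."""
        i = self.trial_ids.index(trial_id)
        L = self.valid_length[i]
        return pd.DataFrame(self.values[i, :L, :], columns=self.feature_names)

    def trial_values(self, i: int) -> np.ndarray:
        """Valid ``(L, F)`` block for trial at positional index ``i``."""
        return self.values[i, : self.valid_length[i], :]

    # -- construction helpers ---------------------------------------------

    @classmethod
    def from_trials(
        cls,
        trials: Sequence[np.ndarray],
        trial_ids: Sequence[str],
        feature_names: Sequence[str],
    ) -> "TrajectoryArray":
        """Stack per-trial ``(L_i, F)`` arrays into one padded array."""
        n = len(trials)
        f = len(feature_names)
        lengths = np.array([t.shape[0] for t in trials], dtype=int)
        m = int(lengths.max()) if n else 0
        values = np.full((n, m, f), np.nan)
        for i, t in enumerate(trials):
            values[i, : lengths[i], :] = t
        return cls(values, list(trial_ids), list(feature_names), lengths)

    def with_features(
        self, new_values: Mapping[str, np.ndarray]
    ) -> "TrajectoryArray":
        """Return a copy with extra feature slabs appended (NaN padded)."""
        slabs = [self.values]
        names = list(self.feature_names)
        pad = np.arange(self.max_points)[None, :] >= self.valid_length[:, None]
        for name, slab in new_values.items():
            if name in names:
                raise ValueError(f"feature {name!r} already present")
            slab = np.asarray(slab, dtype=float).copy()
            slab[pad] = np.nan
            slabs.append(slab[:, :, None])
            names.append(name)
        return TrajectoryArray(
            np.concatenate(slabs, axis=2),
            list(self.trial_ids),
            names,
            self.valid_length.copy(),
        )

    def take(self, indices: np.ndarray) -> "TrajectoryArray":
        """Subset trials by positional index, trimming padding."""
        indices = np.asarray(indices, dtype=int)
        lengths = self.valid_length[indices]
        m = int(lengths.max()) if len(indices) else 0
        return TrajectoryArray(
            self.values[indices, :m, :].copy(),
            [self.trial_ids[i] for i in indices],
            list(self.feature_names),
            lengths,
        )

    def copy(self) -> "TrajectoryArray":
        return TrajectoryArray(
            self.values.copy(),
            list(self.trial_ids),
            list(self.feature_names),
            self.valid_length.copy(),
        )


@dataclass
class TrackingDataset:
    """Trial table plus named trajectory representations plus provenance.

    ``trial_table`` has one row per trial, a unique non-empty ``trial_id``
    column, and arbitrary covariate columns.  All representations share the
    trial_id set of the trial table.  ``provenance`` is an append-only list of
    ``(operation, parameters, timestamp)`` records; operations never mutate a
    dataset in place — they return a new container.
    """

    trial_table: pd.DataFrame
    representations: dict[str, TrajectoryArray] = field(default_factory=dict)
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "trial_id" not in self.trial_table.columns:
            raise ValueError("trial_table must have a trial_id column")
        ids = self.trial_table["trial_id"]
        if ids.duplicated().any() or (ids.astype(str) == "").any():
            raise ValueError("trial_id values must be unique and non-empty")
        id_set = set(ids)
        for name, arr in self.representations.items():
            if set(arr.trial_ids) != id_set:
                raise ValueError(
                    f"representation {name!r} trial ids do not match trial_table"
                )

    # -- provenance --------------------------------------------------------

    def _logged(self, operation: str, **parameters) -> "TrackingDataset":
        rec = {
            "operation": operation,
            "parameters": parameters,
            "timestamp": _dt.datetime.now().isoformat(timespec="seconds"),
        }
        return TrackingDataset(
            self.trial_table,
            dict(self.representations),
            self.provenance + [rec],
        )

    def with_representation(
        self, name: str, arr: TrajectoryArray, operation: str, **parameters
    ) -> "TrackingDataset":
        """Return a new dataset with ``name`` set/replaced, logging one record."""
        ds = self._logged(operation, save_as=name, **parameters)
        ds.representations[name] = arr
        return ds

    def with_trial_table(
        self, table: pd.DataFrame, operation: str, **parameters
    ) -> "TrackingDataset":
        ds = self._logged(operation, **parameters)
        ds.trial_table = table
        return ds

    # -- queries -----------------------------------------------------------

    @property
    def trial_ids(self) -> list[str]:
        return list(self.trial_table["trial_id"])

    @property
    def n_trials(self) -> int:
        return len(self.trial_table)

    def get(self, representation: str) -> TrajectoryArray:
        try:
            return self.representations[representation]
        except KeyError:
            raise KeyError(
                f"unknown representation {representation!r}; "
                f"available: {sorted(self.representations)}"
            ) from None

    def select_ids(self, keep_ids: Iterable[str], operation: str, **parameters):
        """Subset every representation and the trial table to ``keep_ids``."""
        keep = [tid for tid in self.trial_ids if tid in set(keep_ids)]
        if not keep:
            raise ValueError("subset would remove all trials")
        table = (
            self.trial_table[self.trial_table["trial_id"].isin(keep)]
            .reset_index(drop=True)
        )
        reps = {}
        for name, arr in self.representations.items():
            pos = [arr.trial_ids.index(tid) for tid in keep]
            reps[name] = arr.take(np.array(pos, dtype=int))
        removed = self.n_trials - len(keep)
        rec = {
            "operation": operation,
            "parameters": {**parameters, "removed": removed},
            "timestamp": _dt.datetime.now().isoformat(timespec="seconds"),
        }
        return TrackingDataset(table, reps, self.provenance + [rec])
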