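"""Import/export of trajectory logs in long and wide tabular formats.

Long format stacks samples in rows (one identifier tuple per trial); wide
format stores each trial in one row with column groups per feature
(``xpos_1 ... xpos_M``, 1-based).  Both importers produce the same
:class:`~reachtrace.dataset.TrackingDataset`; timestamps are shifted so each
trial starts at 0 (the offset is recorded in provenance).
"""

from __future__ import annotations

import glob as _glob
import logging
import os
import re
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import RAW, TIMESTAMPS, XPOS, YPOS, TrackingDataset, TrajectoryArray

log = logging.getLogger("reachtrace")


def _join_id(values) -> str:
    return "_".join(str(v) for v in values)


def import_long(
    table: pd.DataFrame,
    id_columns: Sequence[str],
    time_col: str = TIMESTAMPS,
    x_col: str = XPOS,
    y_col: str = YPOS,
    screen_y_down: bool = False,
) -> TrackingDataset:
    """Build a dataset from a long-format table (one sample per row).

    ``id_columns`` jointly identify a trial; their values are joined with
    ``"_"`` to form ``trial_id``.  Within a trial, rows are sorted by time,
    duplicate timestamps keep the first row (logged), and rows with a missing
    coordinate are rejected with a logged count.  Columns constant within
    every trial are moved to the trial table.  ``screen_y_down=True`` negates
    y at the boundary for screen coordinate systems with y growing downward.
    """
    if not id_columns:
        raise ValueError("at least one id column is required")
    table = table.copy()
    for c in list(id_columns) + [time_col, x_col, y_col]:
        if c not in table.columns:
            raise ValueError(f"column {c!r} not in table")
    if not np.issubdtype(pd.to_numeric(table[time_col], errors="coerce").dtype, np.number):
        raise ValueError("time column must be numeric")

    bad = table[x_col].isna() | table[y_col].isna()
    if bad.any():
        log.warning("import_long: rejected %d rows with missing coordinates", int(bad.sum()))
    table = table[~bad]

    sample_cols = [time_col, x_col, y_col]
    meta_cols = [c for c in table.columns if c not in sample_cols]

    trials: list[np.ndarray] = []
    trial_ids: list[str] = []
    meta_rows: list[dict] = []
    n_dup = 0
    for key, grp in table.groupby(list(id_columns), sort=False, dropna=False):
        if not isinstance(key, tuple):
            key = (key,)
        if len(grp) < 2:
            raise ValueError(f"trial {_join_id(key)!r} has fewer than 2 samples")
        grp = grp.sort_values(time_col, kind="mergesort")
        dup = grp[time_col].duplicated()
        if dup.any():
            n_dup += int(dup.sum())
            grp = grp[~dup]
        t = grp[time_col].to_numpy(dtype=float)
        x = grp[x_col].to_numpy(dtype=float)
        y = grp[y_col].to_numpy(dtype=float)
        if screen_y_down:
            y = -y
        trials.append(np.column_stack([t - t[0], x, y]))
        trial_ids.append(_join_id(key))
        row = {"trial_id": trial_ids[-1], "_t_offset": t[0]}
        for c in meta_cols:
            vals = grp[c].drop_duplicates()
            if len(vals) == 1:
                row[c] = vals.iloc[0]
        meta_rows.append(row)
    if n_dup:
        log.warning("import_long: dropped %d duplicate-timestamp rows (kept first)", n_dup)

    trial_table = pd.DataFrame(meta_rows)
    offsets = trial_table.pop("_t_offset")
    arr = TrajectoryArray.from_trials(trials, trial_ids, [TIMESTAMPS, XPOS, YPOS])
    ds = TrackingDataset(trial_table, {RAW: arr})
    return ds._logged(
        "import_long",
        id_columns=list(id_columns),
        n_trials=len(trial_ids),
        time_offsets=dict(zip(trial_ids, offsets.tolist())),
        screen_y_down=screen_y_down,
    )


def import_wide(
    table: pd.DataFrame,
    id_column: str = "trial_id",
    prefixes: Sequence[str] = (TIMESTAMPS, XPOS, YPOS),
    sep: str = "_",
    screen_y_down: bool = False,
) -> TrackingDataset:
    """Build a dataset from a wide-format table (one trial per row).

    Feature columns follow the ``prefix_sep_index`` dialect with 1-based
    indices (``xpos_1 ... xpos_M``).  Trailing empty cells become padding;
    ``valid_length`` counts the filled coordinate cells.  Ragged feature
    groups within one trial raise an error naming the trial.
    """
    pat = {p: re.compile(rf"^{re.escape(p)}{re.escape(sep)}(\d+)$") for p in prefixes}
    cols: dict[str, list[tuple[int, str]]] = {p: [] for p in prefixes}
    for c in table.columns:
        for p, rgx in pat.items():
            m = rgx.match(str(c))
            if m:
                cols[p].append((int(m.group(1)), c))
    for p in prefixes:
        if not cols[p]:
            raise ValueError(f"no columns found for feature prefix {p!r}")
        cols[p].sort()

    meta_cols = [
        c for c in table.columns if not any(rgx.match(str(c)) for rgx in pat.values())
    ]
    if id_column not in table.columns:
        table = table.copy()
        table[id_column] = [str(i + 1) for i in range(len(table))]
        meta_cols = [id_column] + meta_cols

    trials, trial_ids = [], []
    for _, row in table.iterrows():
        tid = str(row[id_column])
        feats = {}
        lengths = set()
        for p in prefixes:
            v = pd.to_numeric(
                pd.Series([row[c] for _, c in cols[p]]), errors="coerce"
            ).to_numpy(dtype=float)
            n_valid = int((~np.isnan(v)).sum())
            if np.isnan(v[:n_valid]).any():
                raise ValueError(f"trial {tid!r}: interior missing cells in {p!r}")
            feats[p] = v[:n_valid]
            lengths.add(n_valid)
        if len(lengths) != 1:
            raise ValueError(
                f"trial {tid!r}: ragged feature groups (lengths {sorted(lengths)})"
            )
        t = feats[prefixes[0]]
        x = feats[prefixes[1]]
        y = -feats[prefixes[2]] if screen_y_down else feats[prefixes[2]]
        trials.append(np.column_stack([t - t[0], x, y]))
        trial_ids.append(tid)

    trial_table = table[meta_cols].copy()
    trial_table["trial_id"] = [str(v) for v in trial_table[id_column]]
    if id_column != "trial_id":
        trial_table = trial_table.drop(columns=[id_column])
    trial_table = trial_table[
        ["trial_id"] + [c for c in trial_table.columns if c != "trial_id"]
    ].reset_index(drop=True)
    arr = TrajectoryArray.from_trials(trials, trial_ids, [TIMESTAMPS, XPOS, YPOS])
    ds = TrackingDataset(trial_table, {RAW: arr})
    return ds._logged("import_wide", n_trials=len(trial_ids), screen_y_down=screen_y_down)


def read_folder(dir_path: str, pattern: str = "*.csv", **read_csv_kwargs) -> pd.DataFrame:
    """Row-concatenate all matching delimited files, adding a ``source`` column.

    Columns are unioned; cells absent from a file are left missing.
    """
    paths = sorted(_glob.glob(os.path.join(dir_path, pattern)))
    if not paths:
        raise FileNotFoundError(f"no files matching {pattern!r} in {dir_path!r}")
    frames = []
    for p in paths:
        try:
            df = pd.read_csv(p, **read_csv_kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrap with the file name
            raise ValueError(f"could not read {p!r}: {exc}") from exc
        df["source"] = os.path.basename(p)
        frames.append(df)
    return pd.concat(frames, ignore_index=True, sort=False)


def subset(ds: TrackingDataset, predicate) -> TrackingDataset:
    """Select trials by a pandas query expression or an explicit id list.

    All representations are filtered consistently; provenance records the
    predicate and the number of removed trials.  Removing every trial is an
    error (an empty dataset is unusable).
    """
    if isinstance(predicate, str):
        keep = ds.trial_table.query(predicate)["trial_id"].tolist()
        desc = predicate
    else:
        keep = [str(tid) for tid in predicate]
        missing = set(keep) - set(ds.trial_ids)
        if missing:
            raise KeyError(f"unknown trial ids: {sorted(missing)}")
        desc = f"ids[{len(keep)}]"
    return ds.select_ids(keep, "subset", predicate=desc)


def export_long(ds: TrackingDataset, representation: str = RAW) -> pd.DataFrame:
    """Export one representation as a long table (padding omitted).

    Column names round-trip through :func:`import_long` with
    ``id_columns=["trial_id"]``.
    """
    arr = ds.get(representation)
    frames = []
    for i, tid in enumerate(arr.trial_ids):
        L = arr.valid_length[i]
        df = pd.DataFrame(arr.values[i, :L, :], columns=arr.feature_names)
        df.insert(0, "trial_id", tid)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def export_measures(measures: pd.DataFrame, trial_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Export a measures table, optionally merged with trial metadata.

    The merge is keyed on ``trial_id`` and loses no keys (inner join over an
    identical key set).
    """
    out = measures.copy()
    if trial_table is not None:
        out = trial_table.merge(out, on="trial_id", validate="one_to_one")
    return out
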