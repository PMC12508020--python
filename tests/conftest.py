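"""Shared fixtures: tiny hand-built tables and seeded synthetic datasets."""

import numpy as np
import pandas as pd
import pytest

import reachtrace as rt


@pytest.fixture
def tiny_long_table() -> pd.DataFrame:
    """Two trials, three samples each, with one constant-per-trial column."""
    rows = []
    for tid, cond in (("t1", "typical"), ("t2", "atypical")):
        for i, (ts, x, y) in enumerate([(0, 0, 0), (100, -50, 80), (200, -120, 160)]):
            rows.append({"subject_nr": "s1", "trial": tid, "Condition": cond,
                         "timestamps": ts + (5 if tid == "t2" else 0),
                         "xpos": x * (1 if tid == "t1" else -1), "ypos": y})
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_ds(tiny_long_table) -> rt.TrackingDataset:
    return rt.import_long(tiny_long_table, ["subject_nr", "trial"])


@pytest.fixture(scope="session")
def synth_small():
    """Small default-condition synthetic dataset plus ground truth."""
    ds, truth = rt.generate(rt.SynthSpec(seed=101, n_subjects=8))
    return ds, truth


@pytest.fixture(scope="session")
def synth_prepped(synth_small):
    """Remapped, aligned, time- and length-normalized version."""
    ds, truth = synth_small
    ds = rt.remap_symmetric(ds)
    ds = rt.align_start(ds)
    ds = rt.time_normalize(ds)
    ds = rt.length_normalize(ds)
    return ds, truth


@pytest.fixture(scope="session")
def balanced_lownoise():
    """Balanced five-type mixture at low noise: clustering/typing oracle."""
    mix = {label: 0.2 for label in rt.TYPE_ORDER}
    spec = rt.SynthSpec(
        seed=202, n_subjects=11,
        type_mixture={"typical": dict(mix), "atypical": dict(mix)},
        noise_sd=0.5, jitter_ms=0.0, error_rate=0.0,
    )
    ds, truth = rt.generate(spec)
    ds = rt.remap_symmetric(ds)
    ds = rt.align_start(ds)
    ds = rt.length_normalize(ds)
    return ds, truth


def random_trajectory(rng: np.random.Generator, n_min=5, n_max=60) -> np.ndarray:
    """Random (t, x, y) trial block with strictly increasing timestamps."""
    n = int(rng.integers(n_min, n_max))
    t = np.cumsum(rng.uniform(1.0, 30.0, n))
    t -= t[0]
    x = np.cumsum(rng.normal(0, 20, n))
    y = np.cumsum(rng.normal(0, 20, n))
    return np.column_stack([t, x, y])


def smooth_trajectory(rng: np.random.Generator, n=120) -> np.ndarray:
    """Smooth random (t, x, y) curve, like a real reach path."""
    t = np.linspace(0.0, 1000.0, n)
    u = t / t[-1]
    x = -600 * u
    y = 900 * u
    for k in range(1, 3):
        x = x + rng.normal(0, 40 / k**2) * np.sin(np.pi * k * u)
        y = y + rng.normal(0, 40 / k**2) * np.sin(np.pi * k * u)
    return np.column_stack([t, x, y])


def arc_positions(path_xy: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Arc-length position of each point along a polyline it lies on."""
    seg = np.hypot(*np.diff(path_xy, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    out = np.empty(len(points))
    for i, p in enumerate(points):
        d0 = path_xy[:-1] - p
        d1 = path_xy[1:] - p
        seg_vec = path_xy[1:] - path_xy[:-1]
        with np.errstate(invalid="ignore", divide="ignore"):
            tt = np.clip(-np.einsum("ij,ij->i", d0, seg_vec)
                         / np.maximum(np.einsum("ij,ij->i", seg_vec, seg_vec),
                                      1e-300), 0, 1)
        proj = path_xy[:-1] + tt[:, None] * seg_vec
        dist = np.hypot(*(proj - p).T)
        j = int(np.argmin(dist))
        out[i] = s[j] + tt[j] * seg[j]
    return out


def dataset_from_blocks(blocks) -> rt.TrackingDataset:
    """Wrap raw (t, x, y) blocks as a TrackingDataset."""
    rows = []
    for i, b in enumerate(blocks):
        for ts, x, y in b:
            rows.append({"trial_id": f"r{i}", "timestamps": ts,
                         "xpos": x, "ypos": y})
    return rt.import_long(pd.DataFrame(rows), ["trial_id"])
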