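"""Synthetic two-option forced-choice movement-tracking data.

Emulates the structure of a screen-based categorization task: trials start
at a bottom-center button, the two response boxes sit in the upper corners
(+-665, 974 px relative to the start), and each trial's cursor path is built
from one of the five canonical movement types (straight, curved, cCoM, dCoM,
dCoM2) with known ground truth.

Movement synthesis: the type's prototype polyline is scaled to the layout
and traversed by one minimum-jerk (bell-shaped speed) submovement per
ballistic segment, with programmed pauses between submovements for the
discrete types, a pre-movement initiation idle, i.i.d. Gaussian motor noise
on moving samples (a resting device reports a stable position), optional
integer-pixel quantization, and constant-interval sampling with optional
timestamp jitter.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import RAW, TIME_NORMALIZED, TIMESTAMPS, XPOS, YPOS, TrackingDataset, TrajectoryArray
from .typing import TYPE_ORDER, standard_prototypes

#: per-condition type mixtures mirroring a typicality manipulation; the
#: proportions are frequency-based (counts 506/116/54/52/16 of 744 and
#: 165/38/37/56/24 of 320), so they sum to one exactly
DEFAULT_MIXTURES = {
    "typical": {"straight": 506 / 744, "curved": 116 / 744, "cCoM": 54 / 744,
                "dCoM": 52 / 744, "dCoM2": 16 / 744},
    "atypical": {"straight": 165 / 320, "curved": 38 / 320, "cCoM": 37 / 320,
                 "dCoM": 56 / 320, "dCoM2": 24 / 320},
}


@dataclass
class SynthSpec:
    """Study conditions of the synthetic experiment.

    Defaults emulate a 60-subject design with 19 trials each (10 typical,
    9 atypical), 10-ms sampling, and response boxes at (+-665, 974) px.
    Durations are in ms; ``noise_sd`` is px of isotropic positional noise.
    """

    n_subjects: int = 60
    trials_per_condition: dict = field(
        default_factory=lambda: {"typical": 10, "atypical": 9})
    start: tuple[float, float] = (0.0, 0.0)
    chosen: tuple[float, float] = (-665.0, 974.0)
    type_mixture: dict = field(default_factory=lambda: {
        c: dict(m) for c, m in DEFAULT_MIXTURES.items()})
    noise_sd: float = 1.0
    quantize_px: bool = True
    sampling_interval_ms: float = 10.0
    jitter_ms: float = 0.5
    initiation_median_ms: float = 250.0
    initiation_sigma: float = 0.4
    pause_median_ms: float = 200.0
    pause_sigma: float = 0.4
    # per-submovement duration: lognormal with median base + rate * length,
    # so longer (change-of-mind) paths take longer, as reach data does
    submovement_base_ms: float = 600.0
    submovement_ms_per_px: float = 0.5
    submovement_sigma: float = 0.35
    error_rate: float = 0.067
    mirror_prob: float = 0.5
    min_samples: int = 72
    max_samples: int = 2159
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required for reproducibility")
        for cond, mix in self.type_mixture.items():
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"negative mixture weight in {cond!r}")
            s = sum(mix.values())
            if not np.isclose(s, 1.0):
                raise ValueError(f"mixture for {cond!r} sums to {s}, not 1")
        if self.sampling_interval_ms <= 0:
            raise ValueError("sampling interval must be positive")
        if not 0 <= self.jitter_ms < self.sampling_interval_ms / 2:
            raise ValueError("jitter must be < half the sampling interval")


#: submovement boundaries (vertex indices) per type; smooth types are one
#: ballistic movement, discrete CoM types one per straight leg
_SUBMOVEMENT_VERTICES = {"straight": None, "curved": None, "cCoM": None,
                         "dCoM": [0, 1, 2], "dCoM2": [0, 1, 2, 3]}


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on [0, 1]."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _arc_interp(path: np.ndarray, s_query: np.ndarray) -> np.ndarray:
    """Points along a polyline at the given arc-length positions."""
    seg = np.hypot(*np.diff(path, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return np.column_stack([np.interp(s_query, s, path[:, 0]),
                            np.interp(s_query, s, path[:, 1])])


def _trial_position_fn(segments, init_ms, pauses_ms, durations_ms):
    """Piecewise schedule: (time grid evaluator, total duration).

    ``segments`` is a list of (polyline, arc_length); the cursor idles at
    the start, traverses each segment with a minimum-jerk profile, and
    holds position during inter-submovement pauses.
    """
    events = []  # (t_start, t_end, kind, payload)
    t = init_ms
    pos0 = segments[0][0][0]
    events.append((0.0, t, "hold", pos0))
    for i, ((path, length), dur) in enumerate(zip(segments, durations_ms)):
        events.append((t, t + dur, "move", (path, length)))
        t += dur
        if i < len(segments) - 1:
            events.append((t, t + pauses_ms[i], "hold", path[-1]))
            t += pauses_ms[i]
    total = t

    def position(times: np.ndarray) -> np.ndarray:
        out = np.empty((len(times), 2))
        for t0, t1, kind, payload in events:
            m = (times >= t0) & (times < t1) if t1 < total else \
                (times >= t0) & (times <= t1 + 1e-9)
            if not m.any():
                continue
            if kind == "hold":
                out[m] = payload
            else:
                path, length = payload
                tau = (times[m] - t0) / (t1 - t0)
                out[m] = _arc_interp(path, length * _minimum_jerk(tau))
        return out

    return position, total


def generate(spec: SynthSpec) -> tuple[TrackingDataset, pd.DataFrame]:
    """Generate a dataset plus its ground-truth table.

    The truth table has one row per trial: true type label, mirrored side,
    correctness flag, initiation duration, submovement boundary times and
    total duration — the oracle for recovery and timing tests.
    """
    rng = np.random.default_rng(spec.seed)
    protos = {p.label: p.polyline for p in standard_prototypes().entries}
    sx = spec.chosen[0] - spec.start[0]          # unit x -1 -> chosen
    sy = spec.chosen[1] - spec.start[1]
    scale = np.array([-sx, sy / 1.5])

    trials, trial_ids, meta_rows, truth_rows = [], [], [], []
    for s in range(spec.n_subjects):
        subject = f"S{s + 1:03d}"
        trial_nr = 0
        for cond, n_trials in spec.trials_per_condition.items():
            mix = spec.type_mixture[cond]
            labels = [l for l in TYPE_ORDER if l in mix]
            probs = np.array([mix[l] for l in labels])
            for _ in range(n_trials):
                trial_nr += 1
                label = str(rng.choice(labels, p=probs / probs.sum()))
                poly = protos[label] * scale + np.asarray(spec.start)

                verts = _SUBMOVEMENT_VERTICES[label]
                if verts is None:
                    pieces = [poly]
                else:
                    pieces = [poly[a : b + 1] for a, b in zip(verts, verts[1:])]
                segments = [(p, float(np.hypot(*np.diff(p, axis=0).T).sum()))
                            for p in pieces]

                init = float(rng.lognormal(np.log(spec.initiation_median_ms),
                                           spec.initiation_sigma))
                lengths = np.array([L for _, L in segments])
                medians = spec.submovement_base_ms + spec.submovement_ms_per_px * lengths
                durations = rng.lognormal(np.log(medians), spec.submovement_sigma)
                pauses = [float(rng.lognormal(np.log(spec.pause_median_ms),
                                              spec.pause_sigma))
                          for _ in range(len(segments) - 1)]

                # keep sample counts inside the emulated recording range
                lo = (spec.min_samples + 1) * spec.sampling_interval_ms
                hi = (spec.max_samples - 2) * spec.sampling_interval_ms
                total = init + durations.sum() + sum(pauses)
                if total < lo:
                    durations *= 1 + (lo - total) / durations.sum()
                elif total > hi:
                    shrink = max(hi - init - sum(pauses), 100.0)
                    durations *= shrink / durations.sum()

                position, total = _trial_position_fn(segments, init, pauses, durations)
                n_grid = int(np.floor(total / spec.sampling_interval_ms))
                t = np.arange(n_grid + 1) * spec.sampling_interval_ms
                if spec.jitter_ms > 0 and len(t) > 2:
                    t[1:-1] += rng.uniform(-spec.jitter_ms, spec.jitter_ms,
                                           len(t) - 2)
                if total - t[-1] > 1.0:
                    t = np.append(t, total)
                else:
                    t[-1] = total
                xy = position(t)
                if spec.noise_sd > 0:
                    # motor noise perturbs executed movement; at rest the
                    # device reports a stable position
                    moving = np.ones(len(t), dtype=bool)
                    moving[1:] = np.hypot(*np.diff(xy, axis=0).T) > 0
                    moving[0] = False
                    xy[moving] += rng.normal(0.0, spec.noise_sd,
                                             (int(moving.sum()), 2))
                if spec.quantize_px:
                    xy = np.round(xy)  # screens report integer pixels

                side = "right" if rng.uniform() < spec.mirror_prob else "left"
                if side == "right":
                    xy[:, 0] = 2 * spec.start[0] - xy[:, 0]
                correct = int(rng.uniform() >= spec.error_rate)

                tid = f"{subject}_{trial_nr}"
                trial_ids.append(tid)
                trials.append(np.column_stack([t, xy]))
                meta_rows.append({"trial_id": tid, "subject_id": subject,
                                  "Condition": cond, "correct": correct})
                bounds = np.concatenate([[init], init + np.cumsum(
                    [d + p for d, p in zip(durations, list(pauses) + [0.0])])])
                truth_rows.append({
                    "trial_id": tid, "true_type": label, "side": side,
                    "correct": correct, "initiation_ms": init,
                    "rt_ms": float(total),
                    "n_submovements": len(segments),
                    "boundaries_ms": ";".join(f"{b:.1f}" for b in bounds),
                })

    arr = TrajectoryArray.from_trials(trials, trial_ids,
                                      [TIMESTAMPS, XPOS, YPOS])
    ds = TrackingDataset(pd.DataFrame(meta_rows), {RAW: arr})
    ds = ds._logged("synth.generate", seed=spec.seed,
                    n_trials=len(trial_ids))
    return ds, pd.DataFrame(truth_rows)


def inject_step_effect(
    ds: TrackingDataset,
    truth: pd.DataFrame,
    feature: str = XPOS,
    window: tuple[int, int] = (40, 80),
    magnitude: float = 0.0,
    representation: str = TIME_NORMALIZED,
    condition_column: str = "Condition",
    shifted_level: str = "atypical",
) -> tuple[TrackingDataset, pd.DataFrame]:
    """Add a condition-dependent shift inside a step window (test oracle).

    Steps are 1-based inclusive; magnitude 0 leaves the dataset unchanged.
    The programmed window is recorded in the returned truth table.
    """
    arr = ds.get(representation)
    if feature not in arr.feature_names:
        raise KeyError(f"unknown feature {feature!r}")
    lo, hi = window
    if not 1 <= lo <= hi <= arr.max_points:
        raise ValueError("window out of range")
    arr = arr.copy()
    fi = arr.feature_index(feature)
    shifted = set(
        ds.trial_table.loc[ds.trial_table[condition_column] == shifted_level,
                           "trial_id"]
    )
    for i, tid in enumerate(arr.trial_ids):
        if tid in shifted:
            arr.values[i, lo - 1 : hi, fi] += magnitude
    out = ds.with_representation(
        representation, arr, "synth.inject_step_effect",
        feature=feature, window=list(window), magnitude=magnitude,
    )
    truth = truth.copy()
    truth["effect_feature"] = feature
    truth["effect_window"] = f"{lo}-{hi}"
    truth["effect_magnitude"] = magnitude
    return out, truth
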