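"""Metric-space information analysis of spike trains.

The Victor–Purpura spike-train distance is the minimal cost of transforming
one train into another using spike insertions/deletions (cost 1 each) and
temporal shifts (cost ``q`` per second of displacement); ``q = 2/resolution``
makes two spikes cheaper to delete-and-reinsert than to shift once they are
further apart than the stated temporal resolution. A leave-one-out
nearest-mean classifier over the 25 irregular trials (5 per direction)
produces a confusion matrix whose plug-in mutual information is a lower bound
on the information the train carries about force direction. Finite-sample
bias is estimated by recomputing the information under shuffled labels (class
sizes preserved) and subtracting the mean over shuffles. Running the whole
procedure on successively longer windows, once with current-direction labels
and once with preceding-direction labels, yields the information time courses
used to categorize neurons as 'current', 'previous' or 'mixed' coders.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import CANONICAL_ORDER, Direction
from .session import SessionData, substream


@dataclass(frozen=True)
class InfoConfig:
    resolution_s: float = 0.008  # 0.032 for interstimulus-period analyses
    increment_s: float = 0.005
    n_shuffles: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution_s <= 0 or self.increment_s <= 0:
            raise ValueError("resolution and increment must be positive")
        if self.n_shuffles < 1:
            raise ValueError("need at least one shuffle")

    @property
    def cost_q(self) -> float:
        """Shift cost in 1/s; two spikes q*dt apart cost min(q*dt, 2)."""
        return 2.0 / self.resolution_s


def vp_distance(a: np.ndarray, b: np.ndarray, q: float) -> float:
    """Victor–Purpura distance by the standard O(nm) dynamic program."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return float(n + m)
    prev = [float(j) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [float(i)] + [0.0] * m
        ai = a[i - 1]
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + 1.0,
                cur[j - 1] + 1.0,
                prev[j - 1] + q * abs(ai - b[j - 1]),
            )
        prev = cur
    return prev[m]


def pairwise_distance_matrix(trains: list[np.ndarray], q: float) -> np.ndarray:
    """Symmetric zero-diagonal matrix of VP distances between all train pairs."""
    n = len(trains)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = vp_distance(trains[i], trains[j], q)
    return D


def classify_nearest_mean(distances: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Leave-one-out nearest-class-mean confusion matrix.

    Each trial is assigned to the class with the lowest mean distance to the
    *other* trials of that class (the trial itself is excluded from its own
    class mean). Ties are broken towards the lowest class index, i.e. the
    canonical direction order. Rows are true classes, columns assignments.
    """
    distances = np.asarray(distances, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.arange(labels.max() + 1)
    for c in classes:
        if np.sum(labels == c) < 2:
            raise ValueError(f"class {c} has fewer than 2 trials")
    n = len(labels)
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for i in range(n):
        means = np.empty(len(classes))
        for c in classes:
            members = (labels == c) & (np.arange(n) != i)
            means[c] = distances[i, members].mean()
        cm[labels[i], int(np.argmin(means))] += 1
    return cm


def mi_from_confusion(cm: np.ndarray) -> float:
    """Plug-in mutual information of a confusion matrix, in bits."""
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p = cm / total
    pi = p.sum(axis=1, keepdims=True)
    pj = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (pi * pj))
    return float(np.nansum(terms))


def bias_corrected_info(
    distances: np.ndarray,
    labels: np.ndarray,
    config: InfoConfig | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Shuffle-corrected information (bits); may legitimately be negative.

    The estimate is the plug-in MI under the true labels minus the mean MI
    over ``n_shuffles`` seeded permutations of the label vector (exact class
    sizes preserved).
    """
    config = config or InfoConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    labels = np.asarray(labels, dtype=int)
    true_mi = mi_from_confusion(classify_nearest_mean(distances, labels))
    bias = np.mean(
        [
            mi_from_confusion(classify_nearest_mean(distances, rng.permutation(labels)))
            for _ in range(config.n_shuffles)
        ]
    )
    return float(true_mi - bias)


def info_timecourse(
    trains: list[np.ndarray],
    labels_current: np.ndarray,
    labels_previous: np.ndarray,
    duration_s: float,
    config: InfoConfig | None = None,
) -> pd.DataFrame:
    """Cumulative-window information about current and preceding direction.

    ``trains`` are re-referenced to the window origin. For each window end
    ``k * increment`` (k = 0 .. duration/increment) the trains are truncated
    to the half-open window, one distance matrix is computed and the
    bias-corrected information is evaluated under both label vectors.
    """
    config = config or InfoConfig()
    rng = np.random.default_rng(config.seed)
    n_windows = int(round(duration_s / config.increment_s))
    rows = []
    for k in range(n_windows + 1):
        end = k * config.increment_s
        cut = [t[t < end] for t in trains]
        D = pairwise_distance_matrix(cut, config.cost_q)
        bits_cur = bias_corrected_info(D, labels_current, config, rng)
        bits_prev = bias_corrected_info(D, labels_previous, config, rng)
        rows.append((end, bits_cur, bits_prev))
    return pd.DataFrame(rows, columns=["window_end", "bits_current", "bits_previous"])


def categorize_neuron(curve: pd.DataFrame, min_positive: int = 10) -> dict:
    """Assign a coding category from the two information curves.

    Windows where either corrected information exceeds 0 count as positive;
    with fewer than ``min_positive`` of them the neuron is 'excluded'.
    Otherwise the fraction of positive windows in which the current-direction
    information is at least the preceding-direction information decides:
    >= 0.70 'current', <= 0.30 'previous', else 'mixed'.
    """
    positive = curve[(curve.bits_current > 0) | (curve.bits_previous > 0)]
    n_pos = len(positive)
    if n_pos < min_positive:
        return {"label": "excluded", "n_positive_windows": n_pos, "fraction_current": np.nan}
    frac = float((positive.bits_current >= positive.bits_previous).mean())
    if frac >= 0.70:
        label = "current"
    elif frac <= 0.30:
        label = "previous"
    else:
        label = "mixed"
    return {"label": label, "n_positive_windows": n_pos, "fraction_current": frac}


def _direction_labels(trials: pd.DataFrame, column: str) -> np.ndarray:
    return np.array([Direction(d).index for d in trials[column]])


def neuron_info_analysis(
    session: SessionData,
    neuron_id: int,
    phase: str = "protraction",
    sequence: str = "irregular",
    config: InfoConfig | None = None,
) -> pd.DataFrame:
    """Information time course for one neuron of a session.

    ``phase='protraction'`` windows grow from protraction onset over the
    125 ms protraction at 8 ms resolution; ``phase='interstimulus'`` windows
    grow from the start of the interstimulus period preceding the test trial
    over its 250 ms at 32 ms resolution (the convention used for tonic SA-2
    activity between loadings).
    """
    protocol = session.protocol
    if config is None:
        config = InfoConfig(
            resolution_s=0.008 if phase == "protraction" else 0.032,
            seed=int(substream(session.config.seed, f"info/{neuron_id}").integers(2**31)),
        )
    if phase == "protraction":
        origin, duration = 0.0, protocol.protraction_s
    elif phase == "interstimulus":
        origin, duration = -protocol.interstimulus_s, protocol.interstimulus_s
    else:
        raise ValueError(f"unsupported phase {phase!r}")
    trials = session.analysable(sequence)
    trains = [
        session.spikes_in(neuron_id, int(row.trial), origin, origin + duration)
        for _, row in trials.iterrows()
    ]
    return info_timecourse(
        trains,
        labels_current=_direction_labels(trials, "direction"),
        labels_previous=_direction_labels(trials, "preceding"),
        duration_s=duration,
        config=config,
    )
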