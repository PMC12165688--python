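"""Intertrial variability of firing rates and contactor kinematics.

For each force direction the analysable trials of a sequence share the same
nominal force stimulus, so any intertrial spread reflects loading history
(plus noise). The analyses compute pointwise standard deviations across the
five same-direction trials — of the reciprocal-ISI firing rate for neurons,
and of the 2D tangential position or velocity for the contactor — then
average over directions. Sequence contrasts use paired Wilcoxon signed-rank
tests with Bonferroni correction, on per-neuron time-averages within each
loading phase.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import RateTrace, differentiate, gaussian_smooth, instantaneous_rate
from .protocol import CANONICAL_ORDER
from .session import SessionData

#: Phase windows in seconds relative to protraction onset. "pre" is the
#: interstimulus period preceding the test trial.
PHASE_BOUNDS: dict[str, tuple[float, float]] = {
    "pre": (-0.250, 0.0),
    "protraction": (0.0, 0.125),
    "plateau": (0.125, 0.375),
    "retraction": (0.375, 0.500),
    "interstimulus": (0.500, 0.750),
}


@dataclass(frozen=True)
class SDTrace:
    """Across-trial standard deviation vs. time (relative to protraction onset)."""

    times: np.ndarray
    sd: np.ndarray

    def phase_mean(self, phase: str) -> float:
        """Time-averaged SD within one loading phase (the per-neuron scalar)."""
        lo, hi = PHASE_BOUNDS[phase]
        mask = (self.times >= lo) & (self.times < hi)
        return float(np.mean(self.sd[mask]))


def _rel_grid(rel_window: tuple[float, float], grid_hz: float) -> np.ndarray:
    n = int(round((rel_window[1] - rel_window[0]) * grid_hz))
    return rel_window[0] + np.arange(n) / grid_hz


def rate_sd_timecourse(
    session: SessionData,
    neuron_id: int,
    sequence: str,
    rel_window: tuple[float, float] = (-0.250, 0.750),
    grid_hz: float = 1000.0,
) -> SDTrace:
    """SD (n-1 denominator) of instantaneous firing rate across same-direction
    trials, averaged over the five directions."""
    grid = _rel_grid(rel_window, grid_hz)
    spikes = session.spikes[neuron_id]
    per_direction = []
    trials = session.analysable(sequence)
    for d in CANONICAL_ORDER:
        rows = trials[trials.direction == d.value]
        if len(rows) == 0:
            raise ValueError(f"no analysable trials for direction {d.value}")
        rates = np.stack(
            [
                instantaneous_rate(spikes, row.t_protraction + grid).rate
                for _, row in rows.iterrows()
            ]
        )
        per_direction.append(rates.std(axis=0, ddof=1))
    return SDTrace(times=grid, sd=np.mean(per_direction, axis=0))


def mean_rate_timecourse(
    session: SessionData,
    neuron_ids: list[int],
    sequence: str,
    rel_window: tuple[float, float] = (-0.250, 0.750),
    grid_hz: float = 1000.0,
) -> RateTrace:
    """Instantaneous firing rate averaged over trials, directions and neurons."""
    grid = _rel_grid(rel_window, grid_hz)
    trials = session.analysable(sequence)
    acc = np.zeros_like(grid)
    count = 0
    for nid in neuron_ids:
        spikes = session.spikes[nid]
        for _, row in trials.iterrows():
            acc += instantaneous_rate(spikes, row.t_protraction + grid).rate
            count += 1
    return RateTrace(times=grid, rate=acc / max(count, 1))


def kinematic_sd_timecourse(
    session: SessionData,
    sequence: str,
    signal: str = "position",
    rel_window: tuple[float, float] = (-0.250, 0.750),
    smooth_sigma_s: float = 0.010,
) -> SDTrace:
    """2D tangential variability of the contactor across same-direction trials.

    At each time point ``sd = sqrt(sum_i ||v_i - v_mean||^2 / (n - 1))`` over
    the tangential (x, y) components, averaged over directions. For
    ``signal='velocity'`` positions are Gaussian-smoothed before
    differentiation to keep measurement noise from dominating the derivative.
    """
    if signal not in ("position", "velocity"):
        raise ValueError("signal must be 'position' or 'velocity'")
    fs = session.protocol.mech_sample_rate
    trials = session.analysable(sequence)
    per_direction = []
    times_rel = None
    for d in CANONICAL_ORDER:
        rows = trials[trials.direction == d.value]
        vecs = []
        for _, row in rows.iterrows():
            t_rel, pos = session.contactor_in(int(row.trial), *rel_window)
            times_rel = t_rel
            xy = pos[:, :2]
            if signal == "velocity":
                xy = differentiate(t_rel, gaussian_smooth(xy, smooth_sigma_s, fs))
            vecs.append(xy)
        v = np.stack(vecs)  # (trials, time, 2)
        dev = v - v.mean(axis=0, keepdims=True)
        per_direction.append(np.sqrt((dev**2).sum(axis=(0, 2)) / (v.shape[0] - 1)))
    return SDTrace(times=times_rel, sd=np.mean(per_direction, axis=0))


def phase_compare(
    values_a: np.ndarray, values_b: np.ndarray, n_comparisons: int = 1
) -> dict[str, float]:
    """Paired Wilcoxon signed-rank test with Bonferroni correction.

    ``values_a`` / ``values_b`` are per-neuron (or per-session) paired scalars
    for the two conditions. Identical samples give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal shape")
    if np.allclose(a, b):
        p = 1.0
    else:
        p = float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)
    return {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "p_raw": p,
        "p_corrected": min(1.0, p * n_comparisons),
    }


def sequence_contrast(
    session: SessionData,
    neuron_ids: list[int],
    phases: tuple[str, ...] = ("protraction", "plateau", "retraction", "interstimulus"),
) -> dict[str, dict[str, float]]:
    """Per-phase regular-vs-irregular contrast of firing-rate variability.

    Returns, for each phase, the paired Wilcoxon result over neurons with
    Bonferroni correction for the number of phases tested.
    """
    per_neuron = {}
    for seq in ("regular", "irregular"):
        per_neuron[seq] = [rate_sd_timecourse(session, nid, seq) for nid in neuron_ids]
    results = {}
    for phase in phases:
        a = np.array([tr.phase_mean(phase) for tr in per_neuron["regular"]])
        b = np.array([tr.phase_mean(phase) for tr in per_neuron["irregular"]])
        results[phase] = phase_compare(a, b, n_comparisons=len(phases))
    return results
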