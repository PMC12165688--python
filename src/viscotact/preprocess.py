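"""Shared signal operations: firing-rate estimation, resampling, smoothing,
differentiation and phase slicing.

Conventions: the instantaneous firing rate at time t is the reciprocal of the
interspike interval spanning t, with intervals right-closed — rate is 1/ISI on
``(t_i, t_{i+1}]`` and zero at/before the first spike, after the last spike,
and for trains with fewer than two spikes. All analysis windows are half-open
``[start, end)`` so that phase boundaries are never double counted.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d


@dataclass(frozen=True)
class RateTrace:
    """Firing rate (imp/s, non-negative) on a uniform time grid."""

    times: np.ndarray
    rate: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times) != len(self.rate):
            raise ValueError("times and rate must have equal length")


@dataclass(frozen=True)
class PhaseSchedule:
    """Onsets (session time, s) of the four phases of one loading cycle."""

    protraction: float
    plateau: float
    retraction: float
    interstimulus: float
    end: float

    def __post_init__(self) -> None:
        onsets = (self.protraction, self.plateau, self.retraction, self.interstimulus, self.end)
        if not all(b > a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("phase onsets must be strictly increasing")

    def window(self, phase: str, pad_before_s: float = 0.0, pad_after_s: float = 0.0):
        starts = {
            "protraction": self.protraction,
            "plateau": self.plateau,
            "retraction": self.retraction,
            "interstimulus": self.interstimulus,
        }
        ends = {
            "protraction": self.plateau,
            "plateau": self.retraction,
            "retraction": self.interstimulus,
            "interstimulus": self.end,
        }
        if phase not in starts:
            raise ValueError(f"unknown phase {phase!r}")
        return starts[phase] - pad_before_s, ends[phase] + pad_after_s


def instantaneous_rate(spikes: np.ndarray, times: np.ndarray) -> RateTrace:
    """Reciprocal-ISI firing rate evaluated on a time grid."""
    spikes = np.asarray(spikes, dtype=float)
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(spikes) < 0):
        raise ValueError("spike times must be sorted")
    rate = np.zeros_like(times)
    if len(spikes) >= 2:
        # index of the interval (t_{i-1}, t_i] containing each grid point
        idx = np.searchsorted(spikes, times, side="left")
        inside = (idx >= 1) & (idx <= len(spikes) - 1)
        isi = np.diff(spikes)
        rate[inside] = 1.0 / isi[idx[inside] - 1]
    return RateTrace(times=times, rate=rate)


def resample_linear(
    times: np.ndarray, values: np.ndarray, new_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation onto a uniform grid at ``new_rate`` Hz.

    The new grid spans the same interval; both endpoints are preserved when
    the span is an integer number of new steps.
    """
    if new_rate <= 0:
        raise ValueError("new_rate must be positive")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    n_new = int(np.floor((times[-1] - times[0]) * new_rate + 1e-9)) + 1
    new_times = times[0] + np.arange(n_new) / new_rate
    if values.ndim == 1:
        new_values = np.interp(new_times, times, values)
    else:
        new_values = np.column_stack(
            [np.interp(new_times, times, values[:, k]) for k in range(values.shape[1])]
        )
    return new_times, new_values


def gaussian_smooth(values: np.ndarray, sigma_s: float, sample_rate: float) -> np.ndarray:
    """Gaussian convolution (kernel truncated at ±4σ, reflect-padded edges).

    ``sigma_s = 0`` is the identity. Constant inputs are preserved (DC gain 1)
    and non-negative inputs stay non-negative.
    """
    if sigma_s < 0:
        raise ValueError("sigma_s must be non-negative")
    values = np.asarray(values, dtype=float)
    if sigma_s == 0:
        return values.copy()
    sigma_samples = sigma_s * sample_rate
    return gaussian_filter1d(values, sigma_samples, axis=0, mode="reflect", truncate=4.0)


def differentiate(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Time derivative: central differences inside, one-sided at the ends."""
    times = np.asarray(times, dtype=float)
    if len(times) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(np.asarray(values, dtype=float), times, axis=0)


def slice_window(
    times: np.ndarray, values: np.ndarray, start: float, end: float
) -> tuple[np.ndarray, np.ndarray]:
    """Half-open slice [start, end) of a sampled trace."""
    times = np.asarray(times, dtype=float)
    mask = (times >= start - 1e-12) & (times < end - 1e-12)
    return times[mask], np.asarray(values)[mask]


def slice_spikes(
    spikes: np.ndarray, start: float, end: float, reref: bool = True
) -> np.ndarray:
    """Spikes within the half-open window [start, end).

    With ``reref`` the returned times are re-referenced to the window start.
    A spike exactly at ``end`` is excluded.
    """
    spikes = np.asarray(spikes, dtype=float)
    out = spikes[(spikes >= start) & (spikes < end)]
    return out - start if reref else out
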