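"""Generative tactile afferent models.

Three archetypes mirror the functional classes of first-order tactile neurons
in human glabrous skin:

* **FA-1** (fast adapting, Meissner): velocity-dominant, silent at rest —
  weights only on velocity features and products involving velocity.
* **SA-1** (slowly adapting type I, Merkel): mixed position + velocity
  sensitivity with modest interaction terms.
* **SA-2** (slowly adapting type II, Ruffini-like): position-dominant and
  optionally spontaneous, with a tonic background discharge of 5–30 imp/s
  driven by ``gain * softplus(bias)`` at rest.

Each model maps contactor kinematics to an instantaneous firing rate through
``rate(t + latency) = gain * softplus(w · f(t) + bias)`` where ``f`` holds the
three positions, three velocities and their 15 pairwise products, each divided
by a fixed physical scale (1 mm, 10 mm/s). Dividing by fixed scales rather
than z-scoring keeps the unloaded rest state at exactly zero drive, which the
rest-rate semantics above require. Spikes are drawn from an inhomogeneous
Poisson process by thinning with a 1 ms absolute refractory period, quantized
to a 12.8 kHz grid.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .mechanics import ContactorTrace
from .preprocess import RateTrace, differentiate

POS_SCALE_MM = 0.5
VEL_SCALE_MM_S = 10.0
SPIKE_GRID_HZ = 12800.0

BASE_FEATURES: tuple[str, ...] = ("Px", "Py", "Pz", "dPx", "dPy", "dPz")
PAIR_FEATURES: tuple[tuple[int, int], ...] = tuple(itertools.combinations(range(6), 2))
FEATURE_NAMES: tuple[str, ...] = BASE_FEATURES + tuple(
    f"{BASE_FEATURES[i]}*{BASE_FEATURES[j]}" for i, j in PAIR_FEATURES
)
N_FEATURES = len(FEATURE_NAMES)  # 21

#: indices of pure-position features and of features involving any velocity
POSITION_ONLY_IDX = tuple(
    k
    for k, name in enumerate(FEATURE_NAMES)
    if "d" not in name
)
VELOCITY_IDX = tuple(k for k in range(N_FEATURES) if k not in POSITION_ONLY_IDX)


def softplus(x: np.ndarray | float) -> np.ndarray | float:
    return np.logaddexp(0.0, x)


def softplus_inverse(y: float) -> float:
    if y <= 0:
        raise ValueError("softplus is positive")
    return float(np.log(np.expm1(y)))


def kinematic_features(times: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """(n, 21) scaled feature matrix from a position trace.

    Velocities are central differences of the positions; scaling is by the
    fixed module constants so the rest state maps to the zero vector.
    """
    vel = differentiate(times, pos)
    base = np.column_stack([pos / POS_SCALE_MM, vel / VEL_SCALE_MM_S])
    pairs = np.column_stack([base[:, i] * base[:, j] for i, j in PAIR_FEATURES])
    return np.column_stack([base, pairs])


@dataclass(frozen=True)
class AfferentModel:
    """Ground-truth generative parameters of one synthetic afferent."""

    archetype: str  # "FA1" | "SA1" | "SA2"
    weights: np.ndarray  # (21,) on scaled features
    bias: float
    gain: float  # imp/s
    latency_s: float = 0.015
    refractory_s: float = 0.001
    spontaneous: bool = False

    def __post_init__(self) -> None:
        if self.archetype not in ("FA1", "SA1", "SA2"):
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.refractory_s <= 0:
            raise ValueError("refractory_s must be positive")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (N_FEATURES,):
            raise ValueError(f"weights must have shape ({N_FEATURES},)")
        object.__setattr__(self, "weights", w)
        if self.archetype == "FA1":
            if np.any(w[list(POSITION_ONLY_IDX)] != 0):
                raise ValueError("FA1 models must have zero position-only weights")
            if self.bias > 0:
                raise ValueError("FA1 models must have non-positive bias")

    @property
    def rest_rate(self) -> float:
        """Firing rate at the unloaded rest state (zero features), imp/s."""
        return float(self.gain * softplus(self.bias))


def _draw_weights(rng: np.random.Generator, sd_by_index: dict[int, float]) -> np.ndarray:
    w = np.zeros(N_FEATURES)
    for k, sd in sd_by_index.items():
        w[k] = rng.normal(0.0, sd)
    return w


def _signed_uniform(
    rng: np.random.Generator, lo: float, hi: float, p_positive: float = 0.5
) -> float:
    """Magnitude U(lo, hi) with a (possibly biased) random sign."""
    sign = 1.0 if rng.uniform() < p_positive else -1.0
    return sign * float(rng.uniform(lo, hi))


def make_afferent_population(
    n_fa1: int,
    n_sa1: int,
    n_sa2: int,
    seed: int | np.random.Generator = 0,
    sa2_spontaneous_fraction: float = 1.0,
) -> list[AfferentModel]:
    """Seeded population of afferent models, FA-1 then SA-1 then SA-2."""
    if min(n_fa1, n_sa1, n_sa2) < 0:
        raise ValueError("counts must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    models: list[AfferentModel] = []

    vel_base = [k for k, n in enumerate(BASE_FEATURES) if n.startswith("d")]
    vel_pairs = [k for k in VELOCITY_IDX if k >= 6]
    pos_pairs = [k for k in POSITION_ONLY_IDX if k >= 6]

    # Weight magnitudes are drawn with floors so that most model neurons
    # respond during loading; the normal-axis drive is sign-biased positive so
    # that (as in real samples) most, but not all, neurons are excited rather
    # than suppressed by the indenting ramp — negative-sign draws yield
    # retraction- or release-preferring neurons.
    for _ in range(n_fa1):
        w = _draw_weights(rng, {k: 0.3 for k in vel_pairs})
        w[3] = _signed_uniform(rng, 0.8, 2.0)  # dPx
        w[4] = _signed_uniform(rng, 0.8, 2.0)  # dPy
        w[5] = _signed_uniform(rng, 0.6, 1.4, p_positive=0.75)  # dPz
        models.append(
            AfferentModel(
                archetype="FA1",
                weights=w,
                bias=float(rng.uniform(-4.0, -2.5)),
                gain=float(rng.uniform(25.0, 45.0)),
                spontaneous=False,
            )
        )
    for _ in range(n_sa1):
        w = _draw_weights(rng, {k: 0.3 for k in vel_pairs + pos_pairs})
        w[0] = _signed_uniform(rng, 0.5, 1.5)  # Px
        w[1] = _signed_uniform(rng, 0.5, 1.5)  # Py
        w[2] = _signed_uniform(rng, 0.5, 1.2, p_positive=0.8)  # Pz
        w[3] = _signed_uniform(rng, 0.4, 1.2)  # dPx
        w[4] = _signed_uniform(rng, 0.4, 1.2)  # dPy
        w[5] = _signed_uniform(rng, 0.3, 0.9, p_positive=0.8)  # dPz
        models.append(
            AfferentModel(
                archetype="SA1",
                weights=w,
                bias=float(rng.uniform(-3.5, -2.0)),
                gain=float(rng.uniform(25.0, 45.0)),
                spontaneous=False,
            )
        )
    for i in range(n_sa2):
        spontaneous = (i + 1) <= round(sa2_spontaneous_fraction * n_sa2)
        sd = {k: 0.3 for k in vel_base}
        sd.update({k: 0.15 for k in vel_pairs + pos_pairs})
        w = _draw_weights(rng, sd)
        w[0] = _signed_uniform(rng, 1.5, 4.0)  # Px: tangential-position dominant
        w[1] = _signed_uniform(rng, 1.5, 4.0)  # Py
        w[2] = _signed_uniform(rng, 0.5, 1.2, p_positive=0.7)  # Pz
        gain = float(rng.uniform(15.0, 25.0))
        if spontaneous:
            rest = float(rng.uniform(5.0, 30.0))
            bias = softplus_inverse(rest / gain)
        else:
            bias = float(rng.uniform(-2.0, -1.0))
        models.append(
            AfferentModel(
                archetype="SA2",
                weights=w,
                bias=bias,
                gain=gain,
                spontaneous=spontaneous,
            )
        )
    return models


def make_designed_population(
    n_current: int, n_history: int, seed: int | np.random.Generator = 0
) -> tuple[list[AfferentModel], list[str]]:
    """Population with known coding categories, for category-recovery tests.

    *Current coders* are rest-silent velocity-driven models (FA-1 style) with
    dense, refractoriness-regularized bursts: the normal-axis velocity drive
    makes every direction evoke spikes (no silent class to attract the
    nearest-mean classifier), tangential velocity weights scale the burst by
    the current direction, and position-velocity interaction weights
    (``Pz*dPx``, ``Pz*dPy``) skew its temporal profile per direction, so the
    current direction is carried in spike timing that a short-resolution spike
    metric resolves well.

    *History coders* are transient threshold-crossing bursters: a strong
    normal-axis velocity drive against a negative bias produces one burst per
    loading whose onset time is advanced or delayed by the tangential-position
    drive — dominated early in protraction by the residual (viscoelastic)
    deformation left by the preceding loading. The burst ends with the
    velocity transient, so late windows add little current-direction
    structure and the neurons are expected to be categorized 'previous' or
    'mixed'.

    Returns the models and their designed category labels
    ('current' / 'history').
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    i_pz_dpx = FEATURE_NAMES.index("Pz*dPx")
    i_pz_dpy = FEATURE_NAMES.index("Pz*dPy")
    models: list[AfferentModel] = []
    designed: list[str] = []
    for _ in range(n_current):
        w = np.zeros(N_FEATURES)
        w[3] = _signed_uniform(rng, 0.8, 1.2)
        w[4] = _signed_uniform(rng, 0.8, 1.2)
        w[5] = float(rng.uniform(1.8, 2.4))
        w[i_pz_dpx] = _signed_uniform(rng, 0.3, 0.5)
        w[i_pz_dpy] = _signed_uniform(rng, 0.3, 0.5)
        models.append(
            AfferentModel(
                archetype="FA1",
                weights=w,
                bias=float(rng.uniform(-3.0, -2.0)),
                gain=float(rng.uniform(200.0, 300.0)),
                spontaneous=False,
            )
        )
        designed.append("current")
    for _ in range(n_history):
        w = np.zeros(N_FEATURES)
        w[0] = _signed_uniform(rng, 2.0, 3.0)
        w[1] = _signed_uniform(rng, 2.0, 3.0)
        w[5] = float(rng.uniform(1.8, 2.4))
        models.append(
            AfferentModel(
                archetype="SA2",
                weights=w,
                bias=float(rng.uniform(-3.2, -2.8)),
                gain=float(rng.uniform(150.0, 250.0)),
                spontaneous=False,
            )
        )
        designed.append("history")
    return models, designed


def afferent_rate(contactor: ContactorTrace, model: AfferentModel) -> RateTrace:
    """Instantaneous firing rate driven by a contactor trajectory.

    The output grid is the contactor grid shifted by the model's response
    latency: the rate at ``t + latency`` reflects the kinematics at ``t``.
    """
    features = kinematic_features(contactor.times, contactor.pos)
    drive = features @ model.weights + model.bias
    rate = model.gain * softplus(drive)
    return RateTrace(times=contactor.times + model.latency_s, rate=rate)


def generate_spike_train(
    rate: RateTrace, model: AfferentModel, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Inhomogeneous Poisson spikes by thinning, with absolute refractoriness.

    Candidate events are drawn from a homogeneous Poisson process at the peak
    rate and accepted with probability ``rate(t)/rate_max`` (linear
    interpolation of the rate trace); accepted events are quantized to the
    12.8 kHz grid and any event closer than the refractory period to its
    accepted predecessor is discarded. The result is sorted and strictly
    increasing.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.any(rate.rate < 0):
        raise ValueError("rate must be non-negative")
    t0, t1 = float(rate.times[0]), float(rate.times[-1])
    rmax = float(np.max(rate.rate))
    if rmax <= 0 or t1 <= t0:
        return np.empty(0)
    n_cand = rng.poisson(rmax * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, n_cand))
    keep = rng.uniform(0.0, rmax, n_cand) < np.interp(cand, rate.times, rate.rate)
    accepted = cand[keep]
    # quantize, deduplicate, then impose the dead time
    quantized = np.unique(np.round(accepted * SPIKE_GRID_HZ) / SPIKE_GRID_HZ)
    out: list[float] = []
    last = -np.inf
    for t in quantized:
        if t - last >= model.refractory_s:
            out.append(t)
            last = t
    return np.asarray(out)
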