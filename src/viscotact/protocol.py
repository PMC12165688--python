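"""Force stimulation protocol: directions, force trajectories, and trial sequences.

The loading paradigm applies half-sinusoidal force ramps to the fingertip in
five directions: normal to the skin (N) and angled 20 degrees towards radial
(R), distal (D), ulnar (U) or proximal (P). One loading cycle is a 125 ms
protraction, a 250 ms plateau at 4 N normal force, a 125 ms retraction and a
250 ms interstimulus period; a 0.2 N normal background force is maintained
throughout. Two trial sequences are used: a *regular* sequence repeating the
fixed order (R, D, U, P, N), and an *irregular* sequence in which every
ordered pair of (previous, current) directions occurs exactly once.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class Direction(enum.Enum):
    """Force direction label. Canonical order (R, D, U, P, N) breaks ties."""

    R = "R"
    D = "D"
    U = "U"
    P = "P"
    N = "N"

    @property
    def index(self) -> int:
        return CANONICAL_ORDER.index(self)


CANONICAL_ORDER: tuple[Direction, ...] = (
    Direction.R,
    Direction.D,
    Direction.U,
    Direction.P,
    Direction.N,
)

#: Unit tangential axis per direction in the (x, y) plane.
#: x = radial(+)/ulnar(-), y = distal(+)/proximal(-).
TANGENTIAL_AXIS: dict[Direction, tuple[float, float]] = {
    Direction.R: (1.0, 0.0),
    Direction.D: (0.0, 1.0),
    Direction.U: (-1.0, 0.0),
    Direction.P: (0.0, -1.0),
    Direction.N: (0.0, 0.0),
}


@dataclass(frozen=True)
class ForceProtocol:
    """Timing and amplitude parameters of one loading cycle.

    The normal plateau (4 N) and the tangential plateau (1.4 N) are treated as
    independently controlled primitives; the nominal 20 degree angle is kept
    as metadata only (4·tan 20° = 1.456 N does not reproduce 1.4 N and the
    controlled quantity is not knowable from the published values).
    """

    protraction_s: float = 0.125
    plateau_s: float = 0.250
    retraction_s: float = 0.125
    interstimulus_s: float = 0.250
    normal_plateau: float = 4.0
    tangential_plateau: float = 1.4
    angle_deg: float = 20.0
    background_normal: float = 0.2
    ramp_freq: float = 4.0
    mech_sample_rate: float = 400.0
    spike_grid_rate: float = 12800.0

    def __post_init__(self) -> None:
        for name in ("protraction_s", "plateau_s", "retraction_s", "interstimulus_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.background_normal >= self.normal_plateau:
            raise ValueError("background force must be below the plateau force")
        if self.mech_sample_rate <= 0 or self.spike_grid_rate <= 0:
            raise ValueError("sample rates must be positive")

    @property
    def cycle_s(self) -> float:
        return self.protraction_s + self.plateau_s + self.retraction_s + self.interstimulus_s

    @property
    def samples_per_cycle(self) -> int:
        n = self.cycle_s * self.mech_sample_rate
        n_int = int(round(n))
        if abs(n - n_int) > 1e-9:
            raise ValueError("cycle duration must be an integer number of samples")
        return n_int


@dataclass(frozen=True)
class ForceTrace:
    """Force time series on a uniform grid; columns (x, y, z), newtons.

    z is the compressive normal force (>= 0); x/y are the tangential
    components in the radial/ulnar and distal/proximal axes.
    """

    times: np.ndarray
    force: np.ndarray

    def __post_init__(self) -> None:
        if self.force.shape != (len(self.times), 3):
            raise ValueError("force must be (n, 3)")


def force_envelope(t_rel: np.ndarray, protocol: ForceProtocol) -> np.ndarray:
    """Dimensionless loading envelope (0 at rest, 1 at the plateau).

    The ramps follow half of a raised-cosine cycle of the protocol's ramp
    frequency: during protraction ``sin^2(pi * t / (2 * T_pr))`` which for
    T_pr = 125 ms is exactly half a period of a 4 Hz sinusoid, and the mirror
    image during retraction.
    """
    t = np.asarray(t_rel, dtype=float)
    e = np.zeros_like(t)
    t_pr = protocol.protraction_s
    t_pl_end = t_pr + protocol.plateau_s
    t_re_end = t_pl_end + protocol.retraction_s

    ramp_up = (t >= 0) & (t < t_pr)
    e[ramp_up] = np.sin(np.pi * t[ramp_up] / (2 * t_pr)) ** 2
    e[(t >= t_pr) & (t < t_pl_end)] = 1.0
    ramp_down = (t >= t_pl_end) & (t < t_re_end)
    e[ramp_down] = np.cos(np.pi * (t[ramp_down] - t_pl_end) / (2 * protocol.retraction_s)) ** 2
    return e


def generate_force_trajectory(
    direction: Direction, protocol: ForceProtocol | None = None
) -> ForceTrace:
    """Force trace for a single loading cycle in the given direction.

    The normal force rises from the background (0.2 N) to the plateau (4 N)
    along the half-sinusoid envelope and returns the same way; tangential
    components follow the same envelope scaled to the tangential plateau along
    the direction's axis (identically zero for N).
    """
    protocol = protocol or ForceProtocol()
    n = protocol.samples_per_cycle
    times = np.arange(n) / protocol.mech_sample_rate
    env = force_envelope(times, protocol)
    ax, ay = TANGENTIAL_AXIS[direction]
    force = np.empty((n, 3))
    force[:, 0] = protocol.tangential_plateau * ax * env
    force[:, 1] = protocol.tangential_plateau * ay * env
    force[:, 2] = protocol.background_normal + (
        protocol.normal_plateau - protocol.background_normal
    ) * env
    return ForceTrace(times=times, force=force)


@dataclass(frozen=True)
class SequenceTrial:
    direction: Direction
    analysable: bool


def build_regular_sequence(
    protocol: ForceProtocol | None = None, n_repeats: int = 6, n_warmup: int = 1
) -> list[SequenceTrial]:
    """Fixed-order sequence: ``n_repeats`` repeats of (R, D, U, P, N).

    The first ``n_warmup`` repeats standardize the stimulation history and are
    flagged non-analysable, leaving 5 analysable trials per direction with the
    default 6 repeats.
    """
    trials: list[SequenceTrial] = []
    for rep in range(n_repeats):
        for d in CANONICAL_ORDER:
            trials.append(SequenceTrial(direction=d, analysable=rep >= n_warmup))
    return trials


def _eulerian_order(n_symbols: int, start: int, rng: np.random.Generator) -> list[int]:
    """Eulerian circuit on the complete digraph with self-loops over n symbols.

    Hierholzer's algorithm with seeded edge shuffling. The returned node list
    has n^2 + 1 entries, starts and ends at ``start``, and traverses every
    ordered pair (i, j) exactly once.
    """
    adjacency = {v: list(rng.permutation(n_symbols)) for v in range(n_symbols)}
    stack = [start]
    path: list[int] = []
    while stack:
        v = stack[-1]
        if adjacency[v]:
            stack.append(int(adjacency[v].pop()))
        else:
            path.append(stack.pop())
    path.reverse()
    assert len(path) == n_symbols * n_symbols + 1, "corrupted Euler graph"
    return path


def build_irregular_sequence(
    predecessor: Direction = Direction.N, seed: int = 0
) -> list[Direction]:
    """History-balanced sequence of 25 trials.

    Counting the transition from ``predecessor`` (the last regular trial) into
    the first irregular trial, every ordered pair (previous, current) over the
    five directions occurs exactly once. Constructed as a seeded Eulerian
    circuit on the complete digraph with self-loops.
    """
    rng = np.random.default_rng(seed)
    path = _eulerian_order(len(CANONICAL_ORDER), predecessor.index, rng)
    return [CANONICAL_ORDER[i] for i in path[1:]]


def transition_counts(
    sequence: list[Direction], predecessor: Direction
) -> np.ndarray:
    """5x5 matrix of (previous -> current) transition counts, canonical order."""
    counts = np.zeros((5, 5), dtype=int)
    prev = predecessor
    for d in sequence:
        counts[prev.index, d.index] += 1
        prev = d
    return counts
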