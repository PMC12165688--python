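"""Viscoelastic fingertip mechanics: anisotropic standard-linear-solid model.

Each axis of contactor displacement follows a Zener (standard linear solid)
creep response: an instantaneous elastic term ``F / k_inst`` plus a delayed
compartment with stiffness ``k_delayed`` and relaxation time ``tau`` obeying
``tau * du/dt = F / k_delayed - u``. A static 3x3 coupling matrix mixes the
axes (anisotropic cross-talk), and Gaussian measurement noise is added last.
Seconds-scale ``tau`` values give the model the loading-history memory —
creep during force plateaus, creep recovery during interstimulus periods, and
force/position hysteresis — that the downstream analyses probe.

This is deliberately a linear phenomenological model, not a biofidelic skin
model: the analyses only require history dependence with realistic time
constants and millimetre-scale displacements.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .protocol import ForceTrace


@dataclass(frozen=True)
class ZenerAxis:
    """Per-axis standard-linear-solid parameters.

    k_inst, k_delayed in N/mm; tau in seconds.
    """

    k_inst: float
    k_delayed: float
    tau: float

    def __post_init__(self) -> None:
        if self.k_inst <= 0 or self.k_delayed <= 0:
            raise ValueError("stiffnesses must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def _default_axes() -> tuple[ZenerAxis, ZenerAxis, ZenerAxis]:
    # Tangential axes: soft delayed compartment with a relaxation time around
    # one second, so that a substantial fraction of a loading's tangential
    # creep survives the 250 ms interstimulus period into the next trial while
    # the trace of trials further back decays quickly enough for the
    # immediately preceding loading to dominate the residual state. Normal
    # axis: stiffer and faster, dominated by the repeated identical 4 N
    # plateau.
    return (
        ZenerAxis(k_inst=2.0, k_delayed=1.0, tau=1.2),
        ZenerAxis(k_inst=2.0, k_delayed=1.0, tau=1.2),
        ZenerAxis(k_inst=2.0, k_delayed=6.0, tau=1.0),
    )


def _default_coupling() -> np.ndarray:
    # Unit diagonal with small asymmetric off-diagonal terms: a purely normal
    # force also drags the contactor slightly in the tangential plane, and the
    # two tangential axes are not mechanically independent.
    return np.array(
        [
            [1.00, 0.06, 0.04],
            [0.05, 1.00, 0.03],
            [0.02, 0.03, 1.00],
        ]
    )


@dataclass(frozen=True)
class MechanicsParams:
    axes: tuple[ZenerAxis, ZenerAxis, ZenerAxis] = field(default_factory=_default_axes)
    coupling: np.ndarray = field(default_factory=_default_coupling)
    noise_sd: float = 0.005  # mm, measurement noise on the recorded trace

    def __post_init__(self) -> None:
        coupling = np.asarray(self.coupling, dtype=float)
        if coupling.shape != (3, 3):
            raise ValueError("coupling must be 3x3")
        if not np.allclose(np.diag(coupling), 1.0):
            raise ValueError("coupling must have a unit diagonal")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        object.__setattr__(self, "coupling", coupling)


@dataclass(frozen=True)
class ContactorTrace:
    """Contactor position time series; columns (x, y, z), millimetres.

    Same axis convention as :class:`~viscotact.protocol.ForceTrace`; the
    origin is the unloaded rest position.
    """

    times: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        if self.pos.shape != (len(self.times), 3):
            raise ValueError("pos must be (n, 3)")


def zener_creep_response(axis: ZenerAxis, force: float, t: float | np.ndarray) -> np.ndarray:
    """Closed-form creep under a force step applied at t = 0.

    ``u(t) = F/k_inst + (F/k_delayed) * (1 - exp(-t/tau))`` — the oracle for
    :func:`simulate_contactor` under step loading.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    return force / axis.k_inst + (force / axis.k_delayed) * (1.0 - np.exp(-t / axis.tau))


def simulate_contactor(
    session_force: ForceTrace,
    params: MechanicsParams | None = None,
    seed: int | np.random.Generator = 0,
) -> ContactorTrace:
    """Integrate the Zener model over a (possibly multi-trial) force trace.

    The delayed compartment uses the exact exponential (zero-order-hold)
    update per step, so the discrete solution matches the continuous one for
    piecewise-constant force. Axes are mixed by the coupling matrix after
    integration and seeded Gaussian measurement noise is added last.
    """
    params = params or MechanicsParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = np.asarray(session_force.times, dtype=float)
    if len(times) < 2:
        raise ValueError("force trace too short")
    dt = np.diff(times)
    if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
        raise ValueError("force trace must be on a uniform time grid")
    dt0 = float(dt[0])

    raw = np.empty_like(session_force.force)
    for a, axis in enumerate(params.axes):
        f = session_force.force[:, a]
        target = f / axis.k_delayed
        decay = np.exp(-dt0 / axis.tau)
        # u[n] = decay * u[n-1] + (1 - decay) * target[n-1], u[0] = 0:
        # first-order recursion with a one-step input delay (ZOH on F).
        u = lfilter([0.0, 1.0 - decay], [1.0, -decay], target)
        raw[:, a] = f / axis.k_inst + u

    pos = raw @ params.coupling.T
    if params.noise_sd > 0:
        pos = pos + rng.normal(0.0, params.noise_sd, size=pos.shape)
    return ContactorTrace(times=times, pos=pos)
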