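"""Synthetic session assembly: protocol + mechanics + afferents.

A session concatenates the regular sequence (30 trials, first repeat warm-up)
and the irregular sequence (25 trials, predecessor N) into one continuous
force trace, integrates the viscoelastic mechanics across the whole session
so that deformation history crosses trial boundaries, and generates spike
trains for a population of synthetic afferents. All randomness flows from a
single root seed through named substreams.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .afferents import AfferentModel, afferent_rate, generate_spike_train, make_afferent_population
from .mechanics import ContactorTrace, MechanicsParams, simulate_contactor
from .preprocess import PhaseSchedule, RateTrace, slice_spikes
from .protocol import (
    Direction,
    ForceProtocol,
    ForceTrace,
    build_irregular_sequence,
    build_regular_sequence,
    generate_force_trajectory,
)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child RNG stream of a root seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


@dataclass(frozen=True)
class SessionConfig:
    protocol: ForceProtocol = field(default_factory=ForceProtocol)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    n_fa1: int = 15
    n_sa1: int = 15
    n_sa2: int = 10
    sa2_spontaneous_fraction: float = 1.0
    seed: int = 0


@dataclass
class SessionData:
    """In-memory representation of one synthetic recording session."""

    config: SessionConfig
    trials: pd.DataFrame  # trial, sequence, direction, preceding, analysable, phase onsets
    times: np.ndarray
    force: np.ndarray  # (n, 3) N
    contactor: ContactorTrace  # measured (noisy) trace
    neurons: pd.DataFrame  # id, type, spontaneous
    models: list[AfferentModel]
    spikes: dict[int, np.ndarray]
    rates: dict[int, RateTrace] | None = None  # ground-truth rates (synthetic only)

    @property
    def protocol(self) -> ForceProtocol:
        return self.config.protocol

    def schedule(self, trial: int) -> PhaseSchedule:
        row = self.trials.iloc[trial]
        return PhaseSchedule(
            protraction=row.t_protraction,
            plateau=row.t_plateau,
            retraction=row.t_retraction,
            interstimulus=row.t_interstimulus,
            end=row.t_end,
        )

    def analysable(self, sequence: str) -> pd.DataFrame:
        t = self.trials
        return t[(t.sequence == sequence) & t.analysable]

    def spikes_in(
        self, neuron_id: int, trial: int, rel_start: float, rel_end: float, reref: bool = True
    ) -> np.ndarray:
        """Spikes in [rel_start, rel_end) relative to the trial's protraction onset."""
        t0 = self.trials.iloc[trial].t_protraction
        out = slice_spikes(self.spikes[neuron_id], t0 + rel_start, t0 + rel_end, reref=False)
        return out - (t0 + rel_start) if reref else out

    def contactor_in(self, trial: int, rel_start: float, rel_end: float):
        """Contactor slice on [rel_start, rel_end) relative to protraction onset.

        Returned times are relative to the protraction onset; window bounds
        must be multiples of the mechanical sample step.
        """
        fs = self.protocol.mech_sample_rate
        t0 = self.trials.iloc[trial].t_protraction
        i0 = int(round((t0 + rel_start) * fs))
        i1 = int(round((t0 + rel_end) * fs))
        if i0 < 0 or i1 > len(self.times):
            raise ValueError("window outside recorded session")
        return self.times[i0:i1] - t0, self.contactor.pos[i0:i1]


def _build_trial_table(config: SessionConfig, seed: int) -> pd.DataFrame:
    protocol = config.protocol
    regular = build_regular_sequence(protocol)
    irregular = build_irregular_sequence(
        predecessor=regular[-1].direction, seed=int(substream(seed, "sequence").integers(2**31))
    )
    rows = []
    directions: list[Direction] = []
    for k, tr in enumerate(regular):
        directions.append(tr.direction)
        rows.append(("regular", tr.direction, tr.analysable))
    for d in irregular:
        directions.append(d)
        rows.append(("irregular", d, True))

    cycle = protocol.cycle_s
    records = []
    for k, (sequence, d, analysable) in enumerate(rows):
        t0 = k * cycle
        preceding = directions[k - 1].value if k > 0 else None
        records.append(
            dict(
                trial=k,
                sequence=sequence,
                direction=d.value,
                preceding=preceding,
                analysable=analysable and preceding is not None,
                t_protraction=t0,
                t_plateau=t0 + protocol.protraction_s,
                t_retraction=t0 + protocol.protraction_s + protocol.plateau_s,
                t_interstimulus=t0 + cycle - protocol.interstimulus_s,
                t_end=t0 + cycle,
            )
        )
    return pd.DataFrame.from_records(records)


def generate_dataset(
    config: SessionConfig | None = None,
    seed: int | None = None,
    models: list[AfferentModel] | None = None,
) -> SessionData:
    """Generate a complete synthetic session.

    Deterministic given ``(config, seed)``; ``seed`` overrides ``config.seed``
    when given. Ground-truth afferent parameters and noiseless firing rates
    are retained for recovery tests. An explicit afferent population
    (``models``) replaces the one drawn from the config counts.
    """
    config = config or SessionConfig()
    if seed is not None:
        config = replace(config, seed=int(seed))
    root = config.seed
    protocol = config.protocol

    trials = _build_trial_table(config, root)
    per_trial = [
        generate_force_trajectory(Direction(d), protocol) for d in trials.direction
    ]
    n_cycle = protocol.samples_per_cycle
    n_total = n_cycle * len(trials)
    times = np.arange(n_total) / protocol.mech_sample_rate
    force = np.vstack([ft.force for ft in per_trial])
    session_force = ForceTrace(times=times, force=force)

    true_contactor = simulate_contactor(
        session_force, replace(config.mechanics, noise_sd=0.0), seed=0
    )
    measured = simulate_contactor(
        session_force, config.mechanics, seed=substream(root, "mechanics")
    )

    if models is None:
        models = make_afferent_population(
            config.n_fa1,
            config.n_sa1,
            config.n_sa2,
            seed=substream(root, "afferents"),
            sa2_spontaneous_fraction=config.sa2_spontaneous_fraction,
        )
    neurons = pd.DataFrame(
        dict(
            id=range(len(models)),
            type=[m.archetype for m in models],
            spontaneous=[m.spontaneous for m in models],
        )
    )
    spikes: dict[int, np.ndarray] = {}
    rates: dict[int, RateTrace] = {}
    session_end = n_total / protocol.mech_sample_rate
    for i, m in enumerate(models):
        rate = afferent_rate(true_contactor, m)
        rates[i] = rate
        train = generate_spike_train(rate, m, seed=substream(root, f"spikes/{i}"))
        spikes[i] = train[train < session_end]  # latency can push past the last trial

    return SessionData(
        config=config,
        trials=trials,
        times=times,
        force=force,
        contactor=measured,
        neurons=neurons,
        models=models,
        spikes=spikes,
        rates=rates,
    )
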