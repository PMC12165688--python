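"""Session directory format: plain CSV/JSON/TOML, diff-able and language neutral.

Layout written by :func:`write_session`::

    manifest.json   metadata, seeds, format version, ground-truth neuron params
    trials.csv      trial, sequence, direction, preceding, analysable, phase onsets
    forces.csv      long format: time, axis, value  (N)
    contactor.csv   long format: time, axis, value  (mm)
    spikes.csv      neuron, grid_index, time  (12.8 kHz grid index + seconds)
    config.toml     configuration snapshot

Times are in seconds with 6 decimal places, except spike times which are
stored alongside their integer 12.8 kHz grid index so the read path
reconstructs them exactly.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .afferents import SPIKE_GRID_HZ, AfferentModel
from .mechanics import ContactorTrace, MechanicsParams, ZenerAxis
from .protocol import Direction, ForceProtocol, transition_counts
from .session import SessionConfig, SessionData

FORMAT_VERSION = 1
AXES = ("x", "y", "z")


class SessionFormatError(ValueError):
    """Raised when a session directory fails validation."""


def _long_format(times: np.ndarray, values: np.ndarray) -> pd.DataFrame:
    n = len(times)
    return pd.DataFrame(
        {
            "time": np.round(np.tile(times, 3), 6),
            "axis": np.repeat(AXES, n),
            "value": np.round(values.T.ravel(), 6),
        }
    )


def dump_toml(data: dict, path: Path) -> None:
    """Minimal TOML writer for nested dicts of scalars and flat lists."""

    def fmt(v):
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, (int, float, np.integer, np.floating)):
            return repr(float(v)) if isinstance(v, (float, np.floating)) else str(int(v))
        if isinstance(v, str):
            return json.dumps(v)
        if isinstance(v, (list, tuple, np.ndarray)):
            return "[" + ", ".join(fmt(x) for x in v) + "]"
        raise TypeError(f"unsupported TOML value {v!r}")

    lines: list[str] = []

    def emit(table: dict, prefix: str) -> None:
        scalars = {k: v for k, v in table.items() if not isinstance(v, dict)}
        subtables = {k: v for k, v in table.items() if isinstance(v, dict)}
        if prefix and scalars:
            lines.append(f"[{prefix}]")
        for k, v in scalars.items():
            lines.append(f"{k} = {fmt(v)}")
        for k, v in subtables.items():
            lines.append("")
            emit(v, f"{prefix}.{k}" if prefix else k)

    emit(data, "")
    path.write_text("\n".join(lines) + "\n")


def _config_dict(config: SessionConfig) -> dict:
    mech = config.mechanics
    return {
        "session": {
            "seed": config.seed,
            "n_fa1": config.n_fa1,
            "n_sa1": config.n_sa1,
            "n_sa2": config.n_sa2,
            "sa2_spontaneous_fraction": config.sa2_spontaneous_fraction,
        },
        "protocol": asdict(config.protocol),
        "mechanics": {
            "noise_sd": mech.noise_sd,
            "coupling": [list(map(float, row)) for row in mech.coupling],
            **{
                f"axis_{name}": asdict(ax)
                for name, ax in zip(AXES, mech.axes)
            },
        },
    }


def config_from_dict(data: dict) -> SessionConfig:
    protocol = ForceProtocol(**data.get("protocol", {}))
    mech_data = dict(data.get("mechanics", {}))
    axes = tuple(
        ZenerAxis(**mech_data.pop(f"axis_{name}")) if f"axis_{name}" in mech_data else ax
        for name, ax in zip(AXES, MechanicsParams().axes)
    )
    mechanics = MechanicsParams(
        axes=axes,
        coupling=np.asarray(mech_data.get("coupling", MechanicsParams().coupling)),
        noise_sd=mech_data.get("noise_sd", MechanicsParams().noise_sd),
    )
    sess = data.get("session", {})
    return SessionConfig(
        protocol=protocol,
        mechanics=mechanics,
        n_fa1=int(sess.get("n_fa1", 15)),
        n_sa1=int(sess.get("n_sa1", 15)),
        n_sa2=int(sess.get("n_sa2", 10)),
        sa2_spontaneous_fraction=float(sess.get("sa2_spontaneous_fraction", 1.0)),
        seed=int(sess.get("seed", 0)),
    )


def write_session(session: SessionData, directory: str | Path) -> Path:
    """Write a session to a directory; returns the directory path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    manifest = {
        "format_version": FORMAT_VERSION,
        "seed": session.config.seed,
        "spike_grid_rate": SPIKE_GRID_HZ,
        "mech_sample_rate": session.protocol.mech_sample_rate,
        "n_trials": len(session.trials),
        "neurons": [
            {
                "id": int(i),
                "type": m.archetype,
                "spontaneous": bool(m.spontaneous),
                "weights": [float(w) for w in m.weights],
                "bias": m.bias,
                "gain": m.gain,
                "latency_s": m.latency_s,
                "refractory_s": m.refractory_s,
            }
            for i, m in enumerate(session.models)
        ],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    trials = session.trials.copy()
    for col in ("t_protraction", "t_plateau", "t_retraction", "t_interstimulus", "t_end"):
        trials[col] = trials[col].round(6)
    trials.to_csv(directory / "trials.csv", index=False)

    _long_format(session.times, session.force).to_csv(directory / "forces.csv", index=False)
    _long_format(session.times, session.contactor.pos).to_csv(
        directory / "contactor.csv", index=False
    )

    rows = []
    for nid, spikes in session.spikes.items():
        idx = np.round(spikes * SPIKE_GRID_HZ).astype(int)
        rows.append(pd.DataFrame({"neuron": nid, "grid_index": idx, "time": spikes}))
    spikes_df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["neuron", "grid_index", "time"])
    )
    spikes_df["time"] = spikes_df["time"].round(6)
    spikes_df.to_csv(directory / "spikes.csv", index=False)

    dump_toml(_config_dict(session.config), directory / "config.toml")
    return directory


def read_session(directory: str | Path) -> SessionData:
    """Read and validate a session directory written by :func:`write_session`.

    Ground-truth firing rates are not stored on disk; ``rates`` is ``None``
    on the returned session (regenerate from the manifest seed if needed).
    """
    import tomllib

    directory = Path(directory)
    for fname in (
        "manifest.json",
        "trials.csv",
        "forces.csv",
        "contactor.csv",
        "spikes.csv",
        "config.toml",
    ):
        if not (directory / fname).exists():
            raise SessionFormatError(f"missing {fname} in {directory}")
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest.get("format_version") != FORMAT_VERSION:
        raise SessionFormatError("unsupported format version")

    config = config_from_dict(tomllib.loads((directory / "config.toml").read_text()))
    trials = pd.read_csv(directory / "trials.csv")
    _validate_trials(trials)

    def wide(fname: str) -> np.ndarray:
        df = pd.read_csv(directory / fname)
        pivot = df.pivot(index="time", columns="axis", values="value").sort_index()
        return pivot[list(AXES)].to_numpy()

    force_df = pd.read_csv(directory / "forces.csv")
    times = np.sort(force_df.time.unique())
    force = wide("forces.csv")
    contactor_pos = wide("contactor.csv")

    spikes_df = pd.read_csv(directory / "spikes.csv")
    models = [
        AfferentModel(
            archetype=n["type"],
            weights=np.asarray(n["weights"]),
            bias=n["bias"],
            gain=n["gain"],
            latency_s=n["latency_s"],
            refractory_s=n["refractory_s"],
            spontaneous=n["spontaneous"],
        )
        for n in manifest["neurons"]
    ]
    t_end = trials.t_end.max()
    spikes: dict[int, np.ndarray] = {}
    for nid in range(len(models)):
        sub = spikes_df[spikes_df.neuron == nid]
        st = np.asarray(sub.grid_index, dtype=float) / manifest["spike_grid_rate"]
        if np.any(np.diff(st) <= 0):
            raise SessionFormatError(f"non-monotone spike times for neuron {nid}")
        if len(st) and (st[0] < 0 or st[-1] > t_end):
            raise SessionFormatError(f"spike outside session span for neuron {nid}")
        spikes[nid] = st

    neurons = pd.DataFrame(
        dict(
            id=range(len(models)),
            type=[m.archetype for m in models],
            spontaneous=[m.spontaneous for m in models],
        )
    )
    return SessionData(
        config=config,
        trials=trials,
        times=times,
        force=force,
        contactor=ContactorTrace(times=times, pos=contactor_pos),
        neurons=neurons,
        models=models,
        spikes=spikes,
        rates=None,
    )


def _validate_trials(trials: pd.DataFrame) -> None:
    regular = trials[trials.sequence == "regular"]
    irregular = trials[trials.sequence == "irregular"]
    order = [d.value for d in Direction]
    for rep in range(len(regular) // 5):
        block = list(regular.direction.iloc[5 * rep : 5 * rep + 5])
        if block != order[:5] and block != ["R", "D", "U", "P", "N"]:
            raise SessionFormatError(f"regular repeat {rep} violates fixed order: {block}")
    if len(irregular):
        predecessor = Direction(regular.direction.iloc[-1])
        seq = [Direction(d) for d in irregular.direction]
        counts = transition_counts(seq, predecessor)
        if not np.all(counts == 1):
            bad = np.argwhere(counts != 1)[0]
            pair = (order[bad[0]], order[bad[1]])
            raise SessionFormatError(
                f"irregular sequence transition balance violated at pair {pair}"
            )
    # preceding consistency
    directions = list(trials.direction)
    for k in range(1, len(trials)):
        expected = directions[k - 1]
        actual = trials.preceding.iloc[k]
        if actual != expected:
            raise SessionFormatError(
                f"trial {k}: preceding={actual!r} but previous direction was {expected!r}"
            )
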