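"""Pipeline orchestration: simulate -> variability -> encoding -> information
-> population, with structured logging and reproducible seeded substreams.

Each stage writes tidy CSV/JSON results into the output directory; a combined
``summary.json`` collects the headline numbers. Stages can be run in
isolation against a previously written session directory.
"""
from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import encoding as enc
from . import information as info
from . import population as pop
from . import variability as var
from .protocol import Direction
from .session import SessionConfig, SessionData, generate_dataset
from .session_io import write_session

log = logging.getLogger("viscotact")

STAGES = ("variability", "encoding", "information", "population")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_variability(session: SessionData, out: Path) -> dict:
    neuron_ids = list(session.neurons.id)
    rows = []
    for seq in ("regular", "irregular"):
        for ntype in ("FA1", "SA1", "SA2"):
            ids = list(session.neurons[session.neurons.type == ntype].id)
            traces = [var.rate_sd_timecourse(session, nid, seq) for nid in ids]
            mean_sd = np.mean([t.sd for t in traces], axis=0)
            for t_rel, sd in zip(traces[0].times, mean_sd):
                rows.append(dict(time=t_rel, group=f"{seq}/{ntype}", sd=sd))
        ksd = var.kinematic_sd_timecourse(session, seq)
        for t_rel, sd in zip(ksd.times, ksd.sd):
            rows.append(dict(time=t_rel, group=f"{seq}/position", sd=sd))
    pd.DataFrame(rows).to_csv(out / "variability.csv", index=False)

    stats = var.sequence_contrast(session, neuron_ids)
    ksd_reg = var.kinematic_sd_timecourse(session, "regular")
    ksd_irr = var.kinematic_sd_timecourse(session, "irregular")
    onset = int(np.argmin(np.abs(ksd_reg.times)))
    summary = {
        "phase_tests": stats,
        "phase_scalar": "time-averaged SD within phase",
        "position_sd_ratio_at_onset": float(ksd_irr.sd[onset] / ksd_reg.sd[onset]),
    }
    (out / "variability_stats.json").write_text(json.dumps(_jsonable(summary), indent=1))
    return summary


def run_encoding(
    session: SessionData,
    out: Path,
    config: enc.EncodingConfig | None = None,
    max_neurons: int | None = None,
) -> dict:
    config = config or enc.EncodingConfig(seed=session.config.seed)
    included = [i for i in session.neurons.id if enc.inclusion_filter(session, int(i))]
    if max_neurons is not None:
        included = included[:max_neurons]
    rows = []
    for nid in included:
        res = enc.encode_neuron(session, int(nid), config)
        row = {"neuron": nid, "type": res["type"]}
        for mc in enc.MODEL_CLASSES:
            row[f"r2_{mc}"] = res[mc]["cv_r2"]
        row["r2_reduced6"] = res["reduced"]["cv_r2"]
        row["reduced_drop"] = res["reduced"]["drop_vs_full"]
        row["top6"] = ";".join(res["reduced"]["predictors"])
        rows.append(row)
        log.info("encoding neuron=%s type=%s r2_2way=%.3f", nid, res["type"], row["r2_2way"])
    df = pd.DataFrame(rows)
    df.to_csv(out / "encoding.csv", index=False)
    summary = {"n_included": len(included)}
    for ntype, sub in df.groupby("type"):
        entry = {}
        for mc in enc.MODEL_CLASSES:
            r = np.sqrt(np.clip(sub[f"r2_{mc}"].to_numpy(), 0, None))
            entry[mc] = enc.summarize_r2_fisher(r)["mean_r2"]
        entry["median_reduced_drop"] = float(sub.reduced_drop.median())
        summary[ntype] = entry
    (out / "encoding_summary.json").write_text(json.dumps(_jsonable(summary), indent=1))
    return summary


def run_information(
    session: SessionData, out: Path, max_neurons: int | None = None
) -> dict:
    ids = [i for i in session.neurons.id if enc.inclusion_filter(session, int(i))]
    if max_neurons is not None:
        ids = ids[:max_neurons]
    curves, cats = [], []
    for nid in ids:
        curve = info.neuron_info_analysis(session, int(nid), "protraction")
        curve.insert(0, "neuron", nid)
        curves.append(curve)
        cat = info.categorize_neuron(curve)
        cat["neuron"] = nid
        cat["type"] = session.models[int(nid)].archetype
        cats.append(cat)
        log.info("information neuron=%s category=%s", nid, cat["label"])
    pd.concat(curves, ignore_index=True).to_csv(out / "info_curves.csv", index=False)
    cat_df = pd.DataFrame(cats)
    cat_df.to_csv(out / "categories.csv", index=False)
    summary = {
        "n_analysed": len(ids),
        "category_counts": cat_df.label.value_counts().to_dict(),
    }
    (out / "info_summary.json").write_text(json.dumps(_jsonable(summary), indent=1))
    return summary


def run_population(session: SessionData, out: Path) -> dict:
    results = pop.run_population_geometry(session)
    trials = session.analysable("irregular")
    groups = [Direction(d).value for d in trials.preceding]
    rows, vrows = [], []
    for tp, res in results.items():
        emb = res["embedding"]
        for k in range(len(emb.coords)):
            rows.append(
                dict(
                    time_point=tp,
                    trial=int(trials.trial.iloc[k]),
                    preceding=groups[k],
                    emb_x=emb.coords[k, 0],
                    emb_y=emb.coords[k, 1],
                    ref_x=emb.reference[k, 0],
                    ref_y=emb.reference[k, 1],
                )
            )
        for what in ("reference", "embedding"):
            v = res[f"variance_{what}"]
            vrows.append(
                dict(
                    time_point=tp,
                    representation=what,
                    total=v["total"],
                    within=v["within"],
                    ratio=v["total"] / v["within"],
                )
            )
    pd.DataFrame(rows).to_csv(out / "population_coords.csv", index=False)
    pd.DataFrame(vrows).to_csv(out / "population_variance.csv", index=False)
    summary = {
        "disparity": {str(tp): res["embedding"].disparity for tp, res in results.items()},
        "variance": vrows,
    }
    (out / "population_summary.json").write_text(json.dumps(_jsonable(summary), indent=1))
    return summary


def run_pipeline(
    config: SessionConfig,
    stages: list[str],
    out_dir: str | Path,
    session: SessionData | None = None,
    encoding_config: enc.EncodingConfig | None = None,
    max_neurons: int | None = None,
) -> dict:
    """Execute the requested stages in canonical order; returns the summary.

    ``simulate`` generates (and writes) the session; analysis stages require
    a session, either simulated here or passed in (e.g. from
    :func:`~viscotact.session_io.read_session`).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}
    if "simulate" in stages:
        t0 = time.time()
        session = generate_dataset(config)
        write_session(session, out_dir / "session")
        log.info("stage=simulate seed=%s wall=%.1fs", config.seed, time.time() - t0)
        summary["stages"]["simulate"] = {"n_trials": len(session.trials)}
    runners = {
        "variability": run_variability,
        "encoding": lambda s, o: run_encoding(s, o, encoding_config, max_neurons),
        "information": lambda s, o: run_information(s, o, max_neurons),
        "population": run_population,
    }
    for stage in STAGES:
        if stage in stages:
            if session is None:
                raise ValueError(f"stage {stage!r} requires a session (run simulate first)")
            t0 = time.time()
            summary["stages"][stage] = runners[stage](session, out_dir)
            log.info("stage=%s wall=%.1fs", stage, time.time() - t0)
    (out_dir / "summary.json").write_text(json.dumps(_jsonable(summary), indent=1))
    return summary
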