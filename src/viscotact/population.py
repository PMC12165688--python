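"""SA-2 population geometry: spike-distance matrices, MDS, Procrustes.

The deformation state of the fingertip between loadings is read out from the
tonically active SA-2 models: per-neuron Victor–Purpura distance matrices
over the 25 irregular trials are summed across the population, embedded in
2D by metric MDS (stress majorization), and aligned to the mean tangential
contactor positions by full Procrustes analysis (translation, rotation,
reflection, uniform scaling). Comparing total variance across all 25 trial
points with the mean within-preceding-direction variance quantifies how
strongly trials cluster by the preceding force direction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.manifold import MDS

from .information import pairwise_distance_matrix
from .protocol import Direction
from .session import SessionData, substream

#: default analysis time points, s relative to protraction onset:
#: middle and end of the interstimulus period, end of protraction
TIME_POINTS = (-0.125, 0.0, 0.125)


@dataclass(frozen=True)
class EmbeddingResult:
    """Procrustes-aligned 2D configuration (mm) with its goodness of fit."""

    coords: np.ndarray  # (25, 2), aligned to the reference, mm
    reference: np.ndarray  # (25, 2) mean tangential contactor positions, mm
    stress: float  # raw MDS stress
    disparity: float  # normalized Procrustes residual in [0, 1]


def _window_for(time_point: float, protocol) -> tuple[float, float, float]:
    """(origin, end, resolution) of the spike window ending at a time point.

    Interstimulus time points use windows from the interstimulus start at
    32 ms resolution; protraction time points use windows from protraction
    onset at 8 ms resolution.
    """
    if time_point <= 0:
        return -protocol.interstimulus_s, time_point, 0.032
    return 0.0, time_point, 0.008


def population_distances(
    session: SessionData,
    neuron_ids: list[int],
    time_point: float,
    resolution_s: float | None = None,
) -> np.ndarray:
    """25x25 summed VP distance matrix across the given neurons."""
    if len(neuron_ids) == 0:
        raise ValueError("no neurons given")
    origin, end, default_res = _window_for(time_point, session.protocol)
    q = 2.0 / (resolution_s if resolution_s is not None else default_res)
    trials = session.analysable("irregular")
    total = None
    for nid in neuron_ids:
        trains = [
            session.spikes_in(nid, int(row.trial), origin, end) for _, row in trials.iterrows()
        ]
        D = pairwise_distance_matrix(trains, q)
        total = D if total is None else total + D
    return total


def tonic_sa2_ids(session: SessionData) -> list[int]:
    """Neurons flagged as spontaneously (tonically) active SA-2 models."""
    n = session.neurons
    return list(n[(n.type == "SA2") & n.spontaneous].id)


def mds_embed(
    distances: np.ndarray, dims: int = 2, seed: int = 0, n_init: int = 8
) -> tuple[np.ndarray, float]:
    """Metric MDS by stress majorization (SMACOF), seeded multi-start.

    Returns the best-stress configuration, centered at the origin.
    """
    mds = MDS(
        n_components=dims,
        metric_mds=True,
        metric="precomputed",
        init="random",
        n_init=n_init,
        max_iter=1000,
        eps=1e-9,
        random_state=int(seed) % (2**31),
        normalized_stress=False,
    )
    coords = mds.fit_transform(np.asarray(distances, dtype=float))
    return coords - coords.mean(axis=0), float(mds.stress_)


def procrustes_align(
    raw_coords: np.ndarray, reference: np.ndarray, stress: float = np.nan
) -> EmbeddingResult:
    """Full Procrustes superimposition of an embedding onto a reference.

    Translation, rotation, reflection and uniform scaling are all allowed.
    The disparity is the standardized residual ``1 - (sum of singular
    values)^2`` in [0, 1] (0 = exact match up to similarity transform);
    the returned coordinates live in the reference's space and units.
    """
    X = np.asarray(raw_coords, dtype=float)
    Y = np.asarray(reference, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("configurations must have equal shape")
    mu_y = Y.mean(axis=0)
    X0 = X - X.mean(axis=0)
    Y0 = Y - mu_y
    norm_x = np.linalg.norm(X0)
    norm_y = np.linalg.norm(Y0)
    if norm_x == 0 or norm_y == 0:
        raise ValueError("degenerate (zero-variance) configuration")
    X0 /= norm_x
    Y0 /= norm_y
    u, s, vt = np.linalg.svd(X0.T @ Y0)
    rotation = u @ vt
    scale = s.sum()
    aligned_std = scale * (X0 @ rotation)
    disparity = float(max(0.0, 1.0 - scale**2))
    coords = aligned_std * norm_y + mu_y
    return EmbeddingResult(
        coords=coords, reference=Y, stress=float(stress), disparity=disparity
    )


def reference_positions(
    sessions: SessionData | list[SessionData], time_point: float
) -> np.ndarray:
    """Mean tangential (x, y) contactor position per irregular trial, mm.

    Sampled at ``time_point`` relative to each trial's protraction onset and
    averaged across sessions (trials are matched by irregular-sequence
    position).
    """
    if isinstance(sessions, SessionData):
        sessions = [sessions]
    per_session = []
    for s in sessions:
        fs = s.protocol.mech_sample_rate
        step = 1.0 / fs
        pts = []
        for _, row in s.analysable("irregular").iterrows():
            _, pos = s.contactor_in(int(row.trial), time_point, time_point + step)
            pts.append(pos[0, :2])
        per_session.append(np.asarray(pts))
    return np.mean(per_session, axis=0)


def variance_decomposition(points: np.ndarray, groups: np.ndarray) -> dict[str, float]:
    """Total vs. within-group 2D variance of a point configuration.

    ``total`` is the trace of the covariance over all points; ``within`` is
    the mean over groups of the trace covariance within each group (n-1
    denominators throughout). Their ratio measures clustering by group.
    """
    points = np.asarray(points, dtype=float)
    groups = np.asarray(groups)
    total = float(np.trace(np.cov(points.T, ddof=1)))
    wins = []
    for g in np.unique(groups):
        member = points[groups == g]
        if len(member) < 2:
            raise ValueError("each group needs at least 2 points")
        wins.append(float(np.trace(np.cov(member.T, ddof=1))))
    return {"total": total, "within": float(np.mean(wins))}


def run_population_geometry(
    session: SessionData,
    time_points: tuple[float, ...] = TIME_POINTS,
    neuron_ids: list[int] | None = None,
) -> dict[float, dict]:
    """Full Fig.-8-style analysis at each time point.

    Returns, per time point, the aligned embedding and the variance
    decompositions (grouped by preceding direction) of both the contactor
    reference positions and the aligned SA-2 embedding.
    """
    neuron_ids = neuron_ids if neuron_ids is not None else tonic_sa2_ids(session)
    trials = session.analysable("irregular")
    groups = np.array([Direction(d).index for d in trials.preceding])
    results: dict[float, dict] = {}
    for k, tp in enumerate(time_points):
        D = population_distances(session, neuron_ids, tp)
        seed = int(substream(session.config.seed, f"mds/{k}").integers(2**31))
        raw, stress = mds_embed(D, seed=seed)
        ref = reference_positions(session, tp)
        emb = procrustes_align(raw, ref, stress=stress)
        results[tp] = {
            "embedding": emb,
            "variance_reference": variance_decomposition(ref, groups),
            "variance_embedding": variance_decomposition(emb.coords, groups),
        }
    return results
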