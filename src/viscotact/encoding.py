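"""Predicting time-varying firing rates from contactor kinematics.

Four nested ridge-regression model classes relate a neuron's smoothed firing
rate to contactor movement during the protraction phase of the irregular
sequence: 3D position only, 3D velocity only, position + velocity (6
predictors), and all signals plus their 15 two-way interactions (21
predictors). The regularization strength is selected by an inner 5-fold grid
search; reported R² is the mean over an independent outer 5-fold split.
Fold assignment is by trial, to avoid temporal leakage between adjacent
samples, and features are standardized inside the training folds (a config
switch restores global standardization). Predictors are ranked by
permutation importance on held-out folds and a reduced model refits the top
six.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge
from sklearn.metrics import r2_score
from sklearn.preprocessing import StandardScaler

from .preprocess import differentiate, gaussian_smooth, instantaneous_rate, resample_linear
from .session import SessionData

MODEL_CLASSES = ("pos", "vel", "pos+vel", "2way")
BASE_NAMES = ("Px", "Py", "Pz", "dPx", "dPy", "dPz")


def _default_alphas() -> np.ndarray:
    return np.logspace(-3, 3, 13)


@dataclass(frozen=True)
class EncodingConfig:
    pad_before_s: float = 0.100
    pad_after_s: float = 0.100  # after protraction end -> window [-0.100, 0.225)
    target_rate_hz: float = 1000.0
    smooth_sigma_s: float = 0.010
    rate_advance_s: float = 0.015
    alphas: np.ndarray = field(default_factory=_default_alphas)
    cv_folds: int = 5
    n_perm_repeats: int = 10
    standardize_global: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.alphas) <= 0):
            raise ValueError("alphas must be positive")
        if self.cv_folds < 2:
            raise ValueError("need at least 2 folds")


def inclusion_filter(session: SessionData, neuron_id: int, min_trials: int = 5) -> bool:
    """True iff the neuron fired >= 2 spikes during protraction plus the
    following 100 ms in at least ``min_trials`` of the 25 irregular trials."""
    trials = session.analysable("irregular")
    window_end = session.protocol.protraction_s + 0.100
    n_ok = sum(
        len(session.spikes_in(neuron_id, int(row.trial), 0.0, window_end)) >= 2
        for _, row in trials.iterrows()
    )
    return n_ok >= min_trials


def build_design_matrix(
    base: np.ndarray, model_class: str, base_names: tuple[str, ...] = BASE_NAMES
) -> tuple[np.ndarray, list[str]]:
    """Expand base kinematic signals into the design matrix of a model class.

    ``base`` holds position columns followed by velocity columns (equal
    counts). ``2way`` appends all distinct pairwise products.
    """
    base = np.asarray(base, dtype=float)
    half = base.shape[1] // 2
    if base.shape[1] != 2 * half:
        raise ValueError("base must hold positions then velocities, equal counts")
    names = list(base_names)
    if model_class == "pos":
        return base[:, :half], names[:half]
    if model_class == "vel":
        return base[:, half:], names[half:]
    if model_class == "pos+vel":
        return base, names
    if model_class == "2way":
        pairs = list(itertools.combinations(range(base.shape[1]), 2))
        prod = np.column_stack([base[:, i] * base[:, j] for i, j in pairs])
        prod_names = [f"{names[i]}*{names[j]}" for i, j in pairs]
        return np.column_stack([base, prod]), names + prod_names
    raise ValueError(f"unknown model class {model_class!r}")


def build_trial_data(
    session: SessionData,
    neuron_id: int,
    config: EncodingConfig | None = None,
    y_from_rate: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial kinematic base signals and aligned firing-rate target.

    For every irregular trial: slice the contactor over the padded protraction
    window, linearly resample 400 -> 1000 Hz, Gaussian-smooth (sigma 10 ms),
    differentiate for velocities; the target is the (smoothed) reciprocal-ISI
    firing rate advanced by 15 ms relative to the kinematics, compensating
    conduction and transduction delay. With ``y_from_rate`` the ground-truth
    generative rate replaces the spike-derived rate (noise-free target).
    Returns (base signals (n, 6), y (n,), trial group labels (n,)).
    """
    config = config or EncodingConfig()
    protocol = session.protocol
    rel_start = -config.pad_before_s
    rel_end = protocol.protraction_s + config.pad_after_s
    trials = session.analysable("irregular")
    xs, ys, gs = [], [], []
    mech_step = 1.0 / protocol.mech_sample_rate
    for _, row in trials.iterrows():
        # include one extra mechanical sample so the resampled grid covers the
        # half-open window [rel_start, rel_end) completely
        t_rel, pos = session.contactor_in(int(row.trial), rel_start, rel_end + mech_step)
        grid, pos_hi = resample_linear(t_rel, pos, config.target_rate_hz)
        keep = grid < rel_end - 1e-12
        grid, pos_hi = grid[keep], pos_hi[keep]
        pos_s = gaussian_smooth(pos_hi, config.smooth_sigma_s, config.target_rate_hz)
        vel = differentiate(grid, pos_s)
        abs_grid = row.t_protraction + grid + config.rate_advance_s
        if y_from_rate:
            if session.rates is None:
                raise ValueError("session has no ground-truth rates")
            rt = session.rates[neuron_id]
            y = np.interp(abs_grid, rt.times, rt.rate)
        else:
            y = instantaneous_rate(session.spikes[neuron_id], abs_grid).rate
        y = gaussian_smooth(y, config.smooth_sigma_s, config.target_rate_hz)
        xs.append(np.column_stack([pos_s, vel]))
        ys.append(y)
        gs.append(np.full(len(y), int(row.trial)))
    return np.vstack(xs), np.concatenate(ys), np.concatenate(gs)


def _trial_folds(groups: np.ndarray, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Row masks for a seeded partition of whole trials into folds."""
    trial_ids = np.unique(groups)
    order = rng.permutation(trial_ids)
    return [np.isin(groups, order[k::n_folds]) for k in range(n_folds)]


def _fit_score(X_tr, y_tr, X_te, y_te, alpha: float, standardize: bool) -> float:
    if standardize:
        scaler = StandardScaler().fit(X_tr)
        X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
    model = Ridge(alpha=alpha).fit(X_tr, y_tr)
    return float(r2_score(y_te, model.predict(X_te)))


def _select_alpha(X, y, groups, config: EncodingConfig, rng) -> float:
    folds = _trial_folds(groups, config.cv_folds, rng)
    scores = np.zeros(len(config.alphas))
    for k, mask in enumerate(folds):
        for a, alpha in enumerate(config.alphas):
            scores[a] += _fit_score(
                X[~mask], y[~mask], X[mask], y[mask], alpha, not config.standardize_global
            )
    return float(config.alphas[int(np.argmax(scores))])


def fit_ridge_nested_cv(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray, config: EncodingConfig | None = None
) -> dict:
    """Nested trial-wise cross-validation of a ridge model.

    Outer folds give the reported held-out R² (mean over folds); within each
    outer training set an inner grid search over the alpha grid picks the
    regularization. Degenerate targets (zero variance) are flagged.
    """
    config = config or EncodingConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) < 10 * config.cv_folds:
        raise ValueError("too few samples for nested cross-validation")
    if np.var(y) == 0:
        return {"cv_r2": np.nan, "alpha": np.nan, "fold_r2": [], "degenerate": True}
    if config.standardize_global:
        X = StandardScaler().fit_transform(X)
    rng = np.random.default_rng(config.seed)
    outer = _trial_folds(groups, config.cv_folds, rng)
    fold_r2, fold_alpha = [], []
    for mask in outer:
        alpha = _select_alpha(X[~mask], y[~mask], groups[~mask], config, rng)
        fold_alpha.append(alpha)
        fold_r2.append(
            _fit_score(X[~mask], y[~mask], X[mask], y[mask], alpha, not config.standardize_global)
        )
    return {
        "cv_r2": float(np.mean(fold_r2)),
        "fold_r2": fold_r2,
        "alpha": float(np.median(fold_alpha)),
        "degenerate": False,
    }


def rank_predictors_permutation(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    names: list[str],
    config: EncodingConfig | None = None,
) -> pd.DataFrame:
    """Permutation importance on held-out folds.

    For each outer fold the model (alpha from an inner search on the training
    folds) is fit once; each column of the held-out block is then permuted
    ``n_perm_repeats`` times and the mean drop in held-out R² is the column's
    importance. Ties are broken by canonical column order.
    """
    config = config or EncodingConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(config.seed)
    if config.standardize_global:
        X = StandardScaler().fit_transform(X)
    folds = _trial_folds(groups, config.cv_folds, rng)
    drops = np.zeros(X.shape[1])
    n_eval = 0
    for mask in folds:
        X_tr, y_tr = X[~mask], y[~mask]
        alpha = _select_alpha(X_tr, y_tr, groups[~mask], config, rng)
        if config.standardize_global:
            X_trs, X_tes = X_tr, X[mask]
        else:
            scaler = StandardScaler().fit(X_tr)
            X_trs, X_tes = scaler.transform(X_tr), scaler.transform(X[mask])
        model = Ridge(alpha=alpha).fit(X_trs, y_tr)
        base = r2_score(y[mask], model.predict(X_tes))
        for _ in range(config.n_perm_repeats):
            for col in range(X.shape[1]):
                Xp = X_tes.copy()
                Xp[:, col] = rng.permutation(Xp[:, col])
                drops[col] += base - r2_score(y[mask], model.predict(Xp))
            n_eval += 1
    importance = drops / n_eval
    order = np.lexsort((np.arange(len(names)), -importance))
    return pd.DataFrame(
        {"name": [names[i] for i in order], "importance": importance[order]}
    ).reset_index(drop=True)


def reduced_topk_model(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    names: list[str],
    ranking: pd.DataFrame,
    k: int = 6,
    config: EncodingConfig | None = None,
) -> dict:
    """Refit the full nested-CV procedure on the top-k ranked predictors."""
    if k > len(names):
        raise ValueError("k exceeds the number of predictors")
    top = list(ranking.name.iloc[:k])
    cols = [names.index(n) for n in top]
    result = fit_ridge_nested_cv(X[:, cols], y, groups, config)
    result["predictors"] = top
    return result


def summarize_r2_fisher(r_values: np.ndarray) -> dict[str, float]:
    """Population average of correlation coefficients via Fisher z.

    Values are clipped just inside (-1, 1); the mean of atanh(r) is
    back-transformed and also reported squared (as R²).
    """
    r = np.clip(np.asarray(r_values, dtype=float), -1 + 1e-12, 1 - 1e-12)
    mean_r = float(np.tanh(np.mean(np.arctanh(r))))
    return {"mean_r": mean_r, "mean_r2": mean_r**2}


def encode_neuron(
    session: SessionData,
    neuron_id: int,
    config: EncodingConfig | None = None,
    model_classes: tuple[str, ...] = MODEL_CLASSES,
    y_from_rate: bool = False,
    rank: bool = True,
    k_reduced: int = 6,
) -> dict:
    """Full encoding analysis for one neuron (all requested model classes)."""
    config = config or EncodingConfig()
    base, y, groups = build_trial_data(session, neuron_id, config, y_from_rate=y_from_rate)
    out: dict = {"neuron": neuron_id, "type": session.models[neuron_id].archetype}
    for mc in model_classes:
        X, names = build_design_matrix(base, mc)
        out[mc] = fit_ridge_nested_cv(X, y, groups, config)
    if rank and "2way" in model_classes:
        X, names = build_design_matrix(base, "2way")
        ranking = rank_predictors_permutation(X, y, groups, names, config)
        out["importance"] = ranking
        out["reduced"] = reduced_topk_model(X, y, groups, names, ranking, k_reduced, config)
        out["reduced"]["drop_vs_full"] = out["2way"]["cv_r2"] - out["reduced"]["cv_r2"]
    return out
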