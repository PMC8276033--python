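"""Ensembles of recurrent regressors: the "RNN score" and its convergence.

A tail's RNN score is the arithmetic mean of the predictions of independently
seeded models trained on the identical data (32 members for scoring by
default).  Because single-model predictions are stochastic across seeds, the
number of members needed is established by a bootstrap: from a pool of 64
trained models, random k-subsets are drawn (100 draws per k), the Pearson
correlation of each subset-mean prediction with the observed responses is
computed, and the standard deviation of that correlation over draws is
tracked as k grows.  Convergence is declared where the local slope of the
SD-versus-k curve falls below a threshold (0.0003 by default, reached in the
original analysis above ~15 models).

Also here: seeded 10-fold cross validation for hyperparameter selection, and
the evaluation report (value correlation = Pearson r on raw responses; rank
correlation = Pearson r on average-rank vectors, i.e. Spearman rho).
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    ModelConfig,
    SecretionRecord,
    TrainedModel,
    load_model,
    predict,
    save_model,
    train_model,
)
from .tails import TailSequence

#: Ensemble size used for scoring; pool size used for convergence studies.
DEFAULT_ENSEMBLE_SIZE = 32
DEFAULT_POOL_SIZE = 64
DEFAULT_N_BOOTSTRAP = 100
DEFAULT_SLOPE_THRESHOLD = 0.0003

#: Small scaffolding grid for cross-validation (the working defaults sit inside it).
DEFAULT_GRID: tuple[ModelConfig, ...] = tuple(
    ModelConfig(hidden_size=h, fc_width=f, dropout_rate=d)
    for h in (32, 64)
    for f in (8, 16)
    for d in (0.0, 0.2)
)


@dataclasses.dataclass
class EnsembleModel:
    """Pool of independently seeded models trained on the same data.

    Member ``i`` was trained with seed ``base_seed + i``, so a pool can be
    extended without retraining existing members.
    """

    members: list[TrainedModel]
    base_seed: int

    def __len__(self) -> int:
        return len(self.members)


@dataclasses.dataclass
class EvaluationReport:
    value_correlation: float
    rank_correlation: float
    n: int


@dataclasses.dataclass
class ConvergenceCurve:
    """Bootstrap dispersion of the ensemble-mean correlation versus pool size.

    ``table`` has one row per ensemble size k: mean and SD of Pearson R over
    bootstrap draws, plus the local slope of the SD curve.  ``converged_k``
    is the smallest k whose |slope| is below ``slope_threshold`` (None if
    never reached).
    """

    table: pd.DataFrame
    n_bootstrap: int
    slope_threshold: float
    converged_k: int | None


def train_ensemble(
    data: Sequence[SecretionRecord],
    n_models: int = DEFAULT_ENSEMBLE_SIZE,
    config: ModelConfig = ModelConfig(),
    base_seed: int = 0,
) -> EnsembleModel:
    """Train ``n_models`` members differing only in seed (base_seed + i)."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    members = [
        train_model(data, config.replace(seed=base_seed + i)) for i in range(n_models)
    ]
    return EnsembleModel(members=members, base_seed=base_seed)


def member_predictions(
    ensemble: EnsembleModel, tails: Sequence[TailSequence | str]
) -> np.ndarray:
    """(n_members, n_tails) matrix of per-member predictions."""
    if not ensemble.members:
        raise ValueError("ensemble has no members")
    return np.stack([predict(m, tails) for m in ensemble.members])


def ensemble_predict(
    ensemble: EnsembleModel, tails: Sequence[TailSequence | str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-tail (mean, SD) of member predictions; the mean is the RNN score."""
    preds = member_predictions(ensemble, tails)
    return preds.mean(axis=0), preds.std(axis=0)


def evaluate(predicted: Sequence[float], observed: Sequence[float]) -> EvaluationReport:
    """Correlations between predicted scores and observed responses.

    Value correlation is Pearson r on the raw vectors; rank correlation is
    Pearson r on average-rank vectors (ties share their mean rank), which is
    Spearman's rho with tie correction.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(o) == 0:
        raise ValueError("observed responses are constant; correlation undefined")
    if np.ptp(p) == 0:
        raise ValueError("predicted scores are constant; correlation undefined")
    value_r = stats.pearsonr(p, o).statistic
    rank_r = stats.pearsonr(stats.rankdata(p), stats.rankdata(o)).statistic
    return EvaluationReport(
        value_correlation=float(value_r), rank_correlation=float(rank_r), n=int(p.size)
    )


def convergence_analysis(
    pool: EnsembleModel,
    eval_data: Sequence[SecretionRecord],
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
    rng_seed: int = 0,
    slope_threshold: float = DEFAULT_SLOPE_THRESHOLD,
    with_replacement: bool = False,
    smooth_window: int = 1,
) -> ConvergenceCurve:
    """Bootstrap the ensemble-size dependence of the prediction correlation.

    For each k in 1..len(pool), draw ``n_bootstrap`` random k-subsets of the
    member pool (without replacement within a draw, unless
    ``with_replacement``), compute the Pearson R between each subset's mean
    prediction and the observed responses, and record the mean and SD of R
    over draws.  The local slope of the SD curve is its first difference
    (optionally smoothed over ``smooth_window`` consecutive differences);
    convergence is the smallest k with |slope| < ``slope_threshold``.
    """
    n_pool = len(pool)
    if n_pool < 2:
        raise ValueError("convergence analysis needs a pool of at least 2 models")
    observed = np.array([r.response for r in eval_data])
    if len(np.unique(observed)) < 3:
        raise ValueError("evaluation data needs at least 3 distinct response values")

    preds = member_predictions(pool, [r.tail for r in eval_data])
    o_centered = observed - observed.mean()
    o_norm = np.sqrt((o_centered**2).sum())
    rng = np.random.default_rng(rng_seed)

    ks = np.arange(1, n_pool + 1)
    mean_r = np.empty(n_pool)
    sd_r = np.empty(n_pool)
    for j, k in enumerate(ks):
        rs = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            sel = rng.choice(n_pool, size=k, replace=with_replacement)
            mean_pred = preds[sel].mean(axis=0)
            pc = mean_pred - mean_pred.mean()
            denom = np.sqrt((pc**2).sum()) * o_norm
            rs[b] = (pc @ o_centered) / denom if denom > 0 else np.nan
        mean_r[j] = np.nanmean(rs)
        sd_r[j] = np.nanstd(rs)

    slope = np.full(n_pool, np.nan)
    diffs = np.diff(sd_r)
    if smooth_window > 1 and diffs.size:
        kernel = np.ones(smooth_window) / smooth_window
        diffs = np.convolve(diffs, kernel, mode="same")
    slope[1:] = diffs

    below = np.flatnonzero(np.abs(slope[1:]) < slope_threshold)
    converged_k = int(ks[below[0] + 1]) if below.size else None

    table = pd.DataFrame(
        {"k": ks, "mean_pearson_r": mean_r, "sd_pearson_r": sd_r, "slope": slope}
    )
    return ConvergenceCurve(
        table=table,
        n_bootstrap=n_bootstrap,
        slope_threshold=slope_threshold,
        converged_k=converged_k,
    )


def assign_folds(n: int, folds: int, seed: int) -> np.ndarray:
    """Seeded fold labels 0..folds-1 forming a partition of range(n)."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > n:
        raise ValueError(f"folds ({folds}) exceed sample count ({n})")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(folds), np.diff(np.linspace(0, n, folds + 1).astype(int)))
    return labels[rng.permutation(n)]


def crossvalidate(
    data: Sequence[SecretionRecord],
    folds: int = 10,
    grid: Sequence[ModelConfig] = DEFAULT_GRID,
    seed: int = 0,
) -> tuple[ModelConfig, pd.DataFrame]:
    """K-fold cross validation over a config grid; best = lowest mean val MSE.

    Fold assignment is a seeded partition shared across configs.  Returns the
    winning config and the full per-config score table.
    """
    records = list(data)
    if not grid:
        raise ValueError("config grid is empty")
    labels = assign_folds(len(records), folds, seed)
    rows = []
    for ci, config in enumerate(grid):
        fold_mse = []
        for f in range(folds):
            train = [r for r, l in zip(records, labels) if l != f]
            val = [r for r, l in zip(records, labels) if l == f]
            model = train_model(train, config)
            pred = predict(model, [r.tail for r in val])
            obs = np.array([r.response for r in val])
            fold_mse.append(float(np.mean((pred - obs) ** 2)))
        rows.append({"config_index": ci, "mean_val_mse": float(np.mean(fold_mse)),
                     **dataclasses.asdict(config)})
    table = pd.DataFrame(rows)
    best = grid[int(table["mean_val_mse"].idxmin())]
    return best, table


def save_ensemble(ensemble: EnsembleModel, directory) -> None:
    """Write members as member_NNN.npz plus a JSON manifest."""
    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for i, m in enumerate(ensemble.members):
        save_model(m, d / f"member_{i:03d}.npz")
    manifest = {
        "n_models": len(ensemble.members),
        "base_seed": ensemble.base_seed,
        "config": dataclasses.asdict(ensemble.members[0].config),
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_ensemble(directory) -> EnsembleModel:
    d = pathlib.Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    members = [
        load_model(d / f"member_{i:03d}.npz") for i in range(manifest["n_models"])
    ]
    return EnsembleModel(members=members, base_seed=manifest["base_seed"])
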