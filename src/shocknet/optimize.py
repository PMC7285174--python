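"""Statistical hyperparameter optimization over random-search records.

The optimization principle: rather than promoting the single best random
search model, (1) select the small subset of top-ranked models per depth by
a BAC cutoff, (2) take the per-position *median* of their filter counts and
kernel sizes to predict a robust "median HP" configuration per depth, (3)
re-train that configuration over a learning-rate sweep and keep the best
run.  Alongside, hyperparameter distributions conditional on BAC and
regression-tree importance scores (with surrogate splits, so collinear
predictors such as the derived parameter count still register) describe
which hyperparameters drive performance.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import DatasetSplit
from .estimator import CNNShockClassifier
from .model import HPConfig, layer_shapes
from .train import TrainSettings
from .tree import SurrogateRegressionTree

#: default top-rank BAC cutoffs (percent) per network depth
DEFAULT_CUTOFFS = {1: 96.5, 2: 98.9, 3: 99.1}
DEFAULT_CUTOFF_DEEP = 99.3  # N >= 4

LR_GRID = (0.01, 0.005, 0.001, 0.0005, 0.0001, 0.00005, 0.00001)


def default_cutoff(n_blocks: int) -> float:
    return DEFAULT_CUTOFFS.get(n_blocks, DEFAULT_CUTOFF_DEEP)


def quantile_cutoffs(records: pd.DataFrame, q: float = 0.8) -> dict[int, float]:
    """Per-depth BAC cutoffs at a quantile, for scaled-down runs."""
    return {
        int(n): float(np.quantile(sub["bac"], q))
        for n, sub in records.groupby("n_blocks")
    }


def select_top_ranked(
    records: pd.DataFrame,
    cutoffs: Mapping[int, float] | None = None,
) -> dict[int, pd.DataFrame]:
    """Filter records to those with BAC at or above the per-depth cutoff."""
    out: dict[int, pd.DataFrame] = {}
    for n, sub in records.groupby("n_blocks"):
        n = int(n)
        cut = cutoffs[n] if cutoffs is not None else default_cutoff(n)
        sel = sub[sub["bac"] >= cut].reset_index(drop=True)
        if len(sel) == 0:
            warnings.warn(f"no records reach the cutoff at depth {n}; depth skipped")
            continue
        out[n] = sel
    return out


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def median_hp(
    selection: pd.DataFrame,
    input_len: int,
    pool_size: int = 2,
    dropout: float = 0.3,
) -> HPConfig:
    """Per-position median of filters and kernels over a top-ranked subset.

    Medians use linear interpolation between order statistics and round half
    up to the nearest integer; they are *not* snapped back to the search
    grid (an off-grid median is a legitimate prediction).  The resulting
    configuration must be shape-feasible.
    """
    if len(selection) == 0:
        raise ValueError("empty top-ranked subset")
    n_blocks = int(selection["n_blocks"].iloc[0])
    if (selection["n_blocks"] != n_blocks).any():
        raise ValueError("median_hp expects records of a single depth")
    filters = tuple(
        _round_half_up(float(np.median(selection[f"F{i}"]))) for i in range(1, n_blocks + 1))
    kernels = tuple(
        _round_half_up(float(np.median(selection[f"K{i}"]))) for i in range(1, n_blocks + 1))
    config = HPConfig(n_blocks=n_blocks, filters=filters, kernels=kernels,
                      pool_size=pool_size, dropout=dropout, input_len=input_len)
    shapes = layer_shapes(config)
    if not shapes.feasible:
        bad = next(i for i, (c, p) in enumerate(zip(shapes.conv_len, shapes.pooled_len))
                   if c < 1 or p < 1)
        raise ValueError(f"median configuration infeasible at block {bad + 1}")
    return config


def hp_distributions(records: pd.DataFrame, bin_width: float = 0.25) -> pd.DataFrame:
    """Median/quartile range of each HP within BAC bins (long format).

    Quartiles use linear interpolation; bins with fewer than 4 records get
    missing-value quartile markers (the median is still reported).
    """
    n_blocks = int(records["n_blocks"].iloc[0])
    hp_cols = [f"F{i}" for i in range(1, n_blocks + 1)] + \
              [f"K{i}" for i in range(1, n_blocks + 1)] + ["params"]
    bins = np.floor(records["bac"] / bin_width) * bin_width
    rows = []
    for b, sub in records.groupby(bins):
        for col in hp_cols:
            vals = sub[col].to_numpy(dtype=np.float64)
            enough = len(vals) >= 4
            rows.append({
                "bac_bin": float(b),
                "hp": col,
                "count": len(vals),
                "median": float(np.median(vals)),
                "q1": float(np.percentile(vals, 25)) if enough else np.nan,
                "q3": float(np.percentile(vals, 75)) if enough else np.nan,
            })
    return pd.DataFrame(rows)


def importance_scores(
    records: pd.DataFrame,
    min_records: int = 30,
    max_depth: int = 5,
    min_samples_leaf: int = 5,
) -> pd.DataFrame:
    """Regression-tree importance of {Fi, Ki, Params} for BAC, per depth.

    Scores lie in [0, 1] with the per-depth maximum normalized to 1;
    surrogate splits let correlated predictors share credit.  Depths with a
    constant BAC yield all-zero rows (with a warning).
    """
    out_rows = {}
    for n, sub in records.groupby("n_blocks"):
        n = int(n)
        if len(sub) < min_records:
            raise ValueError(f"need >= {min_records} records at depth {n}, have {len(sub)}")
        cols = [f"F{i}" for i in range(1, n + 1)] + \
               [f"K{i}" for i in range(1, n + 1)] + ["params"]
        X = sub[cols].to_numpy(dtype=np.float64)
        y = sub["bac"].to_numpy(dtype=np.float64)
        tree = SurrogateRegressionTree(max_depth=max_depth,
                                       min_samples_leaf=min_samples_leaf)
        tree.fit(X, y)
        renamed = {c if c != "params" else "Params": s
                   for c, s in zip(cols, tree.importances_)}
        out_rows[n] = renamed
    report = pd.DataFrame.from_dict(out_rows, orient="index")
    report.index.name = "n_blocks"
    return report


@dataclasses.dataclass
class LRSweepResult:
    runs: pd.DataFrame       # lr, run, seed, bac, epochs_trained
    summary: pd.DataFrame    # per-lr min/q1/median/q3/max
    best_lr: float
    best_bac: float
    best_seed: int
    best_clf: CNNShockClassifier


def lr_sweep(
    config: HPConfig,
    train_split: DatasetSplit,
    val_split: DatasetSplit,
    settings: TrainSettings,
    seed: int,
    lrs: Sequence[float] = LR_GRID,
    runs: int = 10,
) -> LRSweepResult:
    """Train ``config`` at each learning rate in ``runs`` independent runs.

    Returns the raw run table, a per-LR distribution summary, and the single
    best run (maximal validation BAC at the ROC operating point).
    """
    if not layer_shapes(config).feasible:
        raise ValueError("infeasible configuration")
    rows = []
    best = None
    for li, lr in enumerate(lrs):
        for r in range(runs):
            run_seed = int(np.random.SeedSequence([seed, li, r]).generate_state(1)[0] % (2**31))
            clf = CNNShockClassifier(
                filters=config.filters, kernels=config.kernels,
                pool_size=config.pool_size, dropout=config.dropout,
                learning_rate=lr, epochs=settings.epochs,
                patience=settings.patience, batch_size=settings.batch_size,
                beta1=settings.beta1, beta2=settings.beta2,
                random_state=run_seed,
            )
            clf.fit(train_split.X, train_split.y)
            b = clf.validation_bac(val_split.X, val_split.y)
            rows.append({"lr": lr, "run": r, "seed": run_seed, "bac": b,
                         "epochs_trained": clf.epochs_trained_})
            if best is None or b > best[0]:
                best = (b, lr, run_seed, clf)
    runs_df = pd.DataFrame(rows)
    summary = runs_df.groupby("lr")["bac"].agg(
        min="min",
        q1=lambda v: float(np.percentile(v, 25)),
        median="median",
        q3=lambda v: float(np.percentile(v, 75)),
        max="max",
    ).reset_index()
    best_bac, best_lr, best_seed, best_clf = best
    return LRSweepResult(runs=runs_df, summary=summary, best_lr=best_lr,
                         best_bac=best_bac, best_seed=best_seed, best_clf=best_clf)


def hpopt_report(
    records: pd.DataFrame,
    input_len: int,
    cutoffs: Mapping[int, float] | None = None,
) -> dict[int, HPConfig]:
    """Predicted median-HP configuration per depth from a record store."""
    selections = select_top_ranked(records, cutoffs)
    out = {}
    for n, sel in selections.items():
        out[n] = median_hp(sel, input_len=input_len)
    return out
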