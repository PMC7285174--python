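"""Random hyperparameter search over the constrained architecture grid.

Configurations are drawn from a fixed grid of filter counts and kernel
sizes, subject to two constraints: each of the {Fi} and {Ki} vectors must
follow a non-strictly monotone (decreasing, increasing or constant) trend
from the first to the last block, and the resulting shapes must stay
feasible under valid padding at the chosen input length.  The shallowest
networks (N = 1) get extra-large filter/kernel options so their parameter
counts are comparable to deeper models.

Monotone vectors are drawn *uniformly over all monotone vectors* by multiset
unranking, which is distribution-identical to iid grid draws filtered by the
monotone rule (every monotone vector has the same iid probability), but
never fails; only shape feasibility is handled by rejection with a bounded
retry budget (generous, because at depth 7 only ~0.2% of monotone kernel
vectors stay feasible under the valid-padding shrink -- re-drawing is cheap
since rejected candidates are never trained).

Trained models accumulate in an append-only CSV store, one row per model,
so interrupted sessions can resume.
"""

from __future__ import annotations

import dataclasses
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import DatasetSplit
from .estimator import CNNShockClassifier
from .model import HPConfig, count_params, layer_shapes
from .train import TrainSettings

MAX_DEPTH = 7


@dataclasses.dataclass(frozen=True)
class SearchGrid:
    """Grid of admissible filter counts and kernel sizes."""

    n_values: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    f_values: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 40, 50)
    f1_extra: tuple[int, ...] = (75, 100, 125, 150, 200)  # N = 1 only
    k_values: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 40, 50, 60, 70, 85, 100)
    k1_extra: tuple[int, ...] = (125, 150, 200)           # N = 1 only

    def filters_for(self, n_blocks: int) -> tuple[int, ...]:
        return tuple(sorted(self.f_values + self.f1_extra)) if n_blocks == 1 else self.f_values

    def kernels_for(self, n_blocks: int) -> tuple[int, ...]:
        return tuple(sorted(self.k_values + self.k1_extra)) if n_blocks == 1 else self.k_values


def is_monotone(vec: Sequence[int]) -> bool:
    """Non-strict monotonicity; constant vectors qualify."""
    v = list(vec)
    return v == sorted(v) or v == sorted(v, reverse=True)


def _sample_multiset(values: Sequence[int], n: int, rng: np.random.Generator) -> list[int]:
    """Uniform multiset of size n from ``values`` (stars-and-bars bijection)."""
    v = len(values)
    picks = np.sort(rng.choice(v + n - 1, size=n, replace=False))
    return [values[int(p - i)] for i, p in enumerate(picks)]


def sample_monotone(values: Sequence[int], n: int, rng: np.random.Generator) -> list[int]:
    """Uniform draw over all non-strictly monotone length-n vectors."""
    values = sorted(values)
    v = len(values)
    if n == 1:
        return [values[int(rng.integers(v))]]
    m = comb(v + n - 1, n)          # distinct non-decreasing vectors
    total = 2 * m - v               # constants counted once
    if int(rng.integers(total)) < m:
        return _sample_multiset(values, n, rng)
    while True:  # non-increasing, non-constant (constant prob is tiny)
        ms = _sample_multiset(values, n, rng)
        if ms[0] != ms[-1]:
            return ms[::-1]


def sample_config(
    grid: SearchGrid,
    n_blocks: int,
    input_len: int,
    seed: int,
    pool_size: int = 2,
    dropout: float = 0.3,
    max_tries: int = 50_000,
) -> HPConfig:
    """Draw one feasible monotone configuration; deterministic given seed."""
    if n_blocks not in grid.n_values:
        raise ValueError(f"depth {n_blocks} not in grid {grid.n_values}")
    rng = np.random.default_rng(seed)
    fv = grid.filters_for(n_blocks)
    kv = grid.kernels_for(n_blocks)
    last = None
    for _ in range(max_tries):
        f = sample_monotone(fv, n_blocks, rng)
        k = sample_monotone(kv, n_blocks, rng)
        config = HPConfig(n_blocks=n_blocks, filters=tuple(f), kernels=tuple(k),
                          pool_size=pool_size, dropout=dropout, input_len=input_len)
        shapes = layer_shapes(config)
        if shapes.feasible:
            return config
        last = (config, shapes)
    config, shapes = last
    bad = next(i for i, (c, p) in enumerate(zip(shapes.conv_len, shapes.pooled_len))
               if c < 1 or p < 1)
    raise RuntimeError(
        f"no feasible configuration within {max_tries} draws at depth {n_blocks}, "
        f"input length {input_len}; binding constraint: block {bad + 1} "
        f"(kernel {config.kernels[bad]} vs length {shapes.conv_len[bad] + config.kernels[bad] - 1})")


@dataclasses.dataclass
class SearchRecord:
    model_index: int
    config: HPConfig
    bac: float
    epochs_trained: int
    params: int
    seed: int

    def to_row(self) -> dict:
        row = {
            "model_index": self.model_index,
            "n_blocks": self.config.n_blocks,
            "config": self.config.to_json(),
            "bac": self.bac,
            "epochs_trained": self.epochs_trained,
            "params": self.params,
            "seed": self.seed,
        }
        for i, (f, k) in enumerate(zip(self.config.filters, self.config.kernels), start=1):
            row[f"F{i}"] = f
            row[f"K{i}"] = k
        return row


_STORE_COLUMNS = (
    ["model_index", "n_blocks", "config", "bac", "epochs_trained", "params", "seed"]
    + [f"F{i}" for i in range(1, MAX_DEPTH + 1)]
    + [f"K{i}" for i in range(1, MAX_DEPTH + 1)]
)


def load_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _append_record(path: Path, record: SearchRecord) -> None:
    row = {c: record.to_row().get(c) for c in _STORE_COLUMNS}
    df = pd.DataFrame([row], columns=_STORE_COLUMNS)
    df.to_csv(path, mode="a", header=not path.exists(), index=False)


def run_search(
    grid: SearchGrid,
    n_blocks: int,
    n_models: int,
    train_split: DatasetSplit,
    val_split: DatasetSplit,
    settings: TrainSettings,
    seed: int,
    store_path: str | Path,
    resume: bool = False,
) -> pd.DataFrame:
    """Train ``n_models`` random configurations at fixed depth; return records.

    Each model gets its own derived seed for sampling, initialization and
    shuffling; validation BAC is measured at the max-BAC ROC point.  Records
    append to the CSV store after every model, so a re-run with
    ``resume=True`` continues where the store left off (and adds nothing if
    it is already complete).
    """
    store_path = Path(store_path)
    start = 0
    if store_path.exists():
        if not resume:
            raise FileExistsError(
                f"store {store_path} exists; pass resume=True to continue")
        existing = load_records(store_path)
        existing = existing[existing["n_blocks"] == n_blocks]
        start = len(existing)
    input_len = train_split.X.shape[1]
    records = []
    for m in range(start, n_models):
        model_seed = int(np.random.SeedSequence([seed, n_blocks, m]).generate_state(1)[0] % (2**31))
        config = sample_config(grid, n_blocks, input_len, seed=model_seed)
        clf = CNNShockClassifier(
            filters=config.filters, kernels=config.kernels,
            pool_size=config.pool_size, dropout=config.dropout,
            learning_rate=settings.lr, decay=settings.decay,
            epochs=settings.epochs, patience=settings.patience,
            batch_size=settings.batch_size, beta1=settings.beta1,
            beta2=settings.beta2, random_state=model_seed,
        )
        clf.fit(train_split.X, train_split.y)
        bac = clf.validation_bac(val_split.X, val_split.y)
        rec = SearchRecord(
            model_index=m, config=config, bac=bac,
            epochs_trained=clf.epochs_trained_,
            params=count_params(config), seed=model_seed,
        )
        _append_record(store_path, rec)
        records.append(rec)
    df = load_records(store_path)
    return df[df["n_blocks"] == n_blocks].reset_index(drop=True)


def records_to_configs(records: pd.DataFrame) -> list[HPConfig]:
    return [HPConfig.from_json(s) for s in records["config"]]
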