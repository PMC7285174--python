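"""Top-rank selection, median-HP prediction, HP distributions, importance."""

import json

import numpy as np
import pandas as pd
import pytest

from shocknet.model import HPConfig
from shocknet.optimize import (hp_distributions, importance_scores, lr_sweep,
                               median_hp, quantile_cutoffs, select_top_ranked)
from shocknet.train import TrainSettings
from shocknet.tree import SurrogateRegressionTree


def _records(rows, n_blocks):
    """Build a record frame from dicts with F*/K* columns and bac."""
    out = []
    for i, r in enumerate(rows):
        f = tuple(r[f"F{j}"] for j in range(1, n_blocks + 1))
        k = tuple(r[f"K{j}"] for j in range(1, n_blocks + 1))
        cfg = HPConfig(n_blocks, f, k, input_len=625)
        row = {"model_index": i, "n_blocks": n_blocks, "config": cfg.to_json(),
               "bac": r["bac"], "epochs_trained": 10, "params": 0, "seed": i}
        row.update({c: v for c, v in r.items() if c != "bac"})
        out.append(row)
    return pd.DataFrame(out)


class TestSelectTopRanked:
    def test_cutoff_filter(self):
        recs = _records([
            dict(F1=5, K1=10, bac=99.4), dict(F1=5, K1=10, bac=99.2),
            dict(F1=5, K1=10, bac=99.35)], n_blocks=1)
        recs["n_blocks"] = 4
        sel = select_top_ranked(recs, {4: 99.3})
        assert len(sel[4]) == 2

    def test_zero_cutoff_selects_all(self):
        recs = _records([dict(F1=5, K1=10, bac=b) for b in (90, 95, 99)], 1)
        sel = select_top_ranked(recs, {1: 0.0})
        assert len(sel[1]) == 3

    def test_planted_subset_recovered_exactly(self, rng):
        rows = [dict(F1=int(f), K1=int(k), bac=float(b))
                for f, k, b in zip(rng.integers(5, 50, 700),
                                   rng.integers(5, 100, 700),
                                   rng.uniform(90, 99.0, 700))]
        for i in rng.choice(700, size=7, replace=False):
            rows[i]["bac"] = float(rng.uniform(99.4, 99.9))
        recs = _records(rows, 1)
        sel = select_top_ranked(recs, {1: 99.3})
        assert len(sel[1]) == 7
        assert (sel[1]["bac"] >= 99.3).all()

    def test_empty_depth_warns_and_skips(self):
        recs = _records([dict(F1=5, K1=10, bac=90.0)], 1)
        with pytest.warns(UserWarning):
            sel = select_top_ranked(recs, {1: 99.0})
        assert sel == {}


class TestMedianHP:
    def test_single_record_identity(self):
        recs = _records([dict(F1=20, F2=10, K1=30, K2=15, bac=99.5)], 2)
        cfg = median_hp(recs, input_len=625)
        assert cfg.filters == (20, 10) and cfg.kernels == (30, 15)

    def test_offgrid_median_shallow_optimum(self):
        # six top models whose F1 median interpolates off-grid to 113
        f1s = [100, 105, 110, 116, 120, 125]
        recs = _records([dict(F1=f, K1=50, bac=99.0) for f in f1s], 1)
        cfg = median_hp(recs, input_len=625)
        assert cfg.filters == (113,) and cfg.kernels == (50,)

    def test_planted_positional_medians(self):
        rows = [dict(F1=10, F2=20, K1=10, K2=30, bac=99),
                dict(F1=20, F2=30, K1=20, K2=40, bac=99),
                dict(F1=30, F2=40, K1=30, K2=50, bac=99)]
        cfg = median_hp(_records(rows, 2), input_len=625)
        assert cfg.filters == (20, 30) and cfg.kernels == (20, 40)

    def test_order_invariance(self, rng):
        rows = [dict(F1=int(f), F2=int(f2), K1=int(k), K2=int(k2), bac=99.0)
                for f, f2, k, k2 in rng.integers(5, 50, size=(9, 4))]
        recs = _records(rows, 2)
        shuffled = recs.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert median_hp(recs, 625) == median_hp(shuffled, 625)

    def test_infeasible_median_raises_with_layer(self):
        rows = [dict(F1=5, F2=5, K1=100, K2=100, bac=99.0)] * 2
        with pytest.raises(ValueError, match="block"):
            median_hp(_records(rows, 2), input_len=250)


class TestHPDistributions:
    def test_identical_records_zero_width(self):
        recs = _records([dict(F1=10, K1=20, bac=99.0)] * 6, 1)
        recs["params"] = 231
        dist = hp_distributions(recs)
        assert (dist["q1"] == dist["q3"]).all()

    def test_quartile_interpolation(self):
        recs = _records([dict(F1=10, K1=k, bac=99.0) for k in (10, 20, 30, 40, 50)], 1)
        recs["params"] = 0
        dist = hp_distributions(recs)
        k1 = dist[dist["hp"] == "K1"].iloc[0]
        assert k1["median"] == 30 and k1["q1"] == 20 and k1["q3"] == 40

    def test_bin_counts_partition_records(self):
        rng = np.random.default_rng(0)
        recs = _records([dict(F1=10, K1=20, bac=float(b))
                         for b in rng.uniform(95, 100, 40)], 1)
        recs["params"] = 0
        dist = hp_distributions(recs)
        assert dist[dist["hp"] == "K1"]["count"].sum() == 40


class TestImportance:
    @staticmethod
    def _planted(seed, n=200):
        rng = np.random.default_rng(seed)
        k1 = rng.choice([5, 10, 20, 30, 50, 70, 100], size=n)
        f1 = rng.choice([5, 10, 20, 30, 50], size=n)
        f2 = rng.choice([5, 10, 20, 30, 50], size=n)
        k2 = rng.choice([5, 10, 20, 30, 50], size=n)
        bac = 95.0 + 3.0 * (k1 > 20) + rng.normal(0, 0.3, n)  # step in K1 only
        rows = [dict(F1=int(a), F2=int(b), K1=int(c), K2=int(d), bac=float(e))
                for a, b, c, d, e in zip(f1, f2, k1, k2, bac)]
        recs = _records(rows, 2)
        recs["params"] = recs["F1"] * 0 + 100  # constant, uninformative
        return recs

    def test_planted_predictor_dominates(self):
        hits = 0
        for seed in range(3):
            report = importance_scores(self._planted(seed))
            row = report.loc[2]
            if row["K1"] == 1.0 and row[["F1", "F2", "K2"]].max() < 0.3:
                hits += 1
        assert hits >= 2

    def test_duplicated_predictor_shares_credit_via_surrogates(self, rng):
        x = rng.normal(size=(100, 1))
        X = np.hstack([x, x.copy(), rng.normal(size=(100, 1))])
        y = (x[:, 0] > 0) * 2.0 + rng.normal(0, 0.1, 100)
        tree = SurrogateRegressionTree().fit(X, y)
        assert tree.importances_[0] > 0 and tree.importances_[1] > 0
        assert tree.importances_[1] > 0.9  # perfect surrogate of the primary

    def test_scores_normalized_to_unit_interval(self):
        report = importance_scores(self._planted(0))
        vals = report.loc[2].dropna()
        assert ((vals >= 0) & (vals <= 1)).all() and vals.max() == 1.0

    def test_constant_response_warns_all_zero(self):
        recs = self._planted(1)
        recs["bac"] = 99.0
        with pytest.warns(UserWarning):
            report = importance_scores(recs)
        assert (report.loc[2].dropna() == 0).all()

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            importance_scores(self._planted(0).head(10))


class TestLRSweep:
    def test_best_equals_argmax_of_run_table(self, tiny_splits):
        tr, va = tiny_splits
        cfg = HPConfig(1, (4,), (10,), input_len=250)
        settings = TrainSettings(epochs=3, patience=2, batch_size=64, seed=0)
        res = lr_sweep(cfg, tr, va, settings, seed=5,
                       lrs=(0.01, 0.001, 0.0001), runs=3)
        assert len(res.runs) == 9
        top = res.runs.loc[res.runs["bac"].idxmax()]
        assert res.best_bac == top["bac"] and res.best_lr == top["lr"]
        assert len(res.summary) == 3
        assert set(res.summary.columns) >= {"lr", "min", "q1", "median", "q3", "max"}

    def test_quantile_cutoffs_per_depth(self):
        recs = pd.concat([
            _records([dict(F1=5, K1=10, bac=float(b)) for b in range(90, 100)], 1),
        ])
        cuts = quantile_cutoffs(recs, q=0.8)
        assert cuts[1] == pytest.approx(np.quantile(range(90, 100), 0.8))
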