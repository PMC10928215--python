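"""Stratification, forest training/pruning, map prediction and evaluation."""

import numpy as np
import pandas as pd
import pytest

from agbmap.agb_model import (
    ModelSpec,
    cell_mean_prediction,
    evaluate_cells,
    predict_map,
    prune_and_retrain,
    r2_rmse,
    stitch,
    stratify,
    train_region_model,
)
from agbmap.covariates import CovariateStack
from agbmap.raster import Grid


def make_cells(rng, n=120, p=4, noise=0.0, names=None):
    names = names or [f"f{i}" for i in range(p)]
    X = rng.uniform(0, 1, size=(n, p))
    y = 100 * X[:, 0] + noise * rng.normal(size=n)
    df = pd.DataFrame(X, columns=names)
    df["agb"] = y
    df["split"] = np.where(np.arange(n) % 5 == 0, "validation", "train")
    df["cell_row"] = np.arange(n)
    df["cell_col"] = np.zeros(n, dtype=int)
    return df


class TestStratify:
    def test_rules_and_partition(self):
        slope = np.array([[5.0, 20.0], [10.0, 12.0]])
        gap = np.array([[False, True], [False, False]])
        forest = np.array([[True, True], [True, False]])
        s = stratify(slope, gap, forest, slope_split=10.0)
        assert s.flat[0, 0] and s.no_cband[0, 1] and s.flat[1, 0]  # slope exactly 10 is flat
        assert not (s.flat | s.rugged | s.no_cband)[1, 1]
        assert s.union.sum() == forest.sum()

    def test_gap_takes_precedence_over_slope(self):
        s = stratify(np.array([[20.0]]), np.array([[True]]), np.array([[True]]))
        assert s.no_cband[0, 0] and not s.rugged[0, 0]


class TestTrain:
    def test_learns_noiseless_linear_signal(self, rng):
        cells = make_cells(rng, n=200)
        m = train_region_model(cells, [f"f{i}" for i in range(4)], seed=0, n_trees=200)
        val = cells[cells["split"] == "validation"]
        pred = m.estimator.predict(val[[f"f{i}" for i in range(4)]].to_numpy())
        r2, _ = r2_rmse(pred, val["agb"].to_numpy())
        assert r2 >= 0.95

    def test_same_seed_identical_predictions(self, rng):
        cells = make_cells(rng)
        feats = [f"f{i}" for i in range(4)]
        a = train_region_model(cells, feats, seed=5, n_trees=50)
        b = train_region_model(cells, feats, seed=5, n_trees=50)
        X = cells[feats].to_numpy()
        np.testing.assert_array_equal(a.estimator.predict(X), b.estimator.predict(X))

    def test_informative_feature_outranks_noise_across_seeds(self):
        # 50-seed majority: node purity of the informative feature beats pure noise
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            cells = make_cells(rng, n=150, p=2, names=["signal", "noise"])
            m = train_region_model(cells, ["signal", "noise"], seed=seed, n_trees=50)
            wins += m.importances["signal"] > m.importances["noise"]
        assert wins > 25

    def test_missing_feature_named_in_error(self, rng):
        cells = make_cells(rng)
        with pytest.raises(KeyError, match="nope"):
            train_region_model(cells, ["f0", "nope"], seed=0)

    def test_too_few_cells_rejected(self, rng):
        cells = make_cells(rng, n=10)
        with pytest.raises(ValueError):
            train_region_model(cells, ["f0"], seed=0)


class TestPrune:
    def test_prunes_to_remainder(self, rng):
        cells = make_cells(rng, n=150, p=15)
        feats = [f"f{i}" for i in range(15)]
        m = train_region_model(cells, feats, seed=1, n_trees=50)
        pruned = prune_and_retrain(m, cells, k=10)
        assert len(pruned.features) == 5
        assert set(pruned.features) <= set(feats)

    def test_zero_variance_features_always_pruned(self, rng):
        cells = make_cells(rng, n=150, p=12)
        for j in range(3):
            cells[f"const{j}"] = 1.0
        feats = [f"f{i}" for i in range(12)] + [f"const{j}" for j in range(3)]
        m = train_region_model(cells, feats, seed=2, n_trees=50)
        pruned = prune_and_retrain(m, cells, k=10)
        assert not any(f.startswith("const") for f in pruned.features)

    def test_tie_break_is_stable_input_order(self, rng):
        cells = make_cells(rng, n=150, p=2, names=["signal", "x"])
        for j in range(4):
            cells[f"z{j}"] = 0.0  # four exactly-tied zero-importance features
        feats = ["signal", "x"] + [f"z{j}" for j in range(4)]
        m = train_region_model(cells, feats, seed=3, n_trees=50)
        pruned_feats = []
        for _ in range(2):
            pruned_feats.append(prune_and_retrain(m, cells, k=3).features)
        assert pruned_feats[0] == pruned_feats[1]
        assert pruned_feats[0][:1] == ["signal"]

    def test_cannot_prune_all(self, rng):
        cells = make_cells(rng)
        m = train_region_model(cells, ["f0", "f1"], seed=0, n_trees=20)
        with pytest.raises(ValueError):
            prune_and_retrain(m, cells, k=2)


class TestPredictStitch:
    def _stack_and_model(self, rng, constant=False):
        g = Grid(10, 10, 50)
        cells = make_cells(rng, n=100, p=3)
        feats = ["f0", "f1", "f2"]
        m = train_region_model(cells, feats, seed=0, n_trees=30)
        stack = CovariateStack(grid=g)
        for i, f in enumerate(feats):
            band = np.full(g.shape, 0.5) if constant else rng.uniform(0, 1, g.shape)
            stack.add(f, band)
        return g, stack, m

    def test_empty_mask_all_nodata(self, rng):
        g, stack, m = self._stack_and_model(rng)
        out = predict_map(m, stack, np.zeros(g.shape, bool))
        assert np.isnan(out).all()

    def test_constant_covariates_constant_prediction(self, rng):
        g, stack, m = self._stack_and_model(rng, constant=True)
        out = predict_map(m, stack, np.ones(g.shape, bool))
        assert np.nanstd(out) == pytest.approx(0.0, abs=1e-9)

    def test_pixelwise_equals_feature_table_oracle(self, rng):
        g, stack, m = self._stack_and_model(rng)
        mask = rng.random(g.shape) < 0.6
        out = predict_map(m, stack, mask)
        X = np.column_stack([stack.bands[f][mask] for f in m.features])
        np.testing.assert_allclose(out[mask], np.maximum(m.estimator.predict(X), 0), atol=1e-12)
        assert np.isnan(out[~mask]).all()

    def test_stitch_each_pixel_from_its_stratum(self, rng):
        shape = (6, 6)
        slope = rng.uniform(0, 20, shape)
        gap = rng.random(shape) < 0.2
        forest = rng.random(shape) < 0.8
        strata = stratify(slope, gap, forest)
        maps = {n: np.full(shape, v) for n, v in (("flat", 1.0), ("rugged", 2.0), ("no_cband", 3.0))}
        out = stitch(maps, strata, forest)
        for name, v in (("flat", 1.0), ("rugged", 2.0), ("no_cband", 3.0)):
            assert (out[strata.as_dict()[name]] == v).all()
        assert np.isnan(out[~forest]).all()

    def test_stitch_rejects_unclaimed_forest_pixels(self):
        from agbmap.agb_model import RegionStrata

        forest = np.ones((2, 2), bool)
        empty = np.zeros((2, 2), bool)
        strata = RegionStrata(flat=empty, rugged=empty, no_cband=empty)
        maps = {n: np.zeros((2, 2)) for n in ("flat", "rugged", "no_cband")}
        with pytest.raises(ValueError, match="no stratum"):
            stitch(maps, strata, forest)

    def test_stitch_passes_through_nodata_inside_stratum(self):
        forest = np.ones((2, 2), bool)
        strata = stratify(np.zeros((2, 2)), np.zeros((2, 2), bool), forest)
        maps = {"flat": np.full((2, 2), np.nan), "rugged": np.zeros((2, 2)), "no_cband": np.zeros((2, 2))}
        out = stitch(maps, strata, forest)
        assert np.isnan(out).all()  # all pixels are flat stratum with nodata map


class TestEvaluate:
    def _setup(self, rng, offset=0.0):
        g = Grid(8, 8, 50)
        truth = rng.uniform(20, 200, g.shape)
        cells = pd.DataFrame({"cell_row": [0, 0, 1, 1], "cell_col": [0, 1, 0, 1]})
        f = 4
        cells["agb"] = [truth[r * f : (r + 1) * f, c * f : (c + 1) * f].mean()
                        for r, c in zip(cells.cell_row, cells.cell_col)]
        cells["split"] = "validation"
        return g, truth + offset, cells, f

    def test_perfect_map_scores_one(self, rng):
        g, pred, cells, f = self._setup(rng)
        r2, rmse, _ = evaluate_cells(pred, cells, g, f)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert rmse == pytest.approx(0.0, abs=1e-9)

    def test_constant_offset_gives_rmse_delta(self, rng):
        g, pred, cells, f = self._setup(rng, offset=12.5)
        r2, rmse, _ = evaluate_cells(pred, cells, g, f)
        assert rmse == pytest.approx(12.5, rel=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_metrics_match_formula_oracle(self, rng):
        pred = rng.uniform(0, 200, 50)
        ref = rng.uniform(0, 200, 50)
        r2, rmse = r2_rmse(pred, ref)
        assert rmse == pytest.approx(np.sqrt(np.mean((pred - ref) ** 2)), rel=1e-12)
        sxy = np.cov(pred, ref)[0, 1]
        assert r2 == pytest.approx(sxy**2 / (pred.var(ddof=1) * ref.var(ddof=1)), rel=1e-9)
        r2_sse, _ = r2_rmse(pred, ref, r2_mode="sse")
        assert r2_sse == pytest.approx(1 - np.sum((ref - pred) ** 2) / np.sum((ref - ref.mean()) ** 2), rel=1e-9)

    def test_zero_reference_variance_undefined_r2(self):
        r2, rmse = r2_rmse(np.array([1.0, 2.0]), np.array([5.0, 5.0]))
        assert np.isnan(r2) and rmse > 0

    def test_cell_mean_prediction_respects_forest_mask(self, rng):
        g = Grid(4, 4, 50)
        pred = np.arange(16, dtype=float).reshape(4, 4)
        forest = np.zeros((4, 4), bool)
        forest[0, 0] = True
        cells = pd.DataFrame({"cell_row": [0], "cell_col": [0]})
        out = cell_mean_prediction(pred, cells, g, 4, forest_mask=forest)
        assert out[0] == 0.0
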