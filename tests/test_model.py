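"""Sobolev network: gradients, loss, training contracts, ensembling."""

import numpy as np
import pytest

import thermosolv as ts
from thermosolv.featurization import (
    assemble_inputs,
    build_schema,
    fit_scaler,
    raw_solution_matrix,
)
from thermosolv.model import (
    _backward,
    _flatten,
    _forward,
    _init_params,
    sobolev_loss,
)


def make_group(temps, logs, solute="CCO", solvent="O", source="s"):
    records = [
        ts.SolubilityRecord(ts.canonicalize(solute), ts.canonicalize(solvent), T, v, source)
        for T, v in zip(temps, logs)
    ]
    return ts.group_experiments(records)[0]


class TestFiniteDifferences:
    def test_two_point_slope(self):
        g = make_group([300.0, 310.0], [-2.0, -1.8])
        np.testing.assert_allclose(ts.finite_difference_gradients(g), [0.02, 0.02])

    def test_exact_on_linear_data(self):
        T = [290.0, 300.0, 315.0, 330.0]
        logs = [-3.0 + 0.015 * (t - 290.0) for t in T]
        np.testing.assert_allclose(ts.finite_difference_gradients(make_group(T, logs)), 0.015)

    def test_single_record_masked(self):
        g = make_group([298.15], [-1.0])
        assert np.isnan(ts.finite_difference_gradients(g)).all()


class TestSobolevLoss:
    def test_reduces_to_mse_at_zero_weight(self):
        y, yh = np.array([0.0, 1.0]), np.array([1.0, 1.0])
        g = np.full(2, np.nan)
        assert sobolev_loss(yh, y, g, g, weight=0.0) == pytest.approx(0.5)

    def test_perfect_prediction_zero_loss(self):
        y = np.array([1.0, 2.0])
        g = np.array([0.01, 0.02])
        assert sobolev_loss(y, y, g, g, weight=1.0) == 0.0

    def test_weighted_arithmetic(self):
        y = np.zeros(2)
        yh = np.ones(2)  # value MSE 1.0
        g = np.zeros(2)
        gh = np.full(2, np.sqrt(2.0))  # gradient MSE 2.0
        assert sobolev_loss(yh, y, gh, g, weight=0.5) == pytest.approx(2.0)

    def test_all_masked_gradient_term_is_zero(self):
        y = np.zeros(3)
        g = np.full(3, np.nan)
        assert sobolev_loss(y + 1, y, y, g, weight=5.0) == pytest.approx(1.0)

    def test_gradient_term_monotone_in_weight(self):
        rng = np.random.default_rng(0)
        y, yh = rng.normal(size=10), rng.normal(size=10)
        g, gh = rng.normal(size=10), rng.normal(size=10)
        losses = [sobolev_loss(yh, y, gh, g, weight=w) for w in (0.0, 0.5, 1.0, 2.0)]
        assert all(b >= a for a, b in zip(losses, losses[1:]))

    def test_negative_weight_rejected(self):
        y = np.zeros(2)
        with pytest.raises(ValueError):
            sobolev_loss(y, y, y, y, weight=-1.0)


class TestBackpropagation:
    @pytest.mark.parametrize("mode", ["concat", "add", "subtract", "multiply"])
    @pytest.mark.parametrize("depth", [0, 2])
    def test_analytic_gradients_match_numeric(self, mode, depth):
        """Double backprop through the tangent pass agrees with finite differences."""
        rng = np.random.default_rng(42)
        cfg = ts.ModelConfig(combine_mode=mode, branch_layers=depth, branch_width=5,
                             hidden_sizes=(7,), sobolev_weight=0.7)
        F = 4
        params = _init_params(cfg, F, rng)
        X = rng.normal(size=(6, 2 * F + 1))
        yt = rng.normal(size=6)
        gt = rng.normal(size=6) * 0.01
        mask = np.array([True, True, True, True, False, False])
        seeds = rng.uniform(0.5, 2.0, size=6)
        lam = cfg.sobolev_weight

        def loss():
            y, g, _ = _forward(params, X, cfg, seeds)
            return np.mean((y - yt) ** 2) + lam * np.mean((g[mask] - gt[mask]) ** 2)

        y, g, caches = _forward(params, X, cfg, seeds)
        y_bar = 2 * (y - yt) / len(y)
        g_bar = np.where(mask, 2 * lam * (g - gt) / mask.sum(), 0.0)
        grads = _backward(params, caches, cfg, y_bar, g_bar)
        for arr, garr in zip(_flatten(params), _flatten(grads)):
            for _, idx in zip(range(3), np.ndindex(*arr.shape)):
                eps, old = 1e-6, arr[idx]
                arr[idx] = old + eps
                lp = loss()
                arr[idx] = old - eps
                lm = loss()
                arr[idx] = old
                numeric = (lp - lm) / (2 * eps)
                assert garr[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-9)

    def test_tangent_equals_numeric_temperature_derivative(self):
        rng = np.random.default_rng(1)
        cfg = ts.ModelConfig(hidden_sizes=(8, 8))
        params = _init_params(cfg, 3, rng)
        X = rng.normal(size=(5, 7))
        seeds = np.full(5, 1.7)
        _, g, _ = _forward(params, X, cfg, seeds)
        dx = 1e-6
        Xp, Xm = X.copy(), X.copy()
        Xp[:, -1] += dx
        Xm[:, -1] -= dx
        yp, _, _ = _forward(params, Xp, cfg, seeds)
        ym, _, _ = _forward(params, Xm, cfg, seeds)
        np.testing.assert_allclose(g, (yp - ym) / (2 * dx) * 1.7, atol=1e-8)


class TestTraining:
    def test_same_seed_identical_predictions(self, small_groups, schema):
        split = ts.split_by_solute(small_groups, 0.15, seed=0)
        scaler = fit_scaler(raw_solution_matrix(split.train, schema))
        tr = assemble_inputs(split.train, scaler, schema)
        va = assemble_inputs(split.validation, scaler, schema)
        cfg = ts.ModelConfig(hidden_sizes=(16,), max_epochs=15, patience=5, seed=4)
        probe = np.stack([s.x for s in va])
        probe_T = np.array([s.temperature for s in va])
        y1, g1 = ts.train_network(tr, va, cfg, scaler, schema).forward(probe, probe_T)
        y2, g2 = ts.train_network(tr, va, cfg, scaler, schema).forward(probe, probe_T)
        np.testing.assert_array_equal(y1, y2)
        np.testing.assert_array_equal(g1, g2)

    def test_empty_sets_rejected(self, small_groups, schema):
        split = ts.split_by_solute(small_groups, 0.15, seed=0)
        scaler = fit_scaler(raw_solution_matrix(split.train, schema))
        tr = assemble_inputs(split.train, scaler, schema)
        cfg = ts.ModelConfig(hidden_sizes=(8,), max_epochs=2)
        with pytest.raises(ValueError):
            ts.train_network(tr, [], cfg, scaler, schema)

    def test_training_log_records_both_loss_terms(self, small_groups, schema):
        split = ts.split_by_solute(small_groups, 0.15, seed=1)
        scaler = fit_scaler(raw_solution_matrix(split.train, schema))
        tr = assemble_inputs(split.train, scaler, schema)
        va = assemble_inputs(split.validation, scaler, schema)
        cfg = ts.ModelConfig(hidden_sizes=(16,), max_epochs=5, patience=5)
        net = ts.train_network(tr, va, cfg, scaler, schema)
        assert net.history
        for row in net.history:
            assert {"epoch", "train_value_mse", "train_gradient_mse", "val_rmse"} <= row.keys()


class TestEnsemble:
    def test_exactly_four_members(self, tiny_ensemble):
        assert len(tiny_ensemble.members) == 4

    def test_members_saw_different_splits(self, tiny_ensemble):
        fingerprints = {m.scaler.fitted_on for m in tiny_ensemble.members}
        assert len(fingerprints) > 1

    def test_prediction_canonical_invariance(self, tiny_ensemble):
        p1 = tiny_ensemble.predict("CCO", "O", 300.0)
        p2 = tiny_ensemble.predict("OCC", "O", 300.0)
        assert p1 == p2

    def test_uncertainty_nonnegative_and_generically_positive(self, tiny_ensemble):
        p = tiny_ensemble.predict("c1ccccc1", "CCO", 310.0)
        assert p.std_log_s > 0

    def test_identical_members_zero_std(self, tiny_ensemble):
        clone = ts.EnsembleModel(members=[tiny_ensemble.members[0]] * 4,
                                 schema=tiny_ensemble.schema)
        assert clone.predict("CCO", "O", 300.0).std_log_s == 0.0

    def test_nonpositive_temperature_rejected(self, tiny_ensemble):
        with pytest.raises(ValueError):
            tiny_ensemble.predict("CCO", "O", -5.0)

    def test_unparseable_structure_rejected(self, tiny_ensemble):
        with pytest.raises(ValueError):
            tiny_ensemble.predict("C(", "O", 300.0)


class TestClampContract:
    def test_constant_prediction_above_clamp(self, tiny_ensemble):
        clamp = tiny_ensemble.config.clamp_T
        base = tiny_ensemble.predict("CCO", "CC(C)=O", clamp)
        for T in (clamp + 5, clamp + 30, clamp + 100):
            assert tiny_ensemble.predict("CCO", "CC(C)=O", T) == base

    def test_zero_gradient_above_clamp(self, tiny_ensemble):
        clamp = tiny_ensemble.config.clamp_T
        g = tiny_ensemble.predict_gradient(["CCO"], ["CC(C)=O"], [clamp + 10.0])
        assert g[0] == 0.0

    def test_gradient_matches_finite_difference_below_clamp(self, tiny_ensemble):
        """Analytic d logS/dT agrees with a central difference of predict."""
        T = 310.0
        g = tiny_ensemble.predict_gradient(["c1ccccc1"], ["CCO"], [T])[0]
        up = tiny_ensemble.predict("c1ccccc1", "CCO", T + 0.5).mean_log_s
        dn = tiny_ensemble.predict("c1ccccc1", "CCO", T - 0.5).mean_log_s
        assert g == pytest.approx((up - dn) / 1.0, abs=1e-3)


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, tiny_ensemble, tmp_path):
        ts.save_ensemble(tiny_ensemble, tmp_path / "model")
        loaded = ts.load_ensemble(tmp_path / "model")
        for solute, solvent, T in [("CCO", "O", 298.15), ("c1ccccc1", "CCO", 330.0)]:
            assert loaded.predict(solute, solvent, T) == tiny_ensemble.predict(solute, solvent, T)

    def test_manifest_written(self, tiny_ensemble, tmp_path):
        import json

        ts.save_ensemble(tiny_ensemble, tmp_path / "model")
        meta = json.loads((tmp_path / "model" / "model.json").read_text())
        assert meta["schema"]["schema_id"] == tiny_ensemble.schema.schema_id
        assert len(meta["members"]) == 4


class TestConfig:
    def test_invalid_combine_mode(self):
        with pytest.raises(ValueError):
            ts.ModelConfig(combine_mode="divide")

    def test_negative_sobolev_weight(self):
        with pytest.raises(ValueError):
            ts.ModelConfig(sobolev_weight=-1.0)

    def test_unknown_temperature_feature(self):
        with pytest.raises(ValueError):
            ts.ModelConfig(temperature_feature="celsius")
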