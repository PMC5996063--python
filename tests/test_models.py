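"""Model construction, training behaviour and the ensemble contract."""

import numpy as np
import pytest

from drugscan import _nn
from drugscan.exceptions import ConfigurationError
from drugscan.models import (ENSEMBLE_CONFIGS, ConvFingerprintRegressor,
                             DrugResponseEnsemble, build_model, load_ensemble,
                             load_model_configs, predict_ensemble, save_ensemble)


class TestConfigRegistry:
    def test_five_published_rows(self):
        cfgs = load_model_configs()
        assert set(ENSEMBLE_CONFIGS) <= set(cfgs)
        table = {"master": (True, 28, "linear", 250),
                 "fully_connected": (True, 31, "linear", 500),
                 "shallow": (True, 24, "linear", 250),
                 "tanh": (True, 31, "tanh", 250),
                 "unified": (False, 17, "linear", 250)}
        for name, (dock, layers, act, epochs) in table.items():
            c = cfgs[name]
            assert c.uses_virtual_docking == dock
            assert c.layer_count == layers
            assert c.dense_activation == act
            assert c.epochs["full"] == epochs

    def test_only_unified_forgoes_virtual_docking(self):
        cfgs = load_model_configs()
        no_dock = [n for n, c in cfgs.items() if not c.uses_virtual_docking]
        assert no_dock == ["unified"]

    def test_dropout_rates_within_published_band(self):
        for c in load_model_configs().values():
            assert 0.10 <= c.dropout_rate <= 0.20

    def test_every_branch_has_conv_pool_dropout(self):
        cfgs = load_model_configs()
        for c in cfgs.values():
            for profile in c.profiles.values():
                stacks = ([profile["body"]] if "body" in profile
                          else [profile["genomic_branch"], profile["drug_branch"]])
                for stack in stacks:
                    kinds = {next(iter(d)) for d in stack}
                    assert {"conv", "pool"} <= kinds
                kinds_all = {next(iter(d)) for stack in
                             ([profile["body"]] if "body" in profile else
                              [profile["genomic_branch"], profile["drug_branch"],
                               profile["head"]])
                             for d in stack}
                assert "dropout" in kinds_all

    def test_unknown_config_name_rejected(self):
        with pytest.raises(ConfigurationError, match="nonesuch"):
            ConvFingerprintRegressor(config="nonesuch", genomic_width=4).fit(
                np.zeros((4, 8)), np.zeros(4))


class TestBuildModel:
    @pytest.mark.parametrize("name", ENSEMBLE_CONFIGS)
    def test_toy_widths_forward_pass(self, name):
        cfg = load_model_configs()[name]
        net = build_model(cfg, 4, 4, rng=0)
        out = net.forward(np.zeros((2, 8), dtype=np.uint8), False, None)
        assert out.shape == (2, 1)
        assert np.isfinite(out).all()

    def test_dual_convergence_has_two_branches(self):
        cfg = load_model_configs()["master"]
        net = build_model(cfg, 32, 24, rng=0)
        assert isinstance(net, _nn.TwoBranchNet)
        assert net.split == 32

    def test_unified_is_single_entity(self):
        cfg = load_model_configs()["unified"]
        net = build_model(cfg, 32, 24, rng=0)
        assert isinstance(net, _nn.SingleBranchNet)


class TestTraining:
    def test_constant_target_converges(self, toy_xy):
        X, _, gw = toy_xy
        y = np.full(len(X), 3.0)
        m = ConvFingerprintRegressor(config="master", genomic_width=gw, epochs=300,
                                     batch_size=None, random_state=0)
        m.fit(X, y)
        assert np.abs(m.predict(X) - 3.0).max() < 0.3

    def test_planted_signal_beats_mean_predictor(self, toy_xy):
        X, y, gw = toy_xy
        m = ConvFingerprintRegressor(config="master", genomic_width=gw, epochs=60,
                                     random_state=0)
        m.fit(X[:90], y[:90])
        mse = float(np.mean((m.predict(X[90:]) - y[90:]) ** 2))
        assert mse < np.var(y[90:])

    def test_same_seed_reproduces_weights_and_log(self, toy_xy):
        X, y, gw = toy_xy
        runs = []
        for _ in range(2):
            m = ConvFingerprintRegressor(config="shallow", genomic_width=gw,
                                         epochs=5, random_state=7)
            m.fit(X, y)
            runs.append(m)
        for a, b in zip(runs[0].net_.all_params, runs[1].net_.all_params):
            np.testing.assert_array_equal(a[0], b[0])
        assert runs[0].training_log_.train_mse == runs[1].training_log_.train_mse

    def test_full_batch_invariant_to_instance_order(self, toy_xy):
        X, y, gw = toy_xy
        perm = np.random.default_rng(1).permutation(len(X))
        preds = []
        for Xi, yi in [(X, y), (X[perm], y[perm])]:
            m = ConvFingerprintRegressor(config="master", genomic_width=gw, epochs=3,
                                         batch_size=None, random_state=3)
            m.fit(Xi, yi)
            preds.append(m.predict(X[:10]))
        # identical up to float32 reduction order over the permuted rows
        np.testing.assert_allclose(preds[0], preds[1], atol=1e-2)

    def test_training_log_lengths(self, toy_xy):
        X, y, gw = toy_xy
        m = ConvFingerprintRegressor(config="tanh", genomic_width=gw, epochs=4,
                                     random_state=0)
        m.fit(X, y, validation_data=(X[:20], y[:20]))
        assert len(m.training_log_.train_mse) == 4
        assert len(m.training_log_.val_mse) == 4

    def test_zeroed_drug_block_makes_predictions_drug_independent(self, toy_xy):
        X, y, gw = toy_xy
        m = ConvFingerprintRegressor(config="master", genomic_width=gw, epochs=5,
                                     random_state=0)
        Xz = X.copy()
        Xz[:, gw:] = 0
        m.fit(Xz, y)
        # one cell-line profile paired with two different (zeroed) drug blocks
        probe = np.tile(Xz[:1], (2, 1))
        out = m.predict(probe)
        assert out[0] == pytest.approx(out[1], abs=1e-6)

    def test_genomic_width_required(self, toy_xy):
        X, y, _ = toy_xy
        with pytest.raises(ConfigurationError):
            ConvFingerprintRegressor(genomic_width=None).fit(X, y)


class _Stub:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value, dtype=float)


class TestEnsembleContract:
    def test_mean_of_identical_members(self):
        X = np.zeros((3, 4))
        assert predict_ensemble([_Stub(1.0)] * 5, X).tolist() == [1.0, 1.0, 1.0]

    def test_arithmetic_mean(self):
        X = np.zeros((2, 4))
        members = [_Stub(v) for v in (-1.0, 0.0, 1.0, 2.0, 3.0)]
        np.testing.assert_allclose(predict_ensemble(members, X), 1.0)

    def test_wrong_member_count_rejected(self):
        with pytest.raises(ConfigurationError):
            predict_ensemble([_Stub(0.0)] * 4, np.zeros((1, 2)))
        with pytest.raises(ConfigurationError):
            DrugResponseEnsemble(configs=("master",), genomic_width=2).fit(
                np.zeros((4, 4)), np.zeros(4))

    def test_ensemble_within_member_envelope(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = rng.normal(size=5)
            members = [_Stub(v) for v in vals]
            out = predict_ensemble(members, np.zeros((1, 2)))[0]
            assert vals.min() <= out <= vals.max()

    def test_fitted_ensemble_mean_is_exact(self, toy_xy):
        X, y, gw = toy_xy
        ens = DrugResponseEnsemble(genomic_width=gw, epochs=2, random_state=0)
        ens.fit(X, y)
        members = ens.predict_members(X[:15])
        np.testing.assert_allclose(ens.predict(X[:15]), members.mean(axis=1),
                                   rtol=0, atol=1e-12)
        assert (ens.predict(X[:15]) >= members.min(axis=1) - 1e-12).all()
        assert (ens.predict(X[:15]) <= members.max(axis=1) + 1e-12).all()


class TestCheckpointRoundTrip:
    def test_save_load_preserves_predictions(self, toy_xy, tmp_path):
        X, y, gw = toy_xy
        ens = DrugResponseEnsemble(genomic_width=gw, epochs=2, random_state=1)
        ens.fit(X, y)
        path = tmp_path / "ens.npz"
        save_ensemble(ens, path)
        loaded = load_ensemble(path)
        np.testing.assert_allclose(loaded.predict(X[:20]), ens.predict(X[:20]),
                                   rtol=1e-6)


class TestEngineGradients:
    def test_finite_difference_agreement(self):
        rng = np.random.default_rng(0)
        gb = _nn.Sequential([_nn.Conv1D(1, 2, 3, 2, rng=rng), _nn.MaxPool1D(2),
                             _nn.Flatten()])
        db = _nn.Sequential([_nn.Conv1D(1, 2, 2, 1, rng=rng), _nn.MaxPool1D(2),
                             _nn.Flatten()])
        ng, nd = ((12 - 3) // 2 + 1) // 2 * 2, ((9 - 2) // 1 + 1) // 2 * 2
        head = _nn.Sequential([_nn.Dense(ng + nd, 5, "tanh", rng=rng),
                               _nn.Dense(5, 1, "linear", rng=rng)])
        net = _nn.TwoBranchNet(gb, db, head, split=12)
        X = rng.random((6, 21)).astype(np.float32)
        y = rng.random(6)

        def loss():
            p = net.forward(X, False, None).ravel()
            return float(np.mean((p - y) ** 2))

        p = net.forward(X, False, None).ravel()
        net.backward(((2 * (p - y) / len(y))[:, None]).astype(np.float32))
        checked = 0
        for slot in net.all_params:
            w, g = slot[0], slot[1]
            flat = w.ravel()
            for k in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                eps = 1e-3
                old = flat[k]
                flat[k] = old + eps
                lp = loss()
                flat[k] = old - eps
                lm = loss()
                flat[k] = old
                num = (lp - lm) / (2 * eps)
                assert g.ravel()[k] == pytest.approx(num, abs=5e-3, rel=5e-2)
                checked += 1
        assert checked >= 20


def test_divergent_training_raises_with_epoch_index(toy_xy):
    from drugscan.exceptions import DivergenceError

    X, y, gw = toy_xy
    with np.errstate(all="ignore"):
        with pytest.raises(DivergenceError) as exc:
            ConvFingerprintRegressor(config="master", genomic_width=gw, epochs=8,
                                     learning_rate=1e12, random_state=0).fit(X, y)
    assert exc.value.epoch >= 0
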