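"""The five-member convolutional ensemble for ln(IC50) regression.

Four member architectures process the two fingerprint blocks in separate
1-D convolutional branches and merge them downstream ("virtual docking" —
the merged features are mixed by a dense layer and convolved further); the
fifth ("unified") convolves the whole concatenated input as one entity.
The ensemble prediction is the arithmetic mean of the five member outputs
in ln(IC50) space.

Estimators follow the scikit-learn contract: hyperparameters in
``__init__``, fitted state in trailing-underscore attributes,
``fit``/``predict``, and compatibility with ``get_params``/``set_params``,
pipelines and model selection.  Inputs are the concatenated binary
fingerprint matrix ``X`` of shape (n_instances, genomic_width + 3072-ish);
``genomic_width`` tells the estimator where the genomic block ends.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import _nn
from .exceptions import ConfigurationError

ENSEMBLE_CONFIGS = ("master", "fully_connected", "shallow", "tanh", "unified")


@dataclass(frozen=True)
class ModelConfig:
    """One member architecture description."""

    name: str
    uses_virtual_docking: bool
    layer_count: int                 # published total, informational
    dense_activation: str            # hidden dense activation: linear | tanh
    dropout_rate: float
    epochs: dict                     # per profile
    profiles: dict = field(repr=False)

    def __post_init__(self):
        if not 0.10 <= self.dropout_rate <= 0.20:
            raise ConfigurationError(
                f"{self.name}: dropout_rate {self.dropout_rate} outside [0.10, 0.20]"
            )
        if self.dense_activation not in ("linear", "tanh"):
            raise ConfigurationError(f"{self.name}: unknown activation {self.dense_activation}")


def load_model_configs(path=None) -> dict[str, ModelConfig]:
    """Load the shipped (or a user-supplied) architecture registry."""
    if path is None:
        text = (importlib.resources.files("drugscan") / "configs/models.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)["models"]
    configs = {}
    for name, spec in raw.items():
        configs[name] = ModelConfig(
            name=name,
            uses_virtual_docking=bool(spec["uses_virtual_docking"]),
            layer_count=int(spec["layer_count"]),
            dense_activation=str(spec["dense_activation"]),
            dropout_rate=float(spec["dropout_rate"]),
            epochs={k: int(v) for k, v in spec["epochs"].items()},
            profiles=spec["profiles"],
        )
    n_unified = sum(1 for c in configs.values() if not c.uses_virtual_docking)
    if n_unified != 1:
        raise ConfigurationError(
            f"exactly one config must forgo virtual docking; found {n_unified}"
        )
    return configs


def _build_stack(descriptors, in_shape, config, rng, *, final_scalar: bool):
    """Translate layer descriptors into engine layers, tracing shapes.

    ``in_shape`` is (channels, length) for convolutional input or (width,)
    for flat input.  Kernel/stride/pool sizes are clamped so tiny toy widths
    still produce a valid network.
    """
    layers = []
    shape = tuple(in_shape)

    def to_conv():
        nonlocal shape
        if len(shape) == 1:
            layers.append(_Reshape1D())
            shape = (1, shape[0])

    def to_flat():
        nonlocal shape
        if len(shape) == 2:
            layers.append(_nn.Flatten())
            shape = (shape[0] * shape[1],)

    for d in descriptors:
        kind, arg = next(iter(d.items()))
        if kind == "conv":
            to_conv()
            c, length = shape
            k = max(1, min(int(arg["kernel"]), length))
            s = max(1, min(int(arg["stride"]), k))
            layer = _nn.Conv1D(c, int(arg["channels"]), k, s, rng=rng)
            layers.append(layer)
            shape = (int(arg["channels"]), layer.out_length(length))
        elif kind == "pool":
            c, length = shape
            p = max(1, min(int(arg), length))
            layers.append(_nn.MaxPool1D(p))
            shape = (c, length // p)
        elif kind == "dropout":
            rate = config.dropout_rate if arg is None else float(arg)
            layers.append(_nn.Dropout(rate))
        elif kind == "dense":
            to_flat()
            act = arg.get("activation") or config.dense_activation
            units = int(arg["units"])
            layers.append(_nn.Dense(shape[0], units, act, rng=rng))
            shape = (units,)
        else:
            raise ConfigurationError(f"unknown layer descriptor {kind!r}")
    if final_scalar:
        to_flat()
        layers.append(_nn.Dense(shape[0], 1, "linear", rng=rng))
        shape = (1,)
    return _nn.Sequential(layers), shape


class _Reshape1D(_nn.Layer):
    """(N, F) -> (N, 1, F) so a dense output can be convolved again."""

    def forward(self, x, train, rng):
        return x[:, None, :]

    def backward(self, grad):
        return grad[:, 0, :]


def build_model(config: ModelConfig, genomic_width: int, drug_width: int,
                profile: str = "scaled", rng=None):
    """Instantiate an untrained network for the given input widths."""
    if genomic_width < 1 or drug_width < 1:
        raise ConfigurationError("fingerprint widths must be >= 1")
    if profile not in config.profiles:
        raise ConfigurationError(f"{config.name}: unknown profile {profile!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    spec = config.profiles[profile]
    def _mark_input(stack):
        if stack.layers and isinstance(stack.layers[0], _nn.Conv1D):
            stack.layers[0].input_layer = True

    if config.uses_virtual_docking:
        gb, gshape = _build_stack(spec["genomic_branch"], (1, genomic_width),
                                  config, rng, final_scalar=False)
        gb.layers.append(_nn.Flatten())
        db, dshape = _build_stack(spec["drug_branch"], (1, drug_width),
                                  config, rng, final_scalar=False)
        db.layers.append(_nn.Flatten())
        _mark_input(gb)
        _mark_input(db)
        merged = int(np.prod(gshape)) + int(np.prod(dshape))
        head, _ = _build_stack(spec["head"], (merged,), config, rng, final_scalar=True)
        return _nn.TwoBranchNet(gb, db, head, split=genomic_width)
    body, _ = _build_stack(spec["body"], (1, genomic_width + drug_width),
                           config, rng, final_scalar=True)
    _mark_input(body)
    return _nn.SingleBranchNet(body)


@dataclass
class TrainingLog:
    """Per-epoch mean squared errors for one member fit."""

    config_name: str
    seed: int
    epochs: int
    train_mse: list
    val_mse: list


class ConvFingerprintRegressor(RegressorMixin, BaseEstimator):
    """One convolutional member network as a scikit-learn regressor.

    Parameters
    ----------
    config : str, default "master"
        Architecture name from the shipped registry (or a ModelConfig).
    genomic_width : int or None
        Boundary between the genomic and molecular blocks of X.  Required.
    profile : {"scaled", "full"}
        "scaled" is a narrow, few-epoch profile sized for CPU benchmarks.
    epochs, batch_size, learning_rate
        Training-loop controls; ``epochs=None`` uses the profile default,
        ``batch_size=None`` trains full-batch (instance-order invariant).
    random_state : int
        Seeds weight initialisation, dropout masks and minibatch shuffling.

    Attributes
    ----------
    net_ : trained network;  training_log_ : TrainingLog
    """

    def __init__(self, config="master", genomic_width=None, profile="scaled",
                 epochs=None, batch_size=256, learning_rate=2e-3, random_state=0):
        self.config = config
        self.genomic_width = genomic_width
        self.profile = profile
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _resolve_config(self) -> ModelConfig:
        if isinstance(self.config, ModelConfig):
            return self.config
        registry = load_model_configs()
        if self.config not in registry:
            raise ConfigurationError(
                f"unknown model config {self.config!r}; available: {sorted(registry)}"
            )
        return registry[self.config]

    def fit(self, X, y, validation_data=None):
        X, y = check_X_y(X, y, dtype=None, y_numeric=True)
        cfg = self._resolve_config()
        if self.genomic_width is None or not 1 <= int(self.genomic_width) < X.shape[1]:
            raise ConfigurationError(
                f"genomic_width must split X's {X.shape[1]} columns into two non-empty blocks"
            )
        gw = int(self.genomic_width)
        rng = np.random.default_rng(self.random_state)
        net = build_model(cfg, gw, X.shape[1] - gw, profile=self.profile, rng=rng)
        epochs = int(self.epochs) if self.epochs is not None else cfg.epochs[self.profile]
        # standardise the target internally for optimiser conditioning
        self._y_mean = float(np.mean(y))
        self._y_sd = float(np.std(y)) or 1.0
        yt = (np.asarray(y, dtype=float) - self._y_mean) / self._y_sd
        Xv = yv = None
        if validation_data is not None:
            Xv = check_array(validation_data[0], dtype=None)
            yv = (np.asarray(validation_data[1], dtype=float) - self._y_mean) / self._y_sd
        log = _nn.fit_network(net, X, yt, epochs=epochs, batch_size=self.batch_size,
                              lr=self.learning_rate, rng=rng, X_val=Xv, y_val=yv)
        self.net_ = net
        self.n_features_in_ = X.shape[1]
        self.training_log_ = TrainingLog(
            config_name=cfg.name, seed=int(self.random_state), epochs=epochs,
            train_mse=[m * self._y_sd ** 2 for m in log["train_mse"]],
            val_mse=[m * self._y_sd ** 2 for m in log["val_mse"]],
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "net_")
        X = check_array(X, dtype=None)
        out = _nn.predict_network(self.net_, X).astype(np.float64)
        return out * self._y_sd + self._y_mean


def predict_ensemble(members, X) -> np.ndarray:
    """Arithmetic mean of exactly five member predictions in ln(IC50) space."""
    members = list(members)
    if len(members) != 5:
        raise ConfigurationError(f"ensemble requires exactly 5 members, got {len(members)}")
    return np.mean([np.asarray(m.predict(X), dtype=float) for m in members], axis=0)


class DrugResponseEnsemble(RegressorMixin, BaseEstimator):
    """The five-model ensemble; prediction is the member mean.

    Shares the member hyperparameters; per-member seeds are spawned
    deterministically from ``random_state``.
    """

    def __init__(self, configs=ENSEMBLE_CONFIGS, genomic_width=None, profile="scaled",
                 epochs=None, batch_size=256, learning_rate=2e-3, random_state=0):
        self.configs = configs
        self.genomic_width = genomic_width
        self.profile = profile
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y, validation_data=None):
        if len(tuple(self.configs)) != 5:
            raise ConfigurationError(
                f"the ensemble is defined as five models, got {len(tuple(self.configs))}"
            )
        seeds = np.random.SeedSequence(self.random_state).generate_state(5) % (2 ** 31)
        self.members_ = []
        for name, seed in zip(self.configs, seeds):
            member = ConvFingerprintRegressor(
                config=name, genomic_width=self.genomic_width, profile=self.profile,
                epochs=self.epochs, batch_size=self.batch_size,
                learning_rate=self.learning_rate, random_state=int(seed),
            )
            member.fit(X, y, validation_data=validation_data)
            self.members_.append(member)
        self.n_features_in_ = X.shape[1] if hasattr(X, "shape") else np.asarray(X).shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "members_")
        return predict_ensemble(self.members_, X)

    def predict_members(self, X) -> np.ndarray:
        """Per-member predictions, shape (n_instances, 5)."""
        check_is_fitted(self, "members_")
        return np.column_stack([m.predict(X) for m in self.members_])


def save_ensemble(ensemble: DrugResponseEnsemble, path) -> None:
    """Persist a fitted ensemble as an .npz checkpoint with a JSON header."""
    import json

    check_is_fitted(ensemble, "members_")
    arrays, meta_members = {}, []
    for i, m in enumerate(ensemble.members_):
        for j, slot in enumerate(m.net_.all_params):
            arrays[f"m{i}_p{j}"] = slot[0]
        meta_members.append({
            "config": m.training_log_.config_name,
            "seed": m.training_log_.seed,
            "epochs": m.training_log_.epochs,
            "y_mean": m._y_mean,
            "y_sd": m._y_sd,
            "n_params": len(m.net_.all_params),
        })
    meta = {
        "profile": ensemble.profile,
        "genomic_width": int(ensemble.genomic_width),
        "n_features_in": int(ensemble.n_features_in_),
        "members": meta_members,
    }
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_ensemble(path) -> DrugResponseEnsemble:
    """Restore an ensemble saved by :func:`save_ensemble`."""
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        ens = DrugResponseEnsemble(
            configs=tuple(m["config"] for m in meta["members"]),
            genomic_width=meta["genomic_width"], profile=meta["profile"],
        )
        registry = load_model_configs()
        ens.members_ = []
        gw = meta["genomic_width"]
        dw = meta["n_features_in"] - gw
        for i, mm in enumerate(meta["members"]):
            member = ConvFingerprintRegressor(
                config=mm["config"], genomic_width=gw, profile=meta["profile"],
                random_state=mm["seed"],
            )
            net = build_model(registry[mm["config"]], gw, dw, profile=meta["profile"],
                              rng=np.random.default_rng(mm["seed"]))
            for j, slot in enumerate(net.all_params):
                slot[0][...] = data[f"m{i}_p{j}"]
            member.net_ = net
            member._y_mean, member._y_sd = mm["y_mean"], mm["y_sd"]
            member.n_features_in_ = meta["n_features_in"]
            member.training_log_ = TrainingLog(mm["config"], mm["seed"], mm["epochs"], [], [])
            ens.members_.append(member)
        ens.n_features_in_ = meta["n_features_in"]
    return ens
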