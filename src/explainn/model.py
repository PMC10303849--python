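"""The interpretable sequence-to-activity architecture.

The model is a neural additive model over DNA sequence: U independent units,
each a single-filter convolutional network, emit one scalar per sequence, and
a single linear layer combines the U scalars into T task outputs. Because the
final layer is linear and the units share no parameters, the model is its own
explanation: predictions decompose exactly into per-unit contributions.

Each unit (``two_fc_layers`` head) is::

    conv(1 filter, 4 x W, valid) -> batch norm -> exponential -> max pool(7, 7)
    -> FC(100) -> batch norm -> ReLU -> dropout(0.3)
    -> FC(1) -> batch norm -> ReLU

The ``global_max_pool`` variant replaces everything after the exponential with
a global max over positions, reducing each unit to a motif-scanner: its output
is the best activation of its filter anywhere on the sequence.

The compute core is pure NumPy with hand-derived gradients; the architecture
is small and fixed, so no autodiff framework is required.
"""

from __future__ import annotations

import json
import copy as _copy
from dataclasses import dataclass, asdict

import numpy as np

from . import _nn
from ._nn import BatchNormState
from .encoding import OneHotSequence

CHECKPOINT_SCHEMA_VERSION = 1

TWO_FC = "two_fc_layers"
GLOBAL_MAX_POOL = "global_max_pool"


class ConfigurationError(ValueError):
    """A model configuration violates an architectural constraint."""


class ShapeError(ValueError):
    """An input's shape is incompatible with the model."""


def conv_geometry(input_length: int, filter_width: int, pool_size: int,
                  pool_stride: int) -> tuple[int, int]:
    """Output lengths of the valid convolution and the subsequent max pool.

    Returns ``(conv_len, pooled_len)`` with ``conv_len = L - W + 1`` and
    ``pooled_len = floor((conv_len - pool_size) / pool_stride) + 1``.
    """
    if input_length < filter_width:
        raise ConfigurationError(
            f"input_length {input_length} < filter_width {filter_width}"
        )
    conv_len = input_length - filter_width + 1
    if conv_len < pool_size:
        raise ConfigurationError(
            f"conv output length {conv_len} < pool_size {pool_size}"
        )
    pooled_len = (conv_len - pool_size) // pool_stride + 1
    return conv_len, pooled_len


@dataclass
class ModelConfig:
    """Hyperparameters of the architecture.

    Defaults follow the reference unit specification: 19-bp filters,
    max pooling with kernel and stride 7, a 100-node hidden FC layer,
    30% dropout, exponential activation after the convolution.
    """

    num_units: int
    input_length: int
    num_tasks: int
    filter_width: int = 19
    pool_size: int = 7
    pool_stride: int = 7
    fc_hidden: int = 100
    dropout_rate: float = 0.30
    unit_activation: str = "exponential"  # or "relu"
    unit_head: str = TWO_FC  # or "global_max_pool"

    def validate(self) -> None:
        if self.num_units < 1:
            raise ConfigurationError("num_units must be >= 1")
        if self.num_tasks < 1:
            raise ConfigurationError("num_tasks must be >= 1")
        if self.filter_width < 1:
            raise ConfigurationError("filter_width must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.unit_activation not in ("exponential", "relu"):
            raise ConfigurationError(
                f"unknown unit_activation {self.unit_activation!r}"
            )
        if self.unit_head not in (TWO_FC, GLOBAL_MAX_POOL):
            raise ConfigurationError(f"unknown unit_head {self.unit_head!r}")
        conv_geometry(self.input_length, self.filter_width,
                      self.pool_size, self.pool_stride)

    @property
    def conv_len(self) -> int:
        return self.input_length - self.filter_width + 1

    @property
    def pooled_len(self) -> int:
        return conv_geometry(self.input_length, self.filter_width,
                             self.pool_size, self.pool_stride)[1]


# --------------------------------------------------------------------------
# pluggable unit submodels
# --------------------------------------------------------------------------

class UnitSubmodel:
    """Interface for a sequence -> scalar predictor pluggable into a unit."""

    input_length: int | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> None:  # accumulate own grads
        pass

    def parameters(self) -> dict:
        return {}

    def gradients(self) -> dict:
        return {}

    def zero_grad(self) -> None:
        pass


class ConstantSubmodel(UnitSubmodel):
    """Emits a fixed scalar for every sequence (testing/stub use)."""

    def __init__(self, value: float, input_length: int | None = None):
        self.value = float(value)
        self.input_length = input_length

    def forward(self, x, training):
        return np.full(x.shape[0], self.value)


class LinearSubmodel(UnitSubmodel):
    """A linear functional of the one-hot matrix: sum(weights * x) + bias."""

    def __init__(self, weights: np.ndarray, bias: float = 0.0):
        self.weights = np.asarray(weights, dtype=float)  # (L, 4)
        self.bias = float(bias)
        self.input_length = self.weights.shape[0]
        self._cache = None
        self._grads = {"weights": np.zeros_like(self.weights),
                       "bias": np.zeros(1)}

    def forward(self, x, training):
        self._cache = x
        return np.einsum("nla,la->n", x, self.weights) + self.bias

    def backward(self, dout):
        self._grads["weights"] += np.einsum("n,nla->la", dout, self._cache)
        self._grads["bias"] += dout.sum()

    def parameters(self):
        return {"weights": self.weights}

    def gradients(self):
        return {"weights": self._grads["weights"]}

    def zero_grad(self):
        for g in self._grads.values():
            g[...] = 0.0


class PredictorSubmodel(UnitSubmodel):
    """Wraps any (N, L, 4) -> (N,) callable, e.g. a pretrained model.

    Gradient-free: always behaves as frozen.
    """

    def __init__(self, fn, input_length: int | None = None):
        self.fn = fn
        self.input_length = input_length

    def forward(self, x, training):
        return np.asarray(self.fn(x), dtype=float).reshape(x.shape[0])


class PluggedUnit:
    """A unit whose layers are replaced by a pluggable submodel.

    With ``head="fc_head_200"`` the scalar submodel output passes through a
    200-node FC layer with ReLU and a final FC(1).
    """

    HEAD_NODES = 200

    def __init__(self, submodel: UnitSubmodel, freeze: bool, head: str,
                 rng: np.random.Generator | None = None):
        if head not in ("none", "fc_head_200"):
            raise ValueError(f"unknown head {head!r}")
        self.submodel = submodel
        self.freeze = bool(freeze)
        self.head = head
        self.params: dict[str, np.ndarray] = {}
        if head == "fc_head_200":
            rng = rng if rng is not None else np.random.default_rng(0)
            h = self.HEAD_NODES
            self.params = {
                "hw1": _nn.uniform_fan_in(rng, (h,), 1),
                "hb1": _nn.uniform_fan_in(rng, (h,), 1),
                "hw2": _nn.uniform_fan_in(rng, (h,), h),
                "hb2": _nn.uniform_fan_in(rng, (1,), h),
            }
        self._cache = None

    def forward(self, x, training):
        s = self.submodel.forward(x, training)
        if self.head == "none":
            self._cache = ("none", None)
            return s
        p = self.params
        pre = s[:, None] * p["hw1"][None, :] + p["hb1"][None, :]
        t, relu_mask = _nn.relu_forward(pre)
        out = t @ p["hw2"] + p["hb2"][0]
        self._cache = ("fc", (s, t, relu_mask))
        return out

    def backward(self, dout):
        kind, cache = self._cache
        grads = {}
        if kind == "none":
            ds = dout
        else:
            s, t, relu_mask = cache
            p = self.params
            grads["hw2"] = t.T @ dout
            grads["hb2"] = np.array([dout.sum()])
            dt = dout[:, None] * p["hw2"][None, :]
            dpre = _nn.relu_backward(dt, relu_mask)
            grads["hw1"] = (dpre * s[:, None]).sum(axis=0)
            grads["hb1"] = dpre.sum(axis=0)
            ds = dpre @ p["hw1"]
        if not self.freeze:
            self.submodel.backward(ds)
        return grads

    def copy(self) -> "PluggedUnit":
        return _copy.deepcopy(self)


# --------------------------------------------------------------------------
# the model
# --------------------------------------------------------------------------

class ExplaiNNModel:
    """U independent single-filter units combined by one linear layer.

    Parameters live in ``params`` (plain float64 arrays) plus three
    per-unit batch-norm states. ``frozen_filter_mask`` marks units whose
    convolutional filters are excluded from updates via gradient
    nullification.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        U, W = config.num_units, config.filter_width
        T = config.num_tasks
        H = config.fc_hidden
        Pp = config.pooled_len

        self.params: dict[str, np.ndarray] = {
            "filters": _nn.uniform_fan_in(rng, (U, 4, W), 4 * W),
        }
        self.bn0 = BatchNormState((U,), axes=(0, 1))
        if config.unit_head == TWO_FC:
            self.params.update({
                "fc1_w": _nn.uniform_fan_in(rng, (U, Pp, H), Pp),
                "fc1_b": _nn.uniform_fan_in(rng, (U, H), Pp),
                "fc2_w": _nn.uniform_fan_in(rng, (U, H), H),
                "fc2_b": _nn.uniform_fan_in(rng, (U,), H),
            })
            self.bn1 = BatchNormState((U, H), axes=(0,))
            self.bn2 = BatchNormState((U,), axes=(0,))
        self.params["final_w"] = _nn.uniform_fan_in(rng, (U, T), U)
        self.params["final_b"] = _nn.uniform_fan_in(rng, (T,), U)

        self.frozen_filter_mask = np.zeros(U, dtype=bool)
        self.plugged: dict[int, PluggedUnit] = {}
        self._cache = None

    # -- bookkeeping -------------------------------------------------------

    @property
    def final_weights(self) -> np.ndarray:
        return self.params["final_w"]

    @property
    def final_bias(self) -> np.ndarray:
        return self.params["final_b"]

    def bn_states(self) -> dict[str, BatchNormState]:
        out = {"bn0": self.bn0}
        if self.config.unit_head == TWO_FC:
            out["bn1"] = self.bn1
            out["bn2"] = self.bn2
        return out

    def trainable_parameters(self) -> dict[str, np.ndarray]:
        """All arrays the optimizer may update (plugged heads included)."""
        out = dict(self.params)
        for name, st in self.bn_states().items():
            out[f"{name}_gamma"] = st.gamma
            out[f"{name}_beta"] = st.beta
        for idx, pu in self.plugged.items():
            for k, v in pu.params.items():
                out[f"plug{idx}_{k}"] = v
            if not pu.freeze:
                for k, v in pu.submodel.parameters().items():
                    out[f"plug{idx}_sub_{k}"] = v
        return out

    def copy(self) -> "ExplaiNNModel":
        return _copy.deepcopy(self)

    # -- input validation --------------------------------------------------

    def _as_batch(self, batch) -> np.ndarray:
        L = self.config.input_length
        if isinstance(batch, np.ndarray):
            x = batch
            if x.ndim == 2:
                x = x[None]
            if x.shape[1] != L:
                raise ShapeError(
                    f"batch has sequence length {x.shape[1]}, model expects {L}"
                )
            return np.asarray(x, dtype=np.float64)
        mats = []
        for i, s in enumerate(batch):
            if isinstance(s, OneHotSequence):
                if s.length != L:
                    raise ShapeError(
                        f"sequence {s.id or i} has length {s.length}, "
                        f"model expects {L}"
                    )
                mats.append(s.matrix)
            else:
                s = np.asarray(s)
                if s.shape[0] != L:
                    raise ShapeError(
                        f"sequence {i} has length {s.shape[0]}, model expects {L}"
                    )
                mats.append(s)
        return np.stack(mats).astype(np.float64)

    # -- forward -----------------------------------------------------------

    def _conv(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Valid cross-correlation of all unit filters with the batch.

        Returns (z (N, P, U), windows (N, P, 4W)) for reuse in backward.
        """
        W = self.config.filter_width
        # windows[n, p, a, w] = x[n, p + w, a]
        win = np.lib.stride_tricks.sliding_window_view(x, W, axis=1)
        n, p = win.shape[:2]
        win_flat = np.ascontiguousarray(win).reshape(n, p, 4 * W)
        filt = self.params["filters"].reshape(self.config.num_units, 4 * W)
        z = win_flat @ filt.T  # (N, P, U)
        return z, win_flat

    def _activation(self, z, training):
        if self.config.unit_activation == "exponential":
            return _nn.exp_forward(z)
        return _nn.relu_forward(z)

    def _activation_backward(self, dy, cache):
        if self.config.unit_activation == "exponential":
            return _nn.exp_backward(dy, cache)
        return _nn.relu_backward(dy, cache)

    def forward(self, batch, training: bool = False,
                rng: np.random.Generator | None = None):
        """Run the model; returns ``(predictions (N, T), unit_outputs (N, U))``.

        In evaluation mode (default) the pass is deterministic: dropout is
        off and batch norm uses its running statistics.
        """
        x = self._as_batch(batch)
        cfg = self.config
        cache: dict = {"x": x, "training": training}

        z, win = self._conv(x)
        cache["win"] = win
        z_bn, cache["bn0"] = _nn.bn_forward(z, self.bn0, training)
        act, cache["act"] = self._activation(z_bn, training)

        if cfg.unit_head == GLOBAL_MAX_POOL:
            unit_out, argpos = _nn.global_maxpool_forward(act)
            cache["gmp"] = (argpos, act.shape)
        else:
            pooled, argpos = _nn.maxpool_forward(act, cfg.pool_size, cfg.pool_stride)
            cache["pool"] = (argpos, act.shape)
            h1 = np.einsum("npu,uph->nuh", pooled, self.params["fc1_w"])
            h1 += self.params["fc1_b"][None]
            cache["pooled"] = pooled
            h1_bn, cache["bn1"] = _nn.bn_forward(h1, self.bn1, training)
            r1, cache["relu1"] = _nn.relu_forward(h1_bn)
            d1, cache["drop"] = _nn.dropout_forward(
                r1, cfg.dropout_rate, rng if rng is not None else np.random.default_rng(0),
                training)
            cache["d1"] = d1
            h2 = np.einsum("nuh,uh->nu", d1, self.params["fc2_w"])
            h2 += self.params["fc2_b"][None]
            h2_bn, cache["bn2"] = _nn.bn_forward(h2, self.bn2, training)
            unit_out, cache["relu2"] = _nn.relu_forward(h2_bn)

        if self.plugged:
            unit_out = unit_out.copy()
            for idx, pu in self.plugged.items():
                unit_out[:, idx] = pu.forward(x, training)

        cache["unit_out"] = unit_out
        pred = unit_out @ self.params["final_w"] + self.params["final_b"]
        self._cache = cache
        return pred, unit_out

    def conv_activations(self, batch) -> np.ndarray:
        """Post-activation (pre-pool) filter responses, evaluation mode.

        Shape (N, conv_len, U); this is the quantity whose per-sequence
        maxima drive filter visualization.
        """
        x = self._as_batch(batch)
        z, _ = self._conv(x)
        z_bn, _ = _nn.bn_forward(z, self.bn0, training=False)
        act, _ = self._activation(z_bn, training=False)
        return act

    def predict(self, batch) -> np.ndarray:
        return self.forward(batch, training=False)[0]

    # -- backward ----------------------------------------------------------

    def backward(self, dpred: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss given d(loss)/d(predictions).

        Must follow a ``forward(..., training=...)`` call on the same batch.
        Frozen filters receive nullified (zero) gradients; frozen plugged
        submodels receive none at all.
        """
        cache = self._cache
        if cache is None:
            raise RuntimeError("backward() called before forward()")
        cfg = self.config
        unit_out = cache["unit_out"]
        grads: dict[str, np.ndarray] = {}

        grads["final_w"] = unit_out.T @ dpred
        grads["final_b"] = dpred.sum(axis=0)
        dunit = dpred @ self.params["final_w"].T  # (N, U)

        for idx, pu in self.plugged.items():
            head_grads = pu.backward(dunit[:, idx])
            for k, v in head_grads.items():
                grads[f"plug{idx}_{k}"] = v
            if not pu.freeze:
                for k, v in pu.submodel.gradients().items():
                    grads[f"plug{idx}_sub_{k}"] = v
            dunit = dunit.copy()
            dunit[:, idx] = 0.0

        if cfg.unit_head == GLOBAL_MAX_POOL:
            argpos, shape = cache["gmp"]
            dact = _nn.global_maxpool_backward(dunit, argpos, shape)
        else:
            dh2_bn = _nn.relu_backward(dunit, cache["relu2"])
            dh2, g2, b2 = _nn.bn_backward(dh2_bn, cache["bn2"])
            grads["bn2_gamma"], grads["bn2_beta"] = g2, b2
            grads["fc2_w"] = np.einsum("nu,nuh->uh", dh2, cache["d1"])
            grads["fc2_b"] = dh2.sum(axis=0)
            dd1 = dh2[:, :, None] * self.params["fc2_w"][None]
            dr1 = _nn.dropout_backward(dd1, cache["drop"])
            dh1_bn = _nn.relu_backward(dr1, cache["relu1"])
            dh1, g1, b1 = _nn.bn_backward(dh1_bn, cache["bn1"])
            grads["bn1_gamma"], grads["bn1_beta"] = g1, b1
            grads["fc1_w"] = np.einsum("npu,nuh->uph", cache["pooled"], dh1)
            grads["fc1_b"] = dh1.sum(axis=0)
            dpooled = np.einsum("nuh,uph->npu", dh1, self.params["fc1_w"])
            argpos, shape = cache["pool"]
            dact = _nn.maxpool_backward(dpooled, argpos, shape)

        dz_bn = self._activation_backward(dact, cache["act"])
        dz, g0, b0 = _nn.bn_backward(dz_bn, cache["bn0"])
        grads["bn0_gamma"], grads["bn0_beta"] = g0, b0
        n, p, u = dz.shape
        dfilt = dz.reshape(n * p, u).T @ cache["win"].reshape(n * p, -1)
        dfilt = dfilt.reshape(u, 4, cfg.filter_width)
        dfilt[self.frozen_filter_mask] = 0.0  # gradient nullification
        grads["filters"] = dfilt
        return grads

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint (config + parameters + BN statistics).

        Plugged submodels are not serialized; checkpoints cover native
        models.
        """
        arrays = {f"param_{k}": v for k, v in self.params.items()}
        for name, st in self.bn_states().items():
            arrays[f"{name}_gamma"] = st.gamma
            arrays[f"{name}_beta"] = st.beta
            arrays[f"{name}_rmean"] = st.running_mean
            arrays[f"{name}_rvar"] = st.running_var
        arrays["frozen_filter_mask"] = self.frozen_filter_mask
        meta = {"schema_version": CHECKPOINT_SCHEMA_VERSION,
                "config": asdict(self.config)}
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ExplaiNNModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta_json"]).decode())
            if meta.get("schema_version") != CHECKPOINT_SCHEMA_VERSION:
                raise ValueError(
                    f"unsupported checkpoint schema {meta.get('schema_version')}"
                )
            model = cls(ModelConfig(**meta["config"]), seed=0)
            for k in model.params:
                model.params[k] = data[f"param_{k}"]
            for name, st in model.bn_states().items():
                st.gamma = data[f"{name}_gamma"]
                st.beta = data[f"{name}_beta"]
                st.running_mean = data[f"{name}_rmean"]
                st.running_var = data[f"{name}_rvar"]
            model.frozen_filter_mask = data["frozen_filter_mask"].astype(bool)
        return model


def build_model(config: ModelConfig, seed: int = 0) -> ExplaiNNModel:
    """Construct a model with the two-FC-layer unit head (the default)."""
    config.validate()
    if config.unit_head != TWO_FC:
        raise ConfigurationError(
            "build_model constructs the two_fc_layers head; use "
            "build_global_maxpool_variant for the ablated architecture"
        )
    return ExplaiNNModel(config, seed=seed)


def build_global_maxpool_variant(config: ModelConfig, seed: int = 0) -> ExplaiNNModel:
    """Construct the ablated variant: conv -> BN -> exp -> global max pool.

    Each unit output equals the maximum activation of its filter anywhere on
    the sequence, i.e. an independent motif scan score.
    """
    cfg = ModelConfig(**{**asdict(config), "unit_head": GLOBAL_MAX_POOL})
    cfg.validate()
    return ExplaiNNModel(cfg, seed=seed)


def plug_unit(model: ExplaiNNModel, unit_index: int, submodel: UnitSubmodel,
              freeze: bool = True, head: str = "none",
              seed: int = 0) -> ExplaiNNModel:
    """Replace one unit's layers with a pluggable sequence->scalar submodel.

    Returns a new model; the original is untouched. With ``freeze=True`` the
    submodel's parameters are excluded from gradient updates entirely.
    """
    if not 0 <= unit_index < model.config.num_units:
        raise IndexError(f"unit index {unit_index} out of range")
    if (submodel.input_length is not None
            and submodel.input_length != model.config.input_length):
        raise ShapeError(
            f"submodel expects length {submodel.input_length}, "
            f"model input length is {model.config.input_length}"
        )
    out = model.copy()
    out.plugged[unit_index] = PluggedUnit(
        submodel, freeze=freeze, head=head, rng=np.random.default_rng(seed))
    return out
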