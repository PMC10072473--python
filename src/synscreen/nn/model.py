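"""The multimodal synergy regressor and its training protocol.

A model is declared by a :class:`ModelConfig`: one feature-encoding
subnetwork per input block (expression always; mutations/CNV optionally,
always fully connected) and a single drug subnetwork whose parameters
are shared between the two drugs of a combination. The learned block
representations are concatenated and fed to a dense prediction head
ending in one linear output unit, trained with mean squared error and
Adam under validation-loss early stopping.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from synscreen.nn.autodiff import Tensor, concat
from synscreen.nn.encoders import ACTIVATIONS, _Base, build_encoder, _dropout

__all__ = [
    "SubnetworkSpec",
    "ModelConfig",
    "TrainConfig",
    "MultimodalRegressor",
    "MeanBaseline",
    "build_multimodal",
    "train",
    "mean_baseline",
]


@dataclass(frozen=True)
class SubnetworkSpec:
    """Declarative description of one feature-encoding subnetwork."""

    input_kind: str  # expr | mut | cnv | drug | onehot
    family: str = "dense"  # dense | conv1d | conv2d | textcnn | gcn | gat
    layer_sizes: tuple[int, ...] = (64,)
    activation: str = "relu"
    dropout_rate: float = 0.0
    l2_penalty: float = 0.0
    kernel_sizes: tuple[int, ...] | None = None
    n_filters: int | None = None
    embed_dim: int | None = None
    attention_heads: int | None = None

    def __post_init__(self) -> None:
        if not self.layer_sizes:
            raise ValueError("layer_sizes must be non-empty")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.l2_penalty < 0.0:
            raise ValueError("l2_penalty must be >= 0")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass(frozen=True)
class ModelConfig:
    """Subnetworks plus head: the full declarative model description.

    One ``drug_spec`` describes both drug subnetworks — their parameters
    are shared. Mutation and CNV subnetworks are always fully connected.
    """

    expr_spec: SubnetworkSpec
    drug_spec: SubnetworkSpec
    mut_spec: SubnetworkSpec | None = None
    cnv_spec: SubnetworkSpec | None = None
    head_layer_sizes: tuple[int, ...] = (64,)
    head_activation: str = "relu"
    head_dropout_rate: float = 0.0
    head_l2_penalty: float = 0.0
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        for name, spec in (("mut", self.mut_spec), ("cnv", self.cnv_spec)):
            if spec is not None and spec.family != "dense":
                raise ValueError(f"the {name} subnetwork must be fully connected (dense)")

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass(frozen=True)
class TrainConfig:
    """The training protocol: MSE loss, Adam, early stopping.

    Defaults follow the screen-modelling protocol: at most 500 epochs,
    early stopping on validation loss with patience 15, mini-batches of
    64.
    """

    max_epochs: int = 500
    early_stop_patience: int = 15
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.max_epochs, self.early_stop_patience, self.batch_size) < 1:
            raise ValueError("epochs, patience and batch size must be positive")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


def _n_rows(inputs: dict) -> int:
    block = next(iter(inputs.values()))
    arr = block[0] if isinstance(block, tuple) else block
    return np.asarray(arr).shape[0]


def _take(inputs: dict, idx: np.ndarray) -> dict:
    out = {}
    for name, block in inputs.items():
        if isinstance(block, tuple):
            out[name] = tuple(np.asarray(a)[idx] for a in block)
        else:
            out[name] = np.asarray(block)[idx]
    return out


class _Head(_Base):
    def __init__(self, config: ModelConfig, n_in: int, rng) -> None:
        super().__init__(None)
        self.config = config
        if config.head_l2_penalty > 0.0:
            self.spec = SubnetworkSpec(
                "head", "dense", config.head_layer_sizes or (1,),
                activation=config.head_activation, l2_penalty=config.head_l2_penalty,
            )
        self.layers = []
        for size in config.head_layer_sizes:
            self.layers.append(self._dense_param(rng, n_in, size))
            n_in = size
        self.out = self._dense_param(rng, n_in, 1)
        self.output_dim = 1

    def __call__(self, t: Tensor, train: bool = False, rng=None) -> Tensor:
        act = ACTIVATIONS[self.config.head_activation]
        for w, b in self.layers:
            t = _dropout(act(t @ w + b), self.config.head_dropout_rate, rng, train)
        w, b = self.out
        return t @ w + b  # single linear output unit


class MultimodalRegressor:
    """Multimodal regressor with a shared drug encoder.

    ``inputs`` is a dict of blocks: ``expr`` (always), ``drug_a`` and
    ``drug_b`` (both encoded by the one shared drug encoder), and
    optionally ``mut`` / ``cnv``. Graph-encoded drug blocks are
    ``(node_features, adjacency, node_mask)`` tuples from
    :func:`synscreen.nn.encoders.pack_graphs`.
    """

    def __init__(self, config: ModelConfig, input_shapes: dict, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        if "expr" not in input_shapes or "drug" not in input_shapes:
            raise ValueError("input_shapes must define at least 'expr' and 'drug'")
        self.encoders = {"expr": build_encoder(config.expr_spec, input_shapes["expr"], rng)}
        self.drug_encoder = build_encoder(config.drug_spec, input_shapes["drug"], rng)
        for name, spec in (("mut", config.mut_spec), ("cnv", config.cnv_spec)):
            if spec is not None:
                if name not in input_shapes:
                    raise ValueError(f"config has a {name} subnetwork but no {name} input shape")
                self.encoders[name] = build_encoder(spec, input_shapes[name], rng)
        width = (
            sum(enc.output_dim for enc in self.encoders.values())
            + 2 * self.drug_encoder.output_dim
        )
        self.head = _Head(config, width, rng)

    # --- forward ----------------------------------------------------------

    def forward(self, inputs: dict, train: bool = False, rng=None) -> Tensor:
        parts = [self.encoders["expr"](inputs["expr"], train, rng)]
        for name in ("mut", "cnv"):
            if name in self.encoders:
                parts.append(self.encoders[name](inputs[name], train, rng))
        parts.append(self.drug_encoder(inputs["drug_a"], train, rng))
        parts.append(self.drug_encoder(inputs["drug_b"], train, rng))
        return self.head(concat(parts, axis=-1), train, rng)

    def predict(self, inputs: dict, batch_size: int = 1024) -> np.ndarray:
        n = _n_rows(inputs)
        chunks = []
        for start in range(0, n, batch_size):
            idx = np.arange(start, min(start + batch_size, n))
            chunks.append(self.forward(_take(inputs, idx)).data)
        return np.concatenate(chunks, axis=0)

    # --- parameters -------------------------------------------------------

    def _modules(self):
        return [*self.encoders.values(), self.drug_encoder, self.head]

    def parameters(self) -> list[Tensor]:
        return [p for mod in self._modules() for p in mod.parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def l2_loss(self):
        total = 0.0
        for mod in self._modules():
            total = total + mod.l2_loss()
        return total

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p.data = w.copy()


def build_multimodal(
    config: ModelConfig, input_shapes: dict, seed: int = 0
) -> MultimodalRegressor:
    """Build a multimodal regressor for the given block input shapes.

    ``input_shapes`` maps block names to per-sample shapes, e.g.
    ``{"expr": (500,), "drug": (1024,)}``; graph drug inputs use the node
    feature width, ``{"drug": (feature_dim,)}``.
    """
    return MultimodalRegressor(config, input_shapes, seed=seed)


class _Adam:
    def __init__(self, params: list[Tensor], lr: float) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g**2
            m_hat = self.m[i] / (1 - self.beta1**self.t)
            v_hat = self.v[i] / (1 - self.beta2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _mse(pred: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((pred.ravel() - np.asarray(y).ravel()) ** 2))


def train(
    model: MultimodalRegressor,
    train_data: tuple[dict, np.ndarray],
    val_data: tuple[dict, np.ndarray],
    cfg: TrainConfig = TrainConfig(),
) -> dict:
    """Train with Adam on MSE under validation-loss early stopping.

    Stops once the validation loss has not improved for
    ``early_stop_patience`` consecutive epochs (or at ``max_epochs``) and
    restores the parameters of the best validation epoch. Returns the
    history dict with per-epoch train/validation losses and the index of
    the restored epoch.
    """
    inputs, y = train_data
    val_inputs, val_y = val_data
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    n = _n_rows(inputs)
    if n == 0 or _n_rows(val_inputs) == 0:
        raise ValueError("training and validation partitions must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    dropout_rng = np.random.default_rng(cfg.seed + 1)
    opt = _Adam(model.parameters(), lr=model.config.learning_rate)
    history: dict = {"train_loss": [], "val_loss": [], "best_epoch": -1}
    best_val = np.inf
    best_weights = model.get_weights()
    since_best = 0
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            batch = _take(inputs, idx)
            pred = model.forward(batch, train=True, rng=dropout_rng)
            err = pred - Tensor(y[idx])
            loss = (err * err).mean() + model.l2_loss()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {float(loss.data)!r} "
                    f"(learning rate {model.config.learning_rate})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        val_loss = _mse(model.predict(val_inputs), val_y)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
            history["best_epoch"] = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                break
    model.set_weights(best_weights)
    return history


class MeanBaseline:
    """Predicts the constant training-set mean for any input."""

    def __init__(self, mean: float) -> None:
        self.mean = float(mean)

    def predict(self, inputs) -> np.ndarray:
        if isinstance(inputs, dict):
            n = _n_rows(inputs)
        else:
            n = np.asarray(inputs).shape[0]
        return np.full((n, 1), self.mean)


def mean_baseline(train_targets) -> MeanBaseline:
    """The random baseline: always predict the average training score."""
    targets = np.asarray(train_targets, dtype=float)
    if targets.size == 0:
        raise ValueError("cannot build a mean baseline from empty targets")
    return MeanBaseline(mean=float(targets.mean()))
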