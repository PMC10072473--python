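"""Feature-encoding subnetworks.

Each omics/drug input block gets its own encoder mapping the block to a
fixed-width representation that the prediction head concatenates:
fully-connected stacks for vectors, 1D/2D convolutions for gene-image
tensors, TextCNN for one-hot SMILES token matrices, and graph
convolution / graph attention over padded molecular-graph batches with
masked mean readout.
"""

from __future__ import annotations

import math

import numpy as np

from synscreen.nn.autodiff import Tensor, concat, unfold1d, unfold2d

__all__ = [
    "ACTIVATIONS",
    "DenseEncoder",
    "Conv1DEncoder",
    "Conv2DEncoder",
    "TextCNNEncoder",
    "GCNEncoder",
    "GATEncoder",
    "build_encoder",
    "pack_graphs",
]

ACTIVATIONS = {
    "relu": lambda t: t.relu(),
    "tanh": lambda t: t.tanh(),
    "sigmoid": lambda t: t.sigmoid(),
    "leaky_relu": lambda t: t.leaky_relu(),
    "linear": lambda t: t,
}


def _glorot(rng: np.random.Generator, n_in: int, n_out: int, *shape) -> np.ndarray:
    limit = math.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=shape or (n_in, n_out))


def _dropout(t: Tensor, rate: float, rng: np.random.Generator | None, train: bool) -> Tensor:
    if not train or rate <= 0.0 or rng is None:
        return t
    mask = (rng.random(t.shape) >= rate).astype(float) / (1.0 - rate)
    return t * Tensor(mask)


class _Base:
    """Common parameter bookkeeping for encoders and heads."""

    def __init__(self, spec) -> None:
        self.spec = spec
        self.weights: list[Tensor] = []  # subject to L2
        self.biases: list[Tensor] = []
        self.output_dim: int = 0

    def _dense_param(self, rng, n_in, n_out):
        w = Tensor(_glorot(rng, n_in, n_out), requires_grad=True)
        b = Tensor(np.zeros(n_out), requires_grad=True)
        self.weights.append(w)
        self.biases.append(b)
        return w, b

    def parameters(self) -> list[Tensor]:
        return [*self.weights, *self.biases]

    def l2_loss(self) -> Tensor | float:
        if self.spec is None or getattr(self.spec, "l2_penalty", 0.0) <= 0.0:
            return 0.0
        total: Tensor | float = 0.0
        for w in self.weights:
            total = total + (w * w).sum() * self.spec.l2_penalty
        return total

    def _act(self, t: Tensor) -> Tensor:
        return ACTIVATIONS[self.spec.activation](t)


class DenseEncoder(_Base):
    """Fully-connected stack for vector inputs (expression, fingerprints,
    embeddings, one-hot identifiers, mutations, CNV)."""

    def __init__(self, spec, input_shape, rng) -> None:
        super().__init__(spec)
        if len(input_shape) != 1:
            raise ValueError(
                f"dense encoder expects a flat input, got shape {input_shape}"
            )
        n_in = input_shape[0]
        self.layers = []
        for size in spec.layer_sizes:
            self.layers.append(self._dense_param(rng, n_in, size))
            n_in = size
        self.output_dim = n_in

    def __call__(self, x, train: bool = False, rng=None) -> Tensor:
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
        for w, b in self.layers:
            t = _dropout(self._act(t @ w + b), self.spec.dropout_rate, rng, train)
        return t


class Conv1DEncoder(_Base):
    """Stacked valid 1D convolutions over a (length, channels) tensor with
    global max pooling."""

    def __init__(self, spec, input_shape, rng) -> None:
        super().__init__(spec)
        if len(input_shape) != 2:
            raise ValueError(
                f"conv1d encoder expects (length, channels) input, got {input_shape}"
            )
        length, channels = input_shape
        kernels = spec.kernel_sizes or [5] * len(spec.layer_sizes)
        if len(kernels) != len(spec.layer_sizes):
            raise ValueError("kernel_sizes must match layer_sizes in length")
        self.kernels = kernels
        self.layers = []
        for k, filters in zip(kernels, spec.layer_sizes):
            if length - k + 1 < 1:
                raise ValueError(f"kernel {k} exceeds remaining length {length}")
            self.layers.append(self._dense_param(rng, k * channels, filters))
            length, channels = length - k + 1, filters
        self.output_dim = channels

    def __call__(self, x, train: bool = False, rng=None) -> Tensor:
        t = Tensor(np.asarray(x))
        for k, (w, b) in zip(self.kernels, self.layers):
            t = _dropout(self._act(unfold1d(t, k) @ w + b), self.spec.dropout_rate, rng, train)
        return t.max(axis=1)


class Conv2DEncoder(_Base):
    """Stacked valid 2D convolutions over a (H, W, C) gene image with global
    max pooling."""

    def __init__(self, spec, input_shape, rng) -> None:
        super().__init__(spec)
        if len(input_shape) != 3:
            raise ValueError(
                f"conv2d encoder expects (height, width, channels) input, got {input_shape}"
            )
        h, w_dim, channels = input_shape
        kernels = spec.kernel_sizes or [3] * len(spec.layer_sizes)
        if len(kernels) != len(spec.layer_sizes):
            raise ValueError("kernel_sizes must match layer_sizes in length")
        self.kernels = kernels
        self.layers = []
        for k, filters in zip(kernels, spec.layer_sizes):
            if h - k + 1 < 1 or w_dim - k + 1 < 1:
                raise ValueError(f"kernel {k} exceeds remaining image ({h},{w_dim})")
            self.layers.append(self._dense_param(rng, k * k * channels, filters))
            h, w_dim, channels = h - k + 1, w_dim - k + 1, filters
        self.output_dim = channels

    def __call__(self, x, train: bool = False, rng=None) -> Tensor:
        t = Tensor(np.asarray(x))
        for k, (w, b) in zip(self.kernels, self.layers):
            t = _dropout(self._act(unfold2d(t, k, k) @ w + b), self.spec.dropout_rate, rng, train)
        b_size = t.shape[0]
        return t.reshape(b_size, -1, t.shape[-1]).max(axis=1)


class TextCNNEncoder(_Base):
    """Parallel-kernel CNN over one-hot SMILES token matrices.

    A position-wise linear embedding of the one-hot rows feeds parallel
    1D convolutions with different kernel widths; each branch is globally
    max-pooled and the branches concatenated, optionally followed by
    dense layers.
    """

    def __init__(self, spec, input_shape, rng) -> None:
        super().__init__(spec)
        if len(input_shape) != 2:
            raise ValueError(
                f"textcnn encoder expects (max_len, vocab) input, got {input_shape}"
            )
        max_len, vocab = input_shape
        self.kernels = spec.kernel_sizes or [3, 4, 5]
        filters = spec.n_filters or 32
        embed = spec.embed_dim or 32
        self.embed = self._dense_param(rng, vocab, embed)
        self.convs = []
        for k in self.kernels:
            if max_len - k + 1 < 1:
                raise ValueError(f"kernel {k} exceeds max_len {max_len}")
            self.convs.append(self._dense_param(rng, k * embed, filters))
        width = filters * len(self.kernels)
        self.fc = []
        for size in spec.layer_sizes:
            self.fc.append(self._dense_param(rng, width, size))
            width = size
        self.output_dim = width

    def __call__(self, x, train: bool = False, rng=None) -> Tensor:
        t = Tensor(np.asarray(x))
        we, be = self.embed
        emb = t @ we + be
        branches = []
        for k, (w, b) in zip(self.kernels, self.convs):
            branches.append(self._act(unfold1d(emb, k) @ w + b).max(axis=1))
        t = concat(branches, axis=-1)
        for w, b in self.fc:
            t = _dropout(self._act(t @ w + b), self.spec.dropout_rate, rng, train)
        return t


def pack_graphs(graphs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pad a list of molecular graphs into batch arrays.

    Returns (node_features (B,A,F), adjacency (B,A,A), node_mask (B,A,1))
    with A the largest atom count in the batch.
    """
    max_atoms = max(g.n_atoms for g in graphs)
    feat_dim = graphs[0].feature_dim
    nodes = np.zeros((len(graphs), max_atoms, feat_dim))
    adj = np.zeros((len(graphs), max_atoms, max_atoms))
    mask = np.zeros((len(graphs), max_atoms, 1))
    for i, g in enumerate(graphs):
        n = g.n_atoms
        nodes[i, :n] = g.node_features
        adj[i, :n, :n] = g.adjacency
        mask[i, :n, 0] = 1.0
    return nodes, adj, mask


def _normalized_adjacency(adj: np.ndarray) -> np.ndarray:
    """Symmetric renormalization D^{-1/2} (A + I) D^{-1/2} per graph."""
    a_hat = adj + np.eye(adj.shape[-1])[None, :, :]
    deg = a_hat.sum(axis=-1)
    inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    return a_hat * inv_sqrt[:, :, None] * inv_sqrt[:, None, :]


class GCNEncoder(_Base):
    """Graph convolution layers with symmetric adjacency renormalization and
    masked mean readout over atoms."""

    def __init__(self, spec, input_shape, rng) -> None:
        super().__init__(spec)
        if len(input_shape) != 1:
            raise ValueError("gcn encoder expects a (feature_dim,) node-feature shape")
        n_in = input_shape[0]
        self.layers = []
        for size in spec.layer_sizes:
            self.layers.append(self._dense_param(rng, n_in, size))
            n_in = size
        self.output_dim = n_in

    def __call__(self, x, train: bool = False, rng=None) -> Tensor:
        nodes, adj, mask = x
        a_norm = Tensor(_normalized_adjacency(np.asarray(adj)))
        mask_t = Tensor(np.asarray(mask))
        t = Tensor(np.asarray(nodes))
        for w, b in self.layers:
            t = _dropout(self._act(a_norm @ (t @ w) + b), self.spec.dropout_rate, rng, train)
        counts = np.asarray(mask).sum(axis=1)  # (B, 1)
        pooled = (t * mask_t).sum(axis=1) * Tensor(1.0 / np.maximum(counts, 1.0))
        return pooled


class GATEncoder(_Base):
    """Graph attention layers (multi-head, concatenated) with masked mean
    readout; attention restricted to bonded neighbors plus self-loops."""

    def __init__(self, spec, input_shape, rng) -> None:
        super().__init__(spec)
        if len(input_shape) != 1:
            raise ValueError("gat encoder expects a (feature_dim,) node-feature shape")
        n_in = input_shape[0]
        self.heads = spec.attention_heads or 2
        self.layers = []
        for size in spec.layer_sizes:
            head_params = []
            for _ in range(self.heads):
                w = Tensor(_glorot(rng, n_in, size), requires_grad=True)
                a_src = Tensor(_glorot(rng, size, 1), requires_grad=True)
                a_dst = Tensor(_glorot(rng, size, 1), requires_grad=True)
                self.weights.extend([w, a_src, a_dst])
                head_params.append((w, a_src, a_dst))
            self.layers.append(head_params)
            n_in = size * self.heads
        self.output_dim = n_in

    def __call__(self, x, train: bool = False, rng=None) -> Tensor:
        nodes, adj, mask = x
        adj = np.asarray(adj)
        eye = np.eye(adj.shape[-1])[None, :, :]
        neighbor_mask = np.clip(adj + eye, 0.0, 1.0)
        penalty = Tensor((1.0 - neighbor_mask) * -1e9)
        mask_np = np.asarray(mask)
        mask_t = Tensor(mask_np)
        t = Tensor(np.asarray(nodes))
        for head_params in self.layers:
            heads_out = []
            for w, a_src, a_dst in head_params:
                wh = t @ w  # (B, A, F')
                src = wh @ a_src  # (B, A, 1)
                dst = wh @ a_dst
                logits = (src + dst.swap_last2()).leaky_relu(0.2) + penalty
                attn = logits.softmax(axis=-1)
                heads_out.append(self._act(attn @ wh))
            t = concat(heads_out, axis=-1) if len(heads_out) > 1 else heads_out[0]
            t = _dropout(t, self.spec.dropout_rate, rng, train)
        counts = mask_np.sum(axis=1)
        pooled = (t * mask_t).sum(axis=1) * Tensor(1.0 / np.maximum(counts, 1.0))
        return pooled


_FAMILIES = {
    "dense": DenseEncoder,
    "conv1d": Conv1DEncoder,
    "conv2d": Conv2DEncoder,
    "textcnn": TextCNNEncoder,
    "gcn": GCNEncoder,
    "gat": GATEncoder,
}


def build_encoder(spec, input_shape, rng):
    try:
        cls = _FAMILIES[spec.family]
    except KeyError:
        raise ValueError(
            f"unknown encoder family {spec.family!r}; choose from {sorted(_FAMILIES)}"
        ) from None
    return cls(spec, tuple(input_shape), rng)
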