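"""GIN molecular encoder with cross-layer aggregation and additive readout.

Each layer updates node i as

    x_i^{l+1} = MLP( (1 + eps) * x_i^l + sum_{j in N_i} x_j^l )

followed by batch normalization and ReLU.  Node features are first
projected from the fixed atom-feature width to ``hidden_dim``; the L layer
outputs are then combined per node by a learnable length-L kernel (one
scalar weight per layer, shared across channels), so local and global
neighbourhood information both reach the final node matrix.  The graph
embedding h(G) is the column-wise sum over nodes (global add pooling),
which makes subgraph embeddings under soft partitions exactly additive.

Batch normalization uses batch statistics in training mode and frozen
running statistics at inference, so single-graph inference never depends
on batch composition.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from ._autograd import Adam, Parameter, Tensor, stack  # noqa: F401 (Adam re-export)
from .mol_io import ATOM_FEATURE_DIM, ATOM_SYMBOLS, MolecularGraph

__all__ = ["EncoderParams", "gin_layer", "encode_graph_nodes", "encode_graph_batch",
           "graph_readout", "feature_layout_hash", "save_checkpoint", "load_checkpoint"]


def feature_layout_hash() -> str:
    """Hash of the frozen atom-feature layout; stored in checkpoints so an
    encoder is never restored onto an incompatible featurizer."""
    desc = f"symbols={','.join(ATOM_SYMBOLS)};degree=0-10;numH=0-10;valence=0-10;aromatic;dim={ATOM_FEATURE_DIM}"
    return hashlib.sha256(desc.encode()).hexdigest()[:16]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class GinMLP:
    """Two-stage affine-ReLU-affine network used inside each GIN layer."""

    def __init__(self, rng: np.random.Generator, dim: int):
        self.W1 = Parameter(_glorot(rng, dim, dim))
        self.b1 = Parameter(np.zeros(dim))
        self.W2 = Parameter(_glorot(rng, dim, dim))
        self.b2 = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return (x @ self.W1 + self.b1).relu() @ self.W2 + self.b2

    def parameters(self):
        return [self.W1, self.b1, self.W2, self.b2]


class BatchNorm:
    """1-D batch normalization over the node axis."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0)
            var = ((x - mu) ** 2).mean(axis=0)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data)
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            xhat = ((x - Tensor(self.running_mean))
                    / Tensor(np.sqrt(self.running_var + self.eps)))
        return xhat * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


class EncoderParams:
    """All weights of the molecular encoder.

    Parameters
    ----------
    hidden_dim : representation width of every layer (default 128).
    n_layers : number of GIN layers L (default 4).
    eps : initial value of the per-layer epsilon in the GIN update.
    learnable_eps : when True each layer's epsilon becomes a trainable scalar.
    """

    def __init__(self, hidden_dim: int = 128, n_layers: int = 4,
                 eps: float = 0.0, learnable_eps: bool = False, seed: int = 0,
                 atom_dim: int = ATOM_FEATURE_DIM):
        if n_layers < 1:
            raise ValueError("need at least one GIN layer")
        rng = np.random.default_rng(seed)
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.atom_dim = atom_dim
        self.learnable_eps = learnable_eps
        self.proj_W = Parameter(_glorot(rng, atom_dim, hidden_dim))
        self.proj_b = Parameter(np.zeros(hidden_dim))
        self.eps = [Parameter(np.array(eps)) if learnable_eps else float(eps)
                    for _ in range(n_layers)]
        self.mlps = [GinMLP(rng, hidden_dim) for _ in range(n_layers)]
        self.norms = [BatchNorm(hidden_dim) for _ in range(n_layers)]
        # cross-layer aggregation kernel, one scalar per layer, mean at init
        self.layer_agg_kernel = Parameter(np.full(n_layers, 1.0 / n_layers))

    def parameters(self) -> list[Parameter]:
        out = [self.proj_W, self.proj_b, self.layer_agg_kernel]
        if self.learnable_eps:
            out.extend(self.eps)
        for mlp, norm in zip(self.mlps, self.norms):
            out.extend(mlp.parameters())
            out.extend(norm.parameters())
        return out

    # ---- serialization -------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {"proj_W": self.proj_W.data, "proj_b": self.proj_b.data,
                 "layer_agg_kernel": self.layer_agg_kernel.data}
        for l in range(self.n_layers):
            state[f"eps_{l}"] = np.asarray(
                self.eps[l].data if self.learnable_eps else self.eps[l])
            mlp, norm = self.mlps[l], self.norms[l]
            state.update({f"mlp{l}_W1": mlp.W1.data, f"mlp{l}_b1": mlp.b1.data,
                          f"mlp{l}_W2": mlp.W2.data, f"mlp{l}_b2": mlp.b2.data,
                          f"bn{l}_gamma": norm.gamma.data, f"bn{l}_beta": norm.beta.data,
                          f"bn{l}_mean": norm.running_mean, f"bn{l}_var": norm.running_var})
        return state

    def load_state_arrays(self, state: dict) -> None:
        self.proj_W.data = np.array(state["proj_W"])
        self.proj_b.data = np.array(state["proj_b"])
        self.layer_agg_kernel.data = np.array(state["layer_agg_kernel"])
        for l in range(self.n_layers):
            if self.learnable_eps:
                self.eps[l].data = np.array(state[f"eps_{l}"])
            else:
                self.eps[l] = float(state[f"eps_{l}"])
            mlp, norm = self.mlps[l], self.norms[l]
            mlp.W1.data = np.array(state[f"mlp{l}_W1"])
            mlp.b1.data = np.array(state[f"mlp{l}_b1"])
            mlp.W2.data = np.array(state[f"mlp{l}_W2"])
            mlp.b2.data = np.array(state[f"mlp{l}_b2"])
            norm.gamma.data = np.array(state[f"bn{l}_gamma"])
            norm.beta.data = np.array(state[f"bn{l}_beta"])
            norm.running_mean = np.array(state[f"bn{l}_mean"])
            norm.running_var = np.array(state[f"bn{l}_var"])

    def config(self) -> dict:
        return {"hidden_dim": self.hidden_dim, "n_layers": self.n_layers,
                "learnable_eps": self.learnable_eps, "atom_dim": self.atom_dim,
                "feature_layout_hash": feature_layout_hash()}


def _adjacency(n: int, edges) -> np.ndarray:
    adj = np.zeros((n, n))
    for i, j in edges:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"edge ({i},{j}) out of range for {n} nodes")
        adj[i, j] = 1.0
    return adj


def gin_layer(node_reprs: Tensor, edges, eps, mlp) -> Tensor:
    """One GIN update: MLP((1+eps) * x_i + sum of neighbour rows).

    ``mlp`` is any callable Tensor -> Tensor; ``eps`` a float or scalar
    Parameter.  Normalization/activation are applied by the encoder
    pipeline, not here.
    """
    node_reprs = node_reprs if isinstance(node_reprs, Tensor) else Tensor(node_reprs)
    n = node_reprs.shape[0]
    adj = Tensor(_adjacency(n, edges))
    eps_t = eps if isinstance(eps, Tensor) else float(eps)
    combined = node_reprs * (1.0 + eps_t) + adj @ node_reprs
    return mlp(combined)


def _encode_nodes(feats: Tensor, adj: np.ndarray, params: EncoderParams,
                  training: bool) -> Tensor:
    """Shared core: projection, L GIN+BN+ReLU layers, cross-layer kernel."""
    x = feats @ params.proj_W + params.proj_b
    adj_t = Tensor(adj)
    layer_stack = []
    for l in range(params.n_layers):
        eps = params.eps[l]
        eps_t = eps if isinstance(eps, Tensor) else float(eps)
        x = params.mlps[l](x * (1.0 + eps_t) + adj_t @ x)
        x = params.norms[l](x, training).relu()
        layer_stack.append(x)
    stacked = stack(layer_stack, axis=0)            # (L, n, hidden)
    kernel = params.layer_agg_kernel.reshape(-1, 1, 1)
    return (stacked * kernel).sum(axis=0)           # (n, hidden)


def encode_graph_nodes(graph: MolecularGraph, params: EncoderParams,
                       training: bool = False) -> Tensor:
    """Node matrix X^G for one molecule (n_atoms x hidden_dim)."""
    if graph.n_atoms == 0:
        raise ValueError(f"empty graph for SMILES {graph.smiles!r}")
    feats = Tensor(graph.node_features)
    adj = _adjacency(graph.n_atoms, graph.edges)
    return _encode_nodes(feats, adj, params, training)


def encode_graph_batch(graphs: list[MolecularGraph], params: EncoderParams,
                       training: bool = False) -> tuple[Tensor, np.ndarray]:
    """Encode a batch as one disjoint-union graph.

    Returns the concatenated node matrix (sum n_i, hidden) and the pooling
    indicator matrix (B, sum n_i) whose product with the node matrix gives
    per-graph readouts.  Batch normalization statistics span the batch.
    """
    if not graphs:
        raise ValueError("empty batch")
    sizes = [g.n_atoms for g in graphs]
    if any(s == 0 for s in sizes):
        raise ValueError("batch contains an empty graph")
    total = sum(sizes)
    feats = np.concatenate([g.node_features for g in graphs], axis=0)
    adj = np.zeros((total, total))
    pool = np.zeros((len(graphs), total))
    offset = 0
    for b, g in enumerate(graphs):
        for i, j in g.edges:
            adj[offset + i, offset + j] = 1.0
        pool[b, offset:offset + g.n_atoms] = 1.0
        offset += g.n_atoms
    nodes = _encode_nodes(Tensor(feats), adj, params, training)
    return nodes, pool


def graph_readout(node_matrix) -> Tensor:
    """Global add pooling: column-wise sum over nodes."""
    node_matrix = node_matrix if isinstance(node_matrix, Tensor) else Tensor(node_matrix)
    if node_matrix.shape[0] == 0:
        raise ValueError("cannot read out an empty node matrix")
    return node_matrix.sum(axis=0)


# --------------------------------------------------------------------------
# checkpointing: .npz archive + JSON sidecar describing the architecture
# --------------------------------------------------------------------------

def save_checkpoint(path, arrays: dict[str, np.ndarray], meta: dict) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = dict(meta)
    meta.setdefault("feature_layout_hash", feature_layout_hash())
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> tuple[dict, dict]:
    """Returns (arrays, meta); rejects checkpoints from another featurizer."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    stored = meta.get("feature_layout_hash")
    if stored is not None and stored != feature_layout_hash():
        raise ValueError("checkpoint was written with an incompatible "
                         "atom-feature layout")
    with np.load(path.with_suffix(".npz")) as npz:
        arrays = {k: npz[k] for k in npz.files}
    return arrays, meta
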