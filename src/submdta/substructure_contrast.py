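"""Soft subgraph extraction and contrastive pre-training of the molecular encoder.

Subgraphs are obtained by recursive two-way soft splits: a learnable
projection of the node matrix followed by a row-wise softmax gives each
node a probability of belonging to either branch, and after T rounds each
node carries S = 2^T soft membership masks that sum to one.  Because the
readout is additive, the S mask-weighted subgraph embeddings sum exactly
to the full-graph embedding.

Two Jensen-Shannon mutual-information terms are maximized:

* subgraph level — each graph embedding h(G) with its own subgraph
  embeddings h(G_i) as positives, and the subgraphs of the other graphs in
  the batch as negatives;
* graph level — h(G) with the reconstructed embedding h(G_hat), built by
  replacing the ceil(S/2) most cross-batch-similar subgraph slots with
  their best-matching foreign subgraph embedding and aggregating the slots
  with a learnable length-S kernel.

Both levels are scored by separate bilinear discriminators and combined
with the JSD estimator

    I = E_pos[-sp(-T(x, y))] - E_neg[sp(T(x, y'))],   sp(x) = log(1 + e^x)

which is maximized; the training loop minimizes its negation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._autograd import Adam, Parameter, Tensor, concatenate, softmax, stack
from .graph_encoder import (EncoderParams, encode_graph_batch, graph_readout,
                            load_checkpoint, save_checkpoint)
from .mol_io import MolecularGraph, smiles_to_graph

logger = logging.getLogger(__name__)

__all__ = [
    "AssignmentMatrix", "SoftPartition", "ReconstructedEmbedding",
    "PretrainBatchResult", "PretrainConfig", "PretrainModel",
    "compute_assignment", "split_soft", "subgraph_readout", "cosine_similarity",
    "reconstruct_batch", "discriminator_score", "jsd_mi", "pretrain_step",
    "pretrain", "discriminator_ranking_accuracy",
]


@dataclass
class AssignmentMatrix:
    """Row-stochastic node-to-branch probabilities from one split."""

    A: Tensor  # (n_nodes, 2)
    W: Tensor  # projection that produced it


@dataclass
class SoftPartition:
    """S = 2^T soft node masks; per node the masks sum to one."""

    T: int
    masks: list  # S Tensors of shape (n_nodes,)

    @property
    def S(self) -> int:
        return len(self.masks)


@dataclass
class ReconstructedEmbedding:
    """h(G_hat) for one graph plus the bookkeeping of the substitution."""

    embedding: Tensor
    replaced_indices: tuple
    donor_ids: tuple  # (batch index, slot) of each donor


@dataclass
class PretrainBatchResult:
    """Losses of one pre-training step (MI terms are <= 0 by construction)."""

    mi_subgraph: float | None
    mi_reconstructed: float | None
    loss: float
    pos_scores: np.ndarray = field(repr=False, default=None)
    neg_scores: np.ndarray = field(repr=False, default=None)


# --------------------------------------------------------------------------
# partition primitives
# --------------------------------------------------------------------------

def compute_assignment(node_matrix, W) -> AssignmentMatrix:
    """Row-wise softmax of node_matrix @ W; each row sums to one."""
    node_matrix = node_matrix if isinstance(node_matrix, Tensor) else Tensor(node_matrix)
    W = W if isinstance(W, Tensor) else Tensor(W)
    if node_matrix.shape[1] != W.shape[0]:
        raise ValueError(f"width mismatch: nodes {node_matrix.shape} vs W {W.shape}")
    return AssignmentMatrix(A=softmax(node_matrix @ W, axis=1), W=W)


def split_soft(node_matrix, T: int, Ws, hard: bool = False) -> SoftPartition:
    """Recursive two-way soft split into S = 2^T masks.

    ``Ws`` supplies one projection per active branch per round, flattened
    round-major: round t consumes 2^t projections.  With ``hard=True`` the
    branch probabilities are thresholded at 0.5 (inspection only; not
    differentiable).
    """
    if T < 0:
        raise ValueError("number of split rounds must be non-negative")
    node_matrix = node_matrix if isinstance(node_matrix, Tensor) else Tensor(node_matrix)
    needed = 2 ** T - 1
    if len(Ws) < needed:
        raise ValueError(f"T={T} needs {needed} projections, got {len(Ws)}")
    n = node_matrix.shape[0]
    masks = [Tensor(np.ones(n))]
    w_idx = 0
    for _ in range(T):
        nxt = []
        for mask in masks:
            A = compute_assignment(node_matrix, Ws[w_idx]).A
            w_idx += 1
            if hard:
                left = Tensor((A.data[:, 0] >= 0.5).astype(float))
                right = Tensor((A.data[:, 0] < 0.5).astype(float))
            else:
                left, right = A[:, 0], A[:, 1]
            nxt.append(mask * left)
            nxt.append(mask * right)
        masks = nxt
    return SoftPartition(T=T, masks=masks)


def subgraph_readout(node_matrix, mask) -> Tensor:
    """Additive readout of mask-weighted node rows."""
    node_matrix = node_matrix if isinstance(node_matrix, Tensor) else Tensor(node_matrix)
    mask = mask if isinstance(mask, Tensor) else Tensor(mask)
    if mask.shape[0] != node_matrix.shape[0]:
        raise ValueError("mask length must equal node count")
    return (node_matrix * mask.reshape(-1, 1)).sum(axis=0)


def cosine_similarity(u, v) -> float:
    """u . v / (||u|| ||v||) on plain vectors."""
    u = np.asarray(u.data if isinstance(u, Tensor) else u, dtype=float)
    v = np.asarray(v.data if isinstance(v, Tensor) else v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(u @ v / (nu * nv))


# --------------------------------------------------------------------------
# reconstruction and scoring
# --------------------------------------------------------------------------

def reconstruct_batch(batch_subgraphs: list, recon_kernel) -> list[ReconstructedEmbedding]:
    """Similarity-based substitution of ceil(S/2) subgraph slots per graph.

    ``batch_subgraphs[g]`` is the list of S subgraph embedding Tensors of
    graph g.  For every slot the maximum cosine similarity against all
    slots of *other* graphs is found; the ceil(S/2) slots with the highest
    cross-batch similarity are replaced by their best-matching foreign
    embedding, and the S slots are combined by the length-S kernel.
    """
    B = len(batch_subgraphs)
    if B < 2:
        raise ValueError("reconstruction needs a batch of at least two graphs")
    S = len(batch_subgraphs[0])
    recon_kernel = (recon_kernel if isinstance(recon_kernel, Tensor)
                    else Tensor(recon_kernel))
    # flat (B*S, h) matrix of detached values for donor search
    flat = np.stack([batch_subgraphs[g][s].data
                     for g in range(B) for s in range(S)])
    norms = np.linalg.norm(flat, axis=1)
    norms[norms == 0] = 1.0
    unit = flat / norms[:, None]
    sim = unit @ unit.T
    owner = np.repeat(np.arange(B), S)
    sim[owner[:, None] == owner[None, :]] = -np.inf  # donors never self
    best_donor = np.argmax(sim, axis=1)
    best_sim = sim[np.arange(B * S), best_donor]
    n_replace = math.ceil(S / 2)
    out = []
    for g in range(B):
        rows = np.arange(g * S, (g + 1) * S)
        order = np.argsort(-best_sim[rows], kind="stable")
        replaced = tuple(sorted(int(i) for i in order[:n_replace]))
        donors = {}
        slots = []
        for s in range(S):
            if s in replaced:
                flat_idx = int(best_donor[rows[s]])
                dg, ds = divmod(flat_idx, S)
                donors[s] = (dg, ds)
                slots.append(batch_subgraphs[dg][ds])
            else:
                slots.append(batch_subgraphs[g][s])
        weighted = [recon_kernel[s] * slots[s] for s in range(S)]
        emb = weighted[0]
        for w in weighted[1:]:
            emb = emb + w
        out.append(ReconstructedEmbedding(
            embedding=emb, replaced_indices=replaced,
            donor_ids=tuple(donors[s] for s in replaced)))
    return out


def discriminator_score(global_emb, candidate_emb, omega) -> Tensor:
    """Bilinear form global^T . Omega . candidate (scalar Tensor)."""
    g = global_emb if isinstance(global_emb, Tensor) else Tensor(global_emb)
    c = candidate_emb if isinstance(candidate_emb, Tensor) else Tensor(candidate_emb)
    omega = omega if isinstance(omega, Tensor) else Tensor(omega)
    if g.shape[0] != omega.shape[0] or c.shape[0] != omega.shape[1]:
        raise ValueError("embedding width does not match discriminator")
    return (g.reshape(1, -1) @ omega @ c.reshape(-1, 1)).reshape(())


def jsd_mi(pos_scores, neg_scores) -> Tensor:
    """Jensen-Shannon MI estimate from positive- and negative-pair scores.

    mean over positives of -sp(-t) minus mean over negatives of sp(t);
    always <= 0, approaching 0 only as positives diverge to +inf and
    negatives to -inf.
    """
    pos = _scores_tensor(pos_scores, "positive")
    neg = _scores_tensor(neg_scores, "negative")
    return -((-pos).softplus().mean()) - neg.softplus().mean()


def _scores_tensor(scores, name: str) -> Tensor:
    if isinstance(scores, Tensor):
        t = scores if scores.ndim == 1 else scores.reshape(-1)
    elif len(scores) and isinstance(scores[0], Tensor):
        t = stack([s.reshape(()) for s in scores], axis=0)
    else:
        t = Tensor(np.asarray(scores, dtype=float))
    if t.data.size == 0:
        raise ValueError(f"empty {name}-score list")
    return t


# --------------------------------------------------------------------------
# pre-training model and loop
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PretrainConfig:
    """Conditions of one pre-training run."""

    hidden_dim: int = 128
    n_layers: int = 4
    T: int = 1                 # split rounds, S = 2^T subgraphs
    batch_size: int = 32
    lr: float = 1e-3
    epochs: int = 20
    loss_subgraph: bool = True
    loss_graph: bool = True
    learnable_eps: bool = False
    seed: int = 0


class PretrainModel:
    """Encoder + split projections + discriminators + reconstruction kernel."""

    def __init__(self, config: PretrainConfig):
        if not (config.loss_subgraph or config.loss_graph):
            raise ValueError("at least one loss component must be enabled")
        self.config = config
        rng = np.random.default_rng(config.seed)
        h = config.hidden_dim
        self.encoder = EncoderParams(hidden_dim=h, n_layers=config.n_layers,
                                     learnable_eps=config.learnable_eps,
                                     seed=config.seed)
        self.S = 2 ** config.T
        scale = 1.0 / np.sqrt(h)
        self.split_Ws = [Parameter(rng.normal(0, scale, size=(h, 2)))
                         for _ in range(2 ** config.T - 1)]
        self.disc_subgraph = Parameter(rng.normal(0, scale, size=(h, h)))
        self.disc_graph = Parameter(rng.normal(0, scale, size=(h, h)))
        self.recon_kernel = Parameter(np.full(self.S, 1.0))

    def parameters(self) -> list[Parameter]:
        return (self.encoder.parameters() + self.split_Ws
                + [self.disc_subgraph, self.disc_graph, self.recon_kernel])

    # ---- persistence ---------------------------------------------------
    def state_arrays(self) -> dict:
        state = {f"enc_{k}": v for k, v in self.encoder.state_arrays().items()}
        for i, W in enumerate(self.split_Ws):
            state[f"split_W{i}"] = W.data
        state["disc_subgraph"] = self.disc_subgraph.data
        state["disc_graph"] = self.disc_graph.data
        state["recon_kernel"] = self.recon_kernel.data
        return state

    def load_state_arrays(self, state: dict) -> None:
        self.encoder.load_state_arrays(
            {k[4:]: v for k, v in state.items() if k.startswith("enc_")})
        for i, W in enumerate(self.split_Ws):
            W.data = np.array(state[f"split_W{i}"])
        self.disc_subgraph.data = np.array(state["disc_subgraph"])
        self.disc_graph.data = np.array(state["disc_graph"])
        self.recon_kernel.data = np.array(state["recon_kernel"])

    def save(self, path) -> None:
        meta = {"kind": "pretrain", **self.encoder.config(),
                "T": self.config.T, "batch_size": self.config.batch_size,
                "lr": self.config.lr, "epochs": self.config.epochs,
                "loss_subgraph": self.config.loss_subgraph,
                "loss_graph": self.config.loss_graph,
                "seed": self.config.seed}
        save_checkpoint(path, self.state_arrays(), meta)

    @classmethod
    def load(cls, path) -> "PretrainModel":
        arrays, meta = load_checkpoint(path)
        config = PretrainConfig(
            hidden_dim=meta["hidden_dim"], n_layers=meta["n_layers"],
            T=meta["T"], batch_size=meta.get("batch_size", 32),
            lr=meta.get("lr", 1e-3), epochs=meta.get("epochs", 20),
            loss_subgraph=meta.get("loss_subgraph", True),
            loss_graph=meta.get("loss_graph", True),
            learnable_eps=meta.get("learnable_eps", False),
            seed=meta.get("seed", 0))
        model = cls(config)
        model.load_state_arrays(arrays)
        return model


def _encode_with_partitions(graphs, model: PretrainModel, training: bool):
    """Shared forward: h(G) (B,h) and per-slot subgraph embeddings (B,h) each."""
    nodes, pool = encode_graph_batch(graphs, model.encoder, training=training)
    pool_t = Tensor(pool)
    hg = pool_t @ nodes                                    # (B, h)
    partition = split_soft(nodes, model.config.T, model.split_Ws)
    slot_embs = [pool_t @ (nodes * m.reshape(-1, 1)) for m in partition.masks]
    return hg, slot_embs, partition


def _diag_offdiag(score_matrix: Tensor):
    B = score_matrix.shape[0]
    idx = np.arange(B)
    pos = score_matrix[idx, idx]
    rows, cols = np.where(~np.eye(B, dtype=bool))
    neg = score_matrix[rows, cols]
    return pos, neg


def pretrain_step(batch, model: PretrainModel, optimizer: Adam,
                  loss_subgraph: bool | None = None,
                  loss_graph: bool | None = None) -> PretrainBatchResult:
    """One optimization step on a batch of SMILES strings or parsed graphs."""
    loss_subgraph = model.config.loss_subgraph if loss_subgraph is None else loss_subgraph
    loss_graph = model.config.loss_graph if loss_graph is None else loss_graph
    if not (loss_subgraph or loss_graph):
        raise ValueError("at least one loss component must be enabled")
    graphs = [g if isinstance(g, MolecularGraph) else smiles_to_graph(g)
              for g in batch]
    if len(graphs) < 2:
        raise ValueError("pre-training needs batches of at least two graphs")

    hg, slot_embs, _ = _encode_with_partitions(graphs, model, training=True)
    B, S = len(graphs), model.S

    terms = []
    mi_sub_val = mi_graph_val = None
    pos_all, neg_all = [], []
    if loss_subgraph:
        pos_list, neg_list = [], []
        projected = hg @ model.disc_subgraph                # (B, h)
        for hs in slot_embs:
            scores = projected @ hs.T                       # (B, B): (G_i, sub of G_j)
            p, n = _diag_offdiag(scores)
            pos_list.append(p)
            neg_list.append(n)
        mi_sub = jsd_mi(concatenate(pos_list), concatenate(neg_list))
        terms.append(mi_sub)
        mi_sub_val = mi_sub.item()
        pos_all.append(np.concatenate([p.data for p in pos_list]))
        neg_all.append(np.concatenate([n.data for n in neg_list]))
    if loss_graph:
        per_graph = [[hs[g] for hs in slot_embs] for g in range(B)]
        recon = reconstruct_batch(per_graph, model.recon_kernel)
        h_hat = stack([r.embedding for r in recon], axis=0)  # (B, h)
        scores = (hg @ model.disc_graph) @ h_hat.T
        p, n = _diag_offdiag(scores)
        mi_graph = jsd_mi(p, n)
        terms.append(mi_graph)
        mi_graph_val = mi_graph.item()
        pos_all.append(p.data)
        neg_all.append(n.data)

    total_mi = terms[0] if len(terms) == 1 else terms[0] + terms[1]
    loss = -total_mi
    optimizer.zero_grad()
    loss.backward()
    optimizer.step()
    return PretrainBatchResult(
        mi_subgraph=mi_sub_val, mi_reconstructed=mi_graph_val,
        loss=loss.item(),
        pos_scores=np.concatenate(pos_all), neg_scores=np.concatenate(neg_all))


def pretrain(smiles_list: list[str], config: PretrainConfig | None = None,
             model: PretrainModel | None = None):
    """Full pre-training loop.  Returns (model, per-epoch mean losses)."""
    config = config or PretrainConfig()
    model = model or PretrainModel(config)
    graphs = [smiles_to_graph(s) for s in smiles_list]
    if len(graphs) < 2:
        raise ValueError("pre-training needs at least two molecules")
    optimizer = Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(graphs))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            if len(idx) < 2:
                continue  # a singleton batch has no negatives
            result = pretrain_step([graphs[i] for i in idx], model, optimizer)
            losses.append(result.loss)
        history.append(float(np.mean(losses)))
        logger.info("pretrain epoch %d/%d mean loss %.4f",
                    epoch + 1, config.epochs, history[-1])
    return model, history


def discriminator_ranking_accuracy(model: PretrainModel,
                                   smiles_list: list[str]) -> float:
    """How well the subgraph discriminator ranks same-graph above
    cross-graph (graph, subgraph) pairs on held-out molecules.

    Returns the fraction of (positive, negative) score pairs ordered
    correctly, with ties counted half.
    """
    graphs = [smiles_to_graph(s) for s in smiles_list]
    hg, slot_embs, _ = _encode_with_partitions(graphs, model, training=False)
    projected = (hg @ model.disc_subgraph).data
    pos, neg = [], []
    for hs in slot_embs:
        scores = projected @ hs.data.T
        pos.append(np.diag(scores))
        neg.append(scores[~np.eye(len(graphs), dtype=bool)])
    pos = np.concatenate(pos)
    neg = np.concatenate(neg)
    greater = (pos[:, None] > neg[None, :]).mean()
    ties = (pos[:, None] == neg[None, :]).mean()
    return float(greater + 0.5 * ties)
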