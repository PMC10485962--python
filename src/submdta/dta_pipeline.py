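"""End-to-end affinity regression: head, training, evaluation, ranking.

The drug embedding (GIN encoder + additive readout) and the protein
embedding (multi-scale BiLSTM) are concatenated and passed through two
dense ReLU layers with dropout and a final linear unit to produce the
scalar affinity.  Training minimizes MSE with Adam; a pre-trained encoder
checkpoint may initialize the molecular branch, after which every
parameter remains trainable.  Evaluation reports MSE, concordance index
and r_m^2 through the metrics module.

The case-study utilities rank a drug library against one target by
predicted affinity (descending, ties broken by input order) and count how
many known binders land inside a given percentile of the library, with
round(100 * rank / N) to the nearest integer (half away from zero) as the
percentile convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from ._autograd import Adam, Parameter, Tensor, concatenate
from .graph_encoder import (EncoderParams, encode_graph_batch, load_checkpoint,
                            save_checkpoint)
from .metrics import MetricsReport, compute_report
from .mol_io import AffinityRecord, MolecularGraph, SmilesParseError, smiles_to_graph
from .protein_encoder import ProteinConfig, ProteinParams, encode_protein_batch
from .substructure_contrast import PretrainModel

logger = logging.getLogger(__name__)

__all__ = ["DtaConfig", "DtaModel", "PredictionSet", "predict_affinity",
           "fit", "evaluate_model", "rank_candidates", "percentile_counts",
           "split_records"]


@dataclass(frozen=True)
class DtaConfig:
    """Architecture and optimization settings of the affinity regressor."""

    hidden_dim: int = 128          # molecular embedding width
    n_layers: int = 4              # GIN layers
    embed_dim: int = 128           # protein n-gram embedding width
    protein_hidden: int = 64       # per-direction LSTM width H
    max_len: int = 1200
    head_dims: tuple = (1024, 512)
    dropout: float = 0.2
    lr: float = 5e-4
    batch_size: int = 128
    epochs: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["head_dims"] = list(self.head_dims)
        return d


class PredictionHead:
    """concat -> affine -> ReLU -> dropout -> affine -> ReLU -> dropout -> affine(1)."""

    def __init__(self, rng: np.random.Generator, in_dim: int, dims: tuple,
                 dropout: float):
        self.dropout = dropout
        widths = [in_dim, *dims, 1]
        self.layers = []
        for a, b in zip(widths[:-1], widths[1:]):
            limit = np.sqrt(6.0 / (a + b))
            self.layers.append((Parameter(rng.uniform(-limit, limit, (a, b))),
                                Parameter(np.zeros(b))))

    def __call__(self, x: Tensor, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        *hidden_layers, (W_out, b_out) = self.layers
        for W, b in hidden_layers:
            x = (x @ W + b).relu()
            if training and self.dropout > 0:
                keep = (rng.random(x.shape) >= self.dropout) / (1.0 - self.dropout)
                x = x * Tensor(keep)
        return x @ W_out + b_out

    def parameters(self):
        return [p for pair in self.layers for p in pair]

    def state_arrays(self) -> dict:
        state = {}
        for i, (W, b) in enumerate(self.layers):
            state[f"head_W{i}"] = W.data
            state[f"head_b{i}"] = b.data
        return state

    def load_state_arrays(self, state: dict) -> None:
        for i, (W, b) in enumerate(self.layers):
            W.data = np.array(state[f"head_W{i}"])
            b.data = np.array(state[f"head_b{i}"])


class DtaModel:
    """Full drug-target affinity regressor."""

    def __init__(self, config: DtaConfig | None = None):
        self.config = config or DtaConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.encoder = EncoderParams(hidden_dim=cfg.hidden_dim,
                                     n_layers=cfg.n_layers, seed=cfg.seed)
        self.protein = ProteinParams(
            ProteinConfig(embed_dim=cfg.embed_dim, hidden=cfg.protein_hidden,
                          max_len=cfg.max_len), seed=cfg.seed + 1)
        in_dim = cfg.hidden_dim + self.protein.output_dim
        self.head = PredictionHead(rng, in_dim, cfg.head_dims, cfg.dropout)

    def parameters(self):
        return (self.encoder.parameters() + self.protein.parameters()
                + self.head.parameters())

    def init_encoder_from(self, pretrained) -> None:
        """Copy encoder weights from a PretrainModel or a checkpoint path."""
        if isinstance(pretrained, (str, bytes)) or hasattr(pretrained, "__fspath__"):
            pretrained = PretrainModel.load(pretrained)
        src = pretrained.encoder
        if (src.hidden_dim != self.encoder.hidden_dim
                or src.n_layers != self.encoder.n_layers):
            raise ValueError(
                f"pre-trained encoder ({src.hidden_dim}d x {src.n_layers}L) does "
                f"not match model ({self.encoder.hidden_dim}d x {self.encoder.n_layers}L)")
        self.encoder.load_state_arrays(src.state_arrays())

    # ---- prediction ----------------------------------------------------
    def predict(self, records_or_pairs, batch_size: int | None = None) -> np.ndarray:
        """Deterministic inference over (smiles, sequence) pairs or records."""
        pairs = [(r.drug_smiles, r.target_sequence) if isinstance(r, AffinityRecord)
                 else tuple(r) for r in records_or_pairs]
        batch_size = batch_size or self.config.batch_size
        graph_cache: dict[str, MolecularGraph] = {}
        out = np.empty(len(pairs))
        for start in range(0, len(pairs), batch_size):
            chunk = pairs[start:start + batch_size]
            preds = _forward_batch(self, chunk, graph_cache, training=False)
            out[start:start + len(chunk)] = preds.data.ravel()
        return out

    # ---- persistence ---------------------------------------------------
    def state_arrays(self) -> dict:
        state = {f"enc_{k}": v for k, v in self.encoder.state_arrays().items()}
        state.update({f"prot_{k}": v for k, v in self.protein.state_arrays().items()})
        state.update(self.head.state_arrays())
        return state

    def save(self, path) -> None:
        save_checkpoint(path, self.state_arrays(),
                        {"kind": "dta", **self.config.to_dict()})

    @classmethod
    def load(cls, path) -> "DtaModel":
        arrays, meta = load_checkpoint(path)
        fields = set(DtaConfig.__dataclass_fields__)
        cfg = DtaConfig(**{k: (tuple(v) if k == "head_dims" else v)
                           for k, v in meta.items() if k in fields})
        model = cls(cfg)
        model.encoder.load_state_arrays(
            {k[4:]: v for k, v in arrays.items() if k.startswith("enc_")})
        model.protein.load_state_arrays(
            {k[5:]: v for k, v in arrays.items() if k.startswith("prot_")})
        model.head.load_state_arrays(arrays)
        return model


def predict_affinity(drug_emb, protein_emb, head: PredictionHead) -> float:
    """Scalar affinity from one drug/protein embedding pair (inference mode)."""
    drug_emb = drug_emb if isinstance(drug_emb, Tensor) else Tensor(drug_emb)
    protein_emb = protein_emb if isinstance(protein_emb, Tensor) else Tensor(protein_emb)
    x = concatenate([drug_emb.reshape(1, -1), protein_emb.reshape(1, -1)], axis=1)
    return float(head(x).data.ravel()[0])


def _forward_batch(model: DtaModel, pairs, graph_cache: dict,
                   training: bool, rng=None) -> Tensor:
    """Predictions (B, 1) for a list of (smiles, sequence) pairs.

    Unique drugs and unique proteins in the batch are each encoded once;
    gradients flow through the shared encodings to every pair that uses them.
    """
    smiles_list = [p[0] for p in pairs]
    seq_list = [p[1] for p in pairs]
    uniq_smiles = list(dict.fromkeys(smiles_list))
    uniq_seqs = list(dict.fromkeys(seq_list))
    for s in uniq_smiles:
        if s not in graph_cache:
            graph_cache[s] = smiles_to_graph(s)
    graphs = [graph_cache[s] for s in uniq_smiles]
    nodes, pool = encode_graph_batch(graphs, model.encoder, training=training)
    drug_embs = Tensor(pool) @ nodes                         # (U_d, h)
    prot_embs = encode_protein_batch(uniq_seqs, model.protein)  # (U_p, 3*2H)
    d_idx = np.array([uniq_smiles.index(s) for s in smiles_list])
    p_idx = np.array([uniq_seqs.index(q) for q in seq_list])
    x = concatenate([drug_embs[d_idx], prot_embs[p_idx]], axis=1)
    return model.head(x, training=training, rng=rng)


def fit(train: list[AffinityRecord], config: DtaConfig | None = None,
        pretrained=None, val: list[AffinityRecord] | None = None):
    """Train an affinity regressor by MSE; returns (model, history).

    ``history`` maps "train_mse" (per-epoch mean batch loss) and, when a
    validation set is given, "val_mse".  With ``pretrained`` the molecular
    encoder starts from the given checkpoint/model; all parameters stay
    trainable.
    """
    if not train:
        raise ValueError("empty training set")
    config = config or DtaConfig()
    model = DtaModel(config)
    if pretrained is not None:
        model.init_encoder_from(pretrained)
    optimizer = Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 2)
    y = np.array([r.affinity for r in train])
    # start the output at the label mean so early epochs fit structure, not scale
    model.head.layers[-1][1].data[:] = y.mean()
    pairs = [(r.drug_smiles, r.target_sequence) for r in train]
    graph_cache: dict[str, MolecularGraph] = {}
    history: dict[str, list] = {"train_mse": []}
    if val is not None:
        history["val_mse"] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(train))
        losses, sizes = [], []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            preds = _forward_batch(model, [pairs[i] for i in idx], graph_cache,
                                   training=True, rng=rng)
            target = Tensor(y[idx].reshape(-1, 1))
            loss = ((preds - target) ** 2).mean()
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
            sizes.append(len(idx))
        history["train_mse"].append(float(np.average(losses, weights=sizes)))
        msg = f"epoch {epoch + 1}/{config.epochs} train_mse {history['train_mse'][-1]:.4f}"
        if val is not None:
            val_pred = model.predict(val)
            val_mse = float(np.mean((val_pred - np.array([r.affinity for r in val])) ** 2))
            history["val_mse"].append(val_mse)
            msg += f" val_mse {val_mse:.4f}"
        logger.info(msg)
    return model, history


def evaluate_model(model: DtaModel, test: list[AffinityRecord]) -> MetricsReport:
    """MSE, CI and r_m^2 of the model on a held-out record list."""
    if not test:
        raise ValueError("empty test set")
    preds = model.predict(test)
    return compute_report([r.affinity for r in test], preds)


def split_records(records: list[AffinityRecord], test_fraction: float = 0.2,
                  seed: int = 0) -> tuple[list[AffinityRecord], list[AffinityRecord]]:
    """Seeded random train/test split over drug-target pairs."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_test = int(round(test_fraction * len(records)))
    test_idx = set(order[:n_test].tolist())
    train = [records[i] for i in range(len(records)) if i not in test_idx]
    test = [records[i] for i in sorted(test_idx)]
    return train, test


# --------------------------------------------------------------------------
# case-study ranking
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictionSet:
    """Ranked predictions of one target against a drug library."""

    records: tuple          # (drug_id, target_id, predicted affinity)
    ranks: tuple            # rank of each record, permutation of 1..N
    n_invalid: int = 0
    invalid_entries: tuple = field(default=())


def rank_candidates(model: DtaModel, target_seq: str, drugs: list[str],
                    target_id: str = "target") -> PredictionSet:
    """Rank a drug library against one target by predicted affinity.

    Sorted descending; ties broken by input order.  Unparseable SMILES are
    excluded, reported and counted.
    """
    valid, invalid = [], []
    for i, s in enumerate(drugs):
        try:
            smiles_to_graph(s)
            valid.append((i, s))
        except SmilesParseError:
            invalid.append((i, s))
    if not valid:
        raise ValueError("no parseable drug in the candidate list")
    if invalid:
        logger.warning("excluded %d unparseable drug entries", len(invalid))
    preds = model.predict([(s, target_seq) for _, s in valid])
    # descending affinity, stable in input order for ties
    order = np.lexsort((np.arange(len(valid)), -preds))
    ranks = np.empty(len(valid), dtype=int)
    ranks[order] = np.arange(1, len(valid) + 1)
    records = tuple((valid[i][1], target_id, float(preds[i]))
                    for i in range(len(valid)))
    return PredictionSet(records=records, ranks=tuple(int(r) for r in ranks),
                         n_invalid=len(invalid), invalid_entries=tuple(invalid))


def percentile_counts(ranks, total: int, cutoff_pct: int) -> int:
    """How many ranks fall within the top ``cutoff_pct`` percent of ``total``.

    A rank r is inside the cutoff when round(100 * r / total) <= cutoff_pct,
    rounding to the nearest integer (half away from zero).
    """
    count = 0
    for r in ranks:
        if not (1 <= r <= total):
            raise ValueError(f"rank {r} outside 1..{total}")
        if math.floor(100.0 * r / total + 0.5) <= cutoff_pct:
            count += 1
    return count
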