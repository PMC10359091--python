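"""Edge-aware graph transformer for bp-specific methylation prediction.

Per block and head, node i attends over its radius-one neighbors j with

    alpha_ij = <q_i, k_j + e_ij> / sum_{u in N(i)} <q_i, k_u + e_iu>,
    <q, k + e> = exp(q^T (k + e) / sqrt(d)),

where q/k/v are affine projections of the node states and e_ij an affine
projection of the edge state. Messages alpha_ij (v_j + e_ij) are summed
over neighbors, heads are concatenated (averaged in the final block),
then LayerNorm and ReLU give the next node state. Edge states are updated
by concatenating each head's attention coefficient with the block-input
edge feature, again followed by LayerNorm and ReLU. A final affine +
sigmoid head maps each node state to 1000 per-bp methylation levels;
training minimizes mean squared error over mask-valid positions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .autodiff import Adam, Tensor, concatenate
from .graphs import PromoterGraph

__all__ = [
    "ModelConfig",
    "ModelParams",
    "init_params",
    "forward",
    "forward_graph",
    "masked_loss",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults follow the selected architecture: 5 blocks, 1 attention head.
    ``carry_edge_state`` feeds each block the previous block's updated edge
    states; switching it off re-projects the raw edge features in every
    block instead. ``edge_transform`` ("log1p" or "none") compresses raw
    edge features (contact counts and bp distances) before projection.
    """

    node_in_dim: int
    edge_in_dim: int = 23
    out_dim: int = 1000
    n_blocks: int = 5
    n_heads: int = 1
    head_dim: int = 64
    learning_rate: float = 1e-3
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0
    carry_edge_state: bool = True
    edge_transform: str = "log1p"
    grad_clip: float = 5.0

    def node_dims(self) -> list[int]:
        """Node-state dimension entering each block (and the final output dim)."""
        dims = [self.node_in_dim]
        for o in range(self.n_blocks):
            last = o == self.n_blocks - 1
            dims.append(self.head_dim if last else self.n_heads * self.head_dim)
        return dims

    def edge_dims(self) -> list[int]:
        """Edge-state dimension entering each block."""
        dims = [self.edge_in_dim]
        for _ in range(self.n_blocks - 1):
            nxt = (
                self.n_heads * (1 + dims[-1])
                if self.carry_edge_state
                else self.edge_in_dim
            )
            dims.append(nxt)
        return dims


class ModelParams:
    """Trainable parameters: per-block per-head projections plus output head."""

    def __init__(self, blocks: list[dict[str, Tensor]], w_out: Tensor, b_out: Tensor):
        self.blocks = blocks
        self.w_out = w_out
        self.b_out = b_out

    def parameters(self) -> list[Tensor]:
        out = []
        for block in self.blocks:
            out.extend(block.values())
        out.extend([self.w_out, self.b_out])
        return out

    def copy_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        for p, a in zip(self.parameters(), arrays):
            p.data = a.copy()


def _xavier(rng, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


def init_params(config: ModelConfig, rng: Optional[np.random.Generator] = None) -> ModelParams:
    rng = rng or np.random.default_rng(config.seed)
    d, H = config.head_dim, config.n_heads
    node_dims, edge_dims = config.node_dims(), config.edge_dims()
    blocks = []
    for o in range(config.n_blocks):
        last = o == config.n_blocks - 1
        nd, ed = node_dims[o], edge_dims[o]
        block: dict[str, Tensor] = {}
        for h in range(H):
            for name, fan_in in (("q", nd), ("k", nd), ("v", nd), ("e", ed)):
                block[f"h{h}_W{name}"] = Tensor(_xavier(rng, fan_in, d))
                block[f"h{h}_b{name}"] = Tensor(np.zeros(d))
        node_out = d if last else H * d
        block["ln_node_g"] = Tensor(np.ones(node_out))
        block["ln_node_b"] = Tensor(np.zeros(node_out))
        if not last:
            edge_out = H * (1 + ed)
            block["ln_edge_g"] = Tensor(np.ones(edge_out))
            block["ln_edge_b"] = Tensor(np.zeros(edge_out))
        blocks.append(block)
    w_out = Tensor(_xavier(rng, node_dims[-1], config.out_dim))
    b_out = Tensor(np.zeros(config.out_dim))
    return ModelParams(blocks, w_out, b_out)


def _layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered / (var + eps).sqrt() * gamma + beta


def _transform_edges(raw: np.ndarray, mode: str) -> np.ndarray:
    if mode == "log1p":
        return np.log1p(raw)
    if mode == "none":
        return raw
    raise ValueError(f"unknown edge_transform {mode!r}")


def prepare_graph(graph: PromoterGraph, config: ModelConfig) -> dict:
    """Precompute the dense constant arrays the forward pass consumes."""
    X, E, A, Y, M = graph.to_dense(edge_dim=config.edge_in_dim)
    A = A.astype(float)
    iso = (A.sum(axis=1) == 0).astype(float)
    return {
        "X": X,
        "E": _transform_edges(E, config.edge_transform),
        "A": A,
        "iso": iso,
        "Y": Y,
        "M": M.astype(float),
        "cell_id": graph.cell_id,
        "chrom": graph.chrom,
    }


def forward(
    X: np.ndarray,
    E: np.ndarray,
    A: np.ndarray,
    params: ModelParams,
    config: ModelConfig,
    iso: Optional[np.ndarray] = None,
    return_internals: bool = False,
):
    """Run the transformer on dense graph arrays.

    X: (n, D) node features; E: (n, n, F) edge features (already
    transformed); A: (n, n) float adjacency mask. Returns a Tensor of
    per-node sigmoid predictions, plus per-block per-head attention
    matrices when ``return_internals``.

    Isolated nodes receive a zero aggregation term (their predictions flow
    from the LayerNorm/ReLU cascade and the output head's bias path).
    """
    n = X.shape[0]
    d, H = config.head_dim, config.n_heads
    if iso is None:
        iso = (A.sum(axis=1) == 0).astype(float)
    x = Tensor(X, requires_grad=False)
    e_state = Tensor(E, requires_grad=False)
    raw_state = e_state
    internals: list[list[np.ndarray]] = []
    sqrt_d = np.sqrt(d)

    for o, block in enumerate(params.blocks):
        last = o == len(params.blocks) - 1
        f_dim = e_state.shape[-1]
        head_msgs, head_alphas = [], []
        for h in range(H):
            q = x @ block[f"h{h}_Wq"] + block[f"h{h}_bq"]
            k = x @ block[f"h{h}_Wk"] + block[f"h{h}_bk"]
            v = x @ block[f"h{h}_Wv"] + block[f"h{h}_bv"]
            e = (
                e_state.reshape(n * n, f_dim) @ block[f"h{h}_We"] + block[f"h{h}_be"]
            ).reshape(n, n, d)
            scores = (q.reshape(n, 1, d) * (k.reshape(1, n, d) + e)).sum(axis=2) / sqrt_d
            # max-subtraction stabilizer: value-identical in exact arithmetic
            masked = np.where(A > 0, scores.data, -np.inf)
            row_max = np.max(masked, axis=1, keepdims=True)
            row_max = np.where(np.isfinite(row_max), row_max, 0.0)
            exps = (scores - row_max).exp() * A
            denom = exps.sum(axis=1, keepdims=True) + iso.reshape(n, 1)
            alpha = exps / denom
            msg = (alpha.reshape(n, n, 1) * (v.reshape(1, n, d) + e)).sum(axis=1)
            head_msgs.append(msg)
            head_alphas.append(alpha)
        if last:
            p_hat = head_msgs[0]
            for m in head_msgs[1:]:
                p_hat = p_hat + m
            p_hat = p_hat / float(H)
        else:
            p_hat = head_msgs[0] if H == 1 else concatenate(head_msgs, axis=1)
        x = _layer_norm(p_hat, block["ln_node_g"], block["ln_node_b"]).relu()
        if np.isnan(x.data).any():
            raise FloatingPointError(f"NaN in node representations at block {o}")
        if not last:
            base = e_state if config.carry_edge_state else raw_state
            pieces = []
            for alpha in head_alphas:
                pieces.append(alpha.reshape(n, n, 1))
                pieces.append(base)
            e_hat = concatenate(pieces, axis=2)
            e_state = _layer_norm(e_hat, block["ln_edge_g"], block["ln_edge_b"]).relu()
        if return_internals:
            internals.append([a.data for a in head_alphas])

    pred = (x @ params.w_out + params.b_out).sigmoid()
    if return_internals:
        return pred, internals
    return pred


def forward_graph(graph: PromoterGraph, params: ModelParams, config: ModelConfig):
    prep = prepare_graph(graph, config)
    return forward(prep["X"], prep["E"], prep["A"], params, config, iso=prep["iso"])


def predict(graph: PromoterGraph, params: ModelParams, config: ModelConfig) -> np.ndarray:
    """Per-node predicted methylation levels in (0, 1), as a plain array."""
    return forward_graph(graph, params, config).data


def masked_loss(pred: Tensor, targets: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean squared error over mask-true positions across all nodes."""
    m = np.asarray(mask, dtype=float)
    count = m.sum()
    if count == 0:
        raise ValueError("empty target mask: no position to score")
    diff = (pred - targets) * m
    return (diff * diff).sum() / count


def _clip_gradients(params: ModelParams, max_norm: float) -> None:
    total = 0.0
    for p in params.parameters():
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = np.sqrt(total)
    if norm > max_norm > 0:
        scale = max_norm / norm
        for p in params.parameters():
            if p.grad is not None:
                p.grad *= scale


@dataclass
class TrainingHistory:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = np.inf
    diverged: bool = False

    def to_table(self) -> str:
        lines = ["epoch\ttrain_loss\tval_loss"]
        for e, tr, va in zip(self.epochs, self.train_loss, self.val_loss):
            lines.append(f"{e}\t{tr:.6f}\t{va:.6f}")
        return "\n".join(lines) + "\n"


def _dataset_loss(prepared: list[dict], params: ModelParams, config: ModelConfig) -> float:
    """Pooled MSE: total squared error / total masked positions across graphs."""
    sse, count = 0.0, 0.0
    for prep in prepared:
        m = prep["M"]
        if m.sum() == 0:
            continue
        pred = forward(prep["X"], prep["E"], prep["A"], params, config, iso=prep["iso"])
        sse += float((((pred.data - prep["Y"]) * m) ** 2).sum())
        count += m.sum()
    return sse / count if count else np.nan


def train(
    train_graphs: Sequence[PromoterGraph],
    val_graphs: Sequence[PromoterGraph],
    config: ModelConfig,
    params: Optional[ModelParams] = None,
    verbose: bool = False,
) -> tuple[ModelParams, TrainingHistory]:
    """Gradient-based training with one graph per update step.

    The model with the best validation loss is returned; training stops
    early after ``patience`` epochs without improvement. Fully
    reproducible given ``config.seed``. On divergence (NaN loss) the last
    good checkpoint is returned with ``history.diverged`` set.
    """
    if not train_graphs or not val_graphs:
        raise ValueError("need at least one training and one validation graph")
    rng = np.random.default_rng(config.seed)
    params = params or init_params(config, rng)
    optimizer = Adam(params.parameters(), lr=config.learning_rate)
    prepared_train = [prepare_graph(g, config) for g in train_graphs]
    prepared_val = [prepare_graph(g, config) for g in val_graphs]
    prepared_train = [p for p in prepared_train if p["M"].sum() > 0]
    if not prepared_train:
        raise ValueError("no training graph has a non-empty target mask")

    history = TrainingHistory()
    best_arrays = params.copy_arrays()
    since_best = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(prepared_train))
        epoch_sse, epoch_count = 0.0, 0.0
        for idx in order:
            prep = prepared_train[idx]
            optimizer.zero_grad()
            try:
                pred = forward(prep["X"], prep["E"], prep["A"], params, config, iso=prep["iso"])
                loss = masked_loss(pred, prep["Y"], prep["M"])
            except FloatingPointError:
                history.diverged = True
                params.load_arrays(best_arrays)
                return params, history
            if np.isnan(loss.data):
                history.diverged = True
                params.load_arrays(best_arrays)
                return params, history
            loss.backward()
            _clip_gradients(params, config.grad_clip)
            optimizer.step()
            epoch_sse += loss.item() * prep["M"].sum()
            epoch_count += prep["M"].sum()
        val_loss = _dataset_loss(prepared_val, params, config)
        history.epochs.append(epoch)
        history.train_loss.append(epoch_sse / epoch_count)
        history.val_loss.append(val_loss)
        if verbose:
            print(f"epoch {epoch}: train {epoch_sse / epoch_count:.4f} val {val_loss:.4f}")
        if val_loss < history.best_val_loss - 1e-9:
            history.best_val_loss = val_loss
            history.best_epoch = epoch
            best_arrays = params.copy_arrays()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    params.load_arrays(best_arrays)
    return params, history


def save_checkpoint(path, params: ModelParams, config: ModelConfig) -> None:
    arrays = {f"p{i}": a for i, a in enumerate(params.copy_arrays())}
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[ModelParams, ModelConfig]:
    data = np.load(path)
    config = ModelConfig(**json.loads(bytes(data["config_json"]).decode()))
    params = init_params(config)
    n = len(params.parameters())
    params.load_arrays([data[f"p{i}"] for i in range(n)])
    return params, config
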