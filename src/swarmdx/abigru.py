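"""Attention bidirectional GRU classifier for tabular rows, in pure numpy.

A patient row is recast as a sequence — one feature per timestep, scalar
input — and consumed by two GRU cells, one reading left-to-right and one
right-to-left.  Per timestep the two hidden states are combined through
shared learned weights (h_t = W_f h_fwd + W_b h_bwd + b), attention pooling
collapses the combined states into one context vector via softmax-normalized
scores e_t = v . tanh(W h_t + b), and a small dense head (ReLU hidden layer,
softmax output) produces the two class probabilities.

The GRU cell follows the standard gating equations:

    r_t = sigmoid(W_r . [h_{t-1}, x_t])          (reset gate)
    z_t = sigmoid(W_z . [h_{t-1}, x_t])          (update gate)
    h~_t = tanh(W . [r_t * h_{t-1}, x_t])        (candidate state)
    h_t = (1 - z_t) * h_{t-1} + z_t * h~_t

Training is plain mini-batch gradient descent on the cross-entropy with
manually derived backpropagation-through-time; gradient correctness is
checked against central finite differences in the test suite.  Dropout (when
enabled) is applied to the combined hidden states during training only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .table import FeatureTable

__all__ = [
    "GRUCellParams",
    "BiGRUCombineParams",
    "AttentionParams",
    "ABiGRUModel",
    "TrainConfig",
    "gru_step",
    "bigru_forward",
    "attention_pool",
    "row_to_sequence",
    "loss_and_grads",
    "train",
    "predict",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    shifted = x - x.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class GRUCellParams:
    """Gate weights acting on the concatenation [h_prev, x_t]."""

    W_r: np.ndarray  # (H, H+D)
    W_z: np.ndarray  # (H, H+D)
    W: np.ndarray  # (H, H+D)
    b_r: np.ndarray  # (H,)
    b_z: np.ndarray  # (H,)
    b: np.ndarray  # (H,)

    @property
    def hidden_size(self) -> int:
        return self.W_r.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_r.shape[1] - self.W_r.shape[0]

    @classmethod
    def initialize(cls, hidden: int, inputs: int, rng: np.random.Generator) -> "GRUCellParams":
        def mat():
            bound = 1.0 / np.sqrt(hidden + inputs)
            return rng.uniform(-bound, bound, size=(hidden, hidden + inputs))

        zeros = lambda: np.zeros(hidden)
        return cls(mat(), mat(), mat(), zeros(), zeros(), zeros())


@dataclass
class BiGRUCombineParams:
    """Shared direction-combination weights: h = W_f h_fwd + W_b h_bwd + b."""

    W_f: np.ndarray  # (H, H)
    W_b: np.ndarray  # (H, H)
    b: np.ndarray  # (H,)


@dataclass
class AttentionParams:
    """Score each timestep: e_t = v . tanh(W h_t + b)."""

    W: np.ndarray  # (H, H)
    b: np.ndarray  # (H,)
    v: np.ndarray  # (H,)


@dataclass
class ABiGRUModel:
    forward_cell: GRUCellParams
    backward_cell: GRUCellParams
    combine: BiGRUCombineParams
    attention: AttentionParams
    W1: np.ndarray  # (H, H) head hidden layer (ReLU)
    b1: np.ndarray
    W2: np.ndarray  # (2, H) class logits
    b2: np.ndarray
    n_features: int

    @property
    def hidden_size(self) -> int:
        return self.forward_cell.hidden_size

    @classmethod
    def initialize(
        cls, n_features: int, hidden_size: int = 8, seed: int = 0, input_size: int = 1
    ) -> "ABiGRUModel":
        """Seeded uniform init scaled by fan-in; biases start at zero."""
        rng = np.random.default_rng(seed)
        H = hidden_size

        def mat(rows, cols):
            bound = 1.0 / np.sqrt(cols)
            return rng.uniform(-bound, bound, size=(rows, cols))

        return cls(
            forward_cell=GRUCellParams.initialize(H, input_size, rng),
            backward_cell=GRUCellParams.initialize(H, input_size, rng),
            combine=BiGRUCombineParams(mat(H, H), mat(H, H), np.zeros(H)),
            attention=AttentionParams(mat(H, H), np.zeros(H), mat(1, H)[0]),
            W1=mat(H, H),
            b1=np.zeros(H),
            W2=mat(2, H),
            b2=np.zeros(2),
            n_features=n_features,
        )

    def parameters(self) -> dict[str, np.ndarray]:
        """Named views of every trainable array (updates mutate the model)."""
        f, b, c, a = self.forward_cell, self.backward_cell, self.combine, self.attention
        return {
            "fwd.W_r": f.W_r, "fwd.W_z": f.W_z, "fwd.W": f.W,
            "fwd.b_r": f.b_r, "fwd.b_z": f.b_z, "fwd.b": f.b,
            "bwd.W_r": b.W_r, "bwd.W_z": b.W_z, "bwd.W": b.W,
            "bwd.b_r": b.b_r, "bwd.b_z": b.b_z, "bwd.b": b.b,
            "comb.W_f": c.W_f, "comb.W_b": c.W_b, "comb.b": c.b,
            "att.W": a.W, "att.b": a.b, "att.v": a.v,
            "head.W1": self.W1, "head.b1": self.b1,
            "head.W2": self.W2, "head.b2": self.b2,
        }

    def save_json(self, path) -> None:
        doc = {
            "n_features": self.n_features,
            "hidden_size": self.hidden_size,
            "params": {k: v.tolist() for k, v in self.parameters().items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)

    @classmethod
    def load_json(cls, path) -> "ABiGRUModel":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        model = cls.initialize(doc["n_features"], doc["hidden_size"])
        params = model.parameters()
        for k, v in doc["params"].items():
            arr = np.asarray(v, dtype=float)
            if arr.shape != params[k].shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {params[k].shape}")
            params[k][...] = arr
        return model


@dataclass
class TrainConfig:
    """Training constants; defaults are the reference configuration
    (learning rate 0.01, 50 epochs, dropout 0.5, batch size 5, ReLU head)."""

    learning_rate: float = 0.01
    epochs: int = 50
    dropout: float = 0.5
    batch_size: int = 5
    optimizer: str = "adam"  # "adam" | "sgd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")


def row_to_sequence(row: np.ndarray) -> np.ndarray:
    """Feature j becomes timestep j with a scalar input: (d,) -> (d, 1)."""
    row = np.asarray(row, dtype=float).ravel()
    if row.size == 0:
        raise ValueError("empty row")
    return row[:, None]


def gru_step(x_t: np.ndarray, h_prev: np.ndarray, cell: GRUCellParams) -> np.ndarray:
    """One gated update; accepts single vectors or (B, .) batches."""
    single = np.asarray(h_prev).ndim == 1
    x = np.atleast_2d(np.asarray(x_t, dtype=float))
    h = np.atleast_2d(np.asarray(h_prev, dtype=float))
    if h.shape[1] != cell.hidden_size or x.shape[1] != cell.input_size:
        raise ValueError(
            f"expected hidden {cell.hidden_size} / input {cell.input_size}, "
            f"got {h.shape[1]} / {x.shape[1]}"
        )
    cat = np.concatenate([h, x], axis=1)
    r = _sigmoid(cat @ cell.W_r.T + cell.b_r)
    z = _sigmoid(cat @ cell.W_z.T + cell.b_z)
    h_cand = np.tanh(np.concatenate([r * h, x], axis=1) @ cell.W.T + cell.b)
    h_new = (1.0 - z) * h + z * h_cand
    return h_new[0] if single else h_new


def _run_direction(X: np.ndarray, cell: GRUCellParams, order: range):
    """Run a cell over timesteps in ``order``; states stored at their
    original timestep index.  Returns (states, per-step caches)."""
    B, T, _ = X.shape
    H = cell.hidden_size
    h = np.zeros((B, H))
    states = np.zeros((B, T, H))
    caches = {}
    for t in order:
        x = X[:, t, :]
        cat = np.concatenate([h, x], axis=1)
        r = _sigmoid(cat @ cell.W_r.T + cell.b_r)
        z = _sigmoid(cat @ cell.W_z.T + cell.b_z)
        h_cand = np.tanh(np.concatenate([r * h, x], axis=1) @ cell.W.T + cell.b)
        caches[t] = (h, x, r, z, h_cand)
        h = (1.0 - z) * h + z * h_cand
        states[:, t, :] = h
    return states, caches


def _combined_states(model: ABiGRUModel, X: np.ndarray):
    T = X.shape[1]
    hf, cache_f = _run_direction(X, model.forward_cell, range(T))
    hb, cache_b = _run_direction(X, model.backward_cell, range(T - 1, -1, -1))
    c = model.combine
    hc = hf @ c.W_f.T + hb @ c.W_b.T + c.b
    return hc, hf, hb, cache_f, cache_b


def bigru_forward(sequence: np.ndarray, model: ABiGRUModel) -> np.ndarray:
    """Per-timestep combined hidden states for one (T, D) sequence."""
    sequence = np.asarray(sequence, dtype=float)
    if sequence.ndim == 1:
        sequence = sequence[:, None]
    if sequence.shape[0] == 0:
        raise ValueError("empty sequence")
    hc, *_ = _combined_states(model, sequence[None, :, :])
    return hc[0]


def attention_pool(states: np.ndarray, att: AttentionParams) -> tuple[np.ndarray, np.ndarray]:
    """Softmax-weighted pooling of (T, H) states into a context vector.

    Returns (context, weights); weights are nonnegative and sum to one.
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    s = np.tanh(states @ att.W.T + att.b)
    e = s @ att.v
    a = _softmax(e)
    return a @ states, a


def _forward_batch(model: ABiGRUModel, X: np.ndarray, dropout_mask: np.ndarray | None = None):
    """Full forward pass with every intermediate cached for backprop."""
    hc_raw, hf, hb, cache_f, cache_b = _combined_states(model, X)
    hc = hc_raw if dropout_mask is None else hc_raw * dropout_mask
    att = model.attention
    s = np.tanh(hc @ att.W.T + att.b)  # (B,T,H)
    e = s @ att.v  # (B,T)
    a = _softmax(e, axis=1)
    V = np.einsum("bt,bth->bh", a, hc)
    pre1 = V @ model.W1.T + model.b1
    z1 = np.maximum(pre1, 0.0)
    logits = z1 @ model.W2.T + model.b2
    probs = _softmax(logits, axis=1)
    cache = dict(
        X=X, hc=hc, hf=hf, hb=hb, cache_f=cache_f, cache_b=cache_b,
        s=s, a=a, V=V, pre1=pre1, z1=z1, probs=probs, dropout_mask=dropout_mask,
    )
    return probs, cache


def _backward_direction(dstates, X, cell, order, caches):
    B, T, _ = X.shape
    H = cell.hidden_size
    g = {k: np.zeros_like(v) for k, v in (
        ("W_r", cell.W_r), ("W_z", cell.W_z), ("W", cell.W),
        ("b_r", cell.b_r), ("b_z", cell.b_z), ("b", cell.b),
    )}
    dh_next = np.zeros((B, H))
    for t in reversed(order):
        h_prev, x, r, z, h_cand = caches[t]
        dh = dstates[:, t, :] + dh_next
        dz = dh * (h_cand - h_prev)
        dh_cand = dh * z
        dh_prev = dh * (1.0 - z)

        dpre_c = dh_cand * (1.0 - h_cand**2)
        rcat = np.concatenate([r * h_prev, x], axis=1)
        g["W"] += dpre_c.T @ rcat
        g["b"] += dpre_c.sum(axis=0)
        dcat_c = dpre_c @ cell.W
        drh = dcat_c[:, :H]
        dr = drh * h_prev
        dh_prev += drh * r

        cat = np.concatenate([h_prev, x], axis=1)
        dpre_r = dr * r * (1.0 - r)
        g["W_r"] += dpre_r.T @ cat
        g["b_r"] += dpre_r.sum(axis=0)
        dh_prev += (dpre_r @ cell.W_r)[:, :H]

        dpre_z = dz * z * (1.0 - z)
        g["W_z"] += dpre_z.T @ cat
        g["b_z"] += dpre_z.sum(axis=0)
        dh_prev += (dpre_z @ cell.W_z)[:, :H]

        dh_next = dh_prev
    return g


def loss_and_grads(
    model: ABiGRUModel,
    X: np.ndarray,
    y_idx: np.ndarray,
    dropout_mask: np.ndarray | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy over a batch of (B, T, 1) sequences and its
    gradient with respect to every named parameter."""
    B, T, _ = X.shape
    probs, cache = _forward_batch(model, X, dropout_mask)
    eps = 1e-12
    loss = -float(np.mean(np.log(probs[np.arange(B), y_idx] + eps)))

    # head
    dlogits = probs.copy()
    dlogits[np.arange(B), y_idx] -= 1.0
    dlogits /= B
    z1, V = cache["z1"], cache["V"]
    gW2 = dlogits.T @ z1
    gb2 = dlogits.sum(axis=0)
    dz1 = dlogits @ model.W2
    dpre1 = dz1 * (cache["pre1"] > 0)
    gW1 = dpre1.T @ V
    gb1 = dpre1.sum(axis=0)
    dV = dpre1 @ model.W1

    # attention pooling: V = sum_t a_t hc_t
    hc, a, s = cache["hc"], cache["a"], cache["s"]
    da = np.einsum("bh,bth->bt", dV, hc)
    dhc = a[:, :, None] * dV[:, None, :]
    de = a * (da - np.sum(da * a, axis=1, keepdims=True))
    att = model.attention
    ds = de[:, :, None] * att.v
    gv = np.einsum("bt,bth->h", de, s)
    dpre_s = ds * (1.0 - s**2)
    gWa = np.einsum("bth,btk->hk", dpre_s, hc)
    gba = dpre_s.sum(axis=(0, 1))
    dhc += dpre_s @ att.W

    if cache["dropout_mask"] is not None:
        dhc = dhc * cache["dropout_mask"]

    # direction combination
    c = model.combine
    hf, hb = cache["hf"], cache["hb"]
    gWf = np.einsum("bth,btk->hk", dhc, hf)
    gWb = np.einsum("bth,btk->hk", dhc, hb)
    gbc = dhc.sum(axis=(0, 1))
    dhf = dhc @ c.W_f
    dhb = dhc @ c.W_b

    gf = _backward_direction(dhf, X, model.forward_cell, range(T), cache["cache_f"])
    gb_ = _backward_direction(dhb, X, model.backward_cell, range(T - 1, -1, -1), cache["cache_b"])

    grads = {
        **{f"fwd.{k}": v for k, v in gf.items()},
        **{f"bwd.{k}": v for k, v in gb_.items()},
        "comb.W_f": gWf, "comb.W_b": gWb, "comb.b": gbc,
        "att.W": gWa, "att.b": gba, "att.v": gv,
        "head.W1": gW1, "head.b1": gb1, "head.W2": gW2, "head.b2": gb2,
    }
    return loss, grads


def _encode_labels(table: FeatureTable) -> np.ndarray:
    return (table.y == table.positive).astype(int)


def train(model: ABiGRUModel, data: FeatureTable, cfg: TrainConfig = TrainConfig()) -> list[float]:
    """Mini-batch gradient descent on the cross-entropy; returns the
    per-epoch mean batch loss history.  Dropout masks are redrawn per batch
    and applied to the combined hidden states during training only."""
    y_idx = _encode_labels(data)
    if len(np.unique(y_idx)) < 2:
        raise ValueError("training data must contain both classes")
    X = data.values()[:, :, None]
    if X.shape[1] != model.n_features:
        raise ValueError(f"model expects {model.n_features} features, data has {X.shape[1]}")
    n = X.shape[0]
    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    # Adam moment estimates (ignored for plain gradient descent)
    m1 = {k: np.zeros_like(v) for k, v in params.items()}
    m2 = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    step = 0
    history: list[float] = []
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb, yb = X[idx], y_idx[idx]
            mask = None
            if cfg.dropout > 0:
                keep = 1.0 - cfg.dropout
                mask = (rng.uniform(size=(len(idx), xb.shape[1], model.hidden_size)) < keep) / keep
            loss, grads = loss_and_grads(model, xb, yb, dropout_mask=mask)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged: non-finite loss {loss} at epoch {len(history)}")
            step += 1
            for k, gradient in grads.items():
                if cfg.optimizer == "adam":
                    m1[k] = beta1 * m1[k] + (1 - beta1) * gradient
                    m2[k] = beta2 * m2[k] + (1 - beta2) * gradient**2
                    m_hat = m1[k] / (1 - beta1**step)
                    v_hat = m2[k] / (1 - beta2**step)
                    params[k] -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + adam_eps)
                else:
                    params[k] -= cfg.learning_rate * gradient
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


def predict(model: ABiGRUModel, rows) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and hard labels (ties go to the positive class).

    ``rows`` may be a FeatureTable (labels mapped back to its alphabet) or a
    plain (B, d) array (labels returned as 0/1 with 1 = positive).
    """
    if isinstance(rows, FeatureTable):
        X = rows.values()
        positive = rows.positive
        others = [v for v in np.unique(rows.y) if v != positive]
        negative = others[0] if len(others) == 1 else 0
    else:
        X = np.atleast_2d(np.asarray(rows, dtype=float))
        positive, negative = 1, 0
    if X.shape[1] != model.n_features:
        raise ValueError(f"model expects {model.n_features} features, got {X.shape[1]}")
    probs, _ = _forward_batch(model, X[:, :, None], dropout_mask=None)
    is_pos = probs[:, 1] >= 0.5
    labels = np.where(is_pos, positive, negative)
    return probs, labels
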