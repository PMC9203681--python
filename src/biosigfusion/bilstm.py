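"""Bidirectional LSTM classifier over selected-feature sequences.

The cell follows the standard gate equations exactly: with sigma the
logistic function and the concatenation a_t = [h_{t-1}, x_t],

    i_t = sigma(W_i a_t + b_i)        (input gate)
    o_t = sigma(W_o a_t + b_o)        (output gate)
    f_t = sigma(W_f a_t + b_f)        (forget gate)
    C_t = f_t * C_{t-1} + i_t * tanh(W_c a_t + b_c)
    h_t = o_t * tanh(C_t)

A forward pass reads the sequence left to right, a backward pass right to
left; the concatenation of the two final hidden states feeds a fully
connected softmax layer.  Training minimises cross-entropy plus an L2
penalty on the weight matrices, with Adam by default (plain SGD available
for the literal gradient-descent update W <- W - eta dL/dW).

Gradients are derived by hand (backpropagation through time) and verified
against finite differences in the test suite; there is no autodiff
dependency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger("biosigfusion")

GATES = ("i", "o", "f", "c")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class LSTMCellParams:
    """Gate weights acting on [h_{t-1}, x_t] plus biases, one set per gate."""

    W: dict[str, np.ndarray]   # each (H, H + D)
    b: dict[str, np.ndarray]   # each (H,)

    @property
    def hidden_size(self) -> int:
        return self.W["i"].shape[0]

    @property
    def input_size(self) -> int:
        return self.W["i"].shape[1] - self.W["i"].shape[0]

    @classmethod
    def init(cls, input_size: int, hidden_size: int,
             rng: np.random.Generator) -> "LSTMCellParams":
        scale = 1.0 / np.sqrt(hidden_size + input_size)
        W = {
            g: rng.uniform(-scale, scale, (hidden_size, hidden_size + input_size))
            for g in GATES
        }
        b = {g: np.zeros(hidden_size) for g in GATES}
        # positive forget bias: standard remedy against early forgetting
        b["f"] += 1.0
        return cls(W=W, b=b)


@dataclass
class BiLSTMModel:
    """Forward and backward cells plus the softmax output layer."""

    forward_cell: LSTMCellParams
    backward_cell: LSTMCellParams
    W_out: np.ndarray            # (C, 2H)
    b_out: np.ndarray            # (C,)
    hyper: dict = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return self.W_out.shape[0]

    @classmethod
    def init(cls, input_size: int, hidden_size: int, n_classes: int,
             seed: int | None = 0, **hyper) -> "BiLSTMModel":
        rng = np.random.default_rng(seed)
        fwd = LSTMCellParams.init(input_size, hidden_size, rng)
        bwd = LSTMCellParams.init(input_size, hidden_size, rng)
        scale = 1.0 / np.sqrt(2 * hidden_size)
        W_out = rng.uniform(-scale, scale, (n_classes, 2 * hidden_size))
        return cls(
            forward_cell=fwd, backward_cell=bwd,
            W_out=W_out, b_out=np.zeros(n_classes), hyper=dict(hyper),
        )

    def _arrays(self) -> dict[str, np.ndarray]:
        d: dict[str, np.ndarray] = {}
        for tag, cell in (("f", self.forward_cell), ("b", self.backward_cell)):
            for g in GATES:
                d[f"{tag}.W_{g}"] = cell.W[g]
                d[f"{tag}.b_{g}"] = cell.b[g]
        d["W_out"] = self.W_out
        d["b_out"] = self.b_out
        return d


# ---------------------------------------------------------------------------
# Cell and forward pass
# ---------------------------------------------------------------------------

def lstm_cell(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    C_prev: np.ndarray,
    params: LSTMCellParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM step; accepts a single step (D,) or a batch (B, D)."""
    single = np.ndim(x_t) == 1
    x_t = np.atleast_2d(np.asarray(x_t, dtype=float))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=float))
    C_prev = np.atleast_2d(np.asarray(C_prev, dtype=float))
    H = params.hidden_size
    if x_t.shape[1] != params.input_size or h_prev.shape[1] != H:
        raise ValueError("input/hidden sizes do not match the cell parameters")
    a = np.concatenate([h_prev, x_t], axis=1)
    i = _sigmoid(a @ params.W["i"].T + params.b["i"])
    o = _sigmoid(a @ params.W["o"].T + params.b["o"])
    f = _sigmoid(a @ params.W["f"].T + params.b["f"])
    c_tilde = np.tanh(a @ params.W["c"].T + params.b["c"])
    C_t = f * C_prev + i * c_tilde
    h_t = o * np.tanh(C_t)
    if single:
        return h_t[0], C_t[0]
    return h_t, C_t


def _run_direction(X: np.ndarray, cell: LSTMCellParams, reverse: bool):
    """Run a batch (B, T, D) through one direction, caching everything the
    backward pass needs.  Returns (h_last, cache)."""
    B, T, _ = X.shape
    H = cell.hidden_size
    order = range(T - 1, -1, -1) if reverse else range(T)
    h = np.zeros((B, H))
    C = np.zeros((B, H))
    cache = []
    for t in order:
        a = np.concatenate([h, X[:, t, :]], axis=1)
        i = _sigmoid(a @ cell.W["i"].T + cell.b["i"])
        o = _sigmoid(a @ cell.W["o"].T + cell.b["o"])
        f = _sigmoid(a @ cell.W["f"].T + cell.b["f"])
        c_tilde = np.tanh(a @ cell.W["c"].T + cell.b["c"])
        C_new = f * C + i * c_tilde
        h = o * np.tanh(C_new)
        cache.append((a, i, o, f, c_tilde, C, C_new))
        C = C_new
    return h, cache


def bilstm_forward(sequence: np.ndarray, model: BiLSTMModel) -> np.ndarray:
    """Class probabilities for one sequence (T, D) or a batch (B, T, D)."""
    X = np.asarray(sequence, dtype=float)
    single = X.ndim == 2
    if single:
        X = X[None]
    hf, _ = _run_direction(X, model.forward_cell, reverse=False)
    hb, _ = _run_direction(X, model.backward_cell, reverse=True)
    logits = np.concatenate([hf, hb], axis=1) @ model.W_out.T + model.b_out
    probs = softmax(logits)
    return probs[0] if single else probs


# ---------------------------------------------------------------------------
# Loss and gradients
# ---------------------------------------------------------------------------

def cross_entropy(probs: np.ndarray, true_label) -> float:
    """Mean negative log-probability of the true labels; probabilities are
    clipped at 1e-12 (with a warning) to avoid log(0)."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    labels = np.atleast_1d(np.asarray(true_label, dtype=int))
    p_true = probs[np.arange(labels.size), labels]
    if np.any(p_true < 1e-12):
        logger.warning("clipping zero predicted probability in cross-entropy")
        p_true = np.maximum(p_true, 1e-12)
    return float(-np.mean(np.log(p_true)))


def _backward_direction(
    cache: list, cell: LSTMCellParams, dh_last: np.ndarray
) -> dict[str, np.ndarray]:
    """BPTT through one direction given the gradient at its final hidden
    state.  Returns gradients keyed like the cell's arrays."""
    H = cell.hidden_size
    grads = {f"W_{g}": np.zeros_like(cell.W[g]) for g in GATES}
    grads.update({f"b_{g}": np.zeros_like(cell.b[g]) for g in GATES})
    dh = dh_last
    dC = np.zeros_like(dh_last)
    for a, i, o, f, c_tilde, C_prev, C_new in reversed(cache):
        tC = np.tanh(C_new)
        do = dh * tC
        dC = dC + dh * o * (1.0 - tC**2)
        df = dC * C_prev
        di = dC * c_tilde
        dct = dC * i
        dz = {
            "i": di * i * (1.0 - i),
            "o": do * o * (1.0 - o),
            "f": df * f * (1.0 - f),
            "c": dct * (1.0 - c_tilde**2),
        }
        da = np.zeros_like(a)
        for g in GATES:
            grads[f"W_{g}"] += dz[g].T @ a
            grads[f"b_{g}"] += dz[g].sum(axis=0)
            da += dz[g] @ cell.W[g]
        dh = da[:, :H]
        dC = dC * f
    return grads


def _loss_and_grads(
    X: np.ndarray, y: np.ndarray, model: BiLSTMModel, l2: float
) -> tuple[float, dict[str, np.ndarray]]:
    """Batch cross-entropy + L2 objective and gradients for every array."""
    B = X.shape[0]
    hf, cache_f = _run_direction(X, model.forward_cell, reverse=False)
    hb, cache_b = _run_direction(X, model.backward_cell, reverse=True)
    hcat = np.concatenate([hf, hb], axis=1)
    logits = hcat @ model.W_out.T + model.b_out
    probs = softmax(logits)
    loss = cross_entropy(probs, y)

    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    grads = {
        "W_out": dlogits.T @ hcat,
        "b_out": dlogits.sum(axis=0),
    }
    H = model.forward_cell.hidden_size
    dhcat = dlogits @ model.W_out
    gf = _backward_direction(cache_f, model.forward_cell, dhcat[:, :H])
    gb = _backward_direction(cache_b, model.backward_cell, dhcat[:, H:])
    for g, src in (("f", gf), ("b", gb)):
        for k, v in src.items():
            grads[f"{g}.{k}"] = v
    if l2 > 0:
        arrays = model._arrays()
        for k, arr in arrays.items():
            if k.startswith(("f.W", "b.W")) or k == "W_out":
                loss += 0.5 * l2 * float(np.sum(arr**2))
                grads[k] = grads[k] + l2 * arr
    return loss, grads


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, arrays: dict[str, np.ndarray], lr: float,
                 b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.v = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.t = 0

    def step(self, arrays: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, arr in arrays.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _as_batch(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:              # (N, T) scalar sequences
        X = X[:, :, None]
    return X


def vectors_to_sequences(features: np.ndarray) -> np.ndarray:
    """Treat each feature vector as a length-T sequence of scalars
    (T = number of selected features, D = 1)."""
    return _as_batch(np.asarray(features, dtype=float))


def train_bilstm(
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray] | None = None,
    hidden_size: int = 80,
    lr: float = 0.01,
    batch_size: int = 40,
    l2: float = 1e-4,
    epochs: int = 60,
    patience: int = 10,
    optimizer: str = "adam",
    seed: int | None = 0,
) -> tuple[BiLSTMModel, dict]:
    """Train a Bi-LSTM classifier.

    Defaults follow the study conditions: Adam, learning rate 0.01, batch
    size 40, 80 hidden units, L2 rate 1e-4.  Early stopping monitors
    validation loss with the given patience and restores the best
    parameters.  ``optimizer="sgd"`` selects the literal gradient-descent
    update instead of Adam.  A NaN loss aborts with diagnostics.
    """
    X, y = _as_batch(train[0]), np.asarray(train[1], dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain at least 2 classes")
    n_classes = int(classes.max()) + 1
    rng = np.random.default_rng(seed)
    model = BiLSTMModel.init(
        X.shape[2], hidden_size, n_classes, seed=seed,
        lr=lr, batch_size=batch_size, l2=l2, optimizer=optimizer,
    )
    arrays = model._arrays()
    adam = _Adam(arrays, lr) if optimizer == "adam" else None

    has_val = val is not None and len(val[1]) > 0
    if has_val:
        Xv, yv = _as_batch(val[0]), np.asarray(val[1], dtype=int)
    history = {"train_loss": [], "val_loss": [], "val_accuracy": []}
    best = {"loss": np.inf, "arrays": None, "epoch": -1}
    n = X.shape[0]
    for epoch in range(epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = perm[start : start + batch_size]
            loss, grads = _loss_and_grads(X[idx], y[idx], model, l2)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"divergent loss {loss} at epoch {epoch}; "
                    f"lr={lr}, batch={batch_size}"
                )
            losses.append(loss)
            if adam is not None:
                adam.step(arrays, grads)
            else:
                for k, arr in arrays.items():
                    arr -= lr * grads[k]
        history["train_loss"].append(float(np.mean(losses)))
        if has_val:
            pv = bilstm_forward(Xv, model)
            vloss = cross_entropy(pv, yv)
            vacc = float(np.mean(np.argmax(pv, axis=1) == yv))
        else:
            vloss = history["train_loss"][-1]
            vacc = float("nan")
        history["val_loss"].append(vloss)
        history["val_accuracy"].append(vacc)
        if vloss < best["loss"] - 1e-12:
            best = {
                "loss": vloss,
                "arrays": {k: v.copy() for k, v in arrays.items()},
                "epoch": epoch,
            }
        elif epoch - best["epoch"] >= patience:
            logger.info("early stop at epoch %d (best %d)", epoch, best["epoch"])
            break
    if best["arrays"] is not None:
        for k, arr in arrays.items():
            arr[...] = best["arrays"][k]
    history["best_epoch"] = best["epoch"]
    return model, history


def predict(
    model: BiLSTMModel, sequences: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Argmax labels and class probabilities per sequence."""
    probs = bilstm_forward(_as_batch(sequences), model)
    return np.argmax(probs, axis=1), probs
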