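"""Minimal feed-forward network machinery for the contrastive pipeline.

A small, dependency-free stack: fully-connected ReLU networks with manual
backpropagation, the Adam optimizer, the batch triplet margin loss on
Euclidean distances, and weighted binary cross-entropy with logits.
Everything operates on float64 NumPy arrays and is deterministic given the
RNG used for initialization and batching.
"""

from __future__ import annotations

import numpy as np

Params = list[tuple[np.ndarray, np.ndarray]]  # [(W, b), ...] per layer


def mlp_init(widths: list[int], rng: np.random.Generator) -> Params:
    """Uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) init for weights and biases
    (the convention of mainstream deep-learning Linear layers); keeps early
    optimizer steps comparable in size to the initial weights."""
    params: Params = []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        w = rng.uniform(-bound, bound, size=(fan_in, fan_out))
        b = rng.uniform(-bound, bound, size=fan_out)
        params.append((w, b))
    return params


def mlp_forward(params: Params, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Forward pass; ReLU on every layer except the last (linear output).

    Returns the output and the list of layer inputs (the backward cache).
    """
    cache = []
    h = x
    for i, (w, b) in enumerate(params):
        cache.append(h)
        h = h @ w + b
        if i < len(params) - 1:
            h = np.maximum(h, 0.0)
    return h, cache


def mlp_backward(params: Params, cache: list[np.ndarray], dout: np.ndarray) -> tuple[Params, np.ndarray]:
    """Backpropagate ``dout`` (dL/d output); returns gradients and dL/dx."""
    grads: Params = [None] * len(params)  # type: ignore[list-item]
    g = dout
    for i in reversed(range(len(params))):
        w, b = params[i]
        h_in = cache[i]
        if i < len(params) - 1:
            # redo the pre-activation to recover the ReLU mask
            pre = h_in @ w + b
            g = g * (pre > 0)
        grads[i] = (h_in.T @ g, g.sum(axis=0))
        g = g @ w.T
    return grads, g


class Adam:
    """Adaptive-moment gradient descent (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: Params, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [(np.zeros_like(w), np.zeros_like(b)) for w, b in params]
        self.v = [(np.zeros_like(w), np.zeros_like(b)) for w, b in params]

    def step(self, params: Params, grads: Params) -> Params:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        out: Params = []
        for i, ((w, b), (gw, gb)) in enumerate(zip(params, grads)):
            mw, mb = self.m[i]
            vw, vb = self.v[i]
            mw = b1 * mw + (1 - b1) * gw
            mb = b1 * mb + (1 - b1) * gb
            vw = b2 * vw + (1 - b2) * gw ** 2
            vb = b2 * vb + (1 - b2) * gb ** 2
            self.m[i], self.v[i] = (mw, mb), (vw, vb)
            mhw, mhb = mw / (1 - b1 ** self.t), mb / (1 - b1 ** self.t)
            vhw, vhb = vw / (1 - b2 ** self.t), vb / (1 - b2 ** self.t)
            out.append((w - self.lr * mhw / (np.sqrt(vhw) + self.eps),
                        b - self.lr * mhb / (np.sqrt(vhb) + self.eps)))
        return out


def euclidean_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.sqrt(np.sum((a - b) ** 2, axis=-1))


def triplet_margin_loss(
    a_emb: np.ndarray, p_emb: np.ndarray, n_emb: np.ndarray, margin: float = 1.0
) -> float:
    """Batch-mean max(d(a,p) - d(a,n) + margin, 0) with Euclidean d."""
    a_emb, p_emb, n_emb = (np.atleast_2d(np.asarray(x, dtype=float)) for x in (a_emb, p_emb, n_emb))
    if not (a_emb.shape == p_emb.shape == n_emb.shape):
        raise ValueError("anchor/positive/negative embedding shapes differ")
    d_ap = euclidean_distances(a_emb, p_emb)
    d_an = euclidean_distances(a_emb, n_emb)
    return float(np.mean(np.maximum(d_ap - d_an + margin, 0.0)))


def triplet_margin_loss_grads(
    a_emb: np.ndarray, p_emb: np.ndarray, n_emb: np.ndarray, margin: float = 1.0,
    eps: float = 1e-12,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Loss plus gradients with respect to the three embedding batches."""
    d_ap = euclidean_distances(a_emb, p_emb)
    d_an = euclidean_distances(a_emb, n_emb)
    viol = d_ap - d_an + margin
    active = viol > 0
    loss = float(np.mean(np.maximum(viol, 0.0)))
    n = a_emb.shape[0]
    u_ap = (a_emb - p_emb) / np.maximum(d_ap, eps)[:, None]
    u_an = (a_emb - n_emb) / np.maximum(d_an, eps)[:, None]
    scale = (active / n)[:, None]
    da = scale * (u_ap - u_an)
    dp = scale * (-u_ap)
    dn = scale * u_an
    return loss, da, dp, dn


def bce_with_logits(
    logits: np.ndarray, targets: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Weighted binary cross-entropy with logits; returns (loss, dL/dlogits).

    ``weights`` is a per-sample weight vector (e.g. the inverse-frequency
    class weight of each sample's class); omitted means all ones.
    """
    logits = np.asarray(logits, dtype=float).ravel()
    targets = np.asarray(targets, dtype=float).ravel()
    w = np.ones_like(logits) if weights is None else np.asarray(weights, dtype=float).ravel()
    # numerically stable softplus(z) - y*z
    per = np.maximum(logits, 0.0) - logits * targets + np.log1p(np.exp(-np.abs(logits)))
    loss = float(np.mean(w * per))
    sig = 1.0 / (1.0 + np.exp(-logits))
    dlogits = w * (sig - targets) / len(logits)
    return loss, dlogits


def sigmoid(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def params_copy(params: Params) -> Params:
    return [(w.copy(), b.copy()) for w, b in params]


def params_equal(a: Params, b: Params) -> bool:
    return len(a) == len(b) and all(
        np.array_equal(wa, wb) and np.array_equal(ba, bb)
        for (wa, ba), (wb, bb) in zip(a, b)
    )


def params_to_jsonable(params: Params) -> list[dict]:
    return [{"W": w.tolist(), "b": b.tolist()} for w, b in params]


def params_from_jsonable(data: list[dict]) -> Params:
    return [(np.asarray(d["W"], dtype=float), np.asarray(d["b"], dtype=float)) for d in data]
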