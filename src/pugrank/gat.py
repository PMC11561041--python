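"""A compact graph attention network (GAT) node classifier in NumPy.

Two attention layers trained full-batch with Adam; gradients are derived
by hand and verified against finite differences in the test suite.  The
classifier consumes soft labels (belief vectors) for unlabeled genes and
one-hot labels for the labeled positives, weighting the two groups by
1/|R| and 1/|U| respectively.

Segment reductions (per-node softmax and neighbourhood sums) run on
edge arrays pre-sorted by destination/source via ``np.*.reduceat``; the
edge set must include a self-loop per node so that no segment is empty.

Class order convention throughout: column 0 = positive, column 1 = negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_LEAKY_SLOPE = 0.2


def _leaky_relu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, _LEAKY_SLOPE * x)


class EdgeIndex:
    """Directed edges (with self-loops) indexed for fast segment reductions.

    Edges are stored in destination-sorted canonical order; ``perm_src``
    re-sorts that order by source for the scatter-to-source reductions in
    the backward pass.
    """

    def __init__(self, src: np.ndarray, dst: np.ndarray, n: int):
        src = np.asarray(src, np.int64)
        dst = np.asarray(dst, np.int64)
        order = np.argsort(dst, kind="stable")
        self.src = src[order]
        self.dst = dst[order]
        self.n = n
        self.n_edges = src.size
        if not (np.isin(np.arange(n), self.dst).all() and np.isin(np.arange(n), self.src).all()):
            raise ValueError("every node needs a self-loop (empty segments)")
        self.starts_dst = np.searchsorted(self.dst, np.arange(n))
        self.counts_dst = np.diff(np.append(self.starts_dst, self.n_edges))
        self.perm_src = np.argsort(self.src, kind="stable")
        src_sorted = self.src[self.perm_src]
        self.starts_src = np.searchsorted(src_sorted, np.arange(n))

    @classmethod
    def with_self_loops(cls, src: np.ndarray, dst: np.ndarray, n: int) -> "EdgeIndex":
        loops = np.arange(n)
        return cls(np.concatenate([src, loops]), np.concatenate([dst, loops]), n)

    # values below are in canonical (dst-sorted) edge order
    def sum_by_dst(self, values: np.ndarray) -> np.ndarray:
        return np.add.reduceat(values, self.starts_dst, axis=0)

    def max_by_dst(self, values: np.ndarray) -> np.ndarray:
        return np.maximum.reduceat(values, self.starts_dst, axis=0)

    def expand_dst(self, per_node: np.ndarray) -> np.ndarray:
        return np.repeat(per_node, self.counts_dst, axis=0)

    def sum_by_src(self, values: np.ndarray) -> np.ndarray:
        return np.add.reduceat(values[self.perm_src], self.starts_src, axis=0)


@dataclass
class _HeadParams:
    W: np.ndarray       # (f_in, f_out)
    a_dst: np.ndarray   # (f_out,) attention coefficient on the centre node
    a_src: np.ndarray   # (f_out,) attention coefficient on the neighbour


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape[-2:])) if len(shape) > 1 else np.sqrt(6.0 / shape[0])
    return rng.uniform(-limit, limit, size=shape)


def _attention_forward(
    X: np.ndarray, p: _HeadParams, ei: EdgeIndex
) -> tuple[np.ndarray, dict]:
    """One attention head: out_i = sum_j alpha_ij (X W)_j over incoming edges."""
    Z = X @ p.W
    pre = (Z @ p.a_dst)[ei.dst] + (Z @ p.a_src)[ei.src]
    e = _leaky_relu(pre)
    mx = ei.max_by_dst(e)
    ex = np.exp(e - ei.expand_dst(mx))
    denom = ei.sum_by_dst(ex)
    alpha = ex / ei.expand_dst(denom)
    out = ei.sum_by_dst(alpha[:, None] * Z[ei.src])
    cache = {"X": X, "Z": Z, "pre": pre, "alpha": alpha}
    return out, cache


def _attention_backward(
    G: np.ndarray, p: _HeadParams, ei: EdgeIndex, cache: dict
) -> tuple[np.ndarray, _HeadParams]:
    """Gradient of the head w.r.t. inputs and parameters given dL/d(out)."""
    X, Z, pre, alpha = cache["X"], cache["Z"], cache["pre"], cache["alpha"]
    G_dst = G[ei.dst]
    Z_src = Z[ei.src]
    g_alpha = np.einsum("ef,ef->e", G_dst, Z_src)
    gZ = ei.sum_by_src(alpha[:, None] * G_dst)
    # segment-softmax backward
    sdot = ei.sum_by_dst(alpha * g_alpha)
    g_e = alpha * (g_alpha - ei.expand_dst(sdot))
    g_pre = g_e * np.where(pre > 0, 1.0, _LEAKY_SLOPE)
    g_s = ei.sum_by_dst(g_pre)
    g_t = ei.sum_by_src(g_pre)
    g_a_dst = Z.T @ g_s
    g_a_src = Z.T @ g_t
    gZ = gZ + g_s[:, None] * p.a_dst[None, :] + g_t[:, None] * p.a_src[None, :]
    gW = X.T @ gZ
    gX = gZ @ p.W.T
    return gX, _HeadParams(W=gW, a_dst=g_a_dst, a_src=g_a_src)


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.clip(x, -60.0, 0.0)))


@dataclass
class GraphAttentionClassifier:
    """Two-layer GAT with multi-head first layer and a 2-class output head."""

    n_features: int
    hidden: int = 16
    heads: int = 4
    learning_rate: float = 0.01
    seed: int = 0
    _params: list[list[_HeadParams]] = field(default_factory=list, repr=False)
    _adam_m: list | None = field(default=None, repr=False)
    _adam_v: list | None = field(default=None, repr=False)
    _adam_t: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        if self.hidden % self.heads:
            raise ValueError("hidden width must be divisible by the number of heads")
        rng = np.random.default_rng(self.seed)
        per_head = self.hidden // self.heads
        layer1 = [
            _HeadParams(
                W=_glorot(rng, (self.n_features, per_head)),
                a_dst=_glorot(rng, (per_head,)),
                a_src=_glorot(rng, (per_head,)),
            )
            for _ in range(self.heads)
        ]
        layer2 = [
            _HeadParams(
                W=_glorot(rng, (self.hidden, 2)),
                a_dst=_glorot(rng, (2,)),
                a_src=_glorot(rng, (2,)),
            )
        ]
        self._params = [layer1, layer2]

    # -- forward -------------------------------------------------------
    def forward(self, X: np.ndarray, ei: EdgeIndex) -> tuple[np.ndarray, list]:
        """Return class probabilities (n, 2) and caches for backprop."""
        head_outs, head_caches = [], []
        for p in self._params[0]:
            out, cache = _attention_forward(X, p, ei)
            head_outs.append(out)
            head_caches.append(cache)
        h_pre = np.concatenate(head_outs, axis=1)
        h = _elu(h_pre)
        logits, cache2 = _attention_forward(h, self._params[1][0], ei)
        logits = logits - logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        probs = expl / expl.sum(axis=1, keepdims=True)
        return probs, [head_caches, h_pre, cache2]

    # -- loss / gradients ----------------------------------------------
    def loss_and_grads(
        self,
        X: np.ndarray,
        ei: EdgeIndex,
        targets: np.ndarray,
        weights: np.ndarray,
    ) -> tuple[float, list[list[_HeadParams]], np.ndarray]:
        """Weighted soft-label negative log likelihood and its gradients.

        loss = sum_i weights_i * ( -sum_c targets[i,c] log probs[i,c] ).
        """
        probs, caches = self.forward(X, ei)
        head_caches, h_pre, cache2 = caches
        logp = np.log(np.clip(probs, 1e-300, None))
        loss = float(-(weights[:, None] * targets * logp).sum())
        g_logits = weights[:, None] * (probs - targets)
        gH, g2 = _attention_backward(g_logits, self._params[1][0], ei, cache2)
        g_h_pre = gH * np.where(h_pre > 0, 1.0, np.exp(np.clip(h_pre, -60.0, 0.0)))
        grads1 = []
        per_head = self.hidden // self.heads
        for k, p in enumerate(self._params[0]):
            gk = g_h_pre[:, k * per_head : (k + 1) * per_head]
            _, gp = _attention_backward(gk, p, ei, head_caches[k])
            grads1.append(gp)
        return loss, [grads1, [g2]], probs

    # -- training ------------------------------------------------------
    def fit_epochs(
        self,
        X: np.ndarray,
        ei: EdgeIndex,
        targets: np.ndarray,
        weights: np.ndarray,
        epochs: int,
    ) -> np.ndarray:
        """Run full-batch Adam for ``epochs`` steps; returns final probabilities."""
        if self._adam_m is None:
            self._adam_m = [
                [_HeadParams(np.zeros_like(p.W), np.zeros_like(p.a_dst), np.zeros_like(p.a_src))
                 for p in layer]
                for layer in self._params
            ]
            self._adam_v = [
                [_HeadParams(np.zeros_like(p.W), np.zeros_like(p.a_dst), np.zeros_like(p.a_src))
                 for p in layer]
                for layer in self._params
            ]
        b1, b2, eps = 0.9, 0.999, 1e-8
        probs = None
        for epoch in range(epochs):
            loss, grads, probs = self.loss_and_grads(X, ei, targets, weights)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            self._adam_t += 1
            t = self._adam_t
            for layer, glayer, mlayer, vlayer in zip(
                self._params, grads, self._adam_m, self._adam_v
            ):
                for p, g, m, v in zip(layer, glayer, mlayer, vlayer):
                    for attr in ("W", "a_dst", "a_src"):
                        gv = getattr(g, attr)
                        mv = getattr(m, attr)
                        vv = getattr(v, attr)
                        mv *= b1
                        mv += (1 - b1) * gv
                        vv *= b2
                        vv += (1 - b2) * gv * gv
                        m_hat = mv / (1 - b1**t)
                        v_hat = vv / (1 - b2**t)
                        getattr(p, attr).__isub__(
                            self.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
                        )
        if probs is None:
            probs, _ = self.forward(X, ei)
        return probs


def soft_label_nll(target: np.ndarray, prediction: np.ndarray) -> float:
    """l(t, p) = -sum_c t_c log p_c for a single 2-vector pair."""
    return float(-(target * np.log(np.clip(prediction, 1e-300, None))).sum())
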