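"""Cross-attention correlation modelling between moving and fixed features.

The moving image's token embeddings act as queries; the fixed image supplies
both keys and values.  Scaled dot-product attention with 1/sqrt(d) scaling
produces, for every moving-image token, a convex combination of fixed-image
value vectors — the correlation features decoded into the displacement field.

Token order is row-major (C order) over the (tx, ty, tz) token lattice:
token ``k`` corresponds to lattice site ``np.unravel_index(k, lattice)``.
"""

from __future__ import annotations

import numpy as np


def flatten_site(site, lattice) -> int:
    """Lattice site -> token index (row-major)."""
    return int(np.ravel_multi_index(site, lattice))


def unflatten_site(k: int, lattice) -> tuple[int, int, int]:
    """Token index -> lattice site (row-major)."""
    return tuple(int(v) for v in np.unravel_index(k, lattice))  # type: ignore[return-value]


def tokens_from_feature_map(fmap: np.ndarray) -> np.ndarray:
    """(C, tx, ty, tz) feature map -> (n_tokens, C) token matrix, row-major."""
    c = fmap.shape[0]
    return np.ascontiguousarray(fmap.reshape(c, -1).T)


def feature_map_from_tokens(tokens: np.ndarray, lattice) -> np.ndarray:
    """(n_tokens, C) -> (C, tx, ty, tz), inverse of tokens_from_feature_map."""
    n, c = tokens.shape
    if n != int(np.prod(lattice)):
        raise ValueError(f"{n} tokens cannot fill lattice {lattice}")
    return np.ascontiguousarray(tokens.T.reshape(c, *lattice))


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def mix_attention(
    query: np.ndarray, key: np.ndarray, value: np.ndarray, return_weights: bool = False
):
    """Scaled dot-product cross-attention.

    ``query``: (n_q, d) moving-image tokens; ``key``/``value``: (n_kv, d)
    fixed-image tokens.  Output row k is ``sum_j softmax_j(q_k . k_j / sqrt(d))
    v_j``; every row of the attention-weight matrix sums to one.
    """
    query, key, value = (np.asarray(a, dtype=np.float64) for a in (query, key, value))
    if query.ndim != 2 or key.ndim != 2 or value.ndim != 2:
        raise ValueError("query/key/value must be 2D token matrices")
    if query.shape[1] != key.shape[1]:
        raise ValueError(
            f"query dim {query.shape[1]} != key dim {key.shape[1]}"
        )
    if key.shape[0] != value.shape[0]:
        raise ValueError("key and value must hold the same number of tokens")
    d = query.shape[1]
    scores = query @ key.T / np.sqrt(d)
    weights = softmax(scores, axis=1)
    out = weights @ value
    if return_weights:
        return out, weights
    return out


class MixAttention:
    """Parameter-free attention layer with an explicit backward pass."""

    def __init__(self) -> None:
        self._cache = None

    def params(self):
        return []

    def forward(self, query: np.ndarray, key: np.ndarray, value: np.ndarray) -> np.ndarray:
        out, weights = mix_attention(query, key, value, return_weights=True)
        self._cache = (query, key, value, weights)
        return out

    def backward(self, g_out: np.ndarray):
        query, key, value, p = self._cache
        d = query.shape[1]
        g_v = p.T @ g_out
        g_p = g_out @ value.T
        # softmax backward per row
        g_s = p * (g_p - (g_p * p).sum(axis=1, keepdims=True))
        g_q = g_s @ key / np.sqrt(d)
        g_k = g_s.T @ query / np.sqrt(d)
        return g_q, g_k, g_v
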