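"""Co-occurrence word embeddings (GloVe-style weighted least squares).

Embeddings are fit to the word-word co-occurrence matrix of the whole
corpus by minimizing

    sum_ij f(X_ij) (w_i . w~_j + b_i + b~_j - log X_ij)^2,
    f(x) = min(1, (x / x_max)^alpha),

with full-batch AdaGrad over the nonzero co-occurrence pairs, which makes
training deterministic given the seed used for initialization. The final
vector for a token is w + w~ as usual.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .text import preprocess  # noqa: F401  (re-exported convenience)


class EmbeddingError(ValueError):
    pass


@dataclass
class EmbeddingTable:
    vocab: dict[str, int]
    vectors: np.ndarray  # (V, d)
    d: int

    def __post_init__(self) -> None:
        if self.d < 2:
            raise EmbeddingError("embedding dimension must be >= 2")
        if self.vectors.shape != (len(self.vocab), self.d):
            raise EmbeddingError("vector matrix does not match vocabulary")
        if not np.all(np.isfinite(self.vectors)):
            raise EmbeddingError("non-finite embedding vectors")

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[self.vocab[token]]

    def cosine(self, a: str, b: str) -> float:
        va, vb = self.vector(a), self.vector(b)
        return float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))


def build_cooccurrence(
    corpus: list[list[str]], window: int = 5
) -> tuple[dict[str, int], np.ndarray, np.ndarray, np.ndarray]:
    """Symmetric, distance-weighted co-occurrence counts.

    Returns (vocab, i_idx, j_idx, counts) over nonzero pairs with i < j
    folded into both directions' totals (the objective is symmetric in the
    final w + w~ vectors).
    """
    vocab: dict[str, int] = {}
    for doc in corpus:
        for tok in doc:
            if tok not in vocab:
                vocab[tok] = len(vocab)
    if len(vocab) < 2:
        raise EmbeddingError("vocabulary must contain at least 2 tokens")
    counts: dict[tuple[int, int], float] = {}
    for doc in corpus:
        idx = [vocab[t] for t in doc]
        for pos, i in enumerate(idx):
            for off in range(1, window + 1):
                if pos + off >= len(idx):
                    break
                j = idx[pos + off]
                if i == j:
                    continue
                key = (i, j) if i < j else (j, i)
                counts[key] = counts.get(key, 0.0) + 1.0 / off
    if not counts:
        # degenerate corpus (e.g. one token per doc): uniform tiny counts
        ids = list(vocab.values())
        counts = {(ids[0], ids[1]): 1.0}
    keys = sorted(counts)
    i_idx = np.array([k[0] for k in keys], dtype=np.int64)
    j_idx = np.array([k[1] for k in keys], dtype=np.int64)
    x = np.array([counts[k] for k in keys])
    return vocab, i_idx, j_idx, x


def train_embeddings(
    corpus: list[list[str]],
    d: int = 50,
    window: int = 5,
    epochs: int = 25,
    seed: int = 0,
    x_max: float = 100.0,
    alpha: float = 0.75,
    lr: float = 0.05,
) -> EmbeddingTable:
    """Fit co-occurrence embeddings on tokenized documents."""
    if not corpus:
        raise EmbeddingError("corpus must be nonempty")
    vocab, i_idx, j_idx, x = build_cooccurrence(corpus, window=window)
    v = len(vocab)
    rng = np.random.default_rng(seed)
    w = (rng.uniform(-0.5, 0.5, (v, d)) / d).astype(np.float64)
    wc = (rng.uniform(-0.5, 0.5, (v, d)) / d).astype(np.float64)
    b = np.zeros(v)
    bc = np.zeros(v)
    gw = np.full((v, d), 1e-8)
    gwc = np.full((v, d), 1e-8)
    gb = np.full(v, 1e-8)
    gbc = np.full(v, 1e-8)
    logx = np.log(x)
    f = np.minimum(1.0, (x / x_max) ** alpha)
    for _ in range(epochs):
        wi, wj = w[i_idx], wc[j_idx]
        diff = np.einsum("nd,nd->n", wi, wj) + b[i_idx] + bc[j_idx] - logx
        g = f * diff  # (N,)
        grad_wi = g[:, None] * wj
        grad_wj = g[:, None] * wi
        dw = np.zeros_like(w)
        dwc = np.zeros_like(wc)
        db = np.zeros_like(b)
        dbc = np.zeros_like(bc)
        np.add.at(dw, i_idx, grad_wi)
        np.add.at(dwc, j_idx, grad_wj)
        np.add.at(db, i_idx, g)
        np.add.at(dbc, j_idx, g)
        gw += dw**2
        gwc += dwc**2
        gb += db**2
        gbc += dbc**2
        w -= lr * dw / np.sqrt(gw)
        wc -= lr * dwc / np.sqrt(gwc)
        b -= lr * db / np.sqrt(gb)
        bc -= lr * dbc / np.sqrt(gbc)
    return EmbeddingTable(vocab=vocab, vectors=w + wc, d=d)
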