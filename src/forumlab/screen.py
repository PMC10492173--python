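"""Post screening: flag posts likely to contain laboratory results.

Two interchangeable classifiers share the ``predict_proba(token_seqs)``
interface:

* :class:`ScreenModel` — a small text CNN over frozen co-occurrence
  embeddings: embedding lookup → parallel 1-D convolutions of widths
  {2,3,4,5} (32 filters each, ReLU) → global max pooling → one dense unit →
  sigmoid, trained with Adam on binary cross-entropy and early stopping on
  a held-out split. Implemented directly in numpy; the parameter count is a
  few tens of thousands, so CPU training on a few hundred labeled posts
  takes seconds.
* :class:`KeywordScreen` — a transparent rule: a post is flagged when it
  contains both a number token and a test-name/unit trigger token. It
  serves as a fast, fully interpretable baseline and may stand in for the
  CNN anywhere downstream.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .catalog import TestCatalog
from .glove import EmbeddingTable
from .text import NUM_TOKEN, preprocess
from .types import ForumPost


class ScreenError(ValueError):
    pass


@dataclass
class ScreenHyper:
    widths: tuple[int, ...] = (2, 3, 4, 5)
    n_filters: int = 32
    max_len: int = 64
    lr: float = 1e-3
    epochs: int = 40
    batch_size: int = 32
    holdout_frac: float = 0.25
    patience: int = 6
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ScreenError("threshold must be in (0,1)")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class ScreenModel:
    """Fitted convolutional screen. Use :func:`train_screen` to build one."""

    def __init__(
        self,
        embeddings: EmbeddingTable,
        hyper: ScreenHyper,
        params: dict[str, np.ndarray],
        holdout: Optional[list[tuple[list[str], bool]]] = None,
    ):
        self.embeddings = embeddings
        self.hyper = hyper
        self.params = params
        self.holdout = holdout or []
        # row 0 is the shared PAD/OOV zero vector
        self._E = np.vstack([np.zeros(embeddings.d), embeddings.vectors])
        self._index = {tok: i + 1 for tok, i in embeddings.vocab.items()}
        for key, val in params.items():
            if not np.all(np.isfinite(val)):
                raise ScreenError(f"non-finite weights in {key}")

    @property
    def threshold(self) -> float:
        return self.hyper.threshold

    def encode(self, seqs: Sequence[list[str]]) -> np.ndarray:
        L = self.hyper.max_len
        X = np.zeros((len(seqs), L), dtype=np.int64)
        for r, seq in enumerate(seqs):
            for c, tok in enumerate(seq[:L]):
                X[r, c] = self._index.get(tok, 0)
        return X

    def _forward(self, X: np.ndarray, want_cache: bool = False):
        B, L = X.shape
        emb = self._E[X]  # (B, L, d)
        pooled_parts, cache = [], []
        for w in self.hyper.widths:
            W, b = self.params[f"W{w}"], self.params[f"b{w}"]
            win = sliding_window_view(emb, w, axis=1)  # (B, P, d, w)
            win = win.transpose(0, 1, 3, 2).reshape(B, L - w + 1, -1)
            Z = win @ W + b
            A = np.maximum(Z, 0.0)
            pooled_parts.append(A.max(axis=1))
            if want_cache:
                cache.append((w, win, Z, A.argmax(axis=1)))
        h = np.concatenate(pooled_parts, axis=1)  # (B, widths*F)
        logit = h @ self.params["v"] + self.params["c"][0]
        p = _sigmoid(logit)
        return (p, h, cache) if want_cache else p

    def predict_proba(self, seqs: Sequence[list[str]]) -> np.ndarray:
        if len(seqs) == 0:
            return np.zeros(0)
        return self._forward(self.encode(seqs))

    # -- persistence: npz weights + json hyperparameter sidecar ------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        vocab_tokens = sorted(self.embeddings.vocab, key=self.embeddings.vocab.get)
        np.savez(
            path,
            vectors=self.embeddings.vectors,
            **{k: v for k, v in self.params.items()},
        )
        sidecar = {
            "hyper": {
                "widths": list(self.hyper.widths),
                "n_filters": self.hyper.n_filters,
                "max_len": self.hyper.max_len,
                "threshold": self.hyper.threshold,
            },
            "vocab": vocab_tokens,
            "d": self.embeddings.d,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "ScreenModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        blob = np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path)
        hyper = ScreenHyper(
            widths=tuple(sidecar["hyper"]["widths"]),
            n_filters=sidecar["hyper"]["n_filters"],
            max_len=sidecar["hyper"]["max_len"],
            threshold=sidecar["hyper"]["threshold"],
        )
        table = EmbeddingTable(
            vocab={t: i for i, t in enumerate(sidecar["vocab"])},
            vectors=blob["vectors"],
            d=sidecar["d"],
        )
        params = {k: blob[k] for k in blob.files if k != "vectors"}
        return cls(table, hyper, params)


def _init_params(
    hyper: ScreenHyper, d: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    params: dict[str, np.ndarray] = {}
    for w in hyper.widths:
        fan_in = w * d
        params[f"W{w}"] = rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, hyper.n_filters))
        params[f"b{w}"] = np.zeros(hyper.n_filters)
    params["v"] = rng.normal(0, 0.05, len(hyper.widths) * hyper.n_filters)
    params["c"] = np.zeros(1)
    return params


def train_screen(
    labeled: Sequence[tuple[list[str], bool]],
    embeddings: EmbeddingTable,
    hyper: Optional[ScreenHyper] = None,
    seed: int = 0,
) -> ScreenModel:
    """Train the convolutional screen on labeled token sequences.

    A stratified held-out split (``holdout_frac``) is reserved for
    evaluation and early stopping and attached to the returned model.
    """
    hyper = hyper or ScreenHyper()
    labels = np.array([bool(y) for _, y in labeled])
    if labels.all() or not labels.any():
        raise ScreenError("training data must contain both classes")
    rng = np.random.default_rng(seed)

    # stratified holdout
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    rng.shuffle(pos)
    rng.shuffle(neg)
    n_hold_p = max(1, int(len(pos) * hyper.holdout_frac))
    n_hold_n = max(1, int(len(neg) * hyper.holdout_frac))
    hold_idx = np.concatenate([pos[:n_hold_p], neg[:n_hold_n]])
    train_idx = np.concatenate([pos[n_hold_p:], neg[n_hold_n:]])
    if not (labels[train_idx].any() and (~labels[train_idx]).any()):
        raise ScreenError("training split lost a class; provide more data")

    model = ScreenModel(
        embeddings, hyper, _init_params(hyper, embeddings.d, rng),
        holdout=[labeled[i] for i in hold_idx],
    )
    X_all = model.encode([labeled[i][0] for i in range(len(labeled))])
    y_all = labels.astype(float)
    Xtr, ytr = X_all[train_idx], y_all[train_idx]
    Xho, yho = X_all[hold_idx], y_all[hold_idx]

    m = {k: np.zeros_like(p) for k, p in model.params.items()}
    vel = {k: np.zeros_like(p) for k, p in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_loss, best_params, stale = np.inf, None, 0

    def holdout_loss() -> float:
        p = model._forward(Xho)
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return float(-np.mean(yho * np.log(p) + (1 - yho) * np.log(1 - p)))

    order = np.arange(len(train_idx))
    for _ in range(hyper.epochs):
        rng.shuffle(order)
        for start in range(0, len(order), hyper.batch_size):
            batch = order[start:start + hyper.batch_size]
            Xb, yb = Xtr[batch], ytr[batch]
            grads = _backward(model, Xb, yb)
            step += 1
            for k in model.params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                vel[k] = beta2 * vel[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1**step)
                vhat = vel[k] / (1 - beta2**step)
                model.params[k] -= hyper.lr * mhat / (np.sqrt(vhat) + eps)
        loss = holdout_loss()
        if loss < best_loss - 1e-5:
            best_loss, stale = loss, 0
            best_params = {k: p.copy() for k, p in model.params.items()}
        else:
            stale += 1
            if stale >= hyper.patience:
                break
    if best_params is not None:
        model.params = best_params
    return model


def _backward(model: ScreenModel, X: np.ndarray, y: np.ndarray) -> dict:
    p, h, cache = model._forward(X, want_cache=True)
    B = len(y)
    dlogit = (p - y) / B
    grads = {
        "v": h.T @ dlogit,
        "c": np.array([dlogit.sum()]),
    }
    F = model.hyper.n_filters
    for k, (w, win, Z, amax) in enumerate(cache):
        dpool = np.outer(dlogit, model.params["v"][k * F:(k + 1) * F])  # (B,F)
        dZ = np.zeros_like(Z)
        rows = np.arange(B)[:, None]
        cols = np.arange(F)[None, :]
        dZ[rows, amax, cols] = dpool
        dZ *= Z > 0
        grads[f"W{w}"] = np.einsum("bpk,bpf->kf", win, dZ)
        grads[f"b{w}"] = dZ.sum(axis=(0, 1))
    return grads


def screen(
    model, posts: Iterable[ForumPost], threshold: Optional[float] = None
) -> list[tuple[str, float, bool]]:
    """Apply a classifier to posts: (post id, probability, flag), input order."""
    posts = list(posts)
    thr = model.threshold if threshold is None else threshold
    probs = model.predict_proba([preprocess(p.text) for p in posts])
    return [(p.id, float(pr), bool(pr >= thr)) for p, pr in zip(posts, probs)]


def evaluate_screen(model, labeled: Sequence[tuple[list[str], bool]]) -> dict:
    """Accuracy and confusion counts on a labeled (held-out) set."""
    if len(labeled) == 0:
        raise ScreenError("evaluation set is empty")
    probs = model.predict_proba([seq for seq, _ in labeled])
    pred = probs >= model.threshold
    truth = np.array([bool(y) for _, y in labeled])
    tp = int(np.sum(pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    return {
        "accuracy": (tp + tn) / len(labeled),
        "tp": tp, "tn": tn, "fp": fp, "fn": fn, "n": len(labeled),
    }


class KeywordScreen:
    """Rule baseline: number token + test-name/unit trigger token."""

    def __init__(self, catalog: Optional[TestCatalog] = None, threshold: float = 0.5):
        catalog = catalog or TestCatalog.default()
        self.threshold = threshold
        triggers: set[str] = set()
        for entry in catalog:
            for syn in entry.synonyms:
                triggers.update(preprocess(syn))
            for unit in entry.units:
                triggers.update(preprocess(unit))
        triggers.discard(NUM_TOKEN)
        # single letters are too promiscuous to be triggers
        self.triggers = {t for t in triggers if len(t) > 1}

    def predict_proba(self, seqs: Sequence[list[str]]) -> np.ndarray:
        out = np.zeros(len(seqs))
        for i, seq in enumerate(seqs):
            toks = set(seq)
            if NUM_TOKEN in toks and toks & self.triggers:
                out[i] = 1.0
        return out
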