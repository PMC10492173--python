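"""Tokenizer, co-occurrence embeddings, and the convolutional screen."""
import numpy as np
import pytest

from forumlab.glove import EmbeddingError, train_embeddings
from forumlab.screen import (
    KeywordScreen,
    ScreenError,
    ScreenHyper,
    evaluate_screen,
    screen,
    train_screen,
)
from forumlab.text import NUM_TOKEN, preprocess
from forumlab.types import ForumPost


@pytest.mark.parametrize(
    "text,expected",
    [
        ("My FSH was 5.5!", ["my", "fsh", "was", NUM_TOKEN]),
        ("", []),
        # documented tokenizer rule: slashes split tokens
        ("LH/FSH 2.2", ["lh", "fsh", NUM_TOKEN]),
        ("DHEA-S: 328 ug/dL", ["dhea", "s", NUM_TOKEN, "ug", "dl"]),
        ("a1c 5.5% fasting", ["a", NUM_TOKEN, "c", NUM_TOKEN, "%", "fasting"]),
    ],
)
def test_preprocess(text, expected):
    assert preprocess(text) == expected


def _toy_corpus():
    # A and B always co-occur; C lives elsewhere
    docs = [["aa", "bb", "filler"] for _ in range(30)]
    docs += [["cc", "other", "words"] for _ in range(30)]
    return docs


def test_embeddings_reflect_cooccurrence():
    table = train_embeddings(_toy_corpus(), d=8, window=3, epochs=60, seed=0)
    assert table.cosine("aa", "bb") > table.cosine("aa", "cc")


def test_embeddings_degenerate_single_doc():
    table = train_embeddings([["only", "two"]], d=2, window=2, epochs=5, seed=0)
    assert np.all(np.isfinite(table.vectors))


def test_embeddings_determinism():
    t1 = train_embeddings(_toy_corpus(), d=4, window=2, epochs=10, seed=3)
    t2 = train_embeddings(_toy_corpus(), d=4, window=2, epochs=10, seed=3)
    assert np.array_equal(t1.vectors, t2.vectors)


def test_embeddings_tiny_vocab_error():
    with pytest.raises(EmbeddingError):
        train_embeddings([["one"]], d=2)


def _separable_labeled(n=200, seed=0):
    """Posts separable by the presence of unit tokens; keyword oracle is
    near-perfect here, and the learned screen must approach it."""
    rng = np.random.default_rng(seed)
    fillers = ["so", "tired", "today", "help", "advice", "doctor", "week"]
    labeled = []
    for i in range(n):
        words = list(rng.choice(fillers, size=6))
        if i % 2 == 0:
            words += ["fsh", "was", "5.5", "u/l"]
            label = True
        else:
            words += ["been", "waiting", "2", "weeks"]
            label = False
        labeled.append((preprocess(" ".join(words)), label))
    return labeled


@pytest.fixture(scope="module")
def toy_embeddings():
    docs = [seq for seq, _ in _separable_labeled(300, seed=5)]
    return train_embeddings(docs, d=16, window=4, epochs=30, seed=1)


def test_screen_learns_separable_corpus(toy_embeddings):
    labeled = _separable_labeled(200, seed=2)
    hyper = ScreenHyper(epochs=25, batch_size=16)
    model = train_screen(labeled, toy_embeddings, hyper, seed=0)
    metrics = evaluate_screen(model, model.holdout)
    assert metrics["accuracy"] >= 0.95


def test_screen_label_symmetry(toy_embeddings):
    labeled = _separable_labeled(200, seed=2)
    flipped = [(seq, not y) for seq, y in labeled]
    hyper = ScreenHyper(epochs=25, batch_size=16)
    acc = evaluate_screen(
        (m := train_screen(labeled, toy_embeddings, hyper, seed=0)), m.holdout
    )["accuracy"]
    acc_flipped = evaluate_screen(
        (m := train_screen(flipped, toy_embeddings, hyper, seed=0)), m.holdout
    )["accuracy"]
    assert acc_flipped == pytest.approx(acc, abs=0.05)


def test_screen_determinism(toy_embeddings):
    labeled = _separable_labeled(120, seed=4)
    hyper = ScreenHyper(epochs=8, batch_size=16)
    m1 = train_screen(labeled, toy_embeddings, hyper, seed=9)
    m2 = train_screen(labeled, toy_embeddings, hyper, seed=9)
    seqs = [s for s, _ in labeled]
    assert np.array_equal(m1.predict_proba(seqs), m2.predict_proba(seqs))


def test_single_class_training_error(toy_embeddings):
    labeled = [(["a", "b"], True)] * 10
    with pytest.raises(ScreenError):
        train_screen(labeled, toy_embeddings)


def test_probabilities_bounded_and_threshold_monotone(toy_embeddings):
    labeled = _separable_labeled(150, seed=6)
    model = train_screen(
        labeled, toy_embeddings, ScreenHyper(epochs=10, batch_size=16), seed=1
    )
    posts = [
        ForumPost(id=f"p{i}", author="u", created_utc=0, title="t",
                  selftext=" ".join(seq))
        for i, (seq, _) in enumerate(labeled[:40])
    ]
    out_lo = screen(model, posts, threshold=0.3)
    out_hi = screen(model, posts, threshold=0.8)
    assert [pid for pid, _, _ in out_lo] == [p.id for p in posts]  # order kept
    for (_, p, _) in out_lo:
        assert 0.0 <= p <= 1.0
    flagged_hi = {pid for pid, _, f in out_hi if f}
    flagged_lo = {pid for pid, _, f in out_lo if f}
    assert flagged_hi <= flagged_lo  # raising threshold never adds posts


def test_screen_empty_input(toy_embeddings):
    labeled = _separable_labeled(60, seed=8)
    model = train_screen(
        labeled, toy_embeddings, ScreenHyper(epochs=5, batch_size=16), seed=1
    )
    assert screen(model, []) == []


def test_evaluate_counts_recount():
    """Accuracy always equals (TP+TN)/total recomputed from the counts."""
    model = KeywordScreen()
    labeled = [
        (preprocess("fsh was 5.5 u/l"), True),
        (preprocess("lh 12 miu/ml"), True),
        (preprocess("feeling tired again"), False),
        (preprocess("been 2 weeks no period"), False),
        (preprocess("fsh results pending"), False),  # no number -> negative
    ]
    m = evaluate_screen(model, labeled)
    assert m["tp"] + m["tn"] + m["fp"] + m["fn"] == m["n"] == len(labeled)
    assert m["accuracy"] == (m["tp"] + m["tn"]) / m["n"]


def test_evaluate_empty_error():
    with pytest.raises(ScreenError):
        evaluate_screen(KeywordScreen(), [])


def test_evaluate_constant_negative_on_all_negative():
    class Never:
        threshold = 0.5

        def predict_proba(self, seqs):
            return np.zeros(len(seqs))

    m = evaluate_screen(Never(), [(["x"], False)] * 7)
    assert m["accuracy"] == 1.0 and m["tp"] == 0 and m["fp"] == 0


def test_model_persistence_round_trip(tmp_path, toy_embeddings):
    from forumlab.screen import ScreenModel

    labeled = _separable_labeled(80, seed=3)
    model = train_screen(
        labeled, toy_embeddings, ScreenHyper(epochs=5, batch_size=16), seed=2
    )
    model.save(tmp_path / "model.npz")
    loaded = ScreenModel.load(tmp_path / "model.npz")
    seqs = [s for s, _ in labeled[:20]]
    assert np.allclose(model.predict_proba(seqs), loaded.predict_proba(seqs))
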