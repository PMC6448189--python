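import logging
import math

import numpy as np
import pytest

import settinglink as sl
from settinglink.errors import DataError
from settinglink.lda import DEFAULT_K_GRID


def _disjoint_docs(n_per_group=20, length=12, seed=0):
    """Two document groups with disjoint vocabularies."""
    rng = np.random.default_rng(seed)
    vocab_a = [f"A{i}" for i in range(10)]
    vocab_b = [f"B{i}" for i in range(10)]
    docs = []
    for _ in range(n_per_group):
        docs.append(list(rng.choice(vocab_a, size=length)))
    for _ in range(n_per_group):
        docs.append(list(rng.choice(vocab_b, size=length)))
    return docs, vocab_a, vocab_b


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_single_topic_degeneracy():
    docs = [["x", "y", "x"], ["y", "z"]]
    model = sl.fit_lda(docs, 1, beta=0.1, iterations=20, burnin=20, seed=1)
    np.testing.assert_allclose(model.theta, 1.0)
    counts = {"x": 2, "y": 2, "z": 1}
    v, n = 3, 5
    expected = np.array([(counts[w] + 0.1) / (n + v * 0.1)
                         for w in model.vocabulary])
    np.testing.assert_allclose(model.phi[0], expected, rtol=1e-12)


def test_simplex_invariants_and_assignment_range(small_data):
    corpus, _, _ = small_data
    model = sl.fit_lda(corpus, 4, iterations=50, burnin=50, seed=2)
    np.testing.assert_allclose(model.phi.sum(axis=1), 1.0, atol=1e-9)
    np.testing.assert_allclose(model.theta.sum(axis=1), 1.0, atol=1e-9)
    assert (model.phi >= 0).all() and (model.theta >= 0).all()
    assert model.z.min() >= 0 and model.z.max() < 4


def test_disjoint_groups_recovered():
    docs, _, _ = _disjoint_docs()
    hits = 0
    for seed in range(5):
        model = sl.fit_lda(docs, 2, alpha=0.1, iterations=200, burnin=200,
                           seed=seed)
        share = (model.theta.max(axis=1) > 0.9).mean()
        hits += share >= 0.9
    assert hits >= 3


def test_fit_rejects_bad_inputs():
    with pytest.raises(DataError, match="empty"):
        sl.fit_lda([["a"], []], 2)
    with pytest.raises(DataError):
        sl.fit_lda([["a"]], 0)
    with pytest.raises(DataError):
        sl.fit_lda([["a"]], 2, iterations=5, burnin=10)


def test_fit_deterministic_given_seed():
    docs, _, _ = _disjoint_docs(n_per_group=5, seed=3)
    m1 = sl.fit_lda(docs, 2, iterations=50, burnin=50, seed=11)
    m2 = sl.fit_lda(docs, 2, iterations=50, burnin=50, seed=11)
    np.testing.assert_array_equal(m1.z, m2.z)
    np.testing.assert_array_equal(m1.phi, m2.phi)


def test_debug_mode_validates_counts():
    docs, _, _ = _disjoint_docs(n_per_group=4, length=6)
    sl.fit_lda(docs, 2, iterations=5, burnin=5, seed=4, debug=True)


def test_document_order_invariant_structure():
    """Reversing document order still assigns each vocabulary block one topic."""
    docs, vocab_a, vocab_b = _disjoint_docs()
    for ordered in (docs, docs[::-1]):
        model = sl.fit_lda(ordered, 2, iterations=200, burnin=200, seed=5)
        ttm = sl.term_topic_probabilities(model)
        idx = {w: i for i, w in enumerate(ttm.vocabulary)}
        top_a = {ttm.matrix[idx[w]].argmax() for w in vocab_a}
        top_b = {ttm.matrix[idx[w]].argmax() for w in vocab_b}
        assert len(top_a) == 1 and len(top_b) == 1 and top_a != top_b


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def test_log_likelihood_empty_corpus_is_zero():
    model = sl.fit_lda([], 3, vocabulary=["a", "b", "c"], iterations=0, burnin=0)
    assert sl.log_likelihood(model) == pytest.approx(0.0, abs=1e-9)


def test_log_likelihood_single_token_closed_form():
    for v in (3, 7, 20):
        vocab = [f"w{i}" for i in range(v)]
        model = sl.fit_lda([["w0"]], 1, vocabulary=vocab, iterations=5, burnin=5)
        assert sl.log_likelihood(model) == pytest.approx(-math.log(v), abs=1e-9)


def test_log_likelihood_matches_gamma_recurrence_brute_force():
    """lnΓ(n+β) − lnΓ(β) = Σ ln(β+i): evaluate the collapsed likelihood by
    cumulative products on a tiny corpus and compare."""
    docs = [["a", "b", "a"], ["b", "c"], ["c", "c", "a", "b"]]
    model = sl.fit_lda(docs, 2, beta=0.3, iterations=30, burnin=30, seed=6)
    beta, V, K = model.beta, model.n_vocab, model.n_topics

    def log_rising(base, n):
        return sum(math.log(base + i) for i in range(int(n)))

    ll = 0.0
    for k in range(K):
        for w in range(V):
            ll += log_rising(beta, model.n_kw[k, w])
        ll -= log_rising(V * beta, model.n_k[k])
    assert sl.log_likelihood(model) == pytest.approx(ll, abs=1e-6)


def test_final_likelihood_above_initial_state():
    docs, _, _ = _disjoint_docs(n_per_group=10, length=10, seed=7)
    model = sl.fit_lda(docs, 2, iterations=100, burnin=100, seed=8)
    assert sl.log_likelihood(model) > model.init_log_likelihood


# ---------------------------------------------------------------------------
# topic-number selection
# ---------------------------------------------------------------------------

def test_default_selection_grid_is_5_to_150_by_5():
    assert DEFAULT_K_GRID == tuple(range(5, 151, 5))


def test_singleton_grid_wins_by_default():
    docs, _, _ = _disjoint_docs(n_per_group=4, length=6)
    best, table = sl.select_num_topics(docs, grid=[7], iterations=10, burnin=10)
    assert best == 7 and list(table["K"]) == [7]


def test_planted_topic_count_recovered():
    hits = 0
    for seed in range(5):
        docs, _, _ = sl.generate_lda_corpus(5, 50, 150, 25.0,
                                            doc_concentration=0.02, seed=seed)
        best, _ = sl.select_num_topics(docs, grid=range(2, 11), seed=seed,
                                       alpha=0.1, iterations=150, burnin=150)
        hits += best in {4, 5, 6}
    assert hits >= 4


# ---------------------------------------------------------------------------
# held-out inference
# ---------------------------------------------------------------------------

def test_inference_self_consistency():
    docs, _, _ = _disjoint_docs(n_per_group=15, length=15, seed=9)
    model = sl.fit_lda(docs, 2, iterations=200, burnin=200, seed=10)
    res = sl.infer_topics(model, docs, iterations=250, burnin=200, seed=11)
    r = np.corrcoef(model.theta.ravel(), res.theta.ravel())[0, 1]
    assert r > 0.9


def test_exclusive_terms_drive_inferred_topic():
    docs, vocab_a, _ = _disjoint_docs()
    model = sl.fit_lda(docs, 2, alpha=0.1, iterations=200, burnin=200, seed=12)
    ttm = sl.term_topic_probabilities(model)
    idx = {w: i for i, w in enumerate(ttm.vocabulary)}
    topic_a = int(np.argmax(ttm.matrix[idx[vocab_a[0]]]))
    res = sl.infer_topics(model, [vocab_a[:5] * 4], iterations=250, burnin=200,
                          seed=13)
    assert res.theta[0, topic_a] > 0.8


def test_oov_and_empty_documents(caplog):
    docs, vocab_a, _ = _disjoint_docs(n_per_group=5)
    model = sl.fit_lda(docs, 2, iterations=50, burnin=50, seed=14)
    with caplog.at_level(logging.WARNING):
        res = sl.infer_topics(model, [["ZZZ", "QQQ"], vocab_a[:3]],
                              iterations=60, burnin=50, seed=15)
    np.testing.assert_allclose(res.theta[0], 0.5, atol=1e-12)
    assert res.n_oov_tokens == 2
    assert any("out-of-vocabulary" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# term-topic probabilities
# ---------------------------------------------------------------------------

def test_term_topic_rows_normalized_and_k1_trivial():
    docs = [["a", "b"], ["b", "c"]]
    m1 = sl.fit_lda(docs, 1, iterations=10, burnin=10)
    ttm1 = sl.term_topic_probabilities(m1)
    np.testing.assert_allclose(ttm1.matrix, 1.0)
    m3 = sl.fit_lda(docs, 3, iterations=10, burnin=10, seed=16)
    ttm3 = sl.term_topic_probabilities(m3)
    np.testing.assert_allclose(ttm3.matrix.sum(axis=1), 1.0, atol=1e-9)


def test_unobserved_term_flagged_uniform():
    model = sl.fit_lda([["a", "b"]], 2, vocabulary=["a", "b", "ghost"],
                       iterations=10, burnin=10, seed=17)
    ttm = sl.term_topic_probabilities(model)
    gi = ttm.vocabulary.index("ghost")
    assert not ttm.observed[gi]
    np.testing.assert_allclose(ttm.matrix[gi], 0.5, atol=1e-12)


def test_exclusive_term_concentrates():
    docs, vocab_a, vocab_b = _disjoint_docs()
    model = sl.fit_lda(docs, 2, alpha=0.1, iterations=200, burnin=200, seed=18)
    ttm = sl.term_topic_probabilities(model)
    idx = {w: i for i, w in enumerate(ttm.vocabulary)}
    for w in vocab_a + vocab_b:
        assert ttm.matrix[idx[w]].max() > 0.9


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_model_save_load_round_trip(tmp_path):
    docs, _, _ = _disjoint_docs(n_per_group=5)
    model = sl.fit_lda(docs, 2, iterations=50, burnin=50, seed=19)
    sl.save_model(model, tmp_path / "model")
    loaded = sl.load_model(tmp_path / "model")
    assert loaded.vocabulary == model.vocabulary
    np.testing.assert_allclose(loaded.phi, model.phi)
    np.testing.assert_allclose(loaded.theta, model.theta)
    assert sl.log_likelihood(loaded) == pytest.approx(sl.log_likelihood(model))
    res = sl.infer_topics(loaded, docs[:2], iterations=30, burnin=20, seed=20)
    assert res.theta.shape == (2, 2)
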