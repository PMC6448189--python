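import numpy as np
import pytest
from scipy.stats import pearsonr

import settinglink as sl
from settinglink.errors import DataError
from settinglink.evaluate import RankedPrediction, assign_folds, mean_metrics
from settinglink.profiles import SettingProfile


def _profile(name, vec):
    return SettingProfile(name, np.asarray(vec, dtype=float), 1)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def test_exact_match_ranks_first_with_unit_correlation():
    train = [_profile("X", [0.1, 0.2, 0.7]), _profile("Y", [0.6, 0.3, 0.1])]
    pred = sl.predict_settings(train, _profile("X", [0.1, 0.2, 0.7]))
    assert pred.ranking[0][0] == "X"
    assert pred.ranking[0][1] == pytest.approx(1.0, abs=1e-12)
    assert len(pred.ranking) == 2


def test_three_profile_ranking_matches_hand_computation():
    train = [
        _profile("A", [0.7, 0.2, 0.1]),
        _profile("B", [0.1, 0.2, 0.7]),
        _profile("C", [0.3, 0.4, 0.3]),
    ]
    test = _profile("q", [0.6, 0.3, 0.1])
    pred = sl.predict_settings(train, test)
    expected = sorted(
        ((p.setting, pearsonr(p.vector, test.vector).statistic) for p in train),
        key=lambda sr: -sr[1])
    assert [c for c, _ in pred.ranking] == [c for c, _ in expected]
    for (_, r1), (_, r2) in zip(pred.ranking, expected):
        assert r1 == pytest.approx(r2, rel=1e-9)


def test_ties_broken_lexicographically():
    v = [0.5, 0.3, 0.2]
    train = [_profile("Zeta", v), _profile("Alpha", v)]
    pred = sl.predict_settings(train, _profile("q", v))
    assert [c for c, _ in pred.ranking] == ["Alpha", "Zeta"]


def test_constant_profile_errors():
    train = [_profile("A", [0.2, 0.3, 0.5]), _profile("B", [0.5, 0.3, 0.2])]
    with pytest.raises(DataError, match="constant"):
        sl.predict_settings(train, _profile("q", [1 / 3] * 3))


# ---------------------------------------------------------------------------
# @k metrics
# ---------------------------------------------------------------------------

def _ranked(true, names):
    n = len(names)
    return RankedPrediction(true, tuple(
        (name, 1.0 - i / n) for i, name in enumerate(names)))


def test_perfect_top1_gives_all_ones():
    preds = [_ranked(s, [s] + [o for o in "ABC" if o != s]) for s in "ABC"]
    m = sl.metrics_at_k(preds, 1, s_total=3)
    assert (m.tp, m.u, m.fp, m.fn) == (3, 3, 0, 0)
    assert m.precision == m.recall == m.f1 == 1.0


def test_hand_worked_three_setting_example():
    preds = [
        _ranked("A", ["B", "C", "A"]),
        _ranked("B", ["B", "C", "A"]),
        _ranked("C", ["A", "C", "B"]),
    ]
    m = sl.metrics_at_k(preds, 2, s_total=3)
    assert (m.tp, m.u, m.fp, m.fn) == (2, 3, 1, 1)
    assert m.precision == pytest.approx(2 / 3)
    assert m.recall == pytest.approx(2 / 3)
    assert m.f1 == pytest.approx(2 / 3)


def test_precision_equals_recall_when_union_saturates():
    """When every gold setting appears in some top-k list, U = S and the
    unique-union FP makes precision and recall coincide."""
    rng = np.random.default_rng(0)
    names = [f"S{i}" for i in range(6)]
    for _ in range(50):
        preds = []
        for s in names:
            order = list(rng.permutation(names))
            preds.append(_ranked(s, order))
        for k in (2, 4, 6):
            m = sl.metrics_at_k(preds, k, s_total=len(names))
            if m.u == len(names):
                assert m.precision == pytest.approx(m.recall)
                assert m.f1 == pytest.approx(m.recall)


def test_recall_non_decreasing_and_full_at_k_equal_s():
    rng = np.random.default_rng(1)
    names = [f"S{i}" for i in range(5)]
    preds = [_ranked(s, list(rng.permutation(names))) for s in names]
    recalls = [sl.metrics_at_k(preds, k, 5).recall for k in range(1, 6)]
    assert all(r2 >= r1 for r1, r2 in zip(recalls, recalls[1:]))
    full = sl.metrics_at_k(preds, 5, 5)
    assert full.precision == full.recall == full.f1 == 1.0
    assert (full.tp, full.u, full.fp, full.fn) == (5, 5, 0, 0)


def test_metric_input_validation():
    preds = [_ranked("A", ["A", "B"]), _ranked("B", ["A", "B"])]
    with pytest.raises(DataError):
        sl.metrics_at_k(preds, 3, 2)          # k beyond list length
    with pytest.raises(DataError):
        sl.metrics_at_k(preds + [_ranked("A", ["A", "B"])], 1, 2)  # dup true
    with pytest.raises(DataError):
        sl.metrics_at_k(preds, 0, 2)


def test_list_slots_fp_strategy():
    preds = [_ranked("A", ["B", "A"]), _ranked("B", ["B", "A"])]
    m = sl.metrics_at_k(preds, 1, 2, fp_strategy="list_slots")
    assert (m.tp, m.fp) == (1, 1)      # two slots, one correct


def test_ranking_container_invariants():
    with pytest.raises(DataError):
        RankedPrediction("A", (("B", 0.1), ("C", 0.5)))   # not sorted
    with pytest.raises(DataError):
        RankedPrediction("A", (("B", 0.5), ("B", 0.1)))   # duplicate


# ---------------------------------------------------------------------------
# fold assignment and cross-validation
# ---------------------------------------------------------------------------

def test_fold_assignment_partitions_and_stratifies(small_data):
    corpus, _, _ = small_data
    fold_of = assign_folds(corpus, 5, seed=3)
    assert set(fold_of) == {d.doc_id for d in corpus}
    for setting, docs in corpus.documents_by_setting().items():
        sizes = np.bincount([fold_of[d.doc_id] for d in docs], minlength=5)
        assert sizes.max() - sizes.min() <= 1


def test_fold_assignment_errors_on_tiny_setting():
    corpus = sl.Corpus([sl.ConceptDocument(f"d{i}", "Tiny", ("C1",))
                        for i in range(3)])
    with pytest.raises(DataError, match="Tiny"):
        assign_folds(corpus, 5, seed=0)


def _fast_lda_cfg():
    return sl.LDAConfig(n_topics=4, iterations=150, burnin=150,
                        infer_iterations=180, infer_burnin=150)


def test_cross_validation_deterministic_and_partitioned(small_data):
    corpus, _, db = small_data
    kwargs = dict(lda_cfg=_fast_lda_cfg(), folds=5, ks=(1, 2, 4), seed=19)
    r1 = sl.cross_validate(corpus, db, **kwargs)
    r2 = sl.cross_validate(corpus, db, **kwargs)
    assert r1.fold_of == r2.fold_of
    assert r1.mean == r2.mean
    counts = np.bincount(list(r1.fold_of.values()), minlength=5)
    assert counts.sum() == len(corpus)


def test_cross_validation_recovers_planted_settings(small_data):
    corpus, _, db = small_data
    res = sl.cross_validate(corpus, db, lda_cfg=_fast_lda_cfg(),
                            folds=5, ks=(1, 4), seed=19)
    assert res.mean[1]["recall"] >= 0.75
    assert res.mean[4]["recall"] == 1.0


def test_holdout_mode(small_data):
    corpus, _, db = small_data
    res = sl.evaluate_holdout(corpus, db, n_test_per_setting=5,
                              lda_cfg=_fast_lda_cfg(), ks=(1, 2), seed=23)
    assert len(res.per_fold) == 1
    held_out = [d for d, f in res.fold_of.items() if f == 0]
    assert len(held_out) == 5 * 4
    assert 0.0 <= res.mean[1]["recall"] <= 1.0


def test_mean_metrics_averages_counts_and_rates():
    a = sl.metrics_at_k([_ranked("A", ["A", "B"]), _ranked("B", ["A", "B"])], 1, 2)
    b = sl.metrics_at_k([_ranked("A", ["A", "B"]), _ranked("B", ["B", "A"])], 1, 2)
    mean = mean_metrics([{1: a}, {1: b}])
    assert mean[1]["tp"] == pytest.approx((a.tp + b.tp) / 2)
    assert mean[1]["recall"] == pytest.approx((a.recall + b.recall) / 2)
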