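import logging
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import chi2_contingency

import settinglink as sl
from settinglink.errors import DataError
from settinglink.filtering import (ContingencyTable, EnrichmentGlobal,
                                   enrichment_fold_per_concept)

# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

def test_contingency_from_toy_corpus(toy_corpus):
    t = sl.build_contingency(toy_corpus, "C0010054", "Cardiology")
    assert (t.a, t.b, t.c, t.d) == (2, 0, 0, 2)


def test_contingency_absent_concept(toy_corpus):
    t = sl.build_contingency(toy_corpus, "C9999999", "Cardiology")
    assert t.a == 0 and t.c == 0 and t.b + t.d == 4


def test_contingency_saturated_concept():
    corpus = sl.Corpus([
        sl.ConceptDocument("a", "X", ("C1",)),
        sl.ConceptDocument("b", "Y", ("C1",)),
    ])
    t = sl.build_contingency(corpus, "C1", "X")
    assert t.b == 0 and t.d == 0


def test_contingency_unknown_setting(toy_corpus):
    with pytest.raises(DataError, match="Oncology"):
        sl.build_contingency(toy_corpus, "C0010054", "Oncology")


# ---------------------------------------------------------------------------
# chi-square statistic
# ---------------------------------------------------------------------------

def test_chi2_independence_is_zero():
    assert sl.chi2_statistic(ContingencyTable(10, 10, 10, 10)) == 0.0


def test_chi2_closed_form_example():
    assert sl.chi2_statistic(ContingencyTable(30, 70, 10, 890)) == pytest.approx(
        195.60, abs=0.005)


def test_chi2_zero_margin_is_zero():
    assert sl.chi2_statistic(ContingencyTable(0, 0, 5, 5)) == 0.0
    assert sl.chi2_statistic(ContingencyTable(0, 5, 0, 5)) == 0.0


def test_chi2_all_zero_table_errors():
    with pytest.raises(DataError):
        sl.chi2_statistic(ContingencyTable(0, 0, 0, 0))


@given(st.tuples(*[st.integers(0, 200)] * 4))
def test_chi2_matches_scipy_reference(counts):
    a, b, c, d = counts
    t = ContingencyTable(a, b, c, d)
    if t.n == 0:
        return
    if min(a + b, c + d, a + c, b + d) == 0:
        assert sl.chi2_statistic(t) == 0.0
        return
    ref, _, _, _ = chi2_contingency([[a, b], [c, d]], correction=False)
    assert sl.chi2_statistic(t) == pytest.approx(float(ref), rel=1e-12, abs=1e-12)


# ---------------------------------------------------------------------------
# TF-IDF score
# ---------------------------------------------------------------------------

def test_tfidf_zero_frequency():
    assert sl.tfidf_score(0, 64, 0) == 0.0


def test_tfidf_printed_form_examples():
    assert sl.tfidf_score(10, 64, 64) == pytest.approx(10 / math.log(2), rel=1e-12)
    assert sl.tfidf_score(5, 64, 4) == pytest.approx(5 / math.log(17), rel=1e-12)
    assert sl.tfidf_score(5, 64, 4) == pytest.approx(1.765, abs=5e-4)


def test_tfidf_inconsistent_nc_errors():
    with pytest.raises(DataError):
        sl.tfidf_score(3, 64, 0)
    with pytest.raises(DataError):
        sl.tfidf_score(3, 8, 9)


@given(f=st.floats(0.1, 100), nc1=st.integers(1, 63), n=st.just(64),
       scale=st.floats(1.1, 5))
def test_tfidf_linear_in_frequency_and_increasing_in_nc(f, nc1, n, scale):
    base = sl.tfidf_score(f, n, nc1)
    assert sl.tfidf_score(f * scale, n, nc1) == pytest.approx(base * scale, rel=1e-9)
    assert sl.tfidf_score(f, n, nc1 + 1) > base


def test_tfidf_conventional_variant_downweights_ubiquitous():
    everywhere = sl.tfidf_score(10, 64, 64, variant="conventional")
    rare = sl.tfidf_score(10, 64, 1, variant="conventional")
    assert rare > everywhere
    assert everywhere == pytest.approx(10 * math.log(2), rel=1e-12)


def test_tfidf_log_base():
    assert sl.tfidf_score(10, 64, 64, log_base=2.0) == pytest.approx(10.0, rel=1e-12)


# ---------------------------------------------------------------------------
# combined scoring
# ---------------------------------------------------------------------------

def test_single_setting_corpus_rejects_all_with_warning(caplog):
    corpus = sl.Corpus([sl.ConceptDocument(f"d{i}", "OnlyOne", ("C1", "C2"))
                        for i in range(5)])
    with caplog.at_level(logging.WARNING):
        scores = sl.score_all(corpus)
    assert scores and not any(s.passed_chi2 for s in scores)
    assert any("single setting" in rec.message for rec in caplog.records)


def test_planted_signature_pairs_pass_chi2():
    cfg = sl.SyntheticConfig(n_settings=4, signature_size=5, n_background=20,
                             docs_per_setting=30, signature_fraction=1.0, seed=17)
    corpus, truth = sl.generate_corpus(cfg)
    scores = {(s.setting, s.concept): s for s in sl.score_all(corpus)}
    for setting, sig in truth.signatures.items():
        for concept in sig:
            key = (setting, concept)
            if key in scores:          # concept actually drawn in this setting
                assert scores[key].passed_chi2


def test_score_all_chi2_agrees_with_direct_contingency(toy_corpus):
    scores = {(s.setting, s.concept): s for s in sl.score_all(toy_corpus)}
    for (setting, concept), sc in scores.items():
        table = sl.build_contingency(toy_corpus, concept, setting)
        assert sc.chi2 == pytest.approx(sl.chi2_statistic(table), rel=1e-12)


def test_threshold_comparisons_are_strict(toy_corpus):
    baseline = sl.score_all(toy_corpus)
    top = max(s.chi2 for s in baseline)
    at_top = sl.score_all(toy_corpus, sl.FilterConfig(chi2_threshold=top))
    assert not any(s.passed_chi2 for s in at_top)


def test_filtering_monotone_in_thresholds(small_data):
    corpus, _, _ = small_data

    def surviving(chi2_thr, tfidf_thr):
        scores = sl.score_all(corpus, sl.FilterConfig(
            chi2_threshold=chi2_thr, tfidf_threshold=tfidf_thr))
        return {(s.setting, s.concept) for s in scores
                if s.passed_chi2 and s.passed_tfidf}

    base = surviving(6.64, 1.0)
    assert surviving(20.0, 1.0) <= base
    assert surviving(6.64, 3.0) <= base
    assert surviving(20.0, 3.0) <= base


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def _four_concept_db():
    return sl.CooccurrenceDB({("A", "B"): 4, ("A", "C"): 2},
                             concepts=["A", "B", "C", "D"])


def test_enrichment_global_manual_example():
    g = sl.enrichment_global(_four_concept_db(), ["A", "B", "C", "D"])
    assert g.total_pair_num == 6
    assert g.total_sem_occ == 6
    assert g.prob_exp == 1.0


def test_enrichment_fold_manual_example():
    db = _four_concept_db()
    g = sl.enrichment_global(db, ["A", "B", "C", "D"])
    r = sl.enrichment_fold(db, ["A", "B", "C"], g)
    assert r.total_pair_num == 3 and r.total_sem_occ == 6
    assert r.prob_obs == 2.0 and r.fold == 2.0 and r.retained


def test_uniform_db_gives_unit_fold_not_retained():
    concepts = [f"C{i}" for i in range(6)]
    db = sl.CooccurrenceDB({(a, b): 7 for i, a in enumerate(concepts)
                            for b in concepts[i + 1:]})
    g = sl.enrichment_global(db, concepts)
    assert g.prob_exp == 7.0
    r = sl.enrichment_fold(db, concepts[:3], g)
    assert r.fold == pytest.approx(1.0, abs=1e-12)
    assert not r.retained       # strict inequality at threshold 1


def test_fold_invariant_under_count_scaling(small_data):
    _, truth, db = small_data
    concepts = db.concepts
    g1 = sl.enrichment_global(db, concepts)
    g2 = sl.enrichment_global(db.scaled(10), concepts)
    for sig in truth.signatures.values():
        f1 = sl.enrichment_fold(db, sig, g1)
        f2 = sl.enrichment_fold(db.scaled(10), sig, g2)
        assert f1.fold == pytest.approx(f2.fold, rel=1e-12)


def test_enrichment_degenerate_inputs():
    db = _four_concept_db()
    with pytest.raises(DataError):
        sl.enrichment_global(db, ["A"])
    g = sl.enrichment_global(db, ["A", "B", "C", "D"])
    with pytest.raises(DataError):
        sl.enrichment_fold(db, ["A"], g)
    empty_g = EnrichmentGlobal(6, 0, 0.0)
    with pytest.raises(DataError):
        sl.enrichment_fold(db, ["A", "B", "C"], empty_g)


def test_per_concept_fold_anchored_pairs():
    db = _four_concept_db()
    g = sl.enrichment_global(db, ["A", "B", "C", "D"])
    r = enrichment_fold_per_concept(db, "A", ["A", "B", "C"], g)
    # pairs (A,B) and (A,C): (4+2)/2 = 3
    assert r.prob_obs == 3.0 and r.fold == 3.0


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def test_representative_recovery_on_planted_corpus(small_data):
    corpus, truth, db = small_data
    outcome = sl.representative_concepts(corpus, db)
    assert set(outcome.representative) == set(truth.signatures)
    for setting, rep in outcome.representative.items():
        sig = truth.signatures[setting]
        assert len(rep & sig) / len(rep | sig) >= 0.8


def test_uniform_database_excludes_every_setting(small_data):
    corpus, _, db = small_data
    universe = db.concepts
    uniform = sl.CooccurrenceDB(
        {(a, b): 5 for i, a in enumerate(universe) for b in universe[i + 1:]})
    outcome = sl.representative_concepts(corpus, uniform)
    assert outcome.representative == {}
    for er in outcome.enrichment.values():
        assert er.fold == pytest.approx(1.0, abs=1e-9)


def test_concept_frequency_table(toy_corpus):
    df = sl.concept_frequency_table(toy_corpus, top_n=1)
    top = dict(zip(df["setting"], df["concept"]))
    assert top["Cardiology"] == "C0020538"      # 3 occurrences across docs
    assert top["Dermatology"] == "C0011603"
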