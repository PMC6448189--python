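"""Representative-concept selection per practice setting.

Three filters are composed, in order:

1. **χ² association** — for each (concept, setting) pair a 2×2
   document-level presence table is tested with the Pearson χ² statistic
   (1 df, no continuity correction); pairs with χ² > 6.64 (P < 0.01) are
   kept.
2. **TF-IDF weighting** — surviving pairs are scored with
   ``TFIDF = Fc,s / log(1 + N/nc)``, where ``Fc,s`` is the frequency of
   concept *c* in setting *s*, ``N`` the total number of settings and
   ``nc`` the number of settings containing the concept; pairs with a
   score strictly greater than 1 are kept.  The score is implemented
   exactly in this form (see ``tfidf_variant`` for a conventional
   multiplicative weighting).
3. **Co-occurrence enrichment** — each setting's surviving concepts are
   checked against a concept-pair co-occurrence database: the setting's
   observed mean pair co-occurrence (``ProbObsSet``) is divided by the
   expected mean over the whole concept collection (``ProbExpSet``);
   settings with an enrichment fold strictly over 1 keep their concepts.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cooccurrence import CooccurrenceDB
from .corpus import Corpus
from .errors import DataError, ValidationError

__all__ = [
    "ContingencyTable",
    "FilterConfig",
    "ConceptSettingScore",
    "EnrichmentGlobal",
    "EnrichmentResult",
    "FilterOutcome",
    "build_contingency",
    "chi2_statistic",
    "tfidf_score",
    "score_all",
    "enrichment_global",
    "enrichment_fold",
    "enrichment_fold_per_concept",
    "representative_concepts",
    "concept_frequency_table",
    "write_scores_tsv",
    "write_enrichment_tsv",
    "write_representative_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """Document-level 2×2 presence table for one (concept, setting) pair.

    ``a``: documents in the setting containing the concept; ``b``: in the
    setting, lacking it; ``c``: outside the setting, containing it;
    ``d``: outside, lacking it.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and conventions for the three-stage filter.

    ``chi2_threshold`` defaults to 6.64, the χ²(1 df) cutoff at P < 0.01;
    ``tfidf_threshold`` and ``fold_threshold`` default to 1.  All three
    comparisons are strict (>).  ``tf_mode`` selects whether ``Fc,s``
    counts concept occurrences (default) or distinct documents.
    """

    n_settings: int | None = None       # N in the TF-IDF score; None = derive
    chi2_threshold: float = 6.64
    tfidf_threshold: float = 1.0
    fold_threshold: float = 1.0
    tf_mode: str = "occurrences"        # or "doc_frequency"
    log_base: float | None = None       # None = natural log
    tfidf_variant: str = "as_printed"   # or "conventional"
    enrichment_scope: str = "both"      # or "per_setting" / "per_concept"
    global_collection: str = "post_filter_union"  # or "full_vocabulary"

    def __post_init__(self) -> None:
        if self.chi2_threshold < 0 or self.tfidf_threshold < 0 or self.fold_threshold < 0:
            raise ValidationError("thresholds must be >= 0")
        if self.n_settings is not None and self.n_settings < 1:
            raise ValidationError("n_settings must be >= 1")
        if self.tf_mode not in {"occurrences", "doc_frequency"}:
            raise ValueError(f"unknown tf_mode {self.tf_mode!r}")
        if self.tfidf_variant not in {"as_printed", "conventional"}:
            raise ValueError(f"unknown tfidf_variant {self.tfidf_variant!r}")
        if self.enrichment_scope not in {"both", "per_setting", "per_concept"}:
            raise ValueError(f"unknown enrichment_scope {self.enrichment_scope!r}")
        if self.global_collection not in {"post_filter_union", "full_vocabulary"}:
            raise ValueError(f"unknown global_collection {self.global_collection!r}")


@dataclass(frozen=True)
class ConceptSettingScore:
    """Scores and filter flags for one (concept, setting) pair."""

    concept: str
    setting: str
    chi2: float
    tfidf: float | None       # None when the pair failed the χ² stage
    fcs: float                # Fc,s under the configured tf_mode
    n_settings_containing: int
    passed_chi2: bool
    passed_tfidf: bool


# ---------------------------------------------------------------------------
# χ² stage
# ---------------------------------------------------------------------------

def build_contingency(corpus: Corpus, concept: str, setting: str) -> ContingencyTable:
    """Document-level presence table for ``concept`` against ``setting``."""
    groups = corpus.documents_by_setting()
    if setting not in groups:
        raise DataError(f"setting {setting!r} not present in corpus")
    a = b = c = d = 0
    for doc in corpus:
        has = concept in doc.concepts
        if doc.setting == setting:
            a, b = (a + 1, b) if has else (a, b + 1)
        else:
            c, d = (c + 1, d) if has else (c, d + 1)
    return ContingencyTable(a, b, c, d)


def chi2_statistic(table: ContingencyTable) -> float:
    """Pearson χ² on a 2×2 table, no continuity correction.

    ``n (ad − bc)² / ((a+b)(c+d)(a+c)(b+d))``; defined as 0 when any
    margin is 0 (no contrast to test).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    if n == 0:
        raise DataError("all-zero contingency table")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)


# ---------------------------------------------------------------------------
# TF-IDF stage
# ---------------------------------------------------------------------------

def tfidf_score(
    fcs: float,
    n_settings: int,
    n_containing: int,
    log_base: float | None = None,
    variant: str = "as_printed",
) -> float:
    """Setting-specificity weight of a concept frequency.

    ``as_printed`` (default) divides the frequency by ``log(1 + N/nc)``;
    ``conventional`` multiplies by it, which down-weights concepts present
    in most settings.  Natural log unless ``log_base`` is given.
    """
    if n_settings < 1:
        raise ValueError("n_settings must be >= 1")
    if fcs == 0:
        return 0.0
    if fcs < 0:
        raise ValueError("frequency must be non-negative")
    if n_containing == 0:
        raise DataError("concept has positive frequency but n_containing == 0")
    if not 1 <= n_containing <= n_settings:
        raise DataError(
            f"n_containing={n_containing} outside [1, {n_settings}]"
        )
    x = math.log(1.0 + n_settings / n_containing)
    if log_base is not None:
        x /= math.log(log_base)
    if variant == "as_printed":
        return fcs / x
    if variant == "conventional":
        return fcs * x
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# Combined χ² → TF-IDF scoring
# ---------------------------------------------------------------------------

def score_all(corpus: Corpus, cfg: FilterConfig | None = None) -> list[ConceptSettingScore]:
    """Score every (concept, setting) pair with ``Fc,s > 0``.

    χ² is computed first for all pairs; the TF-IDF score is computed only
    for pairs passing the χ² cutoff, in keeping with the staged pipeline.
    A single-setting corpus has no contrast: every pair is rejected with a
    logged warning.
    """
    cfg = cfg or FilterConfig()
    groups = corpus.documents_by_setting()
    settings = sorted(groups)
    total_docs = len(corpus)
    docs_in = {s: len(groups[s]) for s in settings}

    presence: dict[str, Counter] = {}
    occurrences: dict[str, Counter] = {}
    for s in settings:
        pres, occ = Counter(), Counter()
        for doc in groups[s]:
            cc = doc.concept_counts()
            pres.update(cc.keys())
            occ.update(cc)
        presence[s], occurrences[s] = pres, occ
    presence_total: Counter = Counter()
    for s in settings:
        presence_total.update(presence[s])
    containing: Counter = Counter()
    for s in settings:
        containing.update(occurrences[s].keys())

    n_for_tfidf = cfg.n_settings if cfg.n_settings is not None else len(settings)
    degenerate = len(settings) < 2
    if degenerate:
        logger.warning(
            "corpus has a single setting; chi-square association is undefined "
            "and every pair is rejected"
        )

    scores: list[ConceptSettingScore] = []
    for s in settings:
        freq = occurrences[s] if cfg.tf_mode == "occurrences" else presence[s]
        for concept in sorted(occurrences[s]):
            fcs = float(freq[concept])
            if degenerate:
                scores.append(ConceptSettingScore(
                    concept, s, 0.0, None, fcs, containing[concept], False, False))
                continue
            a = presence[s][concept]
            table = ContingencyTable(
                a, docs_in[s] - a,
                presence_total[concept] - a,
                total_docs - docs_in[s] - (presence_total[concept] - a),
            )
            chi2 = chi2_statistic(table)
            passed_chi2 = chi2 > cfg.chi2_threshold
            tfidf: float | None = None
            passed_tfidf = False
            if passed_chi2:
                tfidf = tfidf_score(
                    fcs, n_for_tfidf, containing[concept],
                    log_base=cfg.log_base, variant=cfg.tfidf_variant,
                )
                passed_tfidf = tfidf > cfg.tfidf_threshold
            scores.append(ConceptSettingScore(
                concept, s, chi2, tfidf, fcs, containing[concept],
                passed_chi2, passed_tfidf))

    n_chi2 = sum(sc.passed_chi2 for sc in scores)
    n_tfidf = sum(sc.passed_tfidf for sc in scores)
    logger.info(
        "scored %d concept-setting pairs; %d passed chi-square (> %g), "
        "%d also passed TF-IDF (> %g)",
        len(scores), n_chi2, cfg.chi2_threshold, n_tfidf, cfg.tfidf_threshold,
    )
    return scores


# ---------------------------------------------------------------------------
# Enrichment stage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentGlobal:
    """Expected co-occurrence rate over the whole concept collection."""

    total_pair_num: int       # C(|collection|, 2)
    total_sem_occ: int        # summed database counts over those pairs
    prob_exp: float           # total_sem_occ / total_pair_num


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed co-occurrence rate and enrichment fold for one setting."""

    setting: str
    total_pair_num: int
    total_sem_occ: int
    prob_obs: float
    fold: float
    retained: bool


def enrichment_global(db: CooccurrenceDB, concepts: Iterable[str]) -> EnrichmentGlobal:
    """Average pair co-occurrence over all pairs from the collection."""
    cset = set(concepts)
    n = len(cset)
    if n < 2:
        raise DataError(f"concept collection must contain >= 2 concepts (got {n})")
    total_pairs = n * (n - 1) // 2
    total_occ = sum(count for (a, b), count in db.items() if a in cset and b in cset)
    return EnrichmentGlobal(total_pairs, total_occ, total_occ / total_pairs)


def enrichment_fold(
    db: CooccurrenceDB,
    setting_concepts: Iterable[str],
    global_: EnrichmentGlobal,
    fold_threshold: float = 1.0,
    setting: str = "",
) -> EnrichmentResult:
    """Enrichment fold of one setting's concept set against the expectation.

    ``ProbObsSet`` averages the database counts over the setting's
    C(n, 2) pairs; the fold is ``ProbObsSet / ProbExpSet``.  Retained iff
    the fold is strictly greater than ``fold_threshold``.
    """
    cset = sorted(set(setting_concepts))
    if len(cset) < 2:
        raise DataError(
            f"setting {setting!r} has {len(cset)} concepts; need >= 2 for pairs")
    if global_.prob_exp <= 0:
        raise DataError("expected co-occurrence probability is 0; fold undefined")
    total_pairs = len(cset) * (len(cset) - 1) // 2
    total_occ = sum(db.get(a, b) for a, b in combinations(cset, 2))
    prob_obs = total_occ / total_pairs
    fold = prob_obs / global_.prob_exp
    return EnrichmentResult(setting, total_pairs, total_occ, prob_obs, fold,
                            fold > fold_threshold)


def enrichment_fold_per_concept(
    db: CooccurrenceDB,
    concept: str,
    setting_concepts: Iterable[str],
    global_: EnrichmentGlobal,
    fold_threshold: float = 1.0,
    setting: str = "",
) -> EnrichmentResult:
    """Variant anchoring the pair set at one concept.

    Pairs are ``(concept, other)`` for every other concept of the setting;
    useful when a per-concept rather than per-setting gate is wanted.
    """
    others = sorted(set(setting_concepts) - {concept})
    if not others:
        raise DataError(f"concept {concept!r} has no partners in setting {setting!r}")
    if global_.prob_exp <= 0:
        raise DataError("expected co-occurrence probability is 0; fold undefined")
    total_occ = sum(db.get(concept, o) for o in others)
    prob_obs = total_occ / len(others)
    fold = prob_obs / global_.prob_exp
    return EnrichmentResult(f"{setting}:{concept}", len(others), total_occ,
                            prob_obs, fold, fold > fold_threshold)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

@dataclass
class FilterOutcome:
    """Full result of the χ² → TF-IDF → enrichment composition."""

    representative: dict[str, set[str]]
    scores: list[ConceptSettingScore]
    enrichment: dict[str, EnrichmentResult]
    global_enrichment: EnrichmentGlobal | None
    per_concept_enrichment: dict[str, list[EnrichmentResult]] = field(default_factory=dict)


def representative_concepts(
    corpus: Corpus,
    db: CooccurrenceDB,
    cfg: FilterConfig | None = None,
) -> FilterOutcome:
    """Select representative concepts for every setting.

    Composes the three filters.  The enrichment stage can gate at two
    levels: a *setting* whose fold is not strictly above the threshold
    contributes no representative concepts at all, and a *concept* whose
    fold (pairs anchored at that concept within its setting's candidate
    set) is not strictly above the threshold is pruned from the set.  The
    default scope ``"both"`` applies the setting gate and then the
    concept-level pruning — the concept-and-setting-pair reading of the
    fold cutoff, which removes sparse concepts that slipped through the
    χ² stage; ``"per_setting"`` and ``"per_concept"`` apply only one
    gate.  Settings left with fewer than two candidate concepts after
    χ²+TF-IDF cannot form pairs and are excluded with a warning.
    """
    cfg = cfg or FilterConfig()
    scores = score_all(corpus, cfg)
    candidates: dict[str, set[str]] = {}
    for sc in scores:
        if sc.passed_chi2 and sc.passed_tfidf:
            candidates.setdefault(sc.setting, set()).add(sc.concept)

    if cfg.global_collection == "post_filter_union":
        collection: set[str] = set().union(*candidates.values()) if candidates else set()
    else:
        collection = set(corpus.concept_vocabulary)
    if len(collection) < 2:
        raise DataError(
            "fewer than 2 concepts survive chi-square and TF-IDF filtering; "
            "enrichment analysis is impossible")
    global_ = enrichment_global(db, collection)

    representative: dict[str, set[str]] = {}
    enrichment: dict[str, EnrichmentResult] = {}
    per_concept: dict[str, list[EnrichmentResult]] = {}
    for setting in sorted(candidates):
        cset = candidates[setting]
        if len(cset) < 2:
            logger.warning(
                "setting %s has %d candidate concept(s); cannot form pairs, excluded",
                setting, len(cset))
            continue
        result = enrichment_fold(db, cset, global_, cfg.fold_threshold, setting)
        enrichment[setting] = result
        if cfg.enrichment_scope in {"both", "per_setting"} and not result.retained:
            continue
        if cfg.enrichment_scope == "per_setting":
            representative[setting] = set(cset)
            continue
        folds = [
            enrichment_fold_per_concept(db, c, cset, global_,
                                        cfg.fold_threshold, setting)
            for c in sorted(cset)
        ]
        per_concept[setting] = folds
        kept = {f.setting.split(":", 1)[1] for f in folds if f.retained}
        if kept:
            representative[setting] = kept

    logger.info(
        "%d of %d candidate settings retained after enrichment (fold > %g)",
        len(representative), len(candidates), cfg.fold_threshold)
    return FilterOutcome(representative, scores, enrichment, global_, per_concept)


# ---------------------------------------------------------------------------
# Tables / exports
# ---------------------------------------------------------------------------

def concept_frequency_table(corpus: Corpus, top_n: int = 10) -> pd.DataFrame:
    """Top-``top_n`` concepts per setting by occurrence frequency.

    Data replacement for per-setting word clouds: columns ``setting``,
    ``concept``, ``frequency``, sorted by setting then descending
    frequency (ties broken by concept id).
    """
    rows = []
    for setting, docs in sorted(corpus.documents_by_setting().items()):
        counts: Counter = Counter()
        for doc in docs:
            counts.update(doc.concepts)
        top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
        rows.extend({"setting": setting, "concept": c, "frequency": n} for c, n in top)
    return pd.DataFrame(rows, columns=["setting", "concept", "frequency"])


def write_scores_tsv(scores: Sequence[ConceptSettingScore], path: str | Path) -> None:
    df = pd.DataFrame(
        [{
            "setting": sc.setting, "concept": sc.concept, "chi2": sc.chi2,
            "tfidf": "" if sc.tfidf is None else sc.tfidf,
            "Fc_s": sc.fcs, "nc": sc.n_settings_containing,
            "passed_chi2": int(sc.passed_chi2), "passed_tfidf": int(sc.passed_tfidf),
        } for sc in scores]
    )
    df.to_csv(path, sep="\t", index=False)


def write_enrichment_tsv(
    enrichment: Mapping[str, EnrichmentResult], path: str | Path
) -> None:
    df = pd.DataFrame(
        [{
            "setting": er.setting, "pairs": er.total_pair_num,
            "cooccurrences": er.total_sem_occ, "prob_obs": er.prob_obs,
            "fold": er.fold, "retained": int(er.retained),
        } for _, er in sorted(enrichment.items())]
    )
    df.to_csv(path, sep="\t", index=False)


def write_representative_tsv(
    outcome: FilterOutcome, path: str | Path
) -> None:
    """``setting<TAB>concept<TAB>chi2<TAB>tfidf<TAB>Fc_s<TAB>nc`` rows."""
    by_pair = {(sc.setting, sc.concept): sc for sc in outcome.scores}
    rows = []
    for setting in sorted(outcome.representative):
        for concept in sorted(outcome.representative[setting]):
            sc = by_pair[(setting, concept)]
            rows.append({
                "setting": setting, "concept": concept, "chi2": sc.chi2,
                "tfidf": sc.tfidf, "Fc_s": sc.fcs, "nc": sc.n_settings_containing,
            })
    pd.DataFrame(rows, columns=["setting", "concept", "chi2", "tfidf", "Fc_s", "nc"]
                 ).to_csv(path, sep="\t", index=False)
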