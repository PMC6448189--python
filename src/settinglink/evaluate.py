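"""Practice-setting prediction and @k evaluation under cross-validation.

Held-out document groups are folded into the fitted topic model; each
held-out setting's topic profile is ranked against every training
setting's profile by Pearson correlation.  With ``S`` gold settings,
counts at list cutoff *k* are

    TP@k = settings whose own top-k list contains them
    U@k  = distinct settings appearing in the union of top-k lists
    FP@k = U@k − TP@k
    FN@k = S − TP@k

and Precision@k = TP/(TP+FP), Recall@k = TP/(TP+FN),
F1@k = 2·TP/(2·TP+FP+FN).  The FP@k reading reproduces the identity
precision = recall whenever every setting appears in some top-k list.
Cross-validation is stratified by setting; concept filtering and the
topic model are re-fit on each training split so no information leaks
from the held-out fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .cooccurrence import CooccurrenceDB
from .corpus import ConceptDocument, Corpus
from .errors import DataError
from .filtering import FilterConfig, representative_concepts
from .lda import (DEFAULT_BURNIN, DEFAULT_POST_SWEEPS, fit_lda, infer_topics,
                  select_num_topics, term_topic_probabilities)
from .profiles import SettingProfile, profile_from_counts, setting_profile

__all__ = [
    "RankedPrediction",
    "AtKMetrics",
    "LDAConfig",
    "CVResult",
    "predict_settings",
    "metrics_at_k",
    "mean_metrics",
    "cross_validate",
    "evaluate_holdout",
    "assign_folds",
    "write_rankings_tsv",
    "metrics_to_json_dict",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedPrediction:
    """Candidate settings for one held-out setting, best first."""

    true_setting: str
    ranking: tuple[tuple[str, float], ...]   # (candidate, Pearson r), r desc

    def __post_init__(self) -> None:
        names = [c for c, _ in self.ranking]
        if len(names) != len(set(names)):
            raise DataError("ranked candidates must be distinct")
        rs = [r for _, r in self.ranking]
        if any(rs[i] < rs[i + 1] for i in range(len(rs) - 1)):
            raise DataError("ranking must be sorted by non-increasing r")

    def top_k(self, k: int) -> list[str]:
        return [c for c, _ in self.ranking[:k]]


@dataclass(frozen=True)
class AtKMetrics:
    """Counts and rates at one list cutoff."""

    k: int
    tp: int
    fp: int
    fn: int
    u: int
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class LDAConfig:
    """Topic-model settings used inside evaluation splits.

    ``n_topics=None`` triggers per-split selection over ``grid`` by
    log-likelihood (the grid defaults to 5–150 by 5 inside the selection
    routine).
    """

    n_topics: int | None = None
    grid: tuple[int, ...] | None = None
    alpha: float | None = None
    beta: float = 0.1
    iterations: int = DEFAULT_BURNIN
    burnin: int = DEFAULT_BURNIN
    infer_iterations: int = DEFAULT_BURNIN + DEFAULT_POST_SWEEPS
    infer_burnin: int = DEFAULT_BURNIN


@dataclass
class CVResult:
    """Per-fold and mean @k metrics, plus the fold assignment."""

    per_fold: list[dict[int, AtKMetrics]]
    mean: dict[int, dict[str, float]]
    fold_of: dict[str, int]
    rankings: list[list[RankedPrediction]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# ranking and metrics
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx = float(np.sqrt((xc * xc).sum()))
    ny = float(np.sqrt((yc * yc).sum()))
    if nx == 0 or ny == 0:
        raise DataError("constant profile: Pearson correlation undefined")
    return float((xc * yc).sum() / (nx * ny))


def predict_settings(
    train_profiles: Sequence[SettingProfile],
    test_profile: SettingProfile,
) -> RankedPrediction:
    """Rank every training setting by correlation with the test profile.

    Ties in r are broken lexicographically by setting name.
    """
    if len(train_profiles) < 2:
        raise DataError("need at least 2 training profiles to rank")
    scored = [(p.setting, _pearson(p.vector, test_profile.vector))
              for p in train_profiles]
    scored.sort(key=lambda sr: (-sr[1], sr[0]))
    return RankedPrediction(test_profile.setting, tuple(scored))


def metrics_at_k(
    predictions: Sequence[RankedPrediction],
    k: int,
    s_total: int,
    fp_strategy: str = "unique_union",
) -> AtKMetrics:
    """Aggregate @k counts and rates over one set of predictions.

    ``fp_strategy="unique_union"`` (default) counts false positives as
    the distinct predicted settings beyond the correct ones,
    FP = U − TP; ``"list_slots"`` counts every incorrect top-k slot,
    FP = k·|predictions| − TP.
    """
    if k < 1:
        raise DataError("k must be >= 1")
    if fp_strategy not in {"unique_union", "list_slots"}:
        raise ValueError(f"unknown fp_strategy {fp_strategy!r}")
    trues = [p.true_setting for p in predictions]
    if len(trues) != len(set(trues)):
        raise DataError("predictions must cover each true setting exactly once")
    for p in predictions:
        if k > len(p.ranking):
            raise DataError(
                f"k={k} exceeds ranked-list length {len(p.ranking)} "
                f"for setting {p.true_setting!r}")
    union: set[str] = set()
    tp = 0
    for p in predictions:
        top = p.top_k(k)
        union.update(top)
        if p.true_setting in top:
            tp += 1
    u = len(union)
    fp = (u - tp) if fp_strategy == "unique_union" else k * len(predictions) - tp
    fn = s_total - tp
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else 0.0
    return AtKMetrics(k, tp, fp, fn, u, precision, recall, f1)


def mean_metrics(per_fold: Sequence[Mapping[int, AtKMetrics]]) -> dict[int, dict[str, float]]:
    """Arithmetic mean of every count and rate across folds, per k."""
    ks = sorted(per_fold[0])
    out: dict[int, dict[str, float]] = {}
    for k in ks:
        out[k] = {
            name: float(np.mean([getattr(f[k], name) for f in per_fold]))
            for name in ("tp", "fp", "fn", "u", "precision", "recall", "f1")
        }
    return out


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def assign_folds(corpus: Corpus, folds: int, seed: int) -> dict[str, int]:
    """Stratified fold assignment: each setting's documents are shuffled
    with a per-setting sub-seed and dealt round-robin across folds."""
    if folds < 2:
        raise DataError("folds must be >= 2")
    fold_of: dict[str, int] = {}
    for setting, docs in sorted(corpus.documents_by_setting().items()):
        if len(docs) < folds:
            raise DataError(
                f"setting {setting!r} has {len(docs)} documents; "
                f"cannot stratify into {folds} folds")
        rng = np.random.default_rng(derive_seed(seed, "folds", setting))
        order = rng.permutation(len(docs))
        for pos, j in enumerate(order):
            fold_of[docs[j].doc_id] = pos % folds
    return fold_of


def _restrict(docs: Iterable[ConceptDocument], vocab: set[str],
              drop_empty: bool) -> list[ConceptDocument]:
    out = []
    for d in docs:
        kept = tuple(c for c in d.concepts if c in vocab)
        if kept or not drop_empty:
            out.append(ConceptDocument(d.doc_id, d.setting, kept))
    return out


def _evaluate_split(
    train_corpus: Corpus,
    test_corpus: Corpus,
    db: CooccurrenceDB,
    filter_cfg: FilterConfig,
    lda_cfg: LDAConfig,
    ks: Sequence[int],
    s_total: int,
    seed: int,
) -> tuple[dict[int, AtKMetrics], list[RankedPrediction]]:
    outcome = representative_concepts(train_corpus, db, filter_cfg)
    rep = outcome.representative
    if len(rep) < 2:
        raise DataError("fewer than 2 settings retain representative concepts")
    vocab = set().union(*rep.values())
    train_docs = _restrict(train_corpus, vocab, drop_empty=True)
    logger.info("split: %d/%d training documents kept after restriction to "
                "%d representative concepts", len(train_docs),
                len(train_corpus), len(vocab))

    n_topics = lda_cfg.n_topics
    if n_topics is None:
        n_topics, _ = select_num_topics(
            [d.concepts for d in train_docs], grid=lda_cfg.grid,
            seed=derive_seed(seed, "select"), alpha=lda_cfg.alpha,
            beta=lda_cfg.beta, iterations=lda_cfg.iterations,
            burnin=lda_cfg.burnin)
    model = fit_lda(
        [d.concepts for d in train_docs], n_topics,
        alpha=lda_cfg.alpha, beta=lda_cfg.beta,
        iterations=lda_cfg.iterations, burnin=lda_cfg.burnin,
        seed=derive_seed(seed, "fit"), vocabulary=sorted(vocab))
    ttm = term_topic_probabilities(model)
    train_profiles = setting_profile(ttm, rep)

    predictions: list[RankedPrediction] = []
    for setting, docs in sorted(test_corpus.documents_by_setting().items()):
        held = _restrict(docs, vocab, drop_empty=True)
        if not held:
            raise DataError(
                f"held-out setting {setting!r} has no documents with "
                "in-vocabulary concepts")
        result = infer_topics(
            model, [d.concepts for d in held],
            iterations=lda_cfg.infer_iterations, burnin=lda_cfg.infer_burnin,
            seed=derive_seed(seed, "infer", setting))
        test_profile = profile_from_counts(result.term_topic_counts, setting)
        predictions.append(predict_settings(train_profiles, test_profile))
    metrics = {k: metrics_at_k(predictions, k, s_total) for k in ks}
    return metrics, predictions


def cross_validate(
    corpus: Corpus,
    db: CooccurrenceDB,
    filter_cfg: FilterConfig | None = None,
    lda_cfg: LDAConfig | None = None,
    folds: int = 5,
    ks: Sequence[int] = (2, 4, 6, 8, 10),
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold evaluation of setting prediction.

    Representative-concept selection and the topic model are re-run on
    every training split.  The gold setting count for FN@k is the number
    of settings in the full corpus.  Per-fold metrics are averaged into
    the final result.
    """
    filter_cfg = filter_cfg or FilterConfig()
    lda_cfg = lda_cfg or LDAConfig()
    fold_of = assign_folds(corpus, folds, seed)
    s_total = len(corpus.settings)
    per_fold: list[dict[int, AtKMetrics]] = []
    rankings: list[list[RankedPrediction]] = []
    for fold in range(folds):
        train = Corpus(d for d in corpus if fold_of[d.doc_id] != fold)
        test = Corpus(d for d in corpus if fold_of[d.doc_id] == fold)
        metrics, preds = _evaluate_split(
            train, test, db, filter_cfg, lda_cfg, ks, s_total,
            seed=derive_seed(seed, "cv", fold))
        per_fold.append(metrics)
        rankings.append(preds)
        logger.info("fold %d: %s", fold,
                    {k: round(m.recall, 3) for k, m in metrics.items()})
    return CVResult(per_fold, mean_metrics(per_fold), fold_of, rankings)


def evaluate_holdout(
    corpus: Corpus,
    db: CooccurrenceDB,
    n_test_per_setting: int,
    filter_cfg: FilterConfig | None = None,
    lda_cfg: LDAConfig | None = None,
    ks: Sequence[int] = (2, 4, 6, 8, 10),
    seed: int = 0,
) -> CVResult:
    """Single fixed-holdout evaluation: n test documents per setting.

    Mirrors a fixed test split of n notes per setting; everything else as
    in :func:`cross_validate`.
    """
    filter_cfg = filter_cfg or FilterConfig()
    lda_cfg = lda_cfg or LDAConfig()
    test_ids: set[str] = set()
    for setting, docs in sorted(corpus.documents_by_setting().items()):
        if len(docs) <= n_test_per_setting:
            raise DataError(
                f"setting {setting!r} has {len(docs)} documents; cannot hold "
                f"out {n_test_per_setting} and keep training data")
        rng = np.random.default_rng(derive_seed(seed, "holdout", setting))
        chosen = rng.choice(len(docs), size=n_test_per_setting, replace=False)
        test_ids.update(docs[j].doc_id for j in chosen)
    train = Corpus(d for d in corpus if d.doc_id not in test_ids)
    test = Corpus(d for d in corpus if d.doc_id in test_ids)
    metrics, preds = _evaluate_split(
        train, test, db, filter_cfg, lda_cfg, ks, len(corpus.settings),
        seed=derive_seed(seed, "holdout_eval"))
    fold_of = {d.doc_id: (0 if d.doc_id in test_ids else -1) for d in corpus}
    return CVResult([metrics], mean_metrics([metrics]), fold_of, [preds])


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_rankings_tsv(rankings: Sequence[Sequence[RankedPrediction]],
                       path) -> None:
    rows = []
    for fold, preds in enumerate(rankings):
        for p in preds:
            for rank, (cand, r) in enumerate(p.ranking, start=1):
                rows.append({"fold": fold, "true_setting": p.true_setting,
                             "rank": rank, "predicted": cand, "r": r})
    pd.DataFrame(rows, columns=["fold", "true_setting", "rank", "predicted", "r"]
                 ).to_csv(path, sep="\t", index=False)


def metrics_to_json_dict(result: CVResult) -> dict:
    """JSON-ready dict: per-fold and mean metrics keyed by k."""
    def atk_dict(m: AtKMetrics) -> dict:
        return {"TP": m.tp, "FP": m.fp, "FN": m.fn, "U": m.u,
                "precision": m.precision, "recall": m.recall, "f1": m.f1}

    return {
        "folds": [
            {str(k): atk_dict(m) for k, m in sorted(fold.items())}
            for fold in result.per_fold
        ],
        "mean": {str(k): dict(sorted(v.items()))
                 for k, v in sorted(result.mean.items())},
    }
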