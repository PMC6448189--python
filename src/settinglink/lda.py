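"""Latent Dirichlet Allocation by collapsed Gibbs sampling.

Documents are bags of concepts.  The sampler integrates out the topic
mixtures and topic–term distributions and resamples each token's topic
assignment from

    p(z_i = k | ·) ∝ (n_dk + α) (n_kw + β) / (n_k + Vβ)

where the counts exclude token *i*.  A single chain is run; the topic–term
(φ) and document–topic (θ) distributions are read off the final state with
the same Dirichlet smoothing.  Model selection compares the collapsed
log-likelihood log p(w | z, β) across a grid of topic counts; held-out
documents are folded in by Gibbs sampling with the topic–term counts
frozen at their training values.

The per-token sweeps are compiled with numba; all randomness is
deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import gammaln

from ._seeds import derive_seed
from .corpus import Corpus
from .errors import DataError, ValidationError

__all__ = [
    "TopicModel",
    "TermTopicMatrix",
    "InferenceResult",
    "fit_lda",
    "log_likelihood",
    "select_num_topics",
    "infer_topics",
    "term_topic_probabilities",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

DEFAULT_BURNIN = 1000          # discarded sweeps before using the chain
DEFAULT_POST_SWEEPS = 200      # post-burn-in sweeps for held-out accumulation
DEFAULT_K_GRID = tuple(range(5, 151, 5))   # topic-number selection grid


# ---------------------------------------------------------------------------
# numba kernels (sequential per-token sweeps)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _seed_rng(seed):
    np.random.seed(seed)


@njit(cache=False)
def _init_assignments(doc_of, tokens, n_topics, n_dk, n_kw, n_k):
    n = tokens.shape[0]
    z = np.empty(n, np.int64)
    for i in range(n):
        k = np.random.randint(0, n_topics)
        z[i] = k
        n_dk[doc_of[i], k] += 1
        n_kw[k, tokens[i]] += 1
        n_k[k] += 1
    return z


@njit(cache=False)
def _fit_sweeps(doc_of, tokens, z, n_dk, n_kw, n_k, alpha, beta, n_vocab, n_sweeps):
    n_topics = n_k.shape[0]
    vb = n_vocab * beta
    cum = np.empty(n_topics, np.float64)
    n = tokens.shape[0]
    for _ in range(n_sweeps):
        for i in range(n):
            d = doc_of[i]
            w = tokens[i]
            k = z[i]
            n_dk[d, k] -= 1
            n_kw[k, w] -= 1
            n_k[k] -= 1
            total = 0.0
            for kk in range(n_topics):
                total += (n_dk[d, kk] + alpha) * (n_kw[kk, w] + beta) / (n_k[kk] + vb)
                cum[kk] = total
            u = np.random.random() * total
            k = 0
            while k < n_topics - 1 and cum[k] < u:
                k += 1
            z[i] = k
            n_dk[d, k] += 1
            n_kw[k, w] += 1
            n_k[k] += 1


@njit(cache=False)
def _infer_sweeps(doc_of, tokens, z, n_dk, n_kw_train, n_k_train, alpha, beta,
                  n_vocab, burnin, iterations, acc_dk, acc_wk):
    n_topics = n_k_train.shape[0]
    vb = n_vocab * beta
    cum = np.empty(n_topics, np.float64)
    n = tokens.shape[0]
    n_samples = 0
    for sweep in range(iterations):
        for i in range(n):
            d = doc_of[i]
            w = tokens[i]
            k = z[i]
            n_dk[d, k] -= 1
            total = 0.0
            for kk in range(n_topics):
                total += ((n_dk[d, kk] + alpha)
                          * (n_kw_train[kk, w] + beta) / (n_k_train[kk] + vb))
                cum[kk] = total
            u = np.random.random() * total
            k = 0
            while k < n_topics - 1 and cum[k] < u:
                k += 1
            z[i] = k
            n_dk[d, k] += 1
        if sweep >= burnin:
            n_samples += 1
            for i in range(n):
                acc_dk[doc_of[i], z[i]] += 1
                acc_wk[tokens[i], z[i]] += 1
    return n_samples


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class TopicModel:
    """Fitted collapsed-Gibbs LDA state."""

    n_topics: int
    alpha: float
    beta: float
    phi: np.ndarray                 # K×V topic–term probabilities
    theta: np.ndarray               # D×K document–topic probabilities
    vocabulary: list[str]
    n_kw: np.ndarray                # K×V topic–term counts (final state)
    n_k: np.ndarray                 # K topic totals
    seed: int
    init_log_likelihood: float
    z: np.ndarray | None = None     # final token assignments (0-based)
    doc_ids: list[str] | None = None
    vocab_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.vocab_index:
            self.vocab_index = {w: i for i, w in enumerate(self.vocabulary)}

    @property
    def n_vocab(self) -> int:
        return len(self.vocabulary)


@dataclass(frozen=True)
class TermTopicMatrix:
    """Per-term topic membership p(topic | term), one simplex row per term."""

    matrix: np.ndarray              # V×K
    vocabulary: list[str]
    observed: np.ndarray            # V bools; False = term unseen in training

    def row(self, term: str) -> np.ndarray:
        return self.matrix[self.vocabulary.index(term)]


@dataclass(frozen=True)
class InferenceResult:
    """Held-out posterior summary from folded-in Gibbs sampling."""

    theta: np.ndarray               # D_new × K smoothed topic mixtures
    term_topic_counts: np.ndarray   # V×K accumulated post-burn-in assignments
    n_samples: int
    n_oov_tokens: int


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def _as_token_lists(docs: "Corpus | Iterable[Sequence[str]]") -> tuple[list[list[str]], list[str] | None]:
    if isinstance(docs, Corpus):
        return [list(d.concepts) for d in docs], [d.doc_id for d in docs]
    return [list(d) for d in docs], None


def _encode(token_docs: list[list[str]], vocab_index: dict[str, int],
            allow_oov: bool) -> tuple[np.ndarray, np.ndarray, int]:
    """Flatten documents into (doc_of, tokens) index arrays."""
    doc_of: list[int] = []
    tokens: list[int] = []
    n_oov = 0
    for d, words in enumerate(token_docs):
        for w in words:
            idx = vocab_index.get(w)
            if idx is None:
                if not allow_oov:
                    raise DataError(f"token {w!r} outside the model vocabulary")
                n_oov += 1
                continue
            doc_of.append(d)
            tokens.append(idx)
    return (np.asarray(doc_of, dtype=np.int64),
            np.asarray(tokens, dtype=np.int64), n_oov)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_lda(
    docs: "Corpus | Iterable[Sequence[str]]",
    n_topics: int,
    alpha: float | None = None,
    beta: float = 0.1,
    iterations: int = DEFAULT_BURNIN,
    burnin: int = DEFAULT_BURNIN,
    seed: int = 0,
    vocabulary: Sequence[str] | None = None,
    debug: bool = False,
) -> TopicModel:
    """Fit LDA with a single collapsed-Gibbs chain.

    ``alpha`` defaults to ``50 / n_topics`` and ``beta`` to 0.1, the
    conventional defaults of the Gibbs LDA ecosystem.  ``iterations``
    sweeps are run (default equals the burn-in of 1000); φ and θ are read
    off the final state.  Every document must contain at least one token.
    With ``debug=True`` the count tables are re-derived from the
    assignments after every sweep and checked.
    """
    if n_topics < 1:
        raise DataError("n_topics must be >= 1")
    if iterations < burnin:
        raise DataError("iterations must be >= burnin")
    token_docs, doc_ids = _as_token_lists(docs)
    for i, words in enumerate(token_docs):
        if not words:
            did = doc_ids[i] if doc_ids else str(i)
            raise DataError(f"document {did!r} is empty; drop empty documents upstream")
    if alpha is None:
        alpha = 50.0 / n_topics

    if vocabulary is None:
        vocab = sorted({w for words in token_docs for w in words})
    else:
        vocab = list(vocabulary)
    vocab_index = {w: i for i, w in enumerate(vocab)}
    doc_of, tokens, _ = _encode(token_docs, vocab_index, allow_oov=False)

    n_docs, n_vocab = len(token_docs), len(vocab)
    n_dk = np.zeros((n_docs, n_topics), np.int64)
    n_kw = np.zeros((n_topics, n_vocab), np.int64)
    n_k = np.zeros(n_topics, np.int64)

    _seed_rng(derive_seed(seed, "lda_fit"))
    z = _init_assignments(doc_of, tokens, n_topics, n_dk, n_kw, n_k)
    init_ll = _collapsed_ll(n_kw, n_k, beta)
    if debug:
        for _ in range(iterations):
            _fit_sweeps(doc_of, tokens, z, n_dk, n_kw, n_k,
                        float(alpha), float(beta), n_vocab, 1)
            _check_state(doc_of, tokens, z, n_dk, n_kw, n_k, n_topics)
    elif iterations > 0:
        _fit_sweeps(doc_of, tokens, z, n_dk, n_kw, n_k,
                    float(alpha), float(beta), n_vocab, iterations)

    phi = (n_kw + beta) / (n_k + n_vocab * beta)[:, None] if n_vocab else np.zeros((n_topics, 0))
    n_d = n_dk.sum(axis=1)
    theta = (n_dk + alpha) / (n_d + n_topics * alpha)[:, None] if n_docs else np.zeros((0, n_topics))
    return TopicModel(
        n_topics=n_topics, alpha=float(alpha), beta=float(beta),
        phi=phi, theta=theta, vocabulary=vocab, n_kw=n_kw, n_k=n_k,
        seed=seed, init_log_likelihood=float(init_ll), z=z, doc_ids=doc_ids,
    )


def _check_state(doc_of, tokens, z, n_dk, n_kw, n_k, n_topics) -> None:
    ref_dk = np.zeros_like(n_dk)
    ref_kw = np.zeros_like(n_kw)
    for i in range(tokens.shape[0]):
        ref_dk[doc_of[i], z[i]] += 1
        ref_kw[z[i], tokens[i]] += 1
    if not (np.array_equal(ref_dk, n_dk) and np.array_equal(ref_kw, n_kw)
            and np.array_equal(ref_kw.sum(axis=1), n_k)):
        raise AssertionError("Gibbs count tables inconsistent with assignments")
    if (n_dk < 0).any() or (n_kw < 0).any() or (n_k < 0).any():
        raise AssertionError("negative count in Gibbs state")
    if not np.all((z >= 0) & (z < n_topics)):
        raise AssertionError("topic assignment out of range")


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _collapsed_ll(n_kw: np.ndarray, n_k: np.ndarray, beta: float) -> float:
    n_topics, n_vocab = n_kw.shape
    if n_vocab == 0:
        return 0.0
    const = n_topics * (gammaln(n_vocab * beta) - n_vocab * gammaln(beta))
    return float(const + gammaln(n_kw + beta).sum() - gammaln(n_k + n_vocab * beta).sum())


def log_likelihood(model: TopicModel) -> float:
    """Collapsed log p(w | z, β) at the model's final state.

    ``K [lnΓ(Vβ) − V lnΓ(β)] + Σ_k [Σ_w lnΓ(n_kw + β) − lnΓ(n_k + Vβ)]``;
    exactly 0 for a corpus with no tokens.
    """
    return _collapsed_ll(model.n_kw, model.n_k, model.beta)


def select_num_topics(
    docs: "Corpus | Iterable[Sequence[str]]",
    grid: Iterable[int] | None = None,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[int, pd.DataFrame]:
    """Fit one model per candidate K; the highest log-likelihood wins.

    The default grid is 5 to 150 in steps of 5.  Ties prefer the smaller
    K.  Returns the winner and the full ``(K, loglik)`` table.
    """
    grid = list(grid) if grid is not None else list(DEFAULT_K_GRID)
    if not grid:
        raise DataError("topic-number grid is empty")
    token_docs, _ = _as_token_lists(docs)
    rows = []
    for k in grid:
        model = fit_lda(token_docs, k, seed=derive_seed(seed, "select_k", k),
                        **fit_kwargs)
        rows.append({"K": k, "loglik": log_likelihood(model)})
        logger.info("K=%d: log-likelihood %.2f", k, rows[-1]["loglik"])
    table = pd.DataFrame(rows)
    best = int(table.loc[table["loglik"].idxmax(), "K"])
    return best, table


# ---------------------------------------------------------------------------
# held-out inference
# ---------------------------------------------------------------------------

def infer_topics(
    model: TopicModel,
    docs: "Corpus | Iterable[Sequence[str]]",
    iterations: int = DEFAULT_BURNIN + DEFAULT_POST_SWEEPS,
    burnin: int = DEFAULT_BURNIN,
    seed: int = 0,
) -> InferenceResult:
    """Fold held-out documents into a fitted model.

    Gibbs sampling over the new tokens with the topic–term counts frozen
    at their training values; topic assignments are accumulated over the
    post-burn-in sweeps.  Out-of-vocabulary tokens are skipped with a
    warning; a document left with no in-vocabulary tokens receives the
    uniform mixture 1/K.
    """
    if iterations <= burnin:
        raise DataError("iterations must exceed burnin to accumulate samples")
    token_docs, _ = _as_token_lists(docs)
    doc_of, tokens, n_oov = _encode(token_docs, model.vocab_index, allow_oov=True)
    if n_oov:
        logger.warning("skipped %d out-of-vocabulary tokens during inference", n_oov)

    n_docs = len(token_docs)
    n_topics, n_vocab = model.n_topics, model.n_vocab
    n_dk = np.zeros((n_docs, n_topics), np.int64)
    acc_dk = np.zeros((n_docs, n_topics), np.int64)
    acc_wk = np.zeros((n_vocab, n_topics), np.int64)

    _seed_rng(derive_seed(seed, "lda_infer"))
    if tokens.shape[0] > 0:
        dummy_kw = np.zeros((n_topics, n_vocab), np.int64)
        dummy_k = np.zeros(n_topics, np.int64)
        z = _init_assignments(doc_of, tokens, n_topics, n_dk, dummy_kw, dummy_k)
        n_samples = _infer_sweeps(
            doc_of, tokens, z, n_dk, model.n_kw, model.n_k,
            model.alpha, model.beta, n_vocab, burnin, iterations,
            acc_dk, acc_wk)
    else:
        n_samples = iterations - burnin

    n_d = n_dk.sum(axis=1).astype(float)
    mean_dk = acc_dk / max(n_samples, 1)
    theta = (mean_dk + model.alpha) / (n_d + n_topics * model.alpha)[:, None]
    empty = n_d == 0
    if empty.any():
        logger.warning("%d document(s) had no in-vocabulary tokens; uniform "
                       "topic mixture assigned", int(empty.sum()))
        theta[empty] = 1.0 / n_topics
    return InferenceResult(theta=theta, term_topic_counts=acc_wk,
                           n_samples=int(n_samples), n_oov_tokens=n_oov)


# ---------------------------------------------------------------------------
# term–topic probabilities
# ---------------------------------------------------------------------------

def term_topic_probabilities(model: TopicModel, weighting: str = "uniform") -> TermTopicMatrix:
    """p(topic | term), normalized per term.

    Under the default uniform topic prior, ``p(k | w) ∝ φ[k, w]``; with
    ``weighting="corpus_theta"`` topics are weighted by their corpus-mean
    document probability.  Terms never observed in training get an exactly
    uniform row and are flagged.
    """
    if weighting not in {"uniform", "corpus_theta"}:
        raise ValueError(f"unknown weighting {weighting!r}")
    weights = np.ones(model.n_topics)
    if weighting == "corpus_theta" and model.theta.shape[0] > 0:
        weights = model.theta.mean(axis=0)
    raw = (model.phi * weights[:, None]).T          # V×K
    observed = model.n_kw.sum(axis=0) > 0
    matrix = np.empty_like(raw)
    row_sums = raw.sum(axis=1)
    matrix[:] = raw / row_sums[:, None]
    matrix[~observed] = 1.0 / model.n_topics
    return TermTopicMatrix(matrix=matrix, vocabulary=list(model.vocabulary),
                           observed=observed)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: TopicModel, directory: str | Path) -> None:
    """Write φ, θ, topic–term counts, vocabulary and hyperparameters.

    Token-level assignments are not persisted; a reloaded model supports
    likelihood evaluation, term–topic probabilities and held-out
    inference.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / "phi.tsv", model.phi, delimiter="\t", fmt="%.17g")
    np.savetxt(d / "theta.tsv", model.theta, delimiter="\t", fmt="%.17g")
    np.savetxt(d / "n_kw.tsv", model.n_kw, delimiter="\t", fmt="%d")
    with (d / "vocabulary.tsv").open("w", encoding="utf-8") as fh:
        for i, w in enumerate(model.vocabulary):
            fh.write(f"{w}\t{i}\n")
    params = {
        "n_topics": model.n_topics, "alpha": model.alpha, "beta": model.beta,
        "seed": model.seed, "init_log_likelihood": model.init_log_likelihood,
    }
    (d / "params.json").write_text(json.dumps(params, indent=2, sort_keys=True))


def load_model(directory: str | Path) -> TopicModel:
    d = Path(directory)
    params = json.loads((d / "params.json").read_text())
    n_kw = np.loadtxt(d / "n_kw.tsv", delimiter="\t", dtype=np.int64, ndmin=2)
    phi = np.loadtxt(d / "phi.tsv", delimiter="\t", ndmin=2)
    theta = np.loadtxt(d / "theta.tsv", delimiter="\t", ndmin=2)
    if theta.size == 0:
        theta = theta.reshape(0, params["n_topics"])
    vocabulary = []
    with (d / "vocabulary.tsv").open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                vocabulary.append(line.rstrip("\n").split("\t")[0])
    return TopicModel(
        n_topics=int(params["n_topics"]), alpha=float(params["alpha"]),
        beta=float(params["beta"]), phi=phi, theta=theta,
        vocabulary=vocabulary, n_kw=n_kw, n_k=n_kw.sum(axis=1),
        seed=int(params["seed"]),
        init_log_likelihood=float(params["init_log_likelihood"]),
    )
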