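"""Synthetic corpora with planted setting signatures.

Real problem-list corpora are not shareable, so every downstream stage is
exercised on generated data with known structure.  Each practice setting
owns a disjoint *signature* set of concepts; a document from a setting is
a bag of concepts whose tokens come from the setting's signature with
probability ``signature_fraction`` and otherwise from a background pool
shared uniformly by all settings.  A matching co-occurrence database
gives pairs within the same signature an elevated Poisson mean, emulating
literature-level co-occurrence of clinically related concepts.

The module also provides a plain LDA benchmark generator
(:func:`generate_lda_corpus`) with disjoint topic vocabularies, used to
test topic recovery in isolation from the filtering stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

from ._seeds import derive_seed
from .cooccurrence import CooccurrenceDB
from .corpus import ConceptDocument, Corpus
from .errors import ValidationError

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_corpus",
    "generate_cooccurrence_db",
    "generate_lda_corpus",
    "write_ground_truth",
    "read_ground_truth",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the planted-signature generator.

    Parameters
    ----------
    n_settings : S, number of practice settings.
    signature_size : m, signature concepts owned by each setting.
    n_background : B, concepts in the shared background pool.
    docs_per_setting : D, documents generated per setting.
    mean_doc_length : λ, Poisson mean of the document length in concept
        tokens (floored at 1 token).
    signature_fraction : π, probability that a token is drawn from the
        document's own signature rather than the background pool.
    background_cooc_mean : μ0, Poisson mean of the co-occurrence count for
        an arbitrary concept pair.
    signature_cooc_mean : μ1, Poisson mean for a pair inside one
        setting's signature (elevated when μ1 > μ0).
    zipf_exponent : optional power-law exponent for within-pool concept
        popularity (None = uniform); a stress-test knob.
    seed : root seed; all draws derive from it deterministically.
    """

    n_settings: int = 8
    signature_size: int = 20
    n_background: int = 200
    docs_per_setting: int = 100
    mean_doc_length: float = 15.0
    signature_fraction: float = 0.8
    background_cooc_mean: float = 1.0
    signature_cooc_mean: float = 10.0
    zipf_exponent: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_settings, self.signature_size, self.n_background,
               self.docs_per_setting) < 1:
            raise ValidationError("n_settings, signature_size, n_background, "
                                  "docs_per_setting must all be >= 1")
        if self.mean_doc_length <= 0:
            raise ValidationError("mean_doc_length must be > 0")
        if not 0.0 <= self.signature_fraction <= 1.0:
            raise ValidationError("signature_fraction must lie in [0, 1]")
        if self.background_cooc_mean < 0 or self.signature_cooc_mean < 0:
            raise ValidationError("co-occurrence means must be >= 0")

    # -- deterministic concept/setting naming -------------------------------
    def setting_names(self) -> list[str]:
        return [f"Setting{i + 1:02d}" for i in range(self.n_settings)]

    def signature_concepts(self, setting_index: int) -> list[str]:
        base = (setting_index + 1) * 10_000
        return [f"C{base + j:07d}" for j in range(self.signature_size)]

    def background_concepts(self) -> list[str]:
        return [f"C{9_000_000 + j:07d}" for j in range(self.n_background)]


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure: which concepts signal which setting."""

    signatures: dict[str, frozenset[str]]
    background: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        all_sigs: set[str] = set()
        sizes = {len(s) for s in self.signatures.values()}
        if len(sizes) > 1:
            raise ValidationError("signature sets must all have the same size")
        for s in self.signatures.values():
            if all_sigs & s:
                raise ValidationError("signature sets must be pairwise disjoint")
            all_sigs |= s

    @property
    def settings(self) -> list[str]:
        return sorted(self.signatures)

    def setting_of(self, concept: str) -> str | None:
        for setting, sig in self.signatures.items():
            if concept in sig:
                return setting
        return None


def _pool_weights(size: int, exponent: float | None) -> np.ndarray | None:
    if exponent is None:
        return None
    w = (np.arange(1, size + 1, dtype=float)) ** (-exponent)
    return w / w.sum()


def generate_corpus(cfg: SyntheticConfig) -> tuple[Corpus, GroundTruth]:
    """Generate ``S * D`` documents with planted signatures.

    Per-setting draws use sub-seeds derived from ``(seed, setting)``, so the
    documents of one setting are invariant to the presence of the others.
    """
    settings = cfg.setting_names()
    background = cfg.background_concepts()
    bg_weights = _pool_weights(len(background), cfg.zipf_exponent)
    signatures: dict[str, frozenset[str]] = {}
    docs: list[ConceptDocument] = []
    for si, setting in enumerate(settings):
        sig = cfg.signature_concepts(si)
        signatures[setting] = frozenset(sig)
        sig_weights = _pool_weights(len(sig), cfg.zipf_exponent)
        rng = np.random.default_rng(derive_seed(cfg.seed, "corpus", setting))
        for d in range(cfg.docs_per_setting):
            length = max(1, int(rng.poisson(cfg.mean_doc_length)))
            from_sig = rng.random(length) < cfg.signature_fraction
            tokens = [
                (rng.choice(sig, p=sig_weights) if hit
                 else rng.choice(background, p=bg_weights))
                for hit in from_sig
            ]
            docs.append(ConceptDocument(f"{setting}-{d:04d}", setting, tuple(tokens)))
    truth = GroundTruth(signatures=signatures, background=frozenset(background))
    return Corpus(docs), truth


def generate_cooccurrence_db(truth: GroundTruth, cfg: SyntheticConfig) -> CooccurrenceDB:
    """Poisson pair counts over the full concept universe.

    A pair drawn from one setting's signature has mean
    ``signature_cooc_mean``; every other pair has mean
    ``background_cooc_mean``.  Zero draws are simply absent from the store
    (absent ⇒ count 0).
    """
    universe = sorted(set().union(*truth.signatures.values()) | set(truth.background))
    setting_of = {c: s for s, sig in truth.signatures.items() for c in sig}
    pairs = list(combinations(universe, 2))
    means = np.full(len(pairs), float(cfg.background_cooc_mean))
    for i, (a, b) in enumerate(pairs):
        sa = setting_of.get(a)
        if sa is not None and sa == setting_of.get(b):
            means[i] = cfg.signature_cooc_mean
    rng = np.random.default_rng(derive_seed(cfg.seed, "cooccurrence"))
    counts = rng.poisson(means)
    db = CooccurrenceDB(concepts=universe)
    for (a, b), n in zip(pairs, counts):
        if n > 0:
            db.set(a, b, int(n))
    return db


def generate_lda_corpus(
    n_topics: int,
    vocab_size: int,
    n_docs: int,
    mean_doc_length: float,
    doc_concentration: float = 0.5,
    seed: int = 0,
) -> tuple[list[list[str]], np.ndarray, list[str]]:
    """Sample documents from an LDA model with disjoint topic vocabularies.

    The vocabulary is split into ``n_topics`` equal blocks; topic ``k`` is
    uniform over its block.  Document topic weights are
    Dirichlet(``doc_concentration``).  Returns ``(documents, phi,
    vocabulary)`` where ``phi`` is the generating K×V topic–term matrix.
    """
    if vocab_size % n_topics != 0:
        raise ValidationError("vocab_size must be a multiple of n_topics")
    block = vocab_size // n_topics
    vocabulary = [f"C{8_000_000 + j:07d}" for j in range(vocab_size)]
    phi = np.zeros((n_topics, vocab_size))
    for k in range(n_topics):
        phi[k, k * block:(k + 1) * block] = 1.0 / block
    rng = np.random.default_rng(derive_seed(seed, "lda_corpus"))
    docs: list[list[str]] = []
    for _ in range(n_docs):
        theta = rng.dirichlet(np.full(n_topics, doc_concentration))
        length = max(1, int(rng.poisson(mean_doc_length)))
        zs = rng.choice(n_topics, size=length, p=theta)
        words = [vocabulary[k * block + rng.integers(block)] for k in zs]
        docs.append(words)
    return docs, phi, vocabulary


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write signatures as ``setting<TAB>concept`` lines."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for setting in truth.settings:
            for concept in sorted(truth.signatures[setting]):
                fh.write(f"{setting}\t{concept}\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    signatures: dict[str, set[str]] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            setting, concept = line.split("\t")
            signatures.setdefault(setting, set()).add(concept)
    return GroundTruth({s: frozenset(c) for s, c in signatures.items()})
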