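"""Concept-annotated clinical documents and practice-setting handling.

A *corpus* is an ordered collection of notes, each carrying a unique
document id, a practice-setting label and a multiset of normalized
problem concepts (CUI-like identifiers).  Raw institutional setting
labels (e.g. ``Family Medicine BA``) are merged into general settings
(``Family Medicine``) through a user-supplied mapping table; concepts can
be restricted to an allow-list such as a problem-list subset of a
terminology; and fixed-size per-setting samples are drawn for the
downstream association analysis.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from ._seeds import derive_seed
from .errors import DataError, ParseError, ValidationError

__all__ = [
    "ConceptDocument",
    "Corpus",
    "SettingMap",
    "read_corpus",
    "write_corpus",
    "read_setting_map",
    "read_allowlist",
    "aggregate_settings",
    "filter_to_allowlist",
    "sample_per_setting",
]


@dataclass(frozen=True)
class ConceptDocument:
    """One clinical note: id, practice-setting label, multiset of concepts.

    Repeated mentions of a concept are kept as repeats in ``concepts``;
    multiplicity matters for the frequency term of the concept-weighting
    score downstream.
    """

    doc_id: str
    setting: str
    concepts: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValidationError("doc_id must be a non-empty string")
        if not self.setting:
            raise ValidationError(f"document {self.doc_id!r}: empty setting label")
        for c in self.concepts:
            if not c:
                raise ValidationError(f"document {self.doc_id!r}: empty concept id")
        object.__setattr__(self, "concepts", tuple(self.concepts))

    def concept_counts(self) -> Counter:
        """Multiplicity of each concept in this document."""
        return Counter(self.concepts)


class Corpus:
    """Ordered collection of :class:`ConceptDocument` with unique ids."""

    def __init__(self, documents: Iterable[ConceptDocument] = ()):
        self._documents: list[ConceptDocument] = list(documents)
        seen: set[str] = set()
        for doc in self._documents:
            if doc.doc_id in seen:
                raise ValidationError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._documents)

    def __iter__(self) -> Iterator[ConceptDocument]:
        return iter(self._documents)

    def __getitem__(self, i: int) -> ConceptDocument:
        return self._documents[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self._documents == other._documents

    def __repr__(self) -> str:
        return (
            f"<Corpus: {len(self)} documents, "
            f"{len(self.settings)} settings, "
            f"{len(self.concept_vocabulary)} concepts>"
        )

    # -- derived vocabularies ----------------------------------------------
    @property
    def documents(self) -> list[ConceptDocument]:
        return list(self._documents)

    @property
    def settings(self) -> list[str]:
        """Sorted distinct setting labels."""
        return sorted({d.setting for d in self._documents})

    @property
    def concept_vocabulary(self) -> list[str]:
        """Sorted distinct concept ids across all documents."""
        vocab: set[str] = set()
        for d in self._documents:
            vocab.update(d.concepts)
        return sorted(vocab)

    def documents_by_setting(self) -> dict[str, list[ConceptDocument]]:
        groups: dict[str, list[ConceptDocument]] = defaultdict(list)
        for d in self._documents:
            groups[d.setting].append(d)
        return dict(groups)


@dataclass(frozen=True)
class SettingMap:
    """Total mapping from raw setting labels to aggregated setting labels."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        for raw, agg in self.entries.items():
            if not agg:
                raise ValidationError(f"raw setting {raw!r} maps to an empty name")
        object.__setattr__(self, "entries", dict(self.entries))

    def __contains__(self, raw: str) -> bool:
        return raw in self.entries

    def __getitem__(self, raw: str) -> str:
        return self.entries[raw]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Read a corpus from JSON-lines or TSV.

    JSONL: one object per line with keys ``doc_id``, ``setting`` and
    ``concepts`` (array of strings, repeats allowed).  TSV:
    ``doc_id<TAB>setting<TAB>comma-joined concepts``.  ``format`` is
    inferred from the suffix when omitted.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    docs: list[ConceptDocument] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            try:
                if fmt == "jsonl":
                    rec = json.loads(line)
                    doc = ConceptDocument(
                        doc_id=str(rec["doc_id"]),
                        setting=str(rec["setting"]),
                        concepts=tuple(str(c) for c in rec["concepts"]),
                    )
                else:
                    fields = line.split("\t")
                    if len(fields) != 3:
                        raise ValueError(f"expected 3 tab-separated fields, got {len(fields)}")
                    concepts = tuple(fields[2].split(",")) if fields[2] else ()
                    doc = ConceptDocument(fields[0], fields[1], concepts)
            except ValidationError:
                raise
            except (KeyError, ValueError, TypeError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed record: {exc}") from exc
            docs.append(doc)
    return Corpus(docs)


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus as JSONL or TSV (see :func:`read_corpus` for layouts)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in corpus:
            if fmt == "jsonl":
                fh.write(
                    json.dumps(
                        {"doc_id": doc.doc_id, "setting": doc.setting,
                         "concepts": list(doc.concepts)},
                        ensure_ascii=False,
                    )
                    + "\n"
                )
            else:
                fh.write(f"{doc.doc_id}\t{doc.setting}\t{','.join(doc.concepts)}\n")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".jsonl", ".ndjson", ".json"}:
        return "jsonl"
    if suffix in {".tsv", ".txt"}:
        return "tsv"
    raise DataError(f"cannot infer corpus format from suffix {suffix!r}; pass format=")


def read_setting_map(path: str | Path, header: bool = False) -> SettingMap:
    """Read a raw-setting → aggregated-setting TSV (two columns, UTF-8)."""
    path = Path(path)
    entries: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
            entries[fields[0]] = fields[1]
    return SettingMap(entries)


def read_allowlist(path: str | Path) -> set[str]:
    """Read a concept allow-list: one concept id per line."""
    with Path(path).open("r", encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def aggregate_settings(
    corpus: Corpus,
    setting_map: SettingMap,
    unmapped_policy: str = "error",
) -> Corpus:
    """Replace each document's raw setting by its aggregated setting.

    ``unmapped_policy`` controls documents whose raw setting has no map
    entry: ``"error"`` raises (listing the offending settings),
    ``"drop"`` removes them, ``"passthrough"`` keeps the raw label.
    """
    if unmapped_policy not in {"error", "drop", "passthrough"}:
        raise ValueError(f"unknown unmapped_policy {unmapped_policy!r}")
    unmapped = sorted({d.setting for d in corpus if d.setting not in setting_map})
    if unmapped and unmapped_policy == "error":
        raise DataError(
            "settings missing from the aggregation map: " + ", ".join(unmapped)
        )
    out: list[ConceptDocument] = []
    for doc in corpus:
        if doc.setting in setting_map:
            out.append(ConceptDocument(doc.doc_id, setting_map[doc.setting], doc.concepts))
        elif unmapped_policy == "passthrough":
            out.append(doc)
        # drop: skip
    return Corpus(out)


def filter_to_allowlist(
    corpus: Corpus,
    allowed: Iterable[str],
    drop_empty: bool = True,
) -> Corpus:
    """Remove concepts outside ``allowed`` from every document.

    Documents left with no concepts are dropped iff ``drop_empty``.
    """
    if allowed is None:
        raise ValueError("allowed must not be None")
    allowed = set(allowed)
    out: list[ConceptDocument] = []
    for doc in corpus:
        kept = tuple(c for c in doc.concepts if c in allowed)
        if not kept and drop_empty:
            continue
        out.append(ConceptDocument(doc.doc_id, doc.setting, kept))
    return Corpus(out)


def sample_per_setting(corpus: Corpus, n: int, seed: int) -> Corpus:
    """Draw up to ``n`` documents per setting, uniformly without replacement.

    The draw for each setting uses a sub-seed derived from ``(seed,
    setting)``, so adding or removing one setting leaves the samples of the
    others unchanged.  Selected documents keep their original corpus order.
    The study design this mirrors sampled 1000 notes per aggregated setting.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    positions_by_setting: dict[str, list[int]] = defaultdict(list)
    for i, doc in enumerate(corpus):
        positions_by_setting[doc.setting].append(i)
    selected: set[int] = set()
    for setting, positions in positions_by_setting.items():
        rng = np.random.default_rng(derive_seed(seed, "sample_per_setting", setting))
        k = min(n, len(positions))
        chosen = rng.choice(len(positions), size=k, replace=False)
        selected.update(positions[j] for j in chosen)
    return Corpus(doc for i, doc in enumerate(corpus) if i in selected)
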