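"""Symmetric concept-pair co-occurrence store.

Holds article-level co-occurrence counts between concept pairs, the role
played by counts derived from a literature predication database in the
enrichment analysis.  Pairs are unordered; a pair absent from the store
has count zero; self-pairs are rejected.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import ParseError, ValidationError

__all__ = ["CooccurrenceDB", "read_cooccurrence_db", "write_cooccurrence_db"]


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


class CooccurrenceDB:
    """Unordered concept pair → non-negative co-occurrence count."""

    def __init__(
        self,
        counts: Mapping[tuple[str, str], int] | None = None,
        concepts: Iterable[str] | None = None,
    ):
        self._counts: dict[tuple[str, str], int] = {}
        if counts:
            for (a, b), n in counts.items():
                self.set(a, b, n)
        # Explicit universe lets zero-count pairs participate in averages.
        self._concepts: set[str] | None = set(concepts) if concepts is not None else None

    def set(self, a: str, b: str, count: int) -> None:
        if a == b:
            raise ValidationError(f"self-pair ({a!r}, {b!r}) not allowed")
        if count < 0:
            raise ValidationError(f"negative count for pair ({a!r}, {b!r})")
        if count == 0:
            self._counts.pop(_key(a, b), None)
        else:
            self._counts[_key(a, b)] = int(count)

    def get(self, a: str, b: str) -> int:
        """Count for the unordered pair; 0 if absent."""
        if a == b:
            raise ValidationError(f"self-pair ({a!r}, {b!r}) not allowed")
        return self._counts.get(_key(a, b), 0)

    @property
    def concepts(self) -> list[str]:
        """Sorted concept universe (explicit if given, else union of keys)."""
        if self._concepts is not None:
            return sorted(self._concepts)
        universe: set[str] = set()
        for a, b in self._counts:
            universe.add(a)
            universe.add(b)
        return sorted(universe)

    def items(self) -> Iterator[tuple[tuple[str, str], int]]:
        return iter(sorted(self._counts.items()))

    def __len__(self) -> int:
        return len(self._counts)

    def total(self) -> int:
        """Sum of all stored pair counts."""
        return sum(self._counts.values())

    def scaled(self, factor: int) -> "CooccurrenceDB":
        """New store with every pair count multiplied by ``factor``."""
        return CooccurrenceDB(
            {pair: n * factor for pair, n in self._counts.items()},
            concepts=self._concepts,
        )


def read_cooccurrence_db(path: str | Path, header: bool = False) -> CooccurrenceDB:
    """Read ``concept_a<TAB>concept_b<TAB>count`` (pairs stored once)."""
    path = Path(path)
    db = CooccurrenceDB()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated fields")
            try:
                count = int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer count {fields[2]!r}") from exc
            db.set(fields[0], fields[1], count)
    return db


def write_cooccurrence_db(db: CooccurrenceDB, path: str | Path) -> None:
    """Write pairs once, with ``concept_a < concept_b`` lexicographically."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for (a, b), n in db.items():
            fh.write(f"{a}\t{b}\t{n}\n")
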