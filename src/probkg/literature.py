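"""Literature co-occurrence counting.

Entity synonyms are compiled into a multi-pattern string automaton (a trie
with failure links, Aho-Corasick style) so that a single pass over each
document finds every entity mentioned.  A pair's count is the number of
documents mentioning both entities — document-level, so one paper contributes
at most 1 regardless of how often either name appears.

Matching is case-insensitive plain substring matching, which can overmatch
very short names; ``min_synonym_length`` (default 3) filters those out.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Iterator, Optional

import numpy as np

from .graph import CooccurrenceMatrix, EntityCatalog, RelationSpec

__all__ = ["NameMatcher", "build_name_matcher", "count_cooccurrence", "read_corpus"]


class NameMatcher:
    """Maps documents to the set of ``(entity_type, entity_id)`` keys mentioned.

    Behaviorally identical to scanning each synonym against the document with
    a naive substring search, but runs in one pass per document.
    """

    def __init__(self, patterns: dict[str, set[tuple[str, str]]]):
        if not patterns:
            raise ValueError("no synonyms to match")
        for pat in patterns:
            if pat == "":
                raise ValueError("empty synonym")
        # trie over lowercased patterns
        self._next: list[dict[str, int]] = [{}]
        self._out: list[set[tuple[str, str]]] = [set()]
        for pat, keys in patterns.items():
            node = 0
            for ch in pat:
                node = self._next[node].setdefault(ch, self._new_node())
            self._out[node] |= keys
        # failure links via BFS; output sets are merged along them
        self._fail = [0] * len(self._next)
        queue: deque[int] = deque()
        for node in self._next[0].values():
            queue.append(node)
        while queue:
            node = queue.popleft()
            for ch, child in self._next[node].items():
                queue.append(child)
                f = self._fail[node]
                while f and ch not in self._next[f]:
                    f = self._fail[f]
                self._fail[child] = self._next[f].get(ch, 0)
                if self._fail[child] == child:
                    self._fail[child] = 0
                self._out[child] |= self._out[self._fail[child]]

    def _new_node(self) -> int:
        self._next.append({})
        self._out.append(set())
        return len(self._next) - 1

    def match(self, document: str) -> set[tuple[str, str]]:
        """Entities with at least one synonym occurring as a substring."""
        hits: set[tuple[str, str]] = set()
        node = 0
        for ch in document.lower():
            while node and ch not in self._next[node]:
                node = self._fail[node]
            node = self._next[node].get(ch, 0)
            if self._out[node]:
                hits |= self._out[node]
        return hits


def build_name_matcher(
    catalog: EntityCatalog,
    min_synonym_length: int = 3,
) -> NameMatcher:
    """Compile the catalog's synonym dictionary into a :class:`NameMatcher`.

    Synonyms shorter than ``min_synonym_length`` are dropped (substring
    matching overmatches short names).  Raises if an entity's synonym is
    empty, or if no synonym at all survives the length filter.
    """
    patterns: dict[str, set[tuple[str, str]]] = {}
    for etype, table in catalog.synonyms.items():
        for eid, names in table.items():
            for name in names:
                if name == "":
                    raise ValueError(f"empty synonym for entity {eid!r}")
                if len(name) < min_synonym_length:
                    continue
                patterns.setdefault(name.lower(), set()).add((etype, eid))
    if not patterns:
        raise ValueError("no synonyms survive the minimum-length filter")
    return NameMatcher(patterns)


def count_cooccurrence(
    corpus: Iterable[str],
    matcher: NameMatcher,
    spec: RelationSpec,
    catalog: EntityCatalog,
) -> CooccurrenceMatrix:
    """Count, per entity pair of the relation's endpoint types, the number of
    documents mentioning both entities."""
    if not spec.in_literature_set:
        raise ValueError(f"relation {spec.name!r} is not in the literature set")
    n_a = catalog.size(spec.source_type)
    n_b = catalog.size(spec.target_type)
    counts = np.zeros((n_a, n_b), dtype=np.int64)
    for doc in corpus:
        hits = matcher.match(doc)
        rows = [catalog.index(t, e) for t, e in hits if t == spec.source_type]
        cols = [catalog.index(t, e) for t, e in hits if t == spec.target_type]
        if rows and cols:
            counts[np.ix_(rows, cols)] += 1
    return CooccurrenceMatrix(spec, counts)


def read_corpus(path: str, per_file: bool = False) -> Iterator[str]:
    """Yield documents: one per line of a text file, or one per ``.txt`` file
    in a directory when ``per_file`` is set."""
    import os

    if per_file or os.path.isdir(path):
        for name in sorted(os.listdir(path)):
            if name.endswith(".txt"):
                with open(os.path.join(path, name)) as fh:
                    yield fh.read()
    else:
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line:
                    yield line
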