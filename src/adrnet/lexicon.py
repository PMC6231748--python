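"""Typed term lexicon mapping consumer expressions to preferred entity names.

Health consumers describe drugs, diseases and adverse reactions in lay
language ("no appetite" for *anorexia*), so dictionary-based extraction
needs a consumer-health-vocabulary-style lexicon: each preferred term of a
given entity type (``drug``, ``disease`` or ``adr``) carries a set of
surface expressions that all resolve to it.  Matching is performed on
normalized text, so every expression is stored normalized and the
expression index is the single source of truth for "which preferred term
does this phrase mean".

The on-disk dialect is a 3-column UTF-8 TSV with a header row::

    preferred_term<TAB>entity_type<TAB>expression

one row per expression; the preferred term itself is always an expression
of its own entry whether or not a row spells it out.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

ENTITY_TYPES = frozenset({"drug", "disease", "adr"})

_PUNCT = re.compile(r"[^\w\s]|_")
_WS = re.compile(r"\s+")


class LexiconError(ValueError):
    """Raised for invalid lexicon content (collisions, bad entity types)."""


def normalize_expression(text: str) -> str:
    """Normalize a surface expression or free text for matching.

    Lowercases, replaces punctuation with spaces, and collapses runs of
    whitespace.  Idempotent: ``normalize(normalize(x)) == normalize(x)``.

    >>> normalize_expression("No  Appetite!")
    'no appetite'
    """
    text = _PUNCT.sub(" ", text.lower())
    return _WS.sub(" ", text).strip()


@dataclass(frozen=True)
class LexiconEntry:
    """One preferred term with its normalized surface expressions."""

    preferred_term: str
    entity_type: str
    expressions: frozenset[str]

    def __post_init__(self) -> None:
        if self.entity_type not in ENTITY_TYPES:
            raise LexiconError(
                f"unknown entity_type {self.entity_type!r} for "
                f"{self.preferred_term!r}; expected one of {sorted(ENTITY_TYPES)}"
            )
        if not self.expressions:
            raise LexiconError(f"entry {self.preferred_term!r} has no expressions")
        for expr in self.expressions:
            if normalize_expression(expr) != expr:
                raise LexiconError(
                    f"expression {expr!r} of {self.preferred_term!r} is not normalized"
                )


@dataclass
class Lexicon:
    """Validated collection of entries plus the expression lookup index.

    ``expression_index`` maps each normalized expression to exactly one
    ``(preferred_term, entity_type)`` pair; a surface form claimed by two
    preferred terms is a hard load error because every thread-level count
    must be attributable to a single item.
    """

    entries: list[LexiconEntry] = field(default_factory=list)
    expression_index: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self.entries)

    def __contains__(self, preferred_term: str) -> bool:
        return any(e.preferred_term == preferred_term for e in self.entries)

    @property
    def term_types(self) -> dict[str, str]:
        """Mapping preferred term -> entity type."""
        return {e.preferred_term: e.entity_type for e in self.entries}

    def entry(self, preferred_term: str) -> LexiconEntry:
        for e in self.entries:
            if e.preferred_term == preferred_term:
                return e
        raise KeyError(preferred_term)

    def terms(self, entity_type: str | None = None) -> list[str]:
        return [
            e.preferred_term
            for e in self.entries
            if entity_type is None or e.entity_type == entity_type
        ]


def build_lexicon(rows: Iterable[tuple[str, str, str]]) -> Lexicon:
    """Build a lexicon from ``(preferred_term, entity_type, expression)`` rows.

    Rows for the same preferred term are merged; the preferred term itself
    is added to its own expression set.  Cross-entry expression collisions
    and duplicate preferred terms within an entity type are errors.
    """
    grouped: dict[tuple[str, str], set[str]] = {}
    seen_terms: dict[tuple[str, str], None] = {}
    for preferred, etype, expression in rows:
        preferred = normalize_expression(str(preferred))
        etype = str(etype).strip().lower()
        if etype not in ENTITY_TYPES:
            raise LexiconError(
                f"unknown entity_type {etype!r} for {preferred!r}; "
                f"expected one of {sorted(ENTITY_TYPES)}"
            )
        key = (preferred, etype)
        seen_terms[key] = None
        grouped.setdefault(key, set()).add(preferred)
        expr = normalize_expression(str(expression))
        if expr:
            grouped[key].add(expr)

    by_type_term: dict[tuple[str, str], None] = {}
    for preferred, etype in grouped:
        if (etype, preferred) in by_type_term:
            raise LexiconError(f"duplicate preferred term {preferred!r} of type {etype!r}")
        by_type_term[(etype, preferred)] = None

    entries: list[LexiconEntry] = []
    index: dict[str, tuple[str, str]] = {}
    for (preferred, etype), exprs in grouped.items():
        entry = LexiconEntry(preferred, etype, frozenset(exprs))
        for expr in sorted(exprs):
            if expr in index and index[expr][0] != preferred:
                raise LexiconError(
                    f"expression {expr!r} maps to both "
                    f"{index[expr][0]!r} and {preferred!r}"
                )
            index[expr] = (preferred, etype)
        entries.append(entry)
    entries.sort(key=lambda e: (e.entity_type, e.preferred_term))
    return Lexicon(entries=entries, expression_index=index)


def load_lexicon(path: str | Path) -> Lexicon:
    """Load and validate a lexicon from a 3-column TSV file."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return Lexicon()
    required = {"preferred_term", "entity_type", "expression"}
    missing = required - set(df.columns)
    if missing:
        raise LexiconError(f"{path}: missing columns {sorted(missing)}")
    return build_lexicon(
        df[["preferred_term", "entity_type", "expression"]].itertuples(index=False)
    )


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    """Write a lexicon as TSV; round-trips with :func:`load_lexicon`."""
    rows = [
        (e.preferred_term, e.entity_type, expr)
        for e in lexicon.entries
        for expr in sorted(e.expressions)
    ]
    pd.DataFrame(rows, columns=["preferred_term", "entity_type", "expression"]).to_csv(
        path, sep="\t", index=False
    )
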