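"""Dictionary-based entity extraction over normalized thread text.

Matching is greedy left-to-right longest-match over the token stream of
the normalized text, anchored at word boundaries, with non-overlapping
spans — the standard dictionary-NER convention, needed because consumer
health phrases nest ("appetite" inside "appetite loss").  Presence is
binary at thread level: a term mentioned in the post and three comments
counts once, which makes each thread a transaction (a subset of the item
vocabulary) for the downstream co-occurrence analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .corpus import Thread
from .lexicon import Lexicon, normalize_expression

PAIRABLE_TYPES = ("drug", "disease", "adr")


@dataclass(frozen=True)
class EntityMention:
    """A matched expression with its span in the normalized text."""

    thread_id: str
    preferred_term: str
    entity_type: str
    surface: str
    span: tuple[int, int]  # 0-based half-open, normalized-text coordinates


@dataclass
class ThreadEntities:
    """Binary per-thread presence of preferred terms, keyed by entity type."""

    thread_id: str
    present: dict[str, set[str]] = field(
        default_factory=lambda: {t: set() for t in PAIRABLE_TYPES}
    )

    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for terms in self.present.values():
            out |= terms
        return out


def _tokenize(text: str) -> list[tuple[str, int]]:
    """Tokens of a normalized text with their character offsets."""
    tokens: list[tuple[str, int]] = []
    offset = 0
    for tok in text.split(" "):
        if tok:
            tokens.append((tok, offset))
        offset += len(tok) + 1
    return tokens


def match_text(lexicon: Lexicon, text: str, thread_id: str = "") -> list[EntityMention]:
    """Match lexicon expressions in raw text; spans index the normalized text.

    Greedy left-to-right: at each token the longest matching expression
    wins and the scan resumes after it, so matched spans never overlap.
    """
    normalized = normalize_expression(text)
    if not normalized:
        return []
    tokens = _tokenize(normalized)
    index = lexicon.expression_index
    max_len = max((expr.count(" ") + 1 for expr in index), default=0)
    mentions: list[EntityMention] = []
    i = 0
    while i < len(tokens):
        matched = False
        for n in range(min(max_len, len(tokens) - i), 0, -1):
            start = tokens[i][1]
            last_tok, last_off = tokens[i + n - 1]
            end = last_off + len(last_tok)
            phrase = normalized[start:end]
            hit = index.get(phrase)
            if hit is not None:
                preferred, etype = hit
                mentions.append(
                    EntityMention(thread_id, preferred, etype, phrase, (start, end))
                )
                i += n
                matched = True
                break
        if not matched:
            i += 1
    return mentions


def extract_thread(lexicon: Lexicon, thread: Thread) -> ThreadEntities:
    """Union of preferred terms matched anywhere in the post or comments."""
    entities = ThreadEntities(thread_id=thread.thread_id)
    for text in thread.texts:
        for m in match_text(lexicon, text, thread_id=thread.thread_id):
            entities.present.setdefault(m.entity_type, set()).add(m.preferred_term)
    return entities


def extract_corpus(lexicon: Lexicon, corpus: Sequence[Thread]) -> list[ThreadEntities]:
    """Map :func:`extract_thread` over a corpus, preserving order."""
    seen: set[str] = set()
    out: list[ThreadEntities] = []
    for thread in corpus:
        if thread.thread_id in seen:
            raise ValueError(f"duplicate thread_id {thread.thread_id!r}")
        seen.add(thread.thread_id)
        out.append(extract_thread(lexicon, thread))
    return out


def corpus_mentions(lexicon: Lexicon, corpus: Sequence[Thread]) -> list[EntityMention]:
    """All mentions across a corpus (per-text spans, post first)."""
    mentions: list[EntityMention] = []
    for thread in corpus:
        for text in thread.texts:
            mentions.extend(match_text(lexicon, text, thread_id=thread.thread_id))
    return mentions


def write_mentions_tsv(mentions: Iterable[EntityMention], path: str | Path) -> None:
    rows = [
        (m.thread_id, m.entity_type, m.preferred_term, m.surface, m.span[0], m.span[1])
        for m in mentions
    ]
    pd.DataFrame(
        rows,
        columns=["thread_id", "entity_type", "preferred_term", "surface",
                 "span_start", "span_end"],
    ).to_csv(path, sep="\t", index=False)
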