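"""Thread-level co-occurrence counting and lift.

Each thread is a transaction — a set of preferred terms — and association
strength between two items ``a`` and ``b`` is the association-rule *lift*

    lift(a, b) = (count(a, b) / total) / ((count(a) / total) * (count(b) / total))

the ratio of the observed joint thread proportion to the proportion
expected if the items were independent: 1 means independence, above 1
positive association.  Only cross-type pairs are counted — drug-ADR,
disease-ADR and drug-disease — matching the 2-itemsets the downstream
network is built from.  A pair with a zero marginal count has no support
in the data; its lift is *undefined* rather than 0 or infinite, and such
pairs are reported separately so they can never rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .extraction import ThreadEntities

DEFAULT_PAIR_TYPES = frozenset(
    {frozenset({"adr", "drug"}), frozenset({"adr", "disease"}), frozenset({"drug", "disease"})}
)


@dataclass
class CountTable:
    """Per-thread binary presence counts for items and cross-type pairs."""

    total_count: int
    item_count: dict[str, int]
    item_type: dict[str, str]
    pair_count: dict[frozenset[str], int]
    pair_types: frozenset[frozenset[str]] = DEFAULT_PAIR_TYPES

    def pairs(self) -> list[frozenset[str]]:
        """Every countable cross-type pair among the table's items."""
        out = []
        for a, b in combinations(sorted(self.item_count), 2):
            if frozenset({self.item_type[a], self.item_type[b]}) in self.pair_types:
                out.append(frozenset({a, b}))
        return out

    def get_pair(self, a: str, b: str) -> int:
        return self.pair_count.get(frozenset({a, b}), 0)


@dataclass(frozen=True)
class LiftScore:
    a: str
    b: str
    types: tuple[str, str]
    value: float
    defined: bool = True


def count_entities(
    entities: Sequence[ThreadEntities],
    pair_types: Iterable[frozenset[str]] = DEFAULT_PAIR_TYPES,
    vocabulary: Mapping[str, str] | None = None,
) -> CountTable:
    """Count item and pair presence over threads.

    ``vocabulary`` (term -> entity type) optionally forces items into the
    table even when never observed, so their pairs surface as undefined.
    Duplicate thread ids violate the transaction-set model and raise.
    """
    pair_types = frozenset(frozenset(p) for p in pair_types)
    seen_ids: set[str] = set()
    item_count: dict[str, int] = {}
    item_type: dict[str, str] = {}
    pair_count: dict[frozenset[str], int] = {}
    if vocabulary:
        for term, etype in vocabulary.items():
            item_count[term] = 0
            item_type[term] = etype
    for te in entities:
        if te.thread_id in seen_ids:
            raise ValueError(f"duplicate thread_id {te.thread_id!r}")
        seen_ids.add(te.thread_id)
        typed = [
            (term, etype) for etype, terms in te.present.items() for term in sorted(terms)
        ]
        for term, etype in typed:
            item_count[term] = item_count.get(term, 0) + 1
            item_type[term] = etype
        for (ta, tya), (tb, tyb) in combinations(typed, 2):
            if frozenset({tya, tyb}) in pair_types:
                key = frozenset({ta, tb})
                pair_count[key] = pair_count.get(key, 0) + 1
    return CountTable(
        total_count=len(entities),
        item_count=item_count,
        item_type=item_type,
        pair_count=pair_count,
        pair_types=pair_types,
    )


def lift(table: CountTable, a: str, b: str) -> LiftScore:
    """Lift of an item pair from a count table; symmetric in ``a, b``."""
    if table.total_count == 0:
        raise ValueError("lift undefined on an empty table (total_count = 0)")
    n_a = table.item_count.get(a, 0)
    n_b = table.item_count.get(b, 0)
    types = (table.item_type.get(a, "unknown"), table.item_type.get(b, "unknown"))
    if n_a == 0 or n_b == 0:
        return LiftScore(a=a, b=b, types=types, value=0.0, defined=False)
    n_ab = table.get_pair(a, b)
    total = table.total_count
    value = (n_ab / total) / ((n_a / total) * (n_b / total))
    return LiftScore(a=a, b=b, types=types, value=value, defined=True)


def all_pair_lifts(table: CountTable) -> list[LiftScore]:
    """Lift for every countable pair with both marginals positive."""
    scores = []
    for pair in table.pairs():
        a, b = sorted(pair)
        s = lift(table, a, b)
        if s.defined:
            scores.append(s)
    return scores


def undefined_pairs(table: CountTable) -> list[frozenset[str]]:
    """Countable pairs whose lift is undefined (a zero marginal)."""
    return [
        p for p in table.pairs() if any(table.item_count[t] == 0 for t in p)
    ]


def write_lifts_tsv(table: CountTable, scores: Iterable[LiftScore], path: str | Path) -> None:
    rows = []
    for s in scores:
        rows.append(
            (
                s.types[0], s.a, s.types[1], s.b,
                table.item_count.get(s.a, 0), table.item_count.get(s.b, 0),
                table.get_pair(s.a, s.b), table.total_count, s.value,
            )
        )
    pd.DataFrame(
        rows,
        columns=["type_a", "term_a", "type_b", "term_b", "count_a", "count_b",
                 "count_pair", "total", "lift"],
    ).to_csv(path, sep="\t", index=False)
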