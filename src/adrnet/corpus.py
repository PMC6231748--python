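"""Thread corpus: data model, JSONL interchange, and a synthetic generator.

The analysis unit throughout the package is the *thread* — an original
forum post together with all of its comments.  Real crawls of online
health communities are not redistributable, so this module also provides
a synthetic-corpus generator with *planted* co-mention structure:

* each thread draws at most one entity *pattern* (a set of preferred
  terms) from a categorical distribution ``{q_k}`` (residual probability
  mass produces a thread with no planted pattern), and
* every entity in the generator's universe is additionally switched on
  independently with a background rate ``epsilon``.

Entity presence is realized by inserting one uniformly chosen surface
expression of the entity into filler text of the post or a comment.
Because pattern draw and background events are independent, the lift of
any entity pair under the generator has a closed form
(:func:`expected_lift`), which downstream modules use as an analytic
oracle for the co-occurrence statistics they estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .lexicon import Lexicon


class CorpusError(ValueError):
    """Raised for malformed corpus files or invalid generator configs."""


@dataclass(frozen=True)
class Thread:
    """One forum thread: the original post plus all following comments."""

    thread_id: str
    post: str
    comments: tuple[str, ...] = ()
    timestamp: str | None = None

    def __post_init__(self) -> None:
        if not self.post and not self.comments:
            raise CorpusError(f"thread {self.thread_id!r} has empty post and no comments")

    @property
    def texts(self) -> tuple[str, ...]:
        """Post followed by comments, in order."""
        return (self.post, *self.comments)


def read_corpus(path: str | Path) -> list[Thread]:
    """Read a JSONL corpus (one thread object per line), preserving order.

    Each line must be a JSON object with keys ``thread_id``, ``post`` and
    ``comments``; ``timestamp`` is optional.  Malformed lines and duplicate
    thread ids raise :class:`CorpusError` naming the offending line.
    """
    threads: list[Thread] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            missing = {"thread_id", "post", "comments"} - set(obj)
            if missing:
                raise CorpusError(f"{path}:{lineno}: missing keys {sorted(missing)}")
            tid = str(obj["thread_id"])
            if tid in seen:
                raise CorpusError(f"{path}:{lineno}: duplicate thread_id {tid!r}")
            seen.add(tid)
            threads.append(
                Thread(
                    thread_id=tid,
                    post=str(obj["post"]),
                    comments=tuple(str(c) for c in obj["comments"]),
                    timestamp=obj.get("timestamp"),
                )
            )
    return threads


def write_corpus(threads: Iterable[Thread], path: str | Path) -> None:
    """Write threads as JSONL; round-trips with :func:`read_corpus`."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in threads:
            obj: dict = {"thread_id": t.thread_id, "post": t.post, "comments": list(t.comments)}
            if t.timestamp is not None:
                obj["timestamp"] = t.timestamp
            fh.write(json.dumps(obj, ensure_ascii=False, sort_keys=True) + "\n")


_DEFAULT_FILLER = (
    "today", "again", "really", "morning", "doctor", "visit", "week",
    "feeling", "better", "worse", "started", "stopped", "asked", "told",
    "anyone", "else", "thanks", "update", "still", "maybe",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the planted-pattern synthetic corpus.

    ``patterns`` is a list of ``(entity_set, q)`` pairs with ``sum(q) <= 1``;
    the residual mass yields threads with no planted pattern.
    ``background_rate`` switches each universe entity on independently per
    thread.  All pattern entities must be preferred terms of ``lexicon``.
    """

    n_threads: int
    patterns: tuple[tuple[frozenset[str], float], ...]
    background_rate: float
    lexicon: Lexicon
    filler_vocabulary: tuple[str, ...] = _DEFAULT_FILLER
    seed: int = 0
    comments_range: tuple[int, int] = (1, 4)
    words_per_text: tuple[int, int] = (6, 14)

    def __post_init__(self) -> None:
        if self.n_threads < 0:
            raise CorpusError("n_threads must be non-negative")
        if not 0.0 <= self.background_rate < 1.0:
            raise CorpusError("background_rate must lie in [0, 1)")
        total_q = 0.0
        for entities, q in self.patterns:
            if not 0.0 <= q <= 1.0:
                raise CorpusError(f"pattern probability {q} outside [0, 1]")
            total_q += q
            for term in entities:
                if term not in self.lexicon:
                    raise CorpusError(f"pattern entity {term!r} not in lexicon")
        if total_q > 1.0 + 1e-12:
            raise CorpusError(f"pattern probabilities sum to {total_q} > 1")
        if not self.filler_vocabulary:
            raise CorpusError("filler_vocabulary must be non-empty")

    @property
    def entities(self) -> tuple[str, ...]:
        """Sorted universe of entities referenced by any pattern."""
        universe: set[str] = set()
        for entity_set, _ in self.patterns:
            universe |= entity_set
        return tuple(sorted(universe))

    @classmethod
    def from_dict(cls, obj: dict, lexicon: Lexicon) -> "GeneratorConfig":
        """Build a config from a plain JSON-style dict (CLI config files)."""
        patterns = tuple(
            (frozenset(p["entities"]), float(p["q"])) for p in obj.get("patterns", [])
        )
        kwargs: dict = {}
        if "filler_vocabulary" in obj:
            kwargs["filler_vocabulary"] = tuple(obj["filler_vocabulary"])
        return cls(
            n_threads=int(obj["n_threads"]),
            patterns=patterns,
            background_rate=float(obj.get("background_rate", 0.0)),
            lexicon=lexicon,
            seed=int(obj.get("seed", 0)),
            **kwargs,
        )


def _planted_presence(config: GeneratorConfig, rng: np.random.Generator) -> list[set[str]]:
    universe = config.entities
    probs = np.array([q for _, q in config.patterns], dtype=float)
    cut = np.concatenate([np.cumsum(probs), [np.inf]])
    presence: list[set[str]] = []
    for _ in range(config.n_threads):
        present: set[str] = set()
        u = rng.random()
        k = int(np.searchsorted(cut, u, side="right"))
        if k < len(config.patterns):
            present |= config.patterns[k][0]
        if config.background_rate > 0.0:
            for term in universe:
                if rng.random() < config.background_rate:
                    present.add(term)
        presence.append(present)
    return presence


def _filler(config: GeneratorConfig, rng: np.random.Generator) -> list[str]:
    lo, hi = config.words_per_text
    n = int(rng.integers(lo, hi + 1))
    return [config.filler_vocabulary[int(i)]
            for i in rng.integers(0, len(config.filler_vocabulary), size=n)]


def generate_corpus_with_truth(
    config: GeneratorConfig,
) -> tuple[list[Thread], list[set[str]]]:
    """Generate threads and return the planted presence set per thread.

    Deterministic given ``config.seed``.  Each present entity is realized
    exactly once, as a uniformly chosen surface expression inserted at a
    random word boundary of the post or of one comment.
    """
    rng = np.random.default_rng(config.seed)
    presence = _planted_presence(config, rng)
    threads: list[Thread] = []
    lo_c, hi_c = config.comments_range
    for i, present in enumerate(presence):
        n_comments = int(rng.integers(lo_c, hi_c + 1))
        texts = [_filler(config, rng) for _ in range(1 + n_comments)]
        for term in sorted(present):
            expressions = sorted(config.lexicon.entry(term).expressions)
            expr = expressions[int(rng.integers(0, len(expressions)))]
            target = texts[int(rng.integers(0, len(texts)))]
            pos = int(rng.integers(0, len(target) + 1))
            target.insert(pos, expr)
        threads.append(
            Thread(
                thread_id=f"t{i:06d}",
                post=" ".join(texts[0]),
                comments=tuple(" ".join(t) for t in texts[1:]),
            )
        )
    return threads, presence


def generate_corpus(config: GeneratorConfig) -> list[Thread]:
    """Generate a synthetic corpus (see :func:`generate_corpus_with_truth`)."""
    return generate_corpus_with_truth(config)[0]


def expected_lift(config: GeneratorConfig, a: str, b: str) -> float:
    """Closed-form lift of pair ``(a, b)`` under the generator model.

    With ``a_e = sum of q_k over patterns containing e`` and ``a_ab`` the
    analogous joint mass, inclusion-exclusion over the single pattern draw
    and the two independent background events gives::

        P(e)    = a_e + (1 - a_e) * eps
        P(a, b) = a_ab + (a_a - a_ab) * eps + (a_b - a_ab) * eps
                  + (1 - a_a - a_b + a_ab) * eps**2

    and the lift is ``P(a, b) / (P(a) * P(b))``.
    """
    universe = set(config.entities)
    if a not in universe or b not in universe:
        raise CorpusError(f"entities {a!r}, {b!r} must be referenced by the config")
    eps = config.background_rate
    a_a = sum(q for entities, q in config.patterns if a in entities)
    a_b = sum(q for entities, q in config.patterns if b in entities)
    a_ab = sum(q for entities, q in config.patterns if a in entities and b in entities)
    p_a = a_a + (1.0 - a_a) * eps
    p_b = a_b + (1.0 - a_b) * eps
    p_ab = (
        a_ab
        + (a_a - a_ab) * eps
        + (a_b - a_ab) * eps
        + (1.0 - a_a - a_b + a_ab) * eps**2
    )
    if p_a == 0.0 or p_b == 0.0:
        raise CorpusError(f"lift of ({a!r}, {b!r}) undefined: a marginal probability is 0")
    return p_ab / (p_a * p_b)
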