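"""Candidate drug nomination from significant ADRs.

The repositioning hypothesis: if ADR X is significantly associated with
disease D, drugs listing X as a frequent side effect are candidates for
treating D.  Three steps: (1) look up, in a SIDER-style side-effect
table, the drugs listing a significant ADR with strong frequency
evidence — frequency class ``frequent``, ``common`` or ``postmarketing``,
or an occurrence percentage strictly above 10; (2) collect those
drug-disease pairs; (3) remove pairs already published as indications in
a PharmGKB-style table.  The survivors are the repositioning candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .lexicon import normalize_expression
from .significance import SignificanceResult

FREQUENCY_CLASSES = frozenset(
    {"frequent", "common", "postmarketing", "infrequent", "rare", "unknown"}
)
_PASSING_CLASSES = frozenset({"frequent", "common", "postmarketing"})


@dataclass(frozen=True)
class SideEffectRecord:
    """One drug-ADR row with frequency evidence (class and/or percentage)."""

    drug: str
    adr: str
    frequency_class: str | None = None
    frequency_percent: float | None = None

    def __post_init__(self) -> None:
        if self.frequency_class is None and self.frequency_percent is None:
            raise ValueError(
                f"side-effect record ({self.drug!r}, {self.adr!r}) needs a "
                "frequency class or percentage"
            )
        if self.frequency_class is not None and self.frequency_class not in FREQUENCY_CLASSES:
            raise ValueError(f"unknown frequency class {self.frequency_class!r}")
        if self.frequency_percent is not None and not 0.0 <= self.frequency_percent <= 100.0:
            raise ValueError(f"frequency percent {self.frequency_percent} outside [0, 100]")


@dataclass(frozen=True)
class IndicationRecord:
    drug: str
    disease: str


@dataclass(frozen=True)
class Candidate:
    """A nominated drug with its supporting significant ADRs."""

    drug: str
    supporting_adrs: frozenset[str]
    aggregate_score: float
    n_supporting: int


def passes_frequency_filter(record: SideEffectRecord) -> bool:
    """Frequency-evidence gate for a side-effect record.

    Passes iff the class is frequent/common/postmarketing or the
    percentage is strictly above 10 (a listed 10.0% fails).
    """
    if record.frequency_class in _PASSING_CLASSES:
        return True
    return record.frequency_percent is not None and record.frequency_percent > 10.0


def _parse_class(raw: str) -> str | None:
    cleaned = raw.strip().lower()
    if not cleaned:
        return None
    return cleaned if cleaned in FREQUENCY_CLASSES else "unknown"


def load_side_effects(path: str | Path) -> list[SideEffectRecord]:
    """Read a side-effect TSV: drug, adr, frequency_class, frequency_percent.

    Empty cells are allowed; unparseable class strings become ``unknown``
    (which fails the frequency filter).  Terms are normalized on load.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records: list[SideEffectRecord] = []
    for row in df.itertuples(index=False):
        pct_raw = getattr(row, "frequency_percent", "").strip()
        pct = float(pct_raw) if pct_raw else None
        cls = _parse_class(getattr(row, "frequency_class", ""))
        if cls is None and pct is None:
            cls = "unknown"
        records.append(
            SideEffectRecord(
                drug=normalize_expression(row.drug),
                adr=normalize_expression(row.adr),
                frequency_class=cls,
                frequency_percent=pct,
            )
        )
    return records


def load_indications(path: str | Path) -> list[IndicationRecord]:
    """Read an indication TSV with columns drug, disease (normalized)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        IndicationRecord(normalize_expression(r.drug), normalize_expression(r.disease))
        for r in df.itertuples(index=False)
    ]


def find_candidates(
    significant: Sequence[SignificanceResult],
    side_effects: Sequence[SideEffectRecord],
    indications: Sequence[IndicationRecord],
    disease: str,
) -> list[Candidate]:
    """Nominate repositioning candidates for ``disease``.

    A drug qualifies when at least one side-effect record passing the
    frequency filter names a significant ADR, and the drug has no known
    indication for the disease.  ``aggregate_score`` sums the disease-ADR
    scores of the supporting ADRs.  Candidates are sorted by number of
    supporting ADRs, then aggregate score (both descending), then name.
    """
    disease = normalize_expression(disease)
    sig_scores = {r.adr: r.score for r in significant if r.significant}
    indicated = {rec.drug for rec in indications if rec.disease == disease}
    support: dict[str, set[str]] = {}
    for rec in side_effects:
        if rec.adr in sig_scores and passes_frequency_filter(rec):
            support.setdefault(rec.drug, set()).add(rec.adr)
    candidates = [
        Candidate(
            drug=drug,
            supporting_adrs=frozenset(adrs),
            aggregate_score=sum(sig_scores[a] for a in adrs),
            n_supporting=len(adrs),
        )
        for drug, adrs in support.items()
        if drug not in indicated
    ]
    candidates.sort(key=lambda c: (-c.n_supporting, -c.aggregate_score, c.drug))
    return candidates


def write_candidates_tsv(candidates: Iterable[Candidate], path: str | Path) -> None:
    rows = [
        (c.drug, c.n_supporting, ",".join(sorted(c.supporting_adrs)), c.aggregate_score)
        for c in candidates
    ]
    pd.DataFrame(
        rows, columns=["drug", "n_supporting", "supporting_adrs", "aggregate_score"]
    ).to_csv(path, sep="\t", index=False)
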