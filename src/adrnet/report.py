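"""Summary artifacts: ADR detection matrix, evidence counts, correlation.

Also exposes the bundled reference tables for the published Parkinson
disease repositioning study this pipeline reproduces in miniature: the
44 nominated non-Parkinson drugs with their PubMed literature-evidence
flags, and their original labeled indications.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .repositioning import Candidate


@dataclass(frozen=True)
class EvidenceRecord:
    """Literature-evidence flags for one candidate drug.

    ``none`` must hold exactly when neither positive nor negative evidence
    exists — a record claiming both evidence and no-evidence is invalid.
    """

    drug: str
    positive: bool
    negative: bool
    none: bool

    def __post_init__(self) -> None:
        if self.none == (self.positive or self.negative):
            raise ValueError(
                f"evidence flags inconsistent for {self.drug!r}: "
                "'none' must be set iff neither positive nor negative is"
            )


@dataclass(frozen=True)
class EvidenceSummary:
    total: int
    with_evidence: int
    positive: int
    negative: int
    no_evidence: int


@dataclass
class AdrDetectionMatrix:
    """Drug x significant-ADR support flags with per-ADR totals.

    ``flags`` is a boolean DataFrame (rows drugs, columns ADRs);
    ``totals[adr]`` counts drugs supported by the ADR, and
    ``exclusive_totals[adr]`` counts drugs supported *only* by it.
    """

    flags: pd.DataFrame
    totals: pd.Series
    exclusive_totals: pd.Series


def detection_matrix(candidates: Sequence[Candidate]) -> AdrDetectionMatrix:
    """Tabulate which ADR(s) each candidate drug was detected through."""
    if not candidates:
        raise ValueError("detection matrix needs at least one candidate")
    adrs = sorted({a for c in candidates for a in c.supporting_adrs})
    drugs = sorted(c.drug for c in candidates)
    by_drug = {c.drug: c.supporting_adrs for c in candidates}
    flags = pd.DataFrame(
        [[a in by_drug[d] for a in adrs] for d in drugs], index=drugs, columns=adrs
    )
    totals = flags.sum(axis=0)
    exclusive = flags[flags.sum(axis=1) == 1].sum(axis=0).reindex(adrs, fill_value=0)
    return AdrDetectionMatrix(flags=flags, totals=totals, exclusive_totals=exclusive)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; errors on zero variance or length < 2."""
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 2:
        raise ValueError("correlation needs at least 2 observations")
    sx = pd.Series(x, dtype=float)
    sy = pd.Series(y, dtype=float)
    if sx.var() == 0.0 or sy.var() == 0.0:
        raise ValueError("correlation undefined: an input has zero variance")
    return float(stats.pearsonr(sx, sy).statistic)


def evidence_summary(records: Iterable[EvidenceRecord]) -> EvidenceSummary:
    """Count drugs by literature-evidence status."""
    records = list(records)
    with_evidence = sum(1 for r in records if r.positive or r.negative)
    return EvidenceSummary(
        total=len(records),
        with_evidence=with_evidence,
        positive=sum(1 for r in records if r.positive),
        negative=sum(1 for r in records if r.negative),
        no_evidence=len(records) - with_evidence,
    )


def _data_path(name: str) -> Path:
    return Path(resources.files("adrnet.data").joinpath(name))  # type: ignore[arg-type]


def load_evidence_table(path: str | Path | None = None) -> list[EvidenceRecord]:
    """Bundled table of the 44 Parkinson repositioning drugs and their
    published literature-evidence flags (or a user-supplied table with
    columns drug, positive, negative)."""
    path = _data_path("pd_repositioning_evidence.tsv") if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"drug": str, "positive": int, "negative": int})
    return [
        EvidenceRecord(
            drug=r.drug,
            positive=bool(r.positive),
            negative=bool(r.negative),
            none=not (bool(r.positive) or bool(r.negative)),
        )
        for r in df.itertuples(index=False)
    ]


def load_labeled_indications(path: str | Path | None = None) -> pd.DataFrame:
    """Bundled labeled-indication table (columns labeled_indication, drug)."""
    path = _data_path("pd_repositioning_indications.tsv") if path is None else Path(path)
    return pd.read_csv(path, sep="\t", dtype=str)


def write_detection_matrix_tsv(matrix: AdrDetectionMatrix, path: str | Path) -> None:
    out = matrix.flags.astype(int).copy()
    out.loc["total"] = matrix.totals
    out.loc["exclusive_total"] = matrix.exclusive_totals
    out.index.name = "drug"
    out.to_csv(path, sep="\t")
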