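"""End-to-end orchestration: corpus -> entities -> lifts -> network ->
disease-ADR scores -> significant ADRs -> repositioning candidates."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .association import CountTable, LiftScore, all_pair_lifts, count_entities, write_lifts_tsv
from .corpus import Thread
from .extraction import ThreadEntities, extract_corpus
from .lexicon import Lexicon, normalize_expression
from .network import (
    DiseaseAdrScore,
    HeteroNetwork,
    build_network,
    disease_adr_scores,
    write_network_tsv,
)
from .repositioning import (
    Candidate,
    IndicationRecord,
    SideEffectRecord,
    find_candidates,
    write_candidates_tsv,
)
from .report import detection_matrix, write_detection_matrix_tsv
from .significance import SignificanceResult, select_significant, write_significance_tsv


@dataclass
class PipelineResult:
    """All intermediate and final artifacts of one pipeline run."""

    disease: str
    entities: list[ThreadEntities]
    table: CountTable
    lifts: list[LiftScore]
    network: HeteroNetwork
    scores: list[DiseaseAdrScore]
    significance: list[SignificanceResult]
    candidates: list[Candidate]
    parameters: dict = field(default_factory=dict)

    @property
    def significant_adrs(self) -> list[str]:
        return [r.adr for r in self.significance if r.significant]


def run_pipeline(
    corpus: Sequence[Thread],
    lexicon: Lexicon,
    side_effects: Sequence[SideEffectRecord],
    indications: Sequence[IndicationRecord],
    disease: str,
    alpha: float = 0.05,
    min_weight: float = 0.0,
    fdr: bool = False,
) -> PipelineResult:
    """Run the full repositioning pipeline on an in-memory corpus."""
    disease = normalize_expression(disease)
    entities = extract_corpus(lexicon, corpus)
    table = count_entities(entities)
    lifts = all_pair_lifts(table)
    network = build_network(
        lifts, min_weight=min_weight, nodes=sorted(table.item_type.items())
    )
    scores = disease_adr_scores(network, disease)
    significance = select_significant(scores, alpha=alpha, fdr=fdr)
    candidates = find_candidates(significance, side_effects, indications, disease)
    return PipelineResult(
        disease=disease,
        entities=entities,
        table=table,
        lifts=lifts,
        network=network,
        scores=scores,
        significance=significance,
        candidates=candidates,
        parameters={"alpha": alpha, "min_weight": min_weight, "fdr": fdr},
    )


def write_outputs(result: PipelineResult, outdir: str | Path, manifest_extra: dict | None = None) -> None:
    """Write lift, network, significance, candidate and matrix TSVs plus a
    JSON run manifest into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_lifts_tsv(result.table, result.lifts, outdir / "lifts.tsv")
    write_network_tsv(result.network, outdir / "network.tsv")
    write_significance_tsv(result.significance, outdir / "significance.tsv")
    write_candidates_tsv(result.candidates, outdir / "candidates.tsv")
    if result.candidates:
        write_detection_matrix_tsv(
            detection_matrix(result.candidates), outdir / "detection_matrix.tsv"
        )
    manifest = {
        "disease": result.disease,
        "parameters": result.parameters,
        "n_threads": result.table.total_count,
        "n_items": len(result.table.item_count),
        "node_type_counts": result.network.node_type_counts(),
        "n_nodes": result.network.n_nodes,
        "n_links": result.network.n_links,
        "n_scored_adrs": len(result.scores),
        "significant_adrs": result.significant_adrs,
        "n_candidates": len(result.candidates),
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
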