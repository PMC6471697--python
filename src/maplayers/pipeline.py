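"""End-to-end workflow: extract -> place -> merge -> crosstalk.

Composes the stage modules into the full integration procedure: build the
catalyst index from the model's gene rules, place protein nodes on the
metabolic map, merge the proteins layer into the base map, and analyse the
crosstalk between the two layers' gene-set hierarchies.  Returns all stage
artefacts plus a JSON-serialisable run report with per-stage counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .crosstalk import (
    EnrichmentResult,
    GeneSetCollection,
    build_crosstalk_network,
    enrich,
    reaction_regulation_counts,
    shared_proteins,
)
from .gene_association import ProteinReactionMap, build_protein_reaction_map
from .merge import MergeReport, merge_maps
from .model import MapDocument
from .placement import (
    PlacementConfig,
    PlacementResult,
    build_protein_overlay,
    place_proteins,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineOutputs", "run_pipeline"]


@dataclass(frozen=True)
class PipelineOutputs:
    prmap: ProteinReactionMap
    placement: PlacementResult
    overlay: MapDocument
    merged: MapDocument
    merge_report: MergeReport
    shared: frozenset[str]
    enrichment_a: list[EnrichmentResult]
    enrichment_b: list[EnrichmentResult]
    network: nx.Graph
    regulation: pd.DataFrame | None
    report: dict


def run_pipeline(
    doc: MapDocument,
    rules: Sequence[tuple[str, str]],
    id_mapping: Mapping[int, str],
    modules: GeneSetCollection,
    subsystems: GeneSetCollection,
    subsystem_of: Mapping[str, str] | None = None,
    placement_config: PlacementConfig | None = None,
    min_size: int = 10,
    alpha: float = 0.05,
) -> PipelineOutputs:
    """Run the full integration workflow on one base map.

    ``modules`` is the signalling layer's gene sets, ``subsystems`` the
    metabolic layer's.  Rules naming reactions absent from the map are
    dropped with a log message (a model usually covers more reactions than
    a map extract).
    """
    placement_config = placement_config or PlacementConfig()

    prmap_full = build_protein_reaction_map(rules, id_mapping)
    known = {r.reaction_id for r in doc.reactions}
    dropped = sorted(set(prmap_full.by_reaction) - known)
    if dropped:
        logger.info("dropping %d rules for reactions absent from the map", len(dropped))
    prmap = ProteinReactionMap(
        by_reaction={r: s for r, s in prmap_full.by_reaction.items() if r in known},
        unmapped=prmap_full.unmapped,
    )

    placement = place_proteins(doc, prmap, placement_config)
    overlay = build_protein_overlay(placement, doc.canvas)
    merged, merge_report = merge_maps(doc, overlay)

    shared = shared_proteins(modules, subsystems)
    universe = modules.union() | subsystems.union()
    enrichment_a = enrich(modules, shared, universe, min_size=min_size, alpha=alpha)
    enrichment_b = enrich(subsystems, shared, universe, min_size=min_size, alpha=alpha)
    network = build_crosstalk_network(
        modules, subsystems, shared, enrichment_a, enrichment_b
    )
    regulation = (
        reaction_regulation_counts(prmap, subsystem_of, modules, shared)
        if subsystem_of is not None
        else None
    )

    report = {
        "extract": {
            "rules_read": len(rules),
            "reactions_with_catalysts": len(prmap.by_reaction),
            "rules_dropped_absent_reaction": len(dropped),
            "unmapped_gene_count": sum(len(v) for v in prmap.unmapped.values()),
        },
        "placement": dict(placement.stats),
        "merge": merge_report.counts,
        "crosstalk": {
            "shared_proteins": len(shared),
            "modules_hit": sum(
                1 for name, genes in modules.sets.items() if genes & shared
            ),
            "subsystems_hit": sum(
                1 for name, genes in subsystems.sets.items() if genes & shared
            ),
            "edges": network.number_of_edges(),
            "total_edge_weight": int(
                sum(d["weight"] for _, _, d in network.edges(data=True))
            ),
            "enriched_modules": sum(1 for r in enrichment_a if r.significant),
            "enriched_subsystems": sum(1 for r in enrichment_b if r.significant),
        },
    }
    return PipelineOutputs(
        prmap=prmap,
        placement=placement,
        overlay=overlay,
        merged=merged,
        merge_report=merge_report,
        shared=shared,
        enrichment_a=enrichment_a,
        enrichment_b=enrichment_b,
        network=network,
        regulation=regulation,
        report=report,
    )
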