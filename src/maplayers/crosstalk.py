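"""Crosstalk analysis between two map layers' gene-set hierarchies.

A signalling map is organised into functional *modules* and a metabolic
map into *subsystems*; both are distributed as GMT gene sets over HUGO
symbols.  Proteins appearing in both layers tie the hierarchies together:

*   ``shared_proteins`` — the intersection of the two layers' protein
    unions;
*   ``enrich`` — upper-tail hypergeometric test of the shared set against
    each module/subsystem (population = the union of both layers' proteins,
    Bonferroni over the sets actually tested, which are those holding at
    least ``min_size`` proteins);
*   ``build_crosstalk_network`` — the bipartite module<->subsystem graph
    whose edge weights count shared proteins in both sets;
*   ``reaction_regulation_counts`` — how many reactions of each subsystem
    are catalysed by shared proteins of each module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .gene_association import ProteinReactionMap

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "shared_proteins",
    "enrich",
    "build_crosstalk_network",
    "network_to_txt",
    "network_to_sif",
    "reaction_regulation_counts",
    "GmtParseError",
]


class GmtParseError(ValueError):
    """A GMT line does not have the required name/description/genes fields."""


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets of one map layer (GMT content in memory)."""

    sets: dict[str, frozenset[str]]
    layer_label: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap_count: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    p_adjusted: float
    significant: bool


def read_gmt(text: str, layer_label: str = "") -> GeneSetCollection:
    """Parse GMT text: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a line are collapsed; a line with fewer than
    three fields raises :class:`GmtParseError` with its line number.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise GmtParseError(
                f"line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
            )
        name, description, *genes = fields
        genes = [g.strip() for g in genes if g.strip()]
        if not genes:
            raise GmtParseError(f"line {lineno}: gene set {name!r} has no genes")
        sets[name] = frozenset(genes)
        descriptions[name] = description
    return GeneSetCollection(sets=sets, layer_label=layer_label, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection) -> str:
    """Serialize to GMT text (genes sorted for stable output)."""
    lines = []
    for name in collection.sets:
        desc = collection.descriptions.get(name, "")
        genes = sorted(collection.sets[name])
        lines.append("\t".join([name, desc, *genes]))
    return "\n".join(lines) + ("\n" if lines else "")


def shared_proteins(a: GeneSetCollection, b: GeneSetCollection) -> frozenset[str]:
    """Proteins present in both layers: (union of a) ∩ (union of b)."""
    return a.union() & b.union()


def enrich(
    sets: GeneSetCollection,
    query: Iterable[str],
    universe: Iterable[str],
    min_size: int = 10,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` in each gene set.

    For a set holding ``K`` universe proteins, with ``n`` query proteins
    drawn from a universe of ``N``, the p-value is the upper tail
    P[X >= k] of Hypergeometric(N, K, n) at the observed overlap ``k``
    (the survival function).  Only sets with at least ``min_size``
    universe proteins are tested; Bonferroni multiplies by the number of
    tested sets.  The query must be a subset of the universe.
    """
    query = set(query)
    universe = set(universe)
    offenders = sorted(query - universe)
    if offenders:
        raise ValueError(f"query symbols outside the universe: {offenders}")

    sized = {
        name: genes & universe
        for name, genes in sets.sets.items()
    }
    tested = {name: g for name, g in sized.items() if len(g) >= min_size}
    m = len(tested)
    results = []
    for name, genes in tested.items():
        k = len(genes & query)
        # survival function at k-1 gives P[X >= k]
        p = float(hypergeom.sf(k - 1, len(universe), len(genes), len(query)))
        p = min(p, 1.0)
        p_adj = min(1.0, p * m)
        results.append(
            EnrichmentResult(
                set_name=name,
                overlap_count=k,
                set_size=len(genes),
                query_size=len(query),
                universe_size=len(universe),
                p_value=p,
                p_adjusted=p_adj,
                significant=p_adj <= alpha,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def build_crosstalk_network(
    a: GeneSetCollection,
    b: GeneSetCollection,
    shared: Iterable[str],
    enrich_a: Iterable[EnrichmentResult] = (),
    enrich_b: Iterable[EnrichmentResult] = (),
) -> nx.Graph:
    """Bipartite module<->subsystem graph over the shared proteins.

    An edge joins module ``m`` of layer *a* and subsystem ``s`` of layer
    *b* iff their sets intersect within ``shared``; its ``weight`` is the
    intersection size and ``shared_symbols`` lists the proteins.  Nodes
    carry ``layer`` and an ``enriched`` flag from the enrichment results.
    """
    shared = set(shared)
    for sym in sorted(shared - set(a.union())) + sorted(shared - set(b.union())):
        raise ValueError(f"shared symbol {sym!r} missing from a layer's union")

    flag_a = {r.set_name: r.significant for r in enrich_a}
    flag_b = {r.set_name: r.significant for r in enrich_b}
    g = nx.Graph()
    for name in a.sets:
        g.add_node(name, layer=a.layer_label or "a", bipartite=0,
                   enriched=flag_a.get(name, False))
    for name in b.sets:
        g.add_node(name, layer=b.layer_label or "b", bipartite=1,
                   enriched=flag_b.get(name, False))
    for ma, genes_a in a.sets.items():
        for sb, genes_b in b.sets.items():
            common = genes_a & genes_b & shared
            if common:
                g.add_edge(ma, sb, weight=len(common),
                           shared_symbols=tuple(sorted(common)))
    return g


def network_to_txt(g: nx.Graph) -> str:
    """Edge list as tab-separated text: source, target, interaction type,
    number of intersection proteins."""
    lines = ["Source\tTarget\tInteraction\tIntersection"]
    for u, v, data in sorted(g.edges(data=True)):
        lines.append(f"{u}\t{v}\tcrosstalk\t{data['weight']}")
    return "\n".join(lines) + "\n"


def network_to_sif(g: nx.Graph) -> str:
    """Simple interaction format: ``source crosstalk target`` per edge."""
    lines = [f"{u}\tcrosstalk\t{v}" for u, v in sorted(g.edges())]
    return "\n".join(lines) + ("\n" if lines else "")


def read_subsystem_assignment(text: str) -> dict[str, str]:
    """Read a two-column TSV ``reaction_id<TAB>subsystem``.

    Each reaction must map to exactly one subsystem; a second, different
    assignment is rejected (it would double-count reactions downstream).
    """
    out: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if lineno == 1 and parts[0].strip().lower().startswith("reaction"):
            continue
        if len(parts) < 2 or not parts[1].strip():
            raise ValueError(f"line {lineno}: expected 'reaction_id<TAB>subsystem'")
        rid, subsystem = parts[0].strip(), parts[1].strip()
        if rid in out and out[rid] != subsystem:
            raise ValueError(
                f"reaction {rid!r} assigned to both {out[rid]!r} and {subsystem!r}"
            )
        out[rid] = subsystem
    return out


def reaction_regulation_counts(
    prmap: ProteinReactionMap,
    subsystem_of: Mapping[str, str],
    module_sets: GeneSetCollection,
    shared: Iterable[str],
) -> pd.DataFrame:
    """Count, per (module, subsystem) pair, the distinct reactions of the
    subsystem catalysed by at least one shared protein of the module.

    ``subsystem_of`` assigns each reaction to exactly one subsystem;
    reactions missing from it are excluded with a diagnostic column in the
    returned frame's ``attrs['unassigned']``.  Rows with a zero count are
    omitted.
    """
    shared = set(shared)
    unassigned = sorted(r for r in prmap.by_reaction if r not in subsystem_of)
    counts: dict[tuple[str, str], set[str]] = {}
    for rid, symbols in prmap.by_reaction.items():
        if rid not in subsystem_of:
            continue
        subsystem = subsystem_of[rid]
        catalysts = set(symbols) & shared
        if not catalysts:
            continue
        for module, genes in module_sets.sets.items():
            if catalysts & genes:
                counts.setdefault((module, subsystem), set()).add(rid)
    rows = [
        {"module": m, "subsystem": s, "n_reactions": len(rids)}
        for (m, s), rids in sorted(counts.items())
    ]
    df = pd.DataFrame(rows, columns=["module", "subsystem", "n_reactions"])
    df.attrs["unassigned"] = unassigned
    return df
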