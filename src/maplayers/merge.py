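"""Merging two CellDesigner maps into one.

The merge rewrites identifiers but never content: every entity, alias and
reaction of both inputs survives with its name, coordinates (bit-exact)
and annotation notes intact.  Entities sharing a name across the two maps
are deliberately *not* unified — the integrated resource links layers by
protein name downstream, not by merged identity.

The base map keeps its ids; the overlay receives fresh CellDesigner-style
ids (``s<N>``, ``sa<N>``, ``re<N>``) numbered past the base map's maximum.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .model import Alias, Entity, MapDocument, Reaction

__all__ = ["MergeReport", "merge_maps", "CanvasMismatchError"]


class CanvasMismatchError(ValueError):
    """The two maps do not share canvas dimensions."""


@dataclass(frozen=True)
class MergeReport:
    """Old-id -> new-id tables per source plus before/after counts."""

    id_remapping: dict[str, dict[str, str]]  # {"base": {...}, "overlay": {...}}
    counts: dict[str, dict[str, int]]

    def as_dict(self) -> dict:
        return {"id_remapping": self.id_remapping, "counts": self.counts}


def _max_suffix(ids, prefix: str) -> int:
    pat = re.compile(rf"^{prefix}(\d+)$")
    best = 0
    for i in ids:
        m = pat.match(i)
        if m:
            best = max(best, int(m.group(1)))
    return best


def merge_maps(base: MapDocument, overlay: MapDocument) -> tuple[MapDocument, MergeReport]:
    """Merge ``overlay`` into ``base``; returns the merged map and a report.

    Both canvases must have identical dimensions.  No deduplication is
    performed: after-counts are the sums of before-counts.
    """
    if (base.canvas.width, base.canvas.height) != (
        overlay.canvas.width,
        overlay.canvas.height,
    ):
        raise CanvasMismatchError(
            f"canvas mismatch: base {base.canvas.width}x{base.canvas.height} "
            f"vs overlay {overlay.canvas.width}x{overlay.canvas.height}"
        )

    taken = (
        {e.entity_id for e in base.entities}
        | {a.alias_id for a in base.aliases}
        | {r.reaction_id for r in base.reactions}
    )
    next_s = _max_suffix(taken, "s") + 1
    next_sa = _max_suffix(taken, "sa") + 1
    next_re = _max_suffix(taken, "re") + 1

    def fresh(prefix: str, counter: list[int]) -> str:
        while True:
            candidate = f"{prefix}{counter[0]}"
            counter[0] += 1
            if candidate not in taken:
                taken.add(candidate)
                return candidate

    s_ctr, sa_ctr, re_ctr = [next_s], [next_sa], [next_re]
    emap = {e.entity_id: fresh("s", s_ctr) for e in overlay.entities}
    amap = {a.alias_id: fresh("sa", sa_ctr) for a in overlay.aliases}
    rmap = {r.reaction_id: fresh("re", re_ctr) for r in overlay.reactions}

    new_entities = tuple(
        Entity(emap[e.entity_id], e.name, e.entity_class, e.annotation)
        for e in overlay.entities
    )
    new_aliases = tuple(
        Alias(amap[a.alias_id], emap[a.entity_id], a.geometry) for a in overlay.aliases
    )
    new_reactions = tuple(
        Reaction(
            rmap[r.reaction_id],
            tuple(amap[i] for i in r.reactant_alias_ids),
            tuple(amap[i] for i in r.product_alias_ids),
            tuple(amap[i] for i in r.modifier_alias_ids),
            r.annotation,
        )
        for r in overlay.reactions
    )

    merged = MapDocument(
        canvas=base.canvas,
        entities=base.entities + new_entities,
        aliases=base.aliases + new_aliases,
        reactions=base.reactions + new_reactions,
        model_id=base.model_id,
        extra_xml=base.extra_xml + overlay.extra_xml,
    )
    report = MergeReport(
        id_remapping={
            "base": {},  # base ids are preserved
            "overlay": {**emap, **amap, **rmap},
        },
        counts={
            "base": _counts(base),
            "overlay": _counts(overlay),
            "merged": _counts(merged),
        },
    )
    return merged, report


def _counts(doc: MapDocument) -> dict[str, int]:
    return {
        "entities": len(doc.entities),
        "aliases": len(doc.aliases),
        "reactions": len(doc.reactions),
    }
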