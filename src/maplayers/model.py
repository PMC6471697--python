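"""In-memory model of a CellDesigner process-description map.

A *map* is a diagram of molecular interactions laid out on a fixed canvas.
Each molecule is an :class:`Entity`; every visual copy of it on the canvas
is an :class:`Alias` carrying its own bounding box (CellDesigner's
``speciesAlias``).  Reactions connect aliases and may carry a NaviCell-style
annotation whose ``Identifiers`` section lists the HUGO symbols of the
proteins regulating (catalysing) the reaction.

Coordinates follow the CellDesigner convention: origin at the top-left of
the canvas, y increasing downward, and an alias position given by the
top-left corner of its box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "Point",
    "Box",
    "Annotation",
    "Entity",
    "Alias",
    "Reaction",
    "MapDocument",
    "IntegrityError",
    "ANNOTATION_SECTIONS",
    "EntityClass",
]

#: Section names allowed in a NaviCell annotation post.
ANNOTATION_SECTIONS = ("Identifiers", "Maps_Modules", "References", "Confidence")


class EntityClass:
    """Species classes modelled explicitly; everything else is OTHER."""

    PROTEIN = "PROTEIN"
    METABOLITE = "METABOLITE"
    OTHER = "OTHER"

    ALL = (PROTEIN, METABOLITE, OTHER)


class IntegrityError(ValueError):
    """A document (or an edit to one) violates map invariants."""


@dataclass(frozen=True)
class Point:
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinate ({self.x}, {self.y})")

    def __iter__(self):
        yield self.x
        yield self.y


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle: top-left origin plus positive extents."""

    origin: Point
    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(
                f"box extents must be positive, got {self.width}x{self.height}"
            )

    @property
    def center(self) -> Point:
        return Point(self.origin.x + self.width / 2.0, self.origin.y + self.height / 2.0)

    def contains_box(self, other: "Box", tol: float = 1e-9) -> bool:
        return (
            other.origin.x >= self.origin.x - tol
            and other.origin.y >= self.origin.y - tol
            and other.origin.x + other.width <= self.origin.x + self.width + tol
            and other.origin.y + other.height <= self.origin.y + self.height + tol
        )

    def contains_point(self, p: Point, tol: float = 1e-9) -> bool:
        return (
            self.origin.x - tol <= p.x <= self.origin.x + self.width + tol
            and self.origin.y - tol <= p.y <= self.origin.y + self.height + tol
        )


@dataclass(frozen=True)
class Annotation:
    """NaviCell annotation post: named sections holding lists of text values.

    Section names are restricted to ``Identifiers``, ``Maps_Modules``,
    ``References`` and ``Confidence``.
    """

    sections: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, values in self.sections.items():
            if name not in ANNOTATION_SECTIONS:
                raise ValueError(
                    f"unknown annotation section {name!r}; "
                    f"allowed: {', '.join(ANNOTATION_SECTIONS)}"
                )
            if not all(isinstance(v, str) and v for v in values):
                raise ValueError(f"section {name!r} holds an empty value")

    def values(self, section: str) -> tuple[str, ...]:
        return self.sections.get(section, ())

    @property
    def empty(self) -> bool:
        return not self.sections


@dataclass(frozen=True)
class Entity:
    entity_id: str
    name: str
    entity_class: str = EntityClass.OTHER
    annotation: Annotation = field(default_factory=Annotation)

    def __post_init__(self) -> None:
        if self.entity_class not in EntityClass.ALL:
            raise ValueError(f"unknown entity class {self.entity_class!r}")


@dataclass(frozen=True)
class Alias:
    alias_id: str
    entity_id: str
    geometry: Box


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    reactant_alias_ids: tuple[str, ...]
    product_alias_ids: tuple[str, ...]
    modifier_alias_ids: tuple[str, ...] = ()
    annotation: Annotation = field(default_factory=Annotation)

    def __post_init__(self) -> None:
        if not self.reactant_alias_ids or not self.product_alias_ids:
            raise ValueError(
                f"reaction {self.reaction_id!r} needs >=1 reactant and >=1 product"
            )


@dataclass(frozen=True)
class MapDocument:
    """A complete map: entities, their aliases, reactions, and the canvas.

    Instances are validated on construction; use :meth:`validated` after
    manual edits.  ``model_id`` names the SBML model; ``extra_xml`` carries
    unsupported CellDesigner constructs (complexes, compartment internals)
    as opaque serialized blobs so writing round-trips them untouched.
    """

    canvas: Box
    entities: tuple[Entity, ...] = ()
    aliases: tuple[Alias, ...] = ()
    reactions: tuple[Reaction, ...] = ()
    model_id: str = "map"
    extra_xml: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------
    def entity(self, entity_id: str) -> Entity:
        try:
            return self._entity_index[entity_id]
        except KeyError:
            raise KeyError(f"unknown entity id {entity_id!r}") from None

    def alias(self, alias_id: str) -> Alias:
        try:
            return self._alias_index[alias_id]
        except KeyError:
            raise KeyError(f"unknown alias id {alias_id!r}") from None

    def reaction(self, reaction_id: str) -> Reaction:
        try:
            return self._reaction_index[reaction_id]
        except KeyError:
            raise KeyError(f"unknown reaction id {reaction_id!r}") from None

    @property
    def _entity_index(self) -> dict[str, Entity]:
        return {e.entity_id: e for e in self.entities}

    @property
    def _alias_index(self) -> dict[str, Alias]:
        return {a.alias_id: a for a in self.aliases}

    @property
    def _reaction_index(self) -> dict[str, Reaction]:
        return {r.reaction_id: r for r in self.reactions}

    def aliases_of(self, entity_id: str) -> tuple[Alias, ...]:
        return tuple(a for a in self.aliases if a.entity_id == entity_id)

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`IntegrityError` on any invariant violation."""
        problems: list[str] = []
        eids = [e.entity_id for e in self.entities]
        if len(eids) != len(set(eids)):
            dup = sorted({i for i in eids if eids.count(i) > 1})
            problems.append(f"duplicate entity ids: {dup}")
        aids = [a.alias_id for a in self.aliases]
        if len(aids) != len(set(aids)):
            dup = sorted({i for i in aids if aids.count(i) > 1})
            problems.append(f"duplicate alias ids: {dup}")
        rids = [r.reaction_id for r in self.reactions]
        if len(rids) != len(set(rids)):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            problems.append(f"duplicate reaction ids: {dup}")

        eset = set(eids)
        aset = set(aids)
        for a in self.aliases:
            if a.entity_id not in eset:
                problems.append(
                    f"alias {a.alias_id!r} references unknown entity {a.entity_id!r}"
                )
            if not self.canvas.contains_box(a.geometry):
                problems.append(
                    f"alias {a.alias_id!r} box extends outside the canvas"
                )
        referenced = {a.entity_id for a in self.aliases}
        for e in self.entities:
            if e.entity_id not in referenced:
                problems.append(f"entity {e.entity_id!r} has no alias")
        for r in self.reactions:
            for ref in (*r.reactant_alias_ids, *r.product_alias_ids, *r.modifier_alias_ids):
                if ref not in aset:
                    problems.append(
                        f"reaction {r.reaction_id!r} references unknown alias {ref!r}"
                    )
        if problems:
            raise IntegrityError("; ".join(problems))

    # -- functional updates ---------------------------------------------
    def with_components(self, **changes) -> "MapDocument":
        """Return a copy with the given fields replaced (revalidates)."""
        return replace(self, **changes)
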