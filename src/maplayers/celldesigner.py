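"""Reading and writing CellDesigner-flavoured SBML Level 2 maps.

CellDesigner stores the diagram layout inside SBML ``annotation`` elements
under its own namespace: each visual copy of a species is a
``celldesigner:speciesAlias`` with an ``x/y/w/h`` bounding box, and each
reaction names its anchor aliases through ``baseReactant`` /
``baseProduct`` / ``modification`` elements.  This module maps that dialect
onto :class:`~maplayers.model.MapDocument` and back.

Entity and reaction annotations follow the NaviCell post convention: the
SBML ``notes`` body holds ``Section: value`` lines with section names drawn
from ``Identifiers``, ``Maps_Modules``, ``References`` and ``Confidence``.
For a metabolic map, the ``Identifiers`` section of a reaction lists the
HUGO symbols of the proteins regulating it.

Constructs this package does not manipulate (complex species, compartment
layouts, state variables) are carried as opaque XML blobs and re-emitted
verbatim on write, so a parse/write cycle round-trips them.
"""

from __future__ import annotations

import csv
import io
from typing import Iterable, Mapping

from lxml import etree

from .model import (
    ANNOTATION_SECTIONS,
    Alias,
    Annotation,
    Box,
    Entity,
    EntityClass,
    IntegrityError,
    MapDocument,
    Point,
    Reaction,
)

__all__ = [
    "parse_map",
    "write_map",
    "reaction_glyph_position",
    "extract_reaction_genes",
    "glyph_table",
    "CellDesignerParseError",
]

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
CD_NS = "http://www.sbml.org/2001/ns/celldesigner"
XHTML_NS = "http://www.w3.org/1999/xhtml"

_NSMAP = {None: SBML_NS, "celldesigner": CD_NS}


def _sbml(tag: str) -> str:
    return f"{{{SBML_NS}}}{tag}"


def _cd(tag: str) -> str:
    return f"{{{CD_NS}}}{tag}"


class CellDesignerParseError(ValueError):
    """The document is not well-formed CellDesigner SBML."""


# ---------------------------------------------------------------------------
# parsing


def parse_map(xml_text: str | bytes) -> MapDocument:
    """Parse a CellDesigner SBML document into a :class:`MapDocument`.

    Raises :class:`CellDesignerParseError` (naming the line) on malformed
    XML and :class:`~maplayers.model.IntegrityError` on structural
    violations such as an alias without geometry or a dangling reference.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise CellDesignerParseError(
            f"malformed XML at line {exc.lineno}: {exc.msg}"
        ) from exc

    model = root.find(_sbml("model"))
    if model is None:
        raise CellDesignerParseError("document has no <model> element")
    model_id = model.get("id", "map")

    extension = model.find(f"{_sbml('annotation')}/{_cd('extension')}")
    if extension is None:
        raise CellDesignerParseError(
            "model annotation lacks the CellDesigner extension"
        )

    display = extension.find(_cd("modelDisplay"))
    if display is None:
        raise CellDesignerParseError("CellDesigner extension lacks modelDisplay")
    canvas = Box(
        Point(0.0, 0.0),
        float(display.get("sizeX")),
        float(display.get("sizeY")),
    )

    aliases = []
    alias_list = extension.find(_cd("listOfSpeciesAliases"))
    if alias_list is not None:
        for el in alias_list.iterfind(_cd("speciesAlias")):
            alias_id = el.get("id")
            bounds = el.find(_cd("bounds"))
            if bounds is None:
                raise IntegrityError(f"alias {alias_id!r} has no bounds geometry")
            aliases.append(
                Alias(
                    alias_id=alias_id,
                    entity_id=el.get("species"),
                    geometry=Box(
                        Point(float(bounds.get("x")), float(bounds.get("y"))),
                        float(bounds.get("w")),
                        float(bounds.get("h")),
                    ),
                )
            )

    entities = []
    species_list = model.find(_sbml("listOfSpecies"))
    if species_list is not None:
        for el in species_list.iterfind(_sbml("species")):
            entities.append(
                Entity(
                    entity_id=el.get("id"),
                    name=el.get("name", el.get("id")),
                    entity_class=_parse_species_class(el),
                    annotation=_parse_notes(el),
                )
            )

    reactions = []
    reaction_list = model.find(_sbml("listOfReactions"))
    if reaction_list is not None:
        for el in reaction_list.iterfind(_sbml("reaction")):
            ext = el.find(f"{_sbml('annotation')}/{_cd('extension')}")
            if ext is None:
                raise IntegrityError(
                    f"reaction {el.get('id')!r} lacks CellDesigner anchors"
                )
            reactants = [
                b.get("alias")
                for b in ext.iterfind(f"{_cd('baseReactants')}/{_cd('baseReactant')}")
            ]
            products = [
                b.get("alias")
                for b in ext.iterfind(f"{_cd('baseProducts')}/{_cd('baseProduct')}")
            ]
            modifiers = [
                m.get("aliases")
                for m in ext.iterfind(
                    f"{_cd('listOfModification')}/{_cd('modification')}"
                )
                if m.get("aliases")
            ]
            reactions.append(
                Reaction(
                    reaction_id=el.get("id"),
                    reactant_alias_ids=tuple(reactants),
                    product_alias_ids=tuple(products),
                    modifier_alias_ids=tuple(modifiers),
                    annotation=_parse_notes(el),
                )
            )

    extra = [
        etree.tostring(child, encoding="unicode")
        for child in model
        if child.tag
        not in (_sbml("listOfSpecies"), _sbml("listOfReactions"), _sbml("annotation"))
        and not (
            child.tag == _sbml("listOfCompartments") and _is_default_compartments(child)
        )
    ]

    try:
        return MapDocument(
            canvas=canvas,
            entities=tuple(entities),
            aliases=tuple(aliases),
            reactions=tuple(reactions),
            model_id=model_id,
            extra_xml=tuple(extra),
        )
    except IntegrityError:
        raise


def _is_default_compartments(el: etree._Element) -> bool:
    kids = list(el)
    return len(kids) == 1 and kids[0].get("id") == "default"


def _parse_species_class(species_el: etree._Element) -> str:
    cls = species_el.find(
        f"{_sbml('annotation')}/{_cd('extension')}/{_cd('speciesIdentity')}/{_cd('class')}"
    )
    if cls is None or not cls.text:
        return EntityClass.OTHER
    text = cls.text.strip().upper()
    if text == "PROTEIN":
        return EntityClass.PROTEIN
    if text in ("SIMPLE_MOLECULE", "METABOLITE"):
        return EntityClass.METABOLITE
    return EntityClass.OTHER


def _parse_notes(el: etree._Element) -> Annotation:
    """Read ``Section: value`` lines from the notes body."""
    body = el.find(f"{_sbml('notes')}/{{{XHTML_NS}}}body")
    if body is None or not body.text:
        return Annotation()
    sections: dict[str, list[str]] = {}
    for line in body.text.splitlines():
        line = line.strip()
        if ":" not in line:
            continue
        name, _, value = line.partition(":")
        name, value = name.strip(), value.strip()
        if name in ANNOTATION_SECTIONS and value:
            sections.setdefault(name, []).append(value)
    return Annotation({k: tuple(v) for k, v in sections.items()})


# ---------------------------------------------------------------------------
# writing


def write_map(doc: MapDocument) -> str:
    """Serialize a :class:`MapDocument` to CellDesigner SBML text.

    Refuses to serialize a document violating map invariants (the
    constructor enforces them, but documents assembled through mutation of
    copies are re-checked here).
    """
    doc.validate()

    root = etree.Element(_sbml("sbml"), nsmap=_NSMAP, level="2", version="4")
    model = etree.SubElement(root, _sbml("model"), id=doc.model_id)

    annot = etree.SubElement(model, _sbml("annotation"))
    ext = etree.SubElement(annot, _cd("extension"))
    etree.SubElement(ext, _cd("modelVersion")).text = "4.0"
    etree.SubElement(
        ext,
        _cd("modelDisplay"),
        sizeX=_num(doc.canvas.width),
        sizeY=_num(doc.canvas.height),
    )
    alias_list = etree.SubElement(ext, _cd("listOfSpeciesAliases"))
    for a in doc.aliases:
        el = etree.SubElement(
            alias_list, _cd("speciesAlias"), id=a.alias_id, species=a.entity_id
        )
        etree.SubElement(
            el,
            _cd("bounds"),
            x=_num(a.geometry.origin.x),
            y=_num(a.geometry.origin.y),
            w=_num(a.geometry.width),
            h=_num(a.geometry.height),
        )

    has_compartments = any("listOfCompartments" in blob for blob in doc.extra_xml)
    if not has_compartments:
        comp_list = etree.SubElement(model, _sbml("listOfCompartments"))
        etree.SubElement(comp_list, _sbml("compartment"), id="default", size="1")

    species_list = etree.SubElement(model, _sbml("listOfSpecies"))
    for e in doc.entities:
        el = etree.SubElement(
            species_list,
            _sbml("species"),
            id=e.entity_id,
            name=e.name,
            compartment="default",
        )
        _write_notes(el, e.annotation)
        annot_el = etree.SubElement(el, _sbml("annotation"))
        eext = etree.SubElement(annot_el, _cd("extension"))
        ident = etree.SubElement(eext, _cd("speciesIdentity"))
        etree.SubElement(ident, _cd("class")).text = _species_class_text(e.entity_class)

    reaction_list = etree.SubElement(model, _sbml("listOfReactions"))
    for r in doc.reactions:
        el = etree.SubElement(
            reaction_list, _sbml("reaction"), id=r.reaction_id, reversible="false"
        )
        _write_notes(el, r.annotation)
        annot_el = etree.SubElement(el, _sbml("annotation"))
        rext = etree.SubElement(annot_el, _cd("extension"))
        base_r = etree.SubElement(rext, _cd("baseReactants"))
        for aid in r.reactant_alias_ids:
            etree.SubElement(
                base_r,
                _cd("baseReactant"),
                species=doc.alias(aid).entity_id,
                alias=aid,
            )
        base_p = etree.SubElement(rext, _cd("baseProducts"))
        for aid in r.product_alias_ids:
            etree.SubElement(
                base_p,
                _cd("baseProduct"),
                species=doc.alias(aid).entity_id,
                alias=aid,
            )
        if r.modifier_alias_ids:
            mods = etree.SubElement(rext, _cd("listOfModification"))
            for aid in r.modifier_alias_ids:
                etree.SubElement(
                    mods,
                    _cd("modification"),
                    modifiers=doc.alias(aid).entity_id,
                    aliases=aid,
                    type="CATALYSIS",
                )
        lor = etree.SubElement(el, _sbml("listOfReactants"))
        for aid in r.reactant_alias_ids:
            etree.SubElement(
                lor, _sbml("speciesReference"), species=doc.alias(aid).entity_id
            )
        lop = etree.SubElement(el, _sbml("listOfProducts"))
        for aid in r.product_alias_ids:
            etree.SubElement(
                lop, _sbml("speciesReference"), species=doc.alias(aid).entity_id
            )

    for blob in doc.extra_xml:
        model.append(etree.fromstring(blob))

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


def _num(x: float) -> str:
    """Shortest exact decimal form (CellDesigner writes plain decimals)."""
    return repr(float(x))


def _species_class_text(entity_class: str) -> str:
    return {
        EntityClass.PROTEIN: "PROTEIN",
        EntityClass.METABOLITE: "SIMPLE_MOLECULE",
        EntityClass.OTHER: "UNKNOWN",
    }[entity_class]


def _write_notes(el: etree._Element, annotation: Annotation) -> None:
    if annotation.empty:
        return
    notes = etree.SubElement(el, _sbml("notes"))
    body = etree.SubElement(notes, f"{{{XHTML_NS}}}body")
    lines = []
    for section in ANNOTATION_SECTIONS:
        for value in annotation.values(section):
            lines.append(f"{section}: {value}")
    body.text = "\n" + "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# geometry and annotation queries


def reaction_glyph_position(doc: MapDocument, reaction_id: str) -> Point:
    """Coordinate of the reaction's central glyph.

    CellDesigner draws a small square at the middle of each reaction but
    does not store its position in the file; for a two-anchor reaction the
    glyph sits at the midpoint between the first base reactant's and first
    base product's alias centres, which is what this returns.
    """
    r = doc.reaction(reaction_id)
    c1 = doc.alias(r.reactant_alias_ids[0]).geometry.center
    c2 = doc.alias(r.product_alias_ids[0]).geometry.center
    return Point((c1.x + c2.x) / 2.0, (c1.y + c2.y) / 2.0)


def extract_reaction_genes(doc: MapDocument) -> dict[str, list[str]]:
    """Map each annotated reaction to the HUGO symbols in its ``Identifiers``
    section, deduplicated preserving first-seen order.

    Reactions without gene annotations are omitted.  Symbols are matched
    verbatim (case-sensitive); no normalisation is attempted.
    """
    out: dict[str, list[str]] = {}
    for r in doc.reactions:
        seen: list[str] = []
        for value in r.annotation.values("Identifiers"):
            if value not in seen:
                seen.append(value)
        if seen:
            out[r.reaction_id] = seen
    return out


def glyph_table(doc: MapDocument) -> str:
    """All reaction glyph coordinates as a 3-column TSV (reaction_id, x, y)."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    for r in doc.reactions:
        p = reaction_glyph_position(doc, r.reaction_id)
        writer.writerow([r.reaction_id, repr(p.x), repr(p.y)])
    return buf.getvalue()
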