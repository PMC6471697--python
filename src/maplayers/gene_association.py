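"""Protein–reaction association from a metabolic model's gene rules.

Genome-scale reconstructions attach a boolean gene–protein–reaction (GPR)
rule to each reaction, e.g. ``(8639.1 and 26.1) or 314.2`` over Entrez gene
ids with optional transcript suffixes.  For placing catalyst nodes on a map
the boolean structure is irrelevant — any gene appearing in the rule names
a protein that may take part in catalysis — so rules are flattened to the
ordered set of genes they mention, converted to HUGO symbols through a
user-supplied mapping table, and inverted into a protein<->reaction index.

The flattening deliberately ignores complex-vs-isozyme semantics
(``and``/``or`` are treated alike); a warning is logged once per process.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "GprParseError",
    "parse_gpr",
    "to_hugo",
    "ProteinReactionMap",
    "build_protein_reaction_map",
    "read_rules_tsv",
    "read_id_mapping_tsv",
]

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<gene>\d+(?:\.\d+)?)|(?P<op>and|or|AND|OR)|(?P<lpar>\()|(?P<rpar>\)))"
)

_flatten_warned = False


class GprParseError(ValueError):
    """A gene rule is not a well-formed boolean expression."""


def parse_gpr(rule_text: str) -> list[int]:
    """Flatten a GPR rule to the deduplicated, order-preserving list of
    Entrez gene ids it mentions.

    Transcript suffixes (``8639.1``) are stripped; boolean structure is
    discarded.  An empty or blank rule yields an empty list.  Unbalanced
    parentheses or an unrecognised token raise :class:`GprParseError` with
    the character position.
    """
    global _flatten_warned
    if not _flatten_warned:
        logger.warning(
            "GPR boolean structure (complexes vs isozymes) is discarded; "
            "every gene in a rule is treated as a potential catalyst"
        )
        _flatten_warned = True

    genes: list[int] = []
    depth = 0
    pos = 0
    n = len(rule_text)
    while pos < n:
        if rule_text[pos].isspace():
            pos += 1
            continue
        m = _TOKEN_RE.match(rule_text, pos)
        if m is None:
            raise GprParseError(
                f"unknown token at position {pos}: {rule_text[pos:pos + 10]!r}"
            )
        if m.group("gene"):
            gid = int(m.group("gene").split(".")[0])
            if gid not in genes:
                genes.append(gid)
        elif m.group("lpar"):
            depth += 1
        elif m.group("rpar"):
            depth -= 1
            if depth < 0:
                raise GprParseError(f"unbalanced ')' at position {m.start('rpar')}")
        pos = m.end()
    if depth != 0:
        raise GprParseError(f"unbalanced '(' ({depth} unclosed) in rule {rule_text!r}")
    return genes


def to_hugo(
    entrez_ids: Sequence[int], mapping: Mapping[int, str]
) -> tuple[list[str], list[int]]:
    """Convert Entrez ids to HUGO symbols, order-preserving.

    Returns ``(symbols, unmapped_ids)`` — ids missing from the table are
    reported, never silently dropped.
    """
    symbols: list[str] = []
    unmapped: list[int] = []
    for gid in entrez_ids:
        sym = mapping.get(gid)
        if sym is None:
            unmapped.append(gid)
        else:
            symbols.append(sym)
    return symbols, unmapped


@dataclass(frozen=True)
class ProteinReactionMap:
    """Bidirectional catalyst index: reaction -> proteins and its transpose.

    ``by_reaction`` maps each reaction id to the ordered HUGO symbols of
    its (putative) catalysts; ``by_protein`` is the exact transpose.
    """

    by_reaction: dict[str, tuple[str, ...]]
    by_protein: dict[str, tuple[str, ...]] = field(default_factory=dict)
    unmapped: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # derive / verify the transpose
        transpose: dict[str, list[str]] = {}
        for rid, symbols in self.by_reaction.items():
            if len(symbols) != len(set(symbols)):
                raise ValueError(f"duplicate symbols in reaction {rid!r}")
            for sym in symbols:
                transpose.setdefault(sym, []).append(rid)
        derived = {sym: tuple(rids) for sym, rids in transpose.items()}
        if not self.by_protein:
            object.__setattr__(self, "by_protein", derived)
        elif self.by_protein != derived:
            raise ValueError("by_protein is not the transpose of by_reaction")

    @property
    def proteins(self) -> set[str]:
        return set(self.by_protein)

    def to_tsv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf, delimiter="\t", lineterminator="\n")
        for rid in self.by_reaction:
            w.writerow([rid, ",".join(self.by_reaction[rid])])
        return buf.getvalue()


def build_protein_reaction_map(
    rules: Iterable[tuple[str, str]], mapping: Mapping[int, str]
) -> ProteinReactionMap:
    """Build the catalyst index from ``(reaction_id, rule_text)`` pairs.

    Reactions whose rule maps to no HUGO symbol are omitted from
    ``by_reaction``; unmapped Entrez ids are recorded per reaction in
    ``unmapped``.  Parse errors are re-raised with the reaction id.
    """
    by_reaction: dict[str, tuple[str, ...]] = {}
    unmapped: dict[str, tuple[int, ...]] = {}
    for rid, rule_text in rules:
        try:
            genes = parse_gpr(rule_text)
        except GprParseError as exc:
            raise GprParseError(f"reaction {rid!r}: {exc}") from exc
        symbols, missing = to_hugo(genes, mapping)
        # a gene can map to a symbol already present via another transcript
        deduped = list(dict.fromkeys(symbols))
        if missing:
            unmapped[rid] = tuple(missing)
        if deduped:
            by_reaction[rid] = tuple(deduped)
    return ProteinReactionMap(by_reaction=by_reaction, unmapped=unmapped)


def read_rules_tsv(text: str) -> list[tuple[str, str]]:
    """Read a two-column model export: reaction_id <tab> GPR rule.

    A header line starting with ``reaction`` (case-insensitive) is skipped.
    A missing second column is an empty rule.
    """
    rows: list[tuple[str, str]] = []
    for i, line in enumerate(text.splitlines()):
        if not line.strip():
            continue
        parts = line.split("\t")
        if i == 0 and parts[0].strip().lower().startswith("reaction"):
            continue
        rid = parts[0].strip()
        rule = parts[1].strip() if len(parts) > 1 else ""
        rows.append((rid, rule))
    return rows


def read_id_mapping_tsv(text: str) -> dict[int, str]:
    """Read a two-column Entrez -> HUGO table.

    The mapping must be single-valued: two different symbols for one
    Entrez id raise ``ValueError`` naming the id.
    """
    mapping: dict[int, str] = {}
    for i, line in enumerate(text.splitlines()):
        if not line.strip():
            continue
        parts = line.split("\t")
        if i == 0 and not parts[0].strip().isdigit():
            continue  # header
        if len(parts) < 2 or not parts[1].strip():
            raise ValueError(f"line {i + 1}: expected 'entrez<TAB>symbol'")
        gid = int(parts[0].strip())
        sym = parts[1].strip()
        if gid in mapping and mapping[gid] != sym:
            raise ValueError(
                f"conflicting symbols for Entrez {gid}: "
                f"{mapping[gid]!r} vs {sym!r}"
            )
        mapping[gid] = sym
    return mapping
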