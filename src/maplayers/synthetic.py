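"""Synthetic CellDesigner maps with known ground truth.

Real signalling/metabolic map resources are large downloads; everything in
this package is testable offline against small generated bundles instead.
A bundle contains a CellDesigner map (metabolites on a jittered grid,
reactions between them, catalyst symbols in the reaction annotations), the
matching model artefacts (GPR rules over a reserved synthetic Entrez range,
an Entrez->HUGO table), a pair of GMT layers (signalling-style *modules*
and metabolic-style *subsystems*), and ground-truth tables: per-reaction
catalysts, glyph positions, the shared-protein set and the expected
crosstalk edge weights.

Generation is fully deterministic per ``rng_seed``.  The synthetic gene
ids start at 9,000,000 so they can never collide with real Entrez ids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .crosstalk import GeneSetCollection
from .model import Alias, Annotation, Box, Entity, EntityClass, MapDocument, Point, Reaction

__all__ = ["SynthSpec", "SynthBundle", "generate", "PRESETS", "preset"]

_ENTREZ_BASE = 9_000_000


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic bundle.

    ``catalysts_per_reaction`` is an inclusive (lo, hi) range;
    ``shared_fraction`` is the fraction of used catalyst symbols that the
    module layer also contains (these become the shared proteins).
    """

    n_metabolites: int = 8
    n_reactions: int = 4
    catalysts_per_reaction: tuple[int, int] = (1, 3)
    canvas: Box = field(default_factory=lambda: Box(Point(0.0, 0.0), 1000.0, 800.0))
    rng_seed: int = 0
    shared_fraction: float = 0.5
    gene_pool_size: int = 12
    n_modules: int = 3
    n_subsystems: int = 2

    def __post_init__(self) -> None:
        lo, hi = self.catalysts_per_reaction
        if self.n_metabolites < 2 or self.n_reactions < 1:
            raise ValueError("need >=2 metabolites and >=1 reaction")
        if not (1 <= lo <= hi):
            raise ValueError("catalysts_per_reaction range must be non-empty")
        if hi > self.gene_pool_size:
            raise ValueError(
                f"more catalysts per reaction ({hi}) than genes in the pool "
                f"({self.gene_pool_size})"
            )
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError("shared_fraction must be within [0, 1]")


@dataclass(frozen=True)
class SynthBundle:
    doc: MapDocument
    rules_tsv: str
    id_mapping: dict[int, str]
    modules: GeneSetCollection
    subsystems: GeneSetCollection
    subsystem_of: dict[str, str]
    catalysts: dict[str, tuple[str, ...]]  # reaction -> HUGO symbols
    glyphs: dict[str, Point]
    shared: frozenset[str]
    expected_edges: dict[tuple[str, str], int]


def generate(spec: SynthSpec) -> SynthBundle:
    """Generate a bundle; see the module docstring for its contents."""
    rng = np.random.default_rng(spec.rng_seed)
    canvas = spec.canvas

    symbols = [f"SYNP{i:03d}" for i in range(spec.gene_pool_size)]
    entrez = {sym: _ENTREZ_BASE + i for i, sym in enumerate(symbols)}

    # --- metabolites on a jittered grid --------------------------------
    ncols = max(2, math.ceil(math.sqrt(spec.n_metabolites)))
    nrows = math.ceil(spec.n_metabolites / ncols)
    cell_w = canvas.width / ncols
    cell_h = canvas.height / nrows
    box_w, box_h = min(70.0, cell_w * 0.5), min(25.0, cell_h * 0.4)

    entities: list[Entity] = []
    aliases: list[Alias] = []
    for i in range(spec.n_metabolites):
        eid = f"s{i + 1}"
        entities.append(Entity(eid, f"M{i + 1}", EntityClass.METABOLITE))
        row, col = divmod(i, ncols)
        jx = float(rng.uniform(0.1, 0.9 - box_w / cell_w))
        jy = float(rng.uniform(0.1, 0.9 - box_h / cell_h))
        origin = Point(col * cell_w + jx * cell_w, row * cell_h + jy * cell_h)
        aliases.append(Alias(f"sa{i + 1}", eid, Box(origin, box_w, box_h)))
    # exercise multi-alias entities: metabolite 1 gets a second alias
    if spec.n_metabolites >= 4:
        shift = Point(
            min(aliases[0].geometry.origin.x + cell_w / 2, canvas.width - box_w - 1),
            min(aliases[0].geometry.origin.y + cell_h / 2, canvas.height - box_h - 1),
        )
        aliases.append(
            Alias(f"sa{len(aliases) + 1}", "s1", Box(shift, box_w, box_h))
        )

    # --- reactions with annotated catalysts ----------------------------
    lo, hi = spec.catalysts_per_reaction
    reactions: list[Reaction] = []
    catalysts: dict[str, tuple[str, ...]] = {}
    rules_rows: list[str] = ["reaction_id\trule"]
    primary_alias = {f"s{i + 1}": f"sa{i + 1}" for i in range(spec.n_metabolites)}
    for j in range(spec.n_reactions):
        rid = f"re{j + 1}"
        src, dst = rng.choice(spec.n_metabolites, size=2, replace=False)
        k = int(rng.integers(lo, hi + 1))
        picks = rng.choice(spec.gene_pool_size, size=k, replace=False)
        syms = tuple(symbols[p] for p in sorted(picks))
        catalysts[rid] = syms
        reactions.append(
            Reaction(
                reaction_id=rid,
                reactant_alias_ids=(primary_alias[f"s{int(src) + 1}"],),
                product_alias_ids=(primary_alias[f"s{int(dst) + 1}"],),
                annotation=Annotation({"Identifiers": syms}),
            )
        )
        rules_rows.append(f"{rid}\t{_gpr_text(syms, entrez, rng)}")

    doc = MapDocument(
        canvas=canvas,
        entities=tuple(entities),
        aliases=tuple(aliases),
        reactions=tuple(reactions),
        model_id=f"synthetic_{spec.rng_seed}",
    )

    glyphs = {
        r.reaction_id: _midpoint(
            doc.alias(r.reactant_alias_ids[0]).geometry.center,
            doc.alias(r.product_alias_ids[0]).geometry.center,
        )
        for r in reactions
    }

    # --- gene-set layers and ground-truth crosstalk ---------------------
    used = sorted({s for syms in catalysts.values() for s in syms})
    n_shared = round(spec.shared_fraction * len(used))
    shared = frozenset(used[:n_shared])

    subsystem_of = {
        f"re{j + 1}": f"SUBSYS_{j % spec.n_subsystems + 1}" for j in range(spec.n_reactions)
    }
    sub_sets: dict[str, set[str]] = {}
    for rid, subsystem in subsystem_of.items():
        sub_sets.setdefault(subsystem, set()).update(catalysts[rid])
    subsystems = GeneSetCollection(
        sets={k: frozenset(v) for k, v in sorted(sub_sets.items())},
        layer_label="subsystem",
        descriptions={k: "synthetic metabolic subsystem" for k in sub_sets},
    )

    mod_sets: dict[str, set[str]] = {f"MODULE_{i + 1}": set() for i in range(spec.n_modules)}
    for i, sym in enumerate(sorted(shared)):
        mod_sets[f"MODULE_{i % spec.n_modules + 1}"].add(sym)
    for i, name in enumerate(mod_sets):  # private signalling-only genes
        mod_sets[name].update({f"SYNA{i}_{j}" for j in range(2)})
    modules = GeneSetCollection(
        sets={k: frozenset(v) for k, v in sorted(mod_sets.items())},
        layer_label="module",
        descriptions={k: "synthetic signalling module" for k in mod_sets},
    )

    expected_edges: dict[tuple[str, str], int] = {}
    for mname, mgenes in modules.sets.items():
        for sname, sgenes in subsystems.sets.items():
            w = len(mgenes & sgenes & shared)
            if w:
                expected_edges[(mname, sname)] = w

    id_mapping = {entrez[sym]: sym for sym in symbols}
    return SynthBundle(
        doc=doc,
        rules_tsv="\n".join(rules_rows) + "\n",
        id_mapping=id_mapping,
        modules=modules,
        subsystems=subsystems,
        subsystem_of=subsystem_of,
        catalysts=catalysts,
        glyphs=glyphs,
        shared=shared,
        expected_edges=expected_edges,
    )


def _midpoint(a: Point, b: Point) -> Point:
    return Point((a.x + b.x) / 2.0, (a.y + b.y) / 2.0)


def _gpr_text(syms: tuple[str, ...], entrez: dict[str, int], rng: np.random.Generator) -> str:
    """Random boolean rule whose flattening is exactly ``syms``' gene ids."""
    tokens = [f"{entrez[s]}.{int(rng.integers(1, 3))}" for s in syms]
    if len(tokens) == 1:
        return tokens[0]
    ops = [" and " if rng.random() < 0.5 else " or " for _ in tokens[1:]]
    expr = tokens[0]
    for op, tok in zip(ops, tokens[1:]):
        expr = f"({expr}{op}{tok})" if rng.random() < 0.5 else f"{expr}{op}{tok}"
    return expr


PRESETS: dict[str, SynthSpec] = {
    "small": SynthSpec(
        n_metabolites=6,
        n_reactions=2,
        catalysts_per_reaction=(1, 2),
        gene_pool_size=6,
        n_modules=2,
        n_subsystems=2,
    ),
    "dense": SynthSpec(
        n_metabolites=30,
        n_reactions=20,
        catalysts_per_reaction=(1, 5),
        gene_pool_size=18,
        n_modules=4,
        n_subsystems=5,
    ),
}


def preset(name: str, rng_seed: int = 0) -> SynthSpec:
    """Named preset spec (``small`` or ``dense``) with the given seed."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return SynthSpec(**{**base.__dict__, "rng_seed": rng_seed})
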