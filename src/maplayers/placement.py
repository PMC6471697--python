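"""Automatic placement of catalyst protein nodes near their reactions.

Metabolic maps drawn in CellDesigner show metabolites and reactions but no
enzyme nodes; the catalysing proteins live only in reaction annotations,
which makes enzyme-level omics data invisible on the canvas.  The placement
procedure puts one node per catalyst in the empty space *around* the
reaction it regulates, without overlapping existing elements:

1.  Every map element (each species alias, at its box centre, and each
    reaction central glyph) becomes a Voronoi seed; the plane is
    tessellated and each cell clipped to the canvas rectangle.  By
    construction a reaction's cell contains no other element.
2.  A fixed number of points (default 100) is sampled uniformly inside the
    reaction's cell.
3.  K-means with K = number of catalysts clusters the points; the cluster
    centroids become the protein node centres.  Centroids of points inside
    a convex cell stay inside it, so every placed node remains nearest to
    its own reaction.

Repeated symbols across the map get apostrophe-suffixed display names
(``GCK``, ``GCK'``, ``GCK''``) so every placed node is distinguishable.

The whole procedure is deterministic: a single seeded generator is consumed
in sorted reaction-id order.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Point as ShPoint
from shapely.geometry import Polygon as ShPolygon
from shapely.geometry import box as sh_box
from sklearn.cluster import KMeans

from .celldesigner import reaction_glyph_position
from .gene_association import ProteinReactionMap
from .model import Alias, Box, Entity, EntityClass, MapDocument, Point

__all__ = [
    "Seed",
    "VoronoiCell",
    "PlacementConfig",
    "PlacedProtein",
    "PlacementResult",
    "build_seeds",
    "clipped_voronoi",
    "sample_cell",
    "cluster_centroids",
    "place_proteins",
    "placement_table",
    "build_protein_overlay",
]

ALIAS = "ALIAS"
REACTION_GLYPH = "REACTION_GLYPH"

#: golden-angle increment used for the deterministic coincident-seed jitter
_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))
_JITTER_STEP = 1e-3  # canvas units


@dataclass(frozen=True)
class Seed:
    owner_id: str
    location: Point
    owner_kind: str  # ALIAS or REACTION_GLYPH


@dataclass(frozen=True)
class VoronoiCell:
    owner_id: str
    polygon: tuple[Point, ...]  # closed ring implied (last != first)

    def shapely(self) -> ShPolygon:
        return ShPolygon([(p.x, p.y) for p in self.polygon])

    @property
    def area(self) -> float:
        return self.shapely().area


@dataclass(frozen=True)
class PlacementConfig:
    """Tunables of the placement procedure.

    ``n_points`` — points sampled per reaction cell (100 is ample for the
    handful of catalysts a reaction typically has); ``protein_box`` — size
    of created protein nodes in canvas units; ``max_resample`` — how many
    times ``n_points`` may be doubled when a reaction has more catalysts
    than points.
    """

    n_points: int = 100
    rng_seed: int = 0
    protein_width: float = 80.0
    protein_height: float = 40.0
    max_resample: int = 10

    def __post_init__(self) -> None:
        if self.n_points < 1 or self.max_resample < 1:
            raise ValueError("n_points and max_resample must be positive")


@dataclass(frozen=True)
class PlacedProtein:
    symbol: str
    display_name: str
    reaction_id: str
    geometry: Box


@dataclass(frozen=True)
class PlacementResult:
    placed: tuple[PlacedProtein, ...]
    stats: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# seeds


def build_seeds(doc: MapDocument) -> list[Seed]:
    """One seed per species alias (box centre) plus one per reaction glyph.

    Coincident locations are separated by a deterministic golden-angle
    spiral jitter of ~1e-3 canvas units so the tessellation is defined.
    """
    seeds: list[Seed] = []
    for a in doc.aliases:
        seeds.append(Seed(a.alias_id, a.geometry.center, ALIAS))
    for r in doc.reactions:
        seeds.append(
            Seed(r.reaction_id, reaction_glyph_position(doc, r.reaction_id), REACTION_GLYPH)
        )
    return _dejitter(seeds, doc.canvas)


def _dejitter(seeds: list[Seed], canvas: Box) -> list[Seed]:
    seen: dict[tuple[float, float], int] = {}
    out: list[Seed] = []
    for s in seeds:
        key = (s.location.x, s.location.y)
        k = seen.get(key, 0)
        seen[key] = k + 1
        if k == 0:
            out.append(s)
            continue
        # spiral outwards until a free spot inside the canvas is found
        j = k
        while True:
            r = _JITTER_STEP * j
            theta = _GOLDEN_ANGLE * j
            p = Point(s.location.x + r * math.cos(theta), s.location.y + r * math.sin(theta))
            pkey = (p.x, p.y)
            if pkey not in seen and canvas.contains_point(p):
                seen[pkey] = 1
                out.append(Seed(s.owner_id, p, s.owner_kind))
                break
            j += 1
    return out


# ---------------------------------------------------------------------------
# clipped Voronoi tessellation


def clipped_voronoi(seeds: list[Seed], canvas: Box) -> list[VoronoiCell]:
    """Voronoi cells of the seeds, clipped to the canvas rectangle.

    A single seed owns the whole canvas.  For two or more seeds the sites
    are reflected across the four canvas edges; every original site's
    region is then bounded, and intersecting it with the rectangle yields
    the exactly clipped (convex) cell.  Cells tile the canvas.
    """
    if not seeds:
        raise ValueError("at least one seed is required")
    rect = sh_box(
        canvas.origin.x,
        canvas.origin.y,
        canvas.origin.x + canvas.width,
        canvas.origin.y + canvas.height,
    )
    if len(seeds) == 1:
        ring = [Point(x, y) for x, y in rect.exterior.coords[:-1]]
        return [VoronoiCell(seeds[0].owner_id, tuple(ring))]

    pts = np.array([[s.location.x, s.location.y] for s in seeds], dtype=float)
    x0, y0 = canvas.origin.x, canvas.origin.y
    x1, y1 = x0 + canvas.width, y0 + canvas.height
    mirrored = np.vstack(
        [
            pts,
            np.column_stack([2 * x0 - pts[:, 0], pts[:, 1]]),  # left
            np.column_stack([2 * x1 - pts[:, 0], pts[:, 1]]),  # right
            np.column_stack([pts[:, 0], 2 * y0 - pts[:, 1]]),  # top
            np.column_stack([pts[:, 0], 2 * y1 - pts[:, 1]]),  # bottom
        ]
    )
    vor = Voronoi(mirrored)
    cells: list[VoronoiCell] = []
    for i, seed in enumerate(seeds):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:
            raise RuntimeError(
                f"seed {seed.owner_id!r} has an unbounded region after mirroring"
            )
        poly = ShPolygon(vor.vertices[region])
        clipped = poly.intersection(rect)
        if clipped.is_empty or clipped.geom_type != "Polygon":
            raise RuntimeError(f"degenerate clipped cell for seed {seed.owner_id!r}")
        ring = list(clipped.exterior.coords[:-1])
        cells.append(VoronoiCell(seed.owner_id, tuple(Point(x, y) for x, y in ring)))
    return cells


# ---------------------------------------------------------------------------
# in-cell sampling


def sample_cell(cell: VoronoiCell, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` points uniformly and strictly inside the cell polygon.

    Uses exact fan-triangulation sampling (valid for the convex clipped
    cells): a triangle is chosen with probability proportional to its area,
    then a point uniformly within it.  Returns an (n, 2) array.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    poly = cell.shapely()
    if poly.area <= 0:
        raise ValueError(f"cell of {cell.owner_id!r} has zero area")
    verts = np.array([(p.x, p.y) for p in cell.polygon], dtype=float)
    v0 = verts[0]
    tris = [(v0, verts[i], verts[i + 1]) for i in range(1, len(verts) - 1)]
    areas = np.array(
        [
            abs((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])) / 2.0
            for a, b, c in tris
        ],
        dtype=float,
    )
    weights = areas / areas.sum()

    out = np.empty((n, 2), dtype=float)
    filled = 0
    while filled < n:
        need = n - filled
        idx = rng.choice(len(tris), size=need, p=weights)
        u = rng.random(need)
        v = rng.random(need)
        flip = u + v > 1.0
        u[flip], v[flip] = 1.0 - u[flip], 1.0 - v[flip]
        pts = np.array(
            [
                tris[i][0] + u[j] * (tris[i][1] - tris[i][0]) + v[j] * (tris[i][2] - tris[i][0])
                for j, i in enumerate(idx)
            ]
        )
        # keep strictly interior points (boundary hits have measure ~0)
        keep = np.array([poly.contains(ShPoint(p)) for p in pts], dtype=bool)
        kept = pts[keep]
        out[filled : filled + len(kept)] = kept
        filled += len(kept)
    return out


# ---------------------------------------------------------------------------
# clustering


def cluster_centroids(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """K-means centroids of the sampled points (k-means++, 10 restarts).

    Returns a (k, 2) array sorted lexicographically by (x, y) so the
    output order is deterministic.  ``k`` must not exceed the number of
    points — the caller resamples with a larger n in that case.
    """
    points = np.asarray(points, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(points):
        raise ValueError(f"k={k} exceeds the number of points ({len(points)})")
    if k == 1:
        return points.mean(axis=0, keepdims=True)
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=10,
        random_state=int(rng.integers(0, 2**31 - 1)),
    )
    km.fit(points)
    centroids = km.cluster_centers_
    order = np.lexsort((centroids[:, 1], centroids[:, 0]))
    return centroids[order]


# ---------------------------------------------------------------------------
# the full placement procedure


def place_proteins(
    doc: MapDocument, prmap: ProteinReactionMap, config: PlacementConfig | None = None
) -> PlacementResult:
    """Place every catalyst of every mapped reaction inside that reaction's
    Voronoi cell; see the module docstring for the three-step procedure.

    Reactions are processed in sorted id order with a single seeded
    generator, so the result is reproducible bit-for-bit.  Raises if the
    catalyst index names a reaction absent from the map.
    """
    config = config or PlacementConfig()
    known = {r.reaction_id for r in doc.reactions}
    missing = sorted(set(prmap.by_reaction) - known)
    if missing:
        raise KeyError(f"reactions not present in the map: {missing}")

    seeds = build_seeds(doc)
    all_cells = clipped_voronoi(seeds, doc.canvas)
    cells = {
        c.owner_id: c
        for c, s in zip(all_cells, seeds)
        if s.owner_kind == REACTION_GLYPH
    }
    rng = np.random.default_rng(config.rng_seed)

    placed: list[PlacedProtein] = []
    occurrences: dict[str, int] = {}
    reactions_processed = 0
    for rid in sorted(prmap.by_reaction):
        symbols = prmap.by_reaction[rid]
        cell = cells[rid]
        k = len(symbols)
        n = config.n_points
        attempts = 0
        while n < k:
            n *= 2
            attempts += 1
            if attempts > config.max_resample:
                raise RuntimeError(
                    f"reaction {rid!r}: cannot sample enough points for k={k}"
                )
        points = sample_cell(cell, n, rng)
        centroids = cluster_centroids(points, k, rng)
        for sym, centre in zip(symbols, centroids):
            count = occurrences.get(sym, 0)
            occurrences[sym] = count + 1
            display = sym + "'" * count
            geometry = Box(
                Point(
                    centre[0] - config.protein_width / 2.0,
                    centre[1] - config.protein_height / 2.0,
                ),
                config.protein_width,
                config.protein_height,
            )
            placed.append(PlacedProtein(sym, display, rid, geometry))
        reactions_processed += 1

    stats = {
        "proteins_placed": len(occurrences),
        "aliases_created": len(placed),
        "reactions_processed": reactions_processed,
        "reactions_skipped": len(doc.reactions) - reactions_processed,
    }
    return PlacementResult(placed=tuple(placed), stats=stats)


def placement_table(result: PlacementResult) -> str:
    """Intermediate placement table as TSV:
    display_name, symbol, reaction_id, x, y, width, height
    (x, y is the top-left corner of the node box, CellDesigner-style).
    """
    buf = io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(["display_name", "symbol", "reaction_id", "x", "y", "width", "height"])
    for p in result.placed:
        g = p.geometry
        w.writerow(
            [p.display_name, p.symbol, p.reaction_id,
             repr(g.origin.x), repr(g.origin.y), repr(g.width), repr(g.height)]
        )
    return buf.getvalue()


def build_protein_overlay(result: PlacementResult, canvas: Box) -> MapDocument:
    """Convert placed proteins into a proteins-only CellDesigner map.

    One entity per distinct symbol, one alias per placement — a protein
    catalysing several reactions appears as several aliases of the same
    species.  Node boxes are shrunk to the canvas edge when a centroid
    lies too close to the border for the full box.
    """
    symbols = sorted({p.symbol for p in result.placed})
    entity_id = {sym: f"p{i + 1}" for i, sym in enumerate(symbols)}
    entities = tuple(
        Entity(entity_id[sym], sym, EntityClass.PROTEIN) for sym in symbols
    )
    aliases = []
    for i, p in enumerate(result.placed):
        aliases.append(
            Alias(f"pa{i + 1}", entity_id[p.symbol], _clamp_box(p.geometry, canvas))
        )
    return MapDocument(
        canvas=canvas,
        entities=entities,
        aliases=tuple(aliases),
        reactions=(),
        model_id="protein_overlay",
    )


def _clamp_box(b: Box, canvas: Box) -> Box:
    """Shrink a box to fit the canvas while keeping its centre fixed."""
    cx, cy = b.center
    half_w = min(b.width / 2.0, cx - canvas.origin.x, canvas.origin.x + canvas.width - cx)
    half_h = min(b.height / 2.0, cy - canvas.origin.y, canvas.origin.y + canvas.height - cy)
    half_w = max(half_w, 1e-6)
    half_h = max(half_h, 1e-6)
    return Box(Point(cx - half_w, cy - half_h), 2 * half_w, 2 * half_h)
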