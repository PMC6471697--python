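"""Voronoi tessellation, in-cell sampling, K-means, and full placement."""

import numpy as np
import pytest

from maplayers.gene_association import ProteinReactionMap, build_protein_reaction_map, read_rules_tsv
from maplayers.model import Box, Point
from maplayers.placement import (
    ALIAS,
    REACTION_GLYPH,
    PlacementConfig,
    Seed,
    VoronoiCell,
    build_protein_overlay,
    build_seeds,
    clipped_voronoi,
    cluster_centroids,
    place_proteins,
    placement_table,
    sample_cell,
)

CANVAS = Box(Point(0, 0), 100.0, 100.0)


def _seed(i, x, y):
    return Seed(f"n{i}", Point(x, y), ALIAS)


# ---------------------------------------------------------------- seeds


def test_seed_count_is_aliases_plus_reactions(dense_bundle):
    doc = dense_bundle.doc
    seeds = build_seeds(doc)
    assert len(seeds) == len(doc.aliases) + len(doc.reactions)
    kinds = {s.owner_kind for s in seeds}
    assert kinds == {ALIAS, REACTION_GLYPH}


def test_coincident_seeds_are_jittered_deterministically(toy_doc):
    doc = toy_doc.with_components(
        aliases=(
            toy_doc.aliases[0],
            toy_doc.aliases[1],
            # same centre as sa1
            type(toy_doc.aliases[0])("sa3", "s3", toy_doc.aliases[0].geometry),
        )
    )
    seeds1 = build_seeds(doc)
    seeds2 = build_seeds(doc)
    assert seeds1 == seeds2  # deterministic
    locs = [(s.location.x, s.location.y) for s in seeds1]
    assert len(set(locs)) == len(locs)  # all distinct after jitter
    # jitter is tiny
    a, b = seeds1[0].location, seeds1[2].location
    assert 0 < ((a.x - b.x) ** 2 + (a.y - b.y) ** 2) ** 0.5 < 0.01


def test_empty_map_gives_no_seeds():
    from maplayers.model import MapDocument

    assert build_seeds(MapDocument(canvas=CANVAS)) == []


# ------------------------------------------------------- clipped voronoi


def test_two_seeds_split_canvas_at_bisector():
    cells = clipped_voronoi([_seed(1, 25, 50), _seed(2, 75, 50)], CANVAS)
    areas = {c.owner_id: c.area for c in cells}
    assert areas == {"n1": pytest.approx(5000.0), "n2": pytest.approx(5000.0)}
    # the dividing edge is x = 50
    for c in cells:
        xs = sorted({p.x for p in c.polygon})
        assert 50.0 in xs


def test_single_seed_owns_whole_canvas():
    (cell,) = clipped_voronoi([_seed(1, 10, 90)], CANVAS)
    assert cell.area == pytest.approx(100.0 * 100.0)


def test_no_seeds_is_an_error():
    with pytest.raises(ValueError):
        clipped_voronoi([], CANVAS)


def test_random_seeds_tile_canvas_and_match_point_location_oracle():
    """Monte-Carlo oracle: classify uniform points by nearest seed and
    compare cell area fractions; plus the exact tiling identity."""
    rng = np.random.default_rng(42)
    pts = rng.uniform(5, 95, size=(10, 2))
    seeds = [_seed(i, x, y) for i, (x, y) in enumerate(pts)]
    cells = clipped_voronoi(seeds, CANVAS)

    total = sum(c.area for c in cells)
    assert abs(total - 1e4) / 1e4 < 1e-6

    sample = rng.uniform(0, 100, size=(100_000, 2))
    d2 = ((sample[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    frac_oracle = np.bincount(nearest, minlength=len(seeds)) / len(sample)
    frac_cells = np.array([c.area for c in cells]) / 1e4
    assert np.abs(frac_oracle - frac_cells).max() < 0.01


# ----------------------------------------------------------- sampling


def _unit_cell():
    return VoronoiCell("u", (Point(0, 0), Point(1, 0), Point(1, 1), Point(0, 1)))


def test_sample_unit_square_strictly_inside():
    pts = sample_cell(_unit_cell(), 100, np.random.default_rng(0))
    assert pts.shape == (100, 2)
    assert (pts > 0).all() and (pts < 1).all()


def test_sampling_is_reproducible():
    a = sample_cell(_unit_cell(), 50, np.random.default_rng(7))
    b = sample_cell(_unit_cell(), 50, np.random.default_rng(7))
    assert (a == b).all()


def test_triangle_sample_mean_matches_analytic_centroid():
    tri = VoronoiCell("t", (Point(0, 0), Point(9, 0), Point(0, 6)))
    pts = sample_cell(tri, 10_000, np.random.default_rng(1))
    centroid = np.array([3.0, 2.0])  # mean of the vertices
    err = np.abs(pts.mean(axis=0) - centroid)
    assert (err < 0.1).all()  # ~0.01 relative to the 9x6 extent


def test_zero_area_cell_is_an_error():
    line = VoronoiCell("z", (Point(0, 0), Point(1, 0), Point(2, 0)))
    with pytest.raises(ValueError, match="'z'"):
        sample_cell(line, 10, np.random.default_rng(0))


# ----------------------------------------------------------- k-means


def test_k1_is_exact_mean():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(40, 2))
    (c,) = cluster_centroids(pts, 1, rng)
    assert np.allclose(c, pts.mean(axis=0), atol=0, rtol=0)


def test_two_blob_recovery():
    rng = np.random.default_rng(5)
    means = np.array([[0.0, 0.0], [10.0, 10.0]])
    pts = np.vstack(
        [rng.normal(m, 0.01, size=(50, 2)) for m in means]
    )
    cents = cluster_centroids(pts, 2, rng)
    blob_means = np.array([pts[:50].mean(axis=0), pts[50:].mean(axis=0)])
    assert np.abs(np.sort(cents, axis=0) - np.sort(blob_means, axis=0)).max() < 0.05


def test_k_equals_n_gives_the_points_back():
    pts = np.array([[0.0, 0.0], [5.0, 1.0], [2.0, 8.0]])
    cents = cluster_centroids(pts, 3, np.random.default_rng(0))
    assert {tuple(c) for c in cents} == {tuple(p) for p in pts}


def test_k_larger_than_n_is_an_error():
    with pytest.raises(ValueError):
        cluster_centroids(np.zeros((3, 2)), 4, np.random.default_rng(0))


# ------------------------------------------------------ full placement


def _prmap(d):
    return ProteinReactionMap(by_reaction={k: tuple(v) for k, v in d.items()})


def test_counts_and_containment_on_toy(toy_doc):
    pr = _prmap({"re1": ["GCK", "HK1"]})
    res = place_proteins(toy_doc, pr, PlacementConfig(rng_seed=0))
    assert len(res.placed) == 2
    assert res.stats["aliases_created"] == 2
    seeds = build_seeds(toy_doc)
    cells = clipped_voronoi(seeds, toy_doc.canvas)
    cell = {c.owner_id: c for c in cells}["re1"].shapely()
    for p in res.placed:
        from shapely.geometry import Point as ShPoint

        assert cell.contains(ShPoint(tuple(p.geometry.center)))


def test_apostrophe_naming_across_reactions(toy_doc):
    doc = toy_doc.with_components(
        reactions=(
            toy_doc.reactions[0],
            type(toy_doc.reactions[0])("re2", ("sa2",), ("sa1",)),
            type(toy_doc.reactions[0])("re3", ("sa1",), ("sa3",)),
        )
    )
    pr = _prmap({"re1": ["GCK"], "re2": ["GCK"], "re3": ["GCK"]})
    res = place_proteins(doc, pr, PlacementConfig(rng_seed=0))
    assert [p.display_name for p in res.placed] == ["GCK", "GCK'", "GCK''"]


def test_dense_placement_matches_association_counts_and_nearest_seed(dense_bundle):
    doc = dense_bundle.doc
    pr = build_protein_reaction_map(
        read_rules_tsv(dense_bundle.rules_tsv), dense_bundle.id_mapping
    )
    res = place_proteins(doc, pr, PlacementConfig(rng_seed=0))
    per_reaction = {}
    for p in res.placed:
        per_reaction[p.reaction_id] = per_reaction.get(p.reaction_id, 0) + 1
    assert per_reaction == {r: len(s) for r, s in pr.by_reaction.items()}

    # brute-force nearest-seed oracle over ALL seeds
    seeds = build_seeds(doc)
    locs = np.array([[s.location.x, s.location.y] for s in seeds])
    owners = [s.owner_id for s in seeds]
    for p in res.placed:
        c = np.array(tuple(p.geometry.center))
        assert owners[int(((locs - c) ** 2).sum(axis=1).argmin())] == p.reaction_id


def test_placement_is_bit_identical_across_runs(dense_bundle):
    pr = build_protein_reaction_map(
        read_rules_tsv(dense_bundle.rules_tsv), dense_bundle.id_mapping
    )
    cfg = PlacementConfig(rng_seed=11)
    assert place_proteins(dense_bundle.doc, pr, cfg) == place_proteins(
        dense_bundle.doc, pr, cfg
    )


def test_unknown_reaction_in_index_is_an_error(toy_doc):
    with pytest.raises(KeyError, match="reX"):
        place_proteins(toy_doc, _prmap({"reX": ["GCK"]}))


def test_resampling_covers_k_larger_than_n_points(toy_doc):
    pr = _prmap({"re1": [f"P{i}" for i in range(5)]})
    res = place_proteins(toy_doc, pr, PlacementConfig(n_points=2, rng_seed=0))
    assert len(res.placed) == 5


def test_placement_table_and_overlay(toy_doc):
    pr = _prmap({"re1": ["GCK", "HK1"]})
    res = place_proteins(toy_doc, pr, PlacementConfig(rng_seed=0))
    table = placement_table(res)
    assert table.splitlines()[0].startswith("display_name\tsymbol")
    assert len(table.splitlines()) == 3
    overlay = build_protein_overlay(res, toy_doc.canvas)
    assert len(overlay.entities) == 2
    assert len(overlay.aliases) == 2
    # alias centres identical to placement centres
    placed_centres = {tuple(p.geometry.center) for p in res.placed}
    overlay_centres = {tuple(a.geometry.center) for a in overlay.aliases}
    assert placed_centres == overlay_centres
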