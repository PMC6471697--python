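"""GMT I/O, shared proteins, hypergeometric enrichment, crosstalk network."""

import itertools
from math import comb

import pytest

from maplayers.crosstalk import (
    GeneSetCollection,
    GmtParseError,
    build_crosstalk_network,
    enrich,
    network_to_sif,
    network_to_txt,
    reaction_regulation_counts,
    read_gmt,
    read_subsystem_assignment,
    shared_proteins,
    write_gmt,
)
from maplayers.gene_association import ProteinReactionMap


def _coll(sets, label=""):
    return GeneSetCollection(
        sets={k: frozenset(v) for k, v in sets.items()}, layer_label=label
    )


# ----------------------------------------------------------------- GMT


def test_gmt_parse_dedups_within_line():
    c = read_gmt("M1\tdesc\tA\tB\tA\n")
    assert c.sets == {"M1": frozenset({"A", "B"})}
    assert c.descriptions["M1"] == "desc"


def test_gmt_roundtrip():
    c = _coll({"M1": {"A", "B"}, "M2": {"C"}})
    assert read_gmt(write_gmt(c)).sets == c.sets


def test_gmt_empty_and_malformed():
    assert read_gmt("").sets == {}
    with pytest.raises(GmtParseError, match="line 2"):
        read_gmt("M1\td\tA\nM2\tdesc-only\n")


# ------------------------------------------------------ shared proteins


def test_shared_is_intersection_of_unions_and_symmetric():
    a = _coll({"M1": {"A", "B"}, "M2": {"C"}})
    b = _coll({"S1": {"B", "D"}, "S2": {"C"}})
    assert shared_proteins(a, b) == {"B", "C"}
    assert shared_proteins(a, b) == shared_proteins(b, a)
    assert shared_proteins(a, _coll({"S": {"Z"}})) == frozenset()


# ---------------------------------------------------------- enrichment


def _oracle_upper_tail(N, K, n, k):
    """Exact combinatorial sum P[X >= k] for Hypergeometric(N, K, n)."""
    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / total


def test_enrichment_matches_exhaustive_oracle_small_universes():
    """Sweep every (universe<=25, set size, query size) geometry."""
    for N in (5, 8, 12, 20, 25):
        universe = [f"g{i}" for i in range(N)]
        for K in range(1, N + 1):
            for n in range(0, N + 1, max(1, N // 5)):
                sets = _coll({"S": set(universe[:K])})
                query = set(universe[N - n:])
                res = enrich(sets, query, universe, min_size=1)
                (r,) = res
                k = len(set(universe[:K]) & query)
                assert r.overlap_count == k
                assert r.p_value == pytest.approx(
                    _oracle_upper_tail(N, K, n, k), abs=1e-12
                )


def test_zero_overlap_gives_p_exactly_one():
    sets = _coll({"S": {"A", "B", "C"}})
    (r,) = enrich(sets, {"X"}, {"A", "B", "C", "X"}, min_size=1)
    assert r.overlap_count == 0
    assert r.p_value == 1.0


def test_min_size_filter_excludes_undersized_sets():
    sets = _coll({"BIG": {f"g{i}" for i in range(10)}, "SMALL": {f"g{i}" for i in range(9)}})
    universe = {f"g{i}" for i in range(10)} | {"q"}
    res = enrich(sets, {"q", "g0"}, universe, min_size=10)
    assert [r.set_name for r in res] == ["BIG"]
    assert res[0].p_adjusted == pytest.approx(min(1.0, res[0].p_value * 1))


def test_bonferroni_uses_number_of_tested_sets():
    universe = {f"g{i}" for i in range(12)}
    sets = _coll({
        "S1": {f"g{i}" for i in range(10)},
        "S2": {f"g{i}" for i in range(2, 12)},
        "TINY": {"g0"},
    })
    res = enrich(sets, {"g0", "g1", "g2"}, universe, min_size=10)
    assert len(res) == 2  # TINY excluded
    for r in res:
        assert r.p_adjusted == pytest.approx(min(1.0, r.p_value * 2))


def test_query_outside_universe_is_an_error():
    with pytest.raises(ValueError, match="ALIEN"):
        enrich(_coll({"S": {"A"}}), {"ALIEN"}, {"A"})


def test_p_value_monotone_in_overlap():
    N, K, n = 30, 8, 10
    ps = [_oracle_upper_tail(N, K, n, k) for k in range(0, 9)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))
    # and the implementation agrees on a mid case
    universe = [f"g{i}" for i in range(N)]
    sets = _coll({"S": set(universe[:K])})
    for k in (2, 5):
        query = set(universe[:k]) | set(universe[K : K + (n - k)])
        (r,) = enrich(sets, query, universe, min_size=1)
        assert r.p_value == pytest.approx(ps[k], abs=1e-12)


# ------------------------------------------------------------- network


def test_single_edge_network():
    a = _coll({"M1": {"A", "B"}}, "module")
    b = _coll({"S1": {"B"}, "S2": {"C"}}, "subsystem")
    g = build_crosstalk_network(a, b, {"B"})
    assert set(g.edges()) == {("M1", "S1")}
    assert g.edges["M1", "S1"]["weight"] == 1
    assert g.nodes["M1"]["layer"] == "module"
    assert g.nodes["S2"]["layer"] == "subsystem"


def test_empty_shared_gives_edgeless_network():
    a = _coll({"M1": {"A"}})
    b = _coll({"S1": {"B"}})
    g = build_crosstalk_network(a, b, set())
    assert g.number_of_edges() == 0
    assert g.number_of_nodes() == 2


def test_edge_weight_conservation_brute_force(dense_bundle):
    a, b = dense_bundle.modules, dense_bundle.subsystems
    shared = shared_proteins(a, b)
    g = build_crosstalk_network(a, b, shared)
    total = sum(d["weight"] for _, _, d in g.edges(data=True))
    brute = sum(
        len(ga & gb & shared)
        for ga in a.sets.values()
        for gb in b.sets.values()
    )
    assert total == brute


def test_network_exports():
    a = _coll({"M1": {"A", "B"}})
    b = _coll({"S1": {"A", "B"}})
    g = build_crosstalk_network(a, b, {"A", "B"})
    txt = network_to_txt(g)
    assert txt.splitlines()[1] == "M1\tS1\tcrosstalk\t2"
    assert network_to_sif(g) == "M1\tcrosstalk\tS1\n"


# --------------------------------------------- reaction regulation table


def test_regulation_counts_match_brute_force(dense_bundle):
    pr = ProteinReactionMap(by_reaction=dict(dense_bundle.catalysts))
    shared = dense_bundle.shared
    df = reaction_regulation_counts(
        pr, dense_bundle.subsystem_of, dense_bundle.modules, shared
    )
    got = {(r.module, r.subsystem): r.n_reactions for r in df.itertuples()}
    brute = {}
    for mname, mgenes in dense_bundle.modules.sets.items():
        for rid, syms in pr.by_reaction.items():
            if set(syms) & shared & mgenes:
                key = (mname, dense_bundle.subsystem_of[rid])
                brute.setdefault(key, set()).add(rid)
    assert got == {k: len(v) for k, v in brute.items()}


def test_one_reaction_counted_once_despite_multiple_catalysts():
    pr = ProteinReactionMap(by_reaction={"r1": ("A", "B", "C")})
    modules = _coll({"M1": {"A", "B", "C"}})
    df = reaction_regulation_counts(pr, {"r1": "S1"}, modules, {"A", "B", "C"})
    assert df.to_dict("records") == [
        {"module": "M1", "subsystem": "S1", "n_reactions": 1}
    ]


def test_unassigned_reaction_excluded_with_diagnostic():
    pr = ProteinReactionMap(by_reaction={"r1": ("A",), "r2": ("A",)})
    modules = _coll({"M1": {"A"}})
    df = reaction_regulation_counts(pr, {"r1": "S1"}, modules, {"A"})
    assert df.attrs["unassigned"] == ["r2"]
    assert df["n_reactions"].sum() == 1


def test_multi_assignment_rejected_at_load():
    with pytest.raises(ValueError, match="r1"):
        read_subsystem_assignment("r1\tS1\nr1\tS2\n")
    assert read_subsystem_assignment("reaction_id\tsubsystem\nr1\tS1\n") == {"r1": "S1"}
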