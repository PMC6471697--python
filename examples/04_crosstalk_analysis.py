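"""Crosstalk between a signalling layer (modules) and a metabolic layer
(subsystems): shared proteins, hypergeometric enrichment, and the
bipartite crosstalk network.
"""

from maplayers import (
    build_crosstalk_network,
    enrich,
    generate,
    network_to_txt,
    preset,
    shared_proteins,
)

bundle = generate(preset("dense", rng_seed=0))
modules, subsystems = bundle.modules, bundle.subsystems

shared = shared_proteins(modules, subsystems)
universe = modules.union() | subsystems.union()
print(f"{len(shared)} proteins are shared between the two layers "
      f"(universe of {len(universe)} proteins)")

results = enrich(modules, shared, universe, min_size=1)
print("module enrichment (upper-tail hypergeometric, Bonferroni-adjusted):")
for r in results:
    print(f"  {r.set_name:10s} overlap {r.overlap_count}/{r.set_size}  "
          f"p={r.p_value:.3g}  p_adj={r.p_adjusted:.3g}")

net = build_crosstalk_network(modules, subsystems, shared)
print(f"crosstalk network: {net.number_of_nodes()} nodes, "
      f"{net.number_of_edges()} edges; edge weight = shared proteins in "
      f"the module-subsystem intersection")
print(network_to_txt(net), end="")
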