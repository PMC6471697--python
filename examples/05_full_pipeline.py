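"""The full workflow in one call: extract -> place -> merge -> crosstalk.

Prints the per-stage run report; this is the same composition the
``maplayers pipeline`` command runs from the shell.
"""

import json

from maplayers import generate, preset, read_rules_tsv, run_pipeline

bundle = generate(preset("dense", rng_seed=0))
out = run_pipeline(
    bundle.doc,
    read_rules_tsv(bundle.rules_tsv),
    bundle.id_mapping,
    bundle.modules,
    bundle.subsystems,
    bundle.subsystem_of,
    min_size=1,
)
print(json.dumps(out.report, indent=2))
print("placement counts equal the catalyst associations; merge counts sum; "
      "the crosstalk section quantifies how strongly the two layers share "
      "proteins, and the regulation table (below) counts reactions per "
      "module-subsystem pair:")
print(out.regulation.to_string(index=False))
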