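"""Parse a CellDesigner map and locate every reaction's central glyph.

Builds a small synthetic metabolic map, writes it to CellDesigner SBML,
parses it back, and prints the central-glyph coordinate of each reaction —
the anchor point used later for catalyst placement.
"""

from maplayers import generate, glyph_table, parse_map, preset, write_map

bundle = generate(preset("small", rng_seed=0))
xml = write_map(bundle.doc)
doc = parse_map(xml)

print(f"map: {len(doc.entities)} entities, {len(doc.aliases)} aliases, "
      f"{len(doc.reactions)} reactions on a "
      f"{doc.canvas.width:.0f}x{doc.canvas.height:.0f} canvas")
print("reaction glyph positions (midpoint of the anchor alias centres):")
print(glyph_table(doc), end="")
print("each row is: reaction id, x, y in canvas units (origin top-left).")
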