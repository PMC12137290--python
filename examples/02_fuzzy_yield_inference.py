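"""Run Mamdani fuzzy inference for one field record.

Builds the expert rule base over total biomass and maize residue biomass
(low/medium/high sets each, a 3x3 rule grid), infers a crisp yield by
centroid defuzzification, and classifies it into the low (<7.5), medium
(7.5-9) or high (9-10 t/ha) band.
"""

from fohem.fuzzy import build_default_yield_fis, classify_yield, infer
from fohem.synthetic import default_schema

specs = {s.name: s for s in default_schema()}
fis = build_default_yield_fis([specs["total_biomass"], specs["M_residue_biomass"]])
print(f"rule base: {len(fis.rules)} rules over "
      f"{[v.name for v in fis.input_vars]}")

inputs = {"total_biomass": 16.0, "M_residue_biomass": 7500.0}
crisp, _ = infer(fis, inputs)
print(f"inputs: {inputs}")
print(f"crisp yield: {crisp:.2f} t/ha -> category {classify_yield(crisp)!r}")

# High biomass and high residue fire the high-yield rules hardest, so the
# centroid lands in the upper part of the 0-10 t/ha universe.
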