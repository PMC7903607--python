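"""Link clinotype names to genes through a local geneset (GMT) file.

Clinotype names are stripped of non-biological qualifiers and
singularized ("Basophils Percentage" → "Basophil"), then matched as
substrings against geneset names.
"""

from cpa.datamodel import Geneset
from cpa.genelink import map_to_genesets, normalize_clinotype_name

genesets = [
    Geneset("BASOPHIL_ACTIVATION", "demo", ("CCR3", "IL3RA", "ENPP3")),
    Geneset("GLUCOSE_METABOLISM", "demo", ("GCK", "G6PC", "INS")),
    Geneset("MONOCYTE_CHEMOTAXIS", "demo", ("CCL2", "CCR2")),
]

clinotypes = [
    "Basophils Percentage",
    "Monocytes Absolute value",
    "Glucose",
    "Creatinine",
]

for name in clinotypes:
    print(f"{name!r:<28} -> query {normalize_clinotype_name(name)!r}")

result = map_to_genesets(clinotypes, genesets)
print(f"\n{len(result.links)} links, {len(result.unique_pairs())} unique "
      f"(clinotype, gene) pairs, unmatched terms: {result.unmatched}")
for link in result.links:
    print(f"  {link.clinotype:<26} {link.gene:<6} [{link.geneset}]")
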