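"""Parse N-glycan structure codes and extract their modular features.

Builds a few tree codes, canonicalizes them and prints the feature vector:
core class (plain / core-fucosylated / bisected / both), subtype
(oligo-mannose / hybrid / complex), branch motifs, antenna count and the
fucosylation/sialylation classes.
"""

from glycomine import featurize, parse_structure, serialize_canonical
from glycomine.glycan import MAN_TOPOLOGIES

EXAMPLES = {
    "Man5 (oligomannose)": MAN_TOPOLOGIES[5],
    "core-fucosylated biantennary": "N(F)(N(H(H(N(H)))(H(N(H)))))",
    "bisected, sole GlcNAc arms": "N(N(H(N)(H(N))(H(N))))",
    "sialyl-LacNAc + LacdiNAc": "N(N(H(H(N(H(A))))(H(N(N)))))",
}

for name, code in EXAMPLES.items():
    fv = featurize(code)
    canon = serialize_canonical(parse_structure(code))
    print(f"{name}")
    print(f"  canonical code : {canon}")
    print(f"  core / subtype : {fv.core_class} / {fv.subtype}")
    print(f"  branches       : {', '.join(fv.branches)}")
    print(f"  antennae       : {fv.antenna_count}   "
          f"fucosylation: {fv.fucosylation}   "
          f"sialylation: {fv.sialylation}")

# The same tree written with siblings swapped canonicalizes identically,
# so sibling order in the input never creates spurious "new" structures.
a = serialize_canonical(parse_structure("N(N(H(H(N(H)))(H)))", relaxed=True))
b = serialize_canonical(parse_structure("N(N(H(H)(H(N(H)))))", relaxed=True))
print(f"\nsibling-order invariance: {a == b} ({a})")
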