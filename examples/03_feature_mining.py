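"""Mine altered glycan features from a differential IGP table.

Shows the up/down proportion contrast per feature (the up:down ratio),
bisecting + sole-GlcNAc co-occurrence among down-regulated IGPs, and
glycan-shift glycosites carrying both up- and down-regulated structures.
"""

from glycomine import (co_occurrence, detect_site_shifts, feature_summary,
                       has_branch, top_n_glycans)
from glycomine.io import _aggregate
from glycomine.mining import IGP_KEY_COLUMNS, unique_igps
from glycomine.quant import (derive_scaling_factors, differential_table,
                             normalize_channels)
from glycomine import featurize_table
from glycomine.simulate import GeneratorSpec, generate_igp_dataset

ds = generate_igp_dataset(GeneratorSpec(seed=1))
ch = ds.design.channels
rec = featurize_table(ds.igp)
rec[ch] = normalize_channels(rec[ch],
                             derive_scaling_factors(ds.protein[ch]))
diff = differential_table(_aggregate(rec, ch), ds.design)
igps = unique_igps(rec).set_index(IGP_KEY_COLUMNS).join(diff).reset_index()

fs = feature_summary(igps, "sialylation")
print("up/down shares per sialylation class "
      "(ratio > 1: enriched among up-regulated IGPs):")
print(fs[["label", "n_total", "n_up", "n_down",
          "up_down_ratio"]].to_string(index=False))

down = igps["call"] == "down"
frac, num, den = co_occurrence(igps, ("bisecting", True),
                               has_branch("sole GlcNAc"), subset=down)
print(f"\n{num}/{den} down-regulated bisected IGPs also carry a sole "
      f"GlcNAc branch ({100 * frac:.1f}%)")

print("\ntop 5 up-regulated glycans (oligomannose excluded):")
top = top_n_glycans(igps, 5, rank_by="direction", exclude_oligomannose=True)
print(top[top["direction"] == "up"].to_string(index=False))

shifts = detect_site_shifts(igps)
print(f"\n{len(shifts)} glycosites carry both up- and down-regulated "
      "structures (glycan shift):")
s = shifts[0]
core = {k: round(v, 2) for k, v in s.contrasts["core"].items() if v}
print(f"  e.g. {s.protein_id} Asn-{s.glycosite}: core contrast "
      f"(up minus down proportions) {core}")
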