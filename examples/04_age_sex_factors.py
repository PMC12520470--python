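"""Partition differential-IGP variation between age and sex.

For each IGP the other factor is first excluded by mean-centering within
its levels, then a one-way ANOVA on the factor of interest yields a
p-value and the effect size eta^2 = SS_between / SS_total; the IGP is
assigned to the dominant significant factor.
"""

from glycomine import decompose_table, differential_table, featurize_table
from glycomine.io import _aggregate
from glycomine.quant import derive_scaling_factors, normalize_channels
from glycomine.simulate import GeneratorSpec, generate_igp_dataset

ds = generate_igp_dataset(GeneratorSpec(seed=1))
ch = ds.design.channels
rec = featurize_table(ds.igp)
rec[ch] = normalize_channels(rec[ch],
                             derive_scaling_factors(ds.protein[ch]))
agg = _aggregate(rec, ch)
diff = differential_table(agg, ds.design)

differential = agg.loc[diff.index[diff["call"] != "ns"]]
fac = decompose_table(differential, ds.design)
print(f"{len(fac)} differential IGPs decomposed:")
print(fac["assignment"].value_counts().to_string())
print("\nThe planted group contrast is an age contrast, so nearly all "
      "differential IGPs should be (and are) attributed to age; the "
      "3F/2M-per-group design leaves sex-attributable variation near the "
      "false-positive floor.")
one = fac.iloc[0]
print(f"\nexample IGP: p_age={one['p_age']:.2e} eta2_age="
      f"{one['eta2_age']:.2f} vs p_sex={one['p_sex']:.2f} "
      f"eta2_sex={one['eta2_sex']:.2f} -> {one['assignment']}")
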