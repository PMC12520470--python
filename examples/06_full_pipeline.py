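"""Run the whole mining pipeline from files, as the CLI does.

Writes a synthetic dataset to disk, builds a YAML config and calls
run_pipeline; the same flow is available from a shell as

    glycomine simulate --seed 1 --out simdata/
    glycomine run --config config.yaml
"""

import json
import tempfile
from pathlib import Path

from glycomine.io import PipelineConfig, run_pipeline, write_design, \
    write_igp_table
from glycomine.simulate import GeneratorSpec, generate_igp_dataset

workdir = Path(tempfile.mkdtemp(prefix="glycomine_example_"))
ds = generate_igp_dataset(GeneratorSpec(seed=1))
write_igp_table(ds.igp, workdir / "igp_psm.tsv")
ds.protein.reset_index().to_csv(workdir / "protein.tsv", sep="\t",
                                index=False)
ds.phospho.to_csv(workdir / "phospho.tsv", sep="\t", index=False)
write_design(ds.design, workdir / "design.tsv")

config = PipelineConfig(
    igp_table=str(workdir / "igp_psm.tsv"),
    design=str(workdir / "design.tsv"),
    protein_table=str(workdir / "protein.tsv"),
    phospho_table=str(workdir / "phospho.tsv"),
    out_dir=str(workdir / "results"))
manifest = run_pipeline(config)

print(f"results in {workdir / 'results'}:")
for f in sorted((workdir / "results").iterdir()):
    print(" ", f.name)
print("\nstage counts:")
print(json.dumps(manifest["stages"], indent=2, default=str))
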