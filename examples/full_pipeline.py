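"""Run the whole analysis pipeline from files, as the CLI would.

Writes a synthetic survey to disk (observations CSV + marker FASTA),
then runs every stage from one config: community matrices, similarity,
diversity, the two matrix-regression models, H2' specialisation of the
three bipartite networks, the parasitoid x strain projection and the
pairwise sharing summaries.
"""

import json
import tempfile
from pathlib import Path

from symnet import (
    PipelineConfig,
    SyntheticConfig,
    run_pipeline,
    simulate_community,
)

workdir = Path(tempfile.mkdtemp(prefix="symnet_demo_"))
cfg_sim = SyntheticConfig(coupling_parasitoid=0.8, samples_per_species=40, seed=3)
table, truth, seqs = simulate_community(cfg_sim)
table.records.to_csv(workdir / "observations.csv", index=False)
seqs.to_fasta(workdir / "sequences.fasta")

cfg = PipelineConfig(
    observations=str(workdir / "observations.csv"),
    sequences=str(workdir / "sequences.fasta"),
    out_dir=str(workdir / "out"),
    relatedness_mode="one_minus_scaled",
    mmrr_nperm=999,
    h2_n_null=200,
    rarefaction_reps=200,
    seed=42,
)
run_pipeline(cfg)

print(f"\nresult bundle in {cfg.out_dir}:")
for f in sorted(Path(cfg.out_dir).iterdir()):
    print(f"  {f.name}")

res = json.loads((Path(cfg.out_dir) / "mmrr_parasitoid_model.json").read_text())
print(
    f"\nparasitoid model: beta={res['beta'][0]:.3f} (p={res['p_perm'][0]:.4f}) "
    f"for parasitoid similarity,\n                  "
    f"beta={res['beta'][1]:.3f} (p={res['p_perm'][1]:.4f}) for relatedness; "
    f"R2={res['r2']:.3f}"
)
print(
    "The run log (run_log.txt) records every species dropped at each stage; "
    "all\nseeds and the config hash are embedded in the JSON payloads."
)
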