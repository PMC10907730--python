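"""Run the whole analysis end to end on files, as the CLI does.

Writes a simulated AIRR table to disk, runs the pipeline from a RunConfig,
and scores every stage against the planted truth.
"""

import tempfile
from pathlib import Path

import pandas as pd

import ascrep

workdir = Path(tempfile.mkdtemp(prefix="ascrep_example_"))
sim = ascrep.simulate(
    ascrep.SimulationDesign(seed=7, n_sequences_per_population=2000, n_clones=80)
)
paths = sim.write(workdir / "sim")

config = ascrep.RunConfig(
    input_rearrangements=str(paths["rearrangements"]),
    input_germline=str(paths["germline"]),
    outdir=str(workdir / "run"),
)
manifest = ascrep.run_pipeline(config)
print(f"outputs under {config.outdir}:")
for name in sorted(p.name for p in Path(config.outdir).iterdir()):
    print(f"  {name}")
print(f"manifest hash: {manifest['manifest_sha256'][:16]}... "
      "(identical on rerun with the same config)")

annotated, _ = ascrep.read_rearrangements(
    Path(config.outdir) / "rearrangements_annotated.tsv"
)
shm = pd.read_csv(Path(config.outdir) / "shm_sequences.tsv", sep="\t")
report = ascrep.score_recovery(sim, annotated, shm)
print("\nrecovery report:")
for key, value in report.items():
    print(f"  {key}: {value}")
print("clone_ari / precision / recall of 1.0 and a zero sharing-curve error")
print("mean every pipeline stage reproduced the planted design exactly.")
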