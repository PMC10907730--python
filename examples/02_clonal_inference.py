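"""Assign clonal lineages and check recovery against the planted truth.

Lineage rule: same subject, same V gene, same J gene, same junction
length, and >= 85% junction nucleotide identity (single linkage).
"""

from sklearn.metrics import adjusted_rand_score

import ascrep

sim = ascrep.simulate(
    ascrep.SimulationDesign(seed=7, n_sequences_per_population=2000, n_clones=80)
)
annotated, clones = ascrep.assign_clones(sim.rearrangements, threshold=0.85)

print(f"sequences clustered : {len(annotated)}")
print(f"lineages inferred   : {len(clones)}")
print(clones[["clone_id", "v_gene", "j_gene", "junction_length", "n_members",
              "total_size"]].head(5).to_string(index=False))

truth = [sim.truth_clone[s] for s in annotated["sequence_id"]]
ari = adjusted_rand_score(truth, annotated["clone_id"])
print(f"adjusted Rand index vs planted truth: {ari}")
print("ARI = 1.0 means the 85% identity rule recovered every planted clone")
print("exactly; founders were generated too far apart to merge and members")
print("too close to their founder to split.")
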