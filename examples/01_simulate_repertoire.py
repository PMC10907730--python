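"""Generate a synthetic multi-population ASC repertoire with planted truth.

Builds a desk-scale design (4 populations x 2,000 sequences, 80 clones,
5 dominant clones planted everywhere) and prints what was planted.
"""

import ascrep

design = ascrep.SimulationDesign(
    seed=7,
    n_sequences_per_population=2000,
    n_clones=80,
)
sim = ascrep.simulate(design)

df = sim.rearrangements
print(f"sequences generated : {len(df)}")
print(f"populations         : {sorted(df['population'].unique())}")
print(f"clones planted      : {design.n_clones}")
print(f"dominant (expanded) : {design.n_planted_expanded} per population")
print(f"isotype counts      : {df['isotype'].value_counts().to_dict()}")

shared = sum(1 for pops in sim.truth_sharing.values() if len(pops) > 1)
print(f"clones in >1 population: {shared}/{design.n_clones}")

# the planted head of Pop2, as frequencies of the repertoire
sizes = sim.truth_sizes[("S1", "Pop2")]
head = sorted(sizes.items(), key=lambda kv: -kv[1])[:6]
total = sum(sizes.values())
for clone, count in head:
    print(f"  {clone}: {count} reads = {100 * count / total:.2f}%")
print("The top five clones sit well above the tail: each consecutive pair")
print("is separated by ~0.8 percentage points, the planted expansion gaps.")
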