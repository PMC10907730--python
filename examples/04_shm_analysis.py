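"""Quantify V-region somatic hypermutation and intraclonal divergence.

SHM is the percent of compared V positions differing from germline
(gap and N positions excluded; the junction never enters the denominator).
"""

import ascrep

sim = ascrep.simulate(
    ascrep.SimulationDesign(seed=7, n_sequences_per_population=2000, n_clones=80)
)
annotated, _ = ascrep.assign_clones(sim.rearrangements)

shm, qc = ascrep.v_mutation_frequency(annotated)
print(f"sequences scored: {qc['n_scored']} (skipped: {qc['n_skipped']})")
print(f"mean SHM: {shm['shm_pct'].mean():.2f}%  "
      f"(design planted a truncated Normal around {sim.design.shm_mean}%)")

summary = ascrep.shm_summary(shm)
print("\nper population x isotype:")
print(summary.round(3).to_string(index=False))
print("frac_below is the fraction of sequences under 5% SHM — the lightly")
print("mutated tail consistent with recent extrafollicular activation.")

div = ascrep.intraclonal_divergence(annotated, shm)
big = div[div["n_members"] >= 10]
print(f"\nclones with >= 10 members: {len(big)}")
print(f"mean pairwise junction distance among them: "
      f"{big['mean_pairwise_distance'].mean():.2f} nt")
print("Low divergence plus no mutation-distance gradient (rho ~ NaN/0) is")
print("the signature of star-like clones without sequential maturation.")
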