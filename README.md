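# ascrep

Clonal repertoire analysis of circulating antibody-secreting-cell (ASC)
populations from heavy-chain AIRR-seq data.

In systemic lupus erythematosus and other settings with large ASC
expansions, a central question is whether phenotypically distinct ASC
subsets — immature CD19⁺CD138⁻ plasmablasts (Pop 2) through mature
CD19⁻CD138⁺ plasma cells (Pop 5) — arise from shared B-cell precursors.
The repertoire-level evidence is clonal: if the same lineages appear
across maturation stages, the stages share an origin. `ascrep` implements
that analysis as a tested, reusable library:

- **Clonal lineage inference.** Sequences belong to one lineage when they
  come from the same subject, use the same V and J gene, have the same
  CDR3/junction length, and show ≥ 85% junction nucleotide identity.
  Within each (subject, V, J, length) partition, lineages are the
  connected components of the pairwise-identity graph (single linkage).
- **Clonal expansion detection.** Clones are size-ranked by descending
  frequency *f₁ ≥ f₂ ≥ …*; the expanded set is the prefix 1..k where k is
  the last rank with *fₖ − fₖ₊₁ ≥ 0.1* percentage points.
- **Cross-population overlap.** The Morisita-Horn index
  *C = 2 Σxᵢyᵢ·XY / (Σxᵢ²·Y² + Σyᵢ²·X²)* between clone-abundance vectors
  (0 = no shared clones, 1 = identical repertoire), top-N clone-sharing
  curves, global connectivity (percent of one population's clones found in
  another), and circos-ready edge lists.
- **Somatic hypermutation (SHM).** Percent of compared V-region positions
  differing from germline (gaps and N excluded; the junction never counts),
  summarized per population × isotype, plus an intraclonal-divergence
  statistic that distinguishes star-like clones from ladders of sequential
  mutation.
- **Synthetic repertoires with planted truth.** A generator that emulates
  the sequencing design (4 populations/subject, ~50,000 reads/sample,
  heavy-tailed clone sizes with a dominant minority, designed
  cross-population sharing, SHM around 6–8% with a sub-5% tail, IgM/IgG/IgA
  isotypes) and returns the ground truth needed to score every stage.

## Worked example

```python
import ascrep

sim = ascrep.simulate(ascrep.SimulationDesign(
    seed=7, n_sequences_per_population=2000, n_clones=80))
annotated, clones = ascrep.assign_clones(sim.rearrangements, threshold=0.85)

ranked = ascrep.rank_repertoire(annotated, "S1", "Pop5")
ascrep.detect_expanded(ranked, delta=0.1)
mat, results = ascrep.overlap_matrix(annotated, "S1")
res = results[("Pop5", "Pop2")]
print(len(clones), int(ranked.expanded_flags.sum()))
print(round(mat.loc["Pop5", "Pop2"], 3), res.sharing_curve[25],
      res.expanded_connectivity_pct)
```

prints

```
80 5
0.783 72.0 100.0
```

meaning: the 85% rule recovered all 80 planted lineages (adjusted Rand
index 1.0 against the simulation truth); exactly the 5 planted dominant
clones were flagged as expanded in Pop 5; the Pop 5/Pop 2 repertoires have
Morisita-Horn overlap 0.783; 72% of Pop 5's top-25 clones also appear in
Pop 2; and every expanded Pop 5 clone is detected in Pop 2 — the pattern
expected when maturation stages descend from common precursors.

The scripts in `examples/` walk through each capability
(`01_simulate_repertoire.py` … `05_full_pipeline.py`); each prints the
numbers it computes and one line on what they mean. A thin CLI mirrors the
library (`ascrep simulate | assign-clones | metrics | shm | report`).

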