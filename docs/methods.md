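# Methods

## Scope and data model

`ascrep` analyzes heavy-chain AIRR rearrangement tables: one row per
sequenced VDJ with a sequence identifier, subject, sorted-population
label, V/J calls, junction nucleotides, a read-duplicate count, a
constant-region call, and optionally a pre-aligned (observed, germline)
V-region pair. Tables are held as pandas DataFrames with AIRR-standard
column names; validation normalizes gene calls to gene level (allele
suffix stripped at `*`, first gene of a comma-separated ambiguous call),
derives `junction_length` and the isotype (`IGHM→IgM`, `IGHG*→IgG`,
`IGHA*→IgA`, otherwise `unknown`), fills `duplicate_count = 1` when
absent, and drops rows that cannot satisfy the record invariants,
counting every drop reason. Validation is row-order independent.

Upstream steps — base calling, primer handling, V(D)J alignment — are out
of scope; the package starts from aligned rearrangements.

## Clonal lineage inference

Membership in a clonal lineage requires, within one subject: identical V
gene, identical J gene, identical junction length, and junction
nucleotide identity at or above a threshold (default 0.85). Identity is
the fraction of matching positions; `N` matches nothing, including
another `N` — an ambiguous base is evidence of nothing, and counting it
as a match could join unrelated clones.

Within each (subject, V, J, length) partition, lineages are the connected
components of the graph whose edges join pairs at or above the threshold
(single linkage). A pairwise homology criterion without a centroid model
is naturally transitive-closed: A~B and B~C imply one lineage even when
A–C identity falls below threshold. The threshold is inclusive (17/20 =
85% joins) and applied as an integer minimum-match count,
`ceil(threshold·L − 1e-9)`, so boundary cases never depend on float
rounding. Junctions are deduplicated before the pairwise computation, and
match counts are evaluated in row blocks on a byte matrix, keeping memory
bounded on large partitions.

Clone identifiers are `<subject>|<lexicographically smallest member
sequence_id>`, which makes labels deterministic, order-invariant and
stable across reruns. Clones never span subjects: repertoires are
analyzed within patients, and identical junctions in different subjects
are independent recombination events (public clones are out of scope).

The junction (CDR3 plus its conserved flanks) stands in for the CDR3
wherever homology is computed: AIRR tables carry the junction, and with
length matching enforced the two give the same partition up to the two
flank codons, which are nearly invariant. Homology is computed on
nucleotides; the threshold parameter is exposed for users who prefer a
different stringency.

## Rank-abundance and the expansion gap rule

Per (subject, population), clone frequencies are weighted sizes (sum of
`duplicate_count`; a `unique_sequences` mode counts rows) over the
population total, ranked descending with ties broken by clone id. A
clone is *expanded* when it lies in the prefix 1..k, where k is the
largest rank whose frequency exceeds the next-ranked clone's by at least
δ = 0.1 percentage points. Reading the rule as "prefix up to the last
qualifying gap" matches its use as a rank-size inflection detector: the
expanded head ends where the curve flattens for good. Two boundary
choices are explicit: the gap past the final clone never counts (a
repertoire with no internal gap has no expanded clones), and
zero-frequency clones are ignored, so padding a repertoire with absent
clones cannot create a qualifying gap. The alternative reading of the
rule (gap to the next-*larger* neighbor) differs only in indexing; δ is
a parameter everywhere.

## Overlap, sharing and connectivity

Populations are never re-clustered separately — clones are identified
jointly per subject, so a shared `clone_id` means a shared lineage.

* **Morisita-Horn** on weighted clone sizes,
  `C = 2Σxy·XY / (Σx²·Y² + Σy²·X²)`. The squared-proportion form is used
  because duplicate-weighted sizes need not be integers and the index
  must be bounded in [0, 1]; the classical integer-count variant (with
  unbiased Simpson terms `Σx(x−1)/X(X−1)`) is available by flag. The
  expression is grouped so that self-overlap is exactly 1.0 and the index
  is bitwise symmetric in its arguments; disjoint clone sets give exactly
  0.
* **Sharing curves**: for each N, the percent of the reference
  population's top-N clones (N capped at the clone count, capped value as
  denominator) with nonzero size in the target.
* **Global connectivity**: percent of reference clones present in the
  target, optionally restricted to the expanded prefix; an empty expanded
  set yields NA, never 0, because "none of zero clones" is not evidence
  of disconnection.
* **Edge lists** (clone, size in each population) are exported for
  circos-style visualization; no plotting is bundled.

## Somatic hypermutation

SHM per sequence is `100 · mutations / compared positions` over the
V region only — junction diversity is clone-defining, not mutation.
Positions where either string has a gap (`.`/`-`) or an `N` are excluded
from numerator and denominator. When a record carries no aligned pair but
a germline FASTA is supplied, the comparison runs over the leading
`min(length)` positions of the ungapped sequences and the output is
flagged `approximate`; records with no germline route are skipped and
counted. Summaries (mean, median, fraction below 5%) are per
population × isotype and weighted by sequence, not duplicate count — SHM
is a property of a cell's V region, not of its sequencing depth.

Intraclonal divergence per clone reports the mean pairwise junction
Hamming distance (computed per position from character counts, O(mL)),
the number of distinct V-mutation counts, and a Spearman correlation
between each member's mutation count and its junction distance to the
clone's least-mutated member. A ladder of sequential mutation drives
this correlation positive; a star of independent variants around one
founder, or a clone of identical members, does not (NaN when members are
too few or distances are uniform). The statistic is an operationalization
of "sequential progression of somatic mutation" chosen for this package;
distance to the least-mutated member is used rather than mean distance to
all members because the latter is U-shaped along a ladder and carries no
rank signal.

## Synthetic repertoires with planted truth

The generator emulates the sequencing design the pipeline targets —
four sorted ASC populations per subject at a default depth of 50,000
sequences each (the tests and acceptance script run 1,200–5,000 per
population to keep runtimes in seconds, which changes nothing
qualitative), a few hundred clones with a dominant minority, designed
cross-population sharing, SHM near 7% (sd 2%) truncated at zero giving a
natural sub-5% tail, and switched-isotype majorities (IgG 0.55, IgA 0.30,
IgM 0.15, constant within a clone). What it does *not* model: VDJ
recombination biology (no codon structure, junctions are uniform random
nucleotides), sequencing error beyond point mutation, primer or depth
biases, and inter-subject sharing. Passing recovery tests therefore
demonstrates correctness of the inference rules under the stated
separation conditions, not robustness to the full messiness of real
repertoires; the boundary-design test documents how recovery degrades
when intra-clone divergence straddles the threshold.

Three construction choices make the planted truth exact rather than
approximate:

* **Unambiguous clusters.** Founders within one (V, J, length) partition
  are rejection-sampled to pairwise identity < 0.70, and member junctions
  are capped at 5% divergence from their founder. Any two members of one
  clone then share ≥ 90% identity (always joined at 0.85) and members of
  different clones at most 0.80 (never joined), so the planted partition
  is the unique single-linkage solution and clone-recovery ARI = 1.0 is a
  theorem about the design, not a lucky draw.
* **Exact counts.** Per-population clone sizes are constructed, not
  sampled: weights from the clone-size law (power law α = 1.5 by default,
  geometric or explicit available) are converted to integers by
  largest-remainder allocation, so realized frequencies equal planted
  frequencies exactly and frequency assertions are exact.
* **Gap-controlled head and tail.** The expanded head is planted as
  explicit counts descending in steps of ≥ 0.8 percentage points above
  the tail maximum, while consecutive sorted tail counts are capped
  strictly below the 0.1-point delta (cap-and-redistribute, preserving
  totals and the cap). The gap rule then flags exactly the planted head.
  This requires the depth to resolve the delta — a one-read difference
  must be worth less than 0.1 points, i.e. more than 1,000 reads per
  population at the default delta — and shallower designs are rejected as
  infeasible rather than silently mis-planted. The head/tail split is
  solved by a short fixed-point loop (head heights depend on the realized
  tail maximum); a non-converging residual is patched into the tail
  without touching its maximum.

Sharing is realized by seeding the same founder into several populations:
dominant clones into all populations, tail clones into their home
population plus each other population with the design's sharing
probability (0.4 by default — a deliberately high connectivity regime).
`score_recovery` maps assigned clones to truth labels (unanimous-member
mapping), then scores clone ARI, expansion precision/recall,
sharing-curve error against the planted seeding, exact size consistency,
and SHM bias. All randomness flows from one `numpy` Generator seeded by
the mandatory design seed; outputs are byte-identical per seed.

## Pipeline and numerical conventions

`run_pipeline` chains validation → clonal assignment → rank/expansion →
overlap/connectivity → SHM/divergence/isotype and writes TSV/CSV exports
plus a manifest with a config hash and a content hash; no timestamps are
recorded, so reruns are byte-identical and the manifest hash certifies
it. Any stage failure aborts with the stage name. The CLI subcommands
(`simulate`, `assign-clones`, `metrics`, `shm`, `report`) are thin
wrappers over the same functions and inherit their determinism.

Degenerate inputs have defined behavior throughout: empty files,
missing mandatory columns and cross-subject comparisons are hard errors;
empty (subject, population) selections name the offending pair; ratio
denominators of zero give NA; the empty expanded set gives NA
connectivity. Floating-point guards: identity thresholds via integer
match counts; the expansion delta compared with 1e-12 slack; Morisita
grouped for exact boundary values and clamped to [0, 1].

## Known limitations

* Homology clustering is nucleotide-only; amino-acid homology would need
  a translation layer.
* The ungapped-germline SHM fallback assumes the observed V starts at
  germline position 1; indel-containing sequences should use aligned
  pairs.
* Single-linkage can chain distinct clones through intermediates in very
  dense partitions; the brute-force equivalence tests confirm the
  implementation, not the biological model.
* The intraclonal-divergence rank statistic needs ≥ 3 scored members and
  non-uniform distances; small clones report NA.
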