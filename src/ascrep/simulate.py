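"""Synthetic multi-population AIRR repertoires with planted ground truth.

The generator emulates the data shape of heavy-chain repertoire sequencing
of sorted antibody-secreting-cell populations: several populations per
subject, a heavy-tailed clone-size distribution with a handful of dominant
clones, a designed fraction of clones shared across populations, per-
sequence V-region point mutation (SHM) around a 6-8% mean, and IgM/IgG/IgA
isotype labels.  Every stage of the analysis pipeline can be scored
against the planted truth it returns.

Design guarantees (what makes the truth unambiguous):

* clone founders within one (V, J, junction-length) partition are rejection
  sampled to pairwise junction identity < 0.70, and member junctions stay
  within a capped divergence of their founder, so the 85% single-linkage
  rule recovers the planted partition exactly;
* per-population clone counts are constructed, not sampled: an explicit
  descending head of ``n_planted_expanded`` clones separated by controlled
  frequency gaps sits on a tail whose consecutive sorted-count differences
  are capped strictly below the expansion delta, so the 0.1-point gap rule
  flags exactly the planted head;
* counts hit the requested total exactly (largest-remainder allocation),
  so frequency assertions are exact rather than approximate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_V_POOL = (
    "IGHV1-2", "IGHV1-69", "IGHV3-23", "IGHV3-30",
    "IGHV4-34", "IGHV4-59", "IGHV5-51", "IGHV6-1",
)
DEFAULT_J_POOL = ("IGHJ1", "IGHJ2", "IGHJ3", "IGHJ4", "IGHJ5", "IGHJ6")

_C_CALL = {"IgM": "IGHM", "IgG": "IGHG1", "IgA": "IGHA1"}


@dataclass
class SimulationDesign:
    """Parameters of a planted-truth repertoire simulation.

    Defaults mirror the sequencing design the pipeline targets: four ASC
    populations per subject at ~50,000 sequences each, a few hundred
    clones with a dominant minority, SHM around 7% with a sub-5% tail,
    and isotype-switched majorities.
    """

    seed: int
    n_subjects: int = 1
    populations: tuple[str, ...] = aio.POPULATIONS
    n_sequences_per_population: int = 50_000
    n_clones: int = 500
    clone_size_law: str = "power_law"      # power_law | geometric | explicit
    clone_size_param: float = 1.5          # alpha for power_law, p for geometric
    explicit_tail_weights: tuple[float, ...] | None = None
    sharing_prob: float = 0.4              # scalar default for the sharing matrix
    sharing_matrix: dict | None = None     # {(pop_a, pop_b): prob}, overrides scalar
    n_planted_expanded: int = 5
    expansion_delta: float = 0.1           # percentage points (the detection rule)
    head_gap_pts: float = 0.8              # planted gap between consecutive head clones
    intra_clone_mut_rate: float = 0.02     # per-position junction mutation probability
    max_intra_divergence: float = 0.05     # hard cap on member-founder junction divergence
    max_founder_identity: float = 0.70     # rejection bound within a partition
    shm_mean: float = 7.0                  # percent of V positions mutated
    shm_sd: float = 2.0
    isotype_probs: dict = field(
        default_factory=lambda: {"IgM": 0.15, "IgG": 0.55, "IgA": 0.30}
    )
    v_gene_pool: tuple[str, ...] = DEFAULT_V_POOL
    j_gene_pool: tuple[str, ...] = DEFAULT_J_POOL
    junction_length_range: tuple[int, int] = (36, 60)  # nt, in-frame steps of 3
    v_region_length: int = 270

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if not 0 <= self.sharing_prob <= 1:
            raise ValueError("sharing_prob must be in [0, 1]")
        if self.n_planted_expanded > self.n_clones:
            raise ValueError("n_planted_expanded cannot exceed n_clones")
        if self.n_planted_expanded >= self.n_clones / 2:
            raise ValueError("the planted head must be a minority of clones")
        probs = self.isotype_probs
        if abs(sum(probs.values()) - 1) > 1e-9 or any(p < 0 for p in probs.values()):
            raise ValueError("isotype_probs must be a probability distribution")
        lo, hi = self.junction_length_range
        if lo < 9 or hi < lo:
            raise ValueError("junction_length_range invalid")
        # the gap rule counts in units of 100/depth percentage points: a
        # single-read difference between tail clones must stay below the
        # expansion delta, or planted truth cannot be gap-free
        if self._tail_diff_cap() < 1:
            raise ValueError(
                "infeasible design: at depth "
                f"{self.n_sequences_per_population} a one-read clone-size "
                f"difference already exceeds expansion_delta={self.expansion_delta}; "
                "increase the depth or the delta"
            )
        # crude feasibility bound: founders must fit in junction space
        n_partitions = len(self.v_gene_pool) * len(self.j_gene_pool)
        if self.n_clones > n_partitions * 4 ** min(8, lo):
            raise ValueError("n_clones too large for the junction space")

    def _tail_diff_cap(self) -> int:
        """Largest clone-count difference strictly below the expansion delta."""
        return (
            math.ceil(
                self.expansion_delta * self.n_sequences_per_population / 100.0 - 1e-9
            )
            - 1
        )

    def sharing(self, a: str, b: str) -> float:
        if self.sharing_matrix is not None:
            return self.sharing_matrix.get((a, b), self.sharing_matrix.get((b, a), 0.0))
        return self.sharing_prob


@dataclass
class SimulatedRepertoire:
    """A generated AIRR table plus the planted truth for scoring."""

    design: SimulationDesign
    rearrangements: pd.DataFrame
    germline: dict[str, str]
    truth_clone: dict[str, str]                 # sequence_id -> true clone label
    truth_sharing: dict[str, tuple[str, ...]]   # clone -> populations seeded
    truth_expanded: dict[tuple[str, str], tuple[str, ...]]  # (subject, pop) -> head clones
    truth_shm: dict[str, int]                   # sequence_id -> planted V mutations
    truth_sizes: dict[tuple[str, str], dict[str, int]]  # (subject, pop) -> clone -> count

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the AIRR TSV, germline FASTA and truth JSON; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "rearrangements": outdir / "rearrangements.tsv",
            "germline": outdir / "germline_v.fasta",
            "truth": outdir / "truth.json",
        }
        aio.write_rearrangements(self.rearrangements, paths["rearrangements"])
        aio.write_germline_fasta(self.germline, paths["germline"])
        truth = {
            "truth_clone": self.truth_clone,
            "truth_sharing": {k: list(v) for k, v in self.truth_sharing.items()},
            "truth_expanded": {
                f"{s}/{p}": list(v) for (s, p), v in self.truth_expanded.items()
            },
            "truth_shm": self.truth_shm,
            "truth_sizes": {
                f"{s}/{p}": v for (s, p), v in self.truth_sizes.items()
            },
        }
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
        return paths


def _random_junction(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


def _identity(a: str, b: str) -> float:
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    return float((x == y).mean())


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights`` (exact sum)."""
    shares = weights / weights.sum() * total
    base = np.floor(shares).astype(int)
    rem = total - int(base.sum())
    if rem > 0:
        order = np.argsort(-(shares - base), kind="stable")
        base[order[:rem]] += 1
    return base


def _tail_counts(
    rng: np.random.Generator,
    design: SimulationDesign,
    m: int,
    total: int,
    d_cap: int,
) -> np.ndarray:
    """Descending tail counts summing to ``total``: min 1, consecutive
    sorted differences <= ``d_cap`` (strictly below the expansion delta)."""
    if total < m:
        raise ValueError(
            f"infeasible design: {total} sequences cannot seed {m} tail clones"
        )
    if design.clone_size_law == "power_law":
        w = (np.arange(1, m + 1, dtype=float)) ** (-design.clone_size_param)
        w = rng.permuted(w)  # weight-to-clone pairing is random
    elif design.clone_size_law == "geometric":
        w = rng.geometric(design.clone_size_param, size=m).astype(float)
    elif design.clone_size_law == "explicit":
        if design.explicit_tail_weights is None or len(design.explicit_tail_weights) != m:
            raise ValueError("explicit law requires explicit_tail_weights of tail size")
        w = np.asarray(design.explicit_tail_weights, dtype=float)
    else:
        raise ValueError(f"unknown clone_size_law {design.clone_size_law!r}")
    counts = _largest_remainder(w, total)
    counts = np.sort(counts)[::-1]
    # floor at 1, then re-balance from the largest entries
    deficit = int((counts < 1).sum() - (counts[counts < 1]).sum())
    counts = np.maximum(counts, 1)
    i = 0
    while deficit > 0:
        if counts[i % m] > 1:
            counts[i % m] -= 1
            deficit -= 1
        i += 1
    counts = np.sort(counts)[::-1]
    # cap consecutive differences, bottom-up
    for i in range(m - 2, -1, -1):
        counts[i] = min(counts[i], counts[i + 1] + d_cap)
    short = total - int(counts.sum())
    q, r = divmod(short, m)
    counts += q
    if r:
        counts[m - r:] += 1  # adding to a sorted suffix can only shrink gaps
    counts = np.sort(counts)[::-1]
    return counts


def _population_counts(
    rng: np.random.Generator,
    design: SimulationDesign,
    n_total: int,
    n_head: int,
    n_tail: int,
) -> tuple[np.ndarray, np.ndarray]:
    """(head counts, tail counts) for one population, summing to ``n_total``.

    Head counts descend in steps of at least the planted gap; the smallest
    head clone sits one planted gap above the largest tail clone.  Solved by
    a short fixed-point loop because the head heights depend on the realized
    tail maximum.
    """
    d_cap = design._tail_diff_cap()
    g = max(d_cap + 1, math.ceil(design.head_gap_pts * n_total / 100.0))
    if n_head == 0:
        return np.array([], dtype=int), _tail_counts(rng, design, n_tail, n_total, d_cap)
    # draw the tail shape once; the loop only rescales totals
    state = rng.bit_generator.state
    head_total_guess = n_head * g * (n_head + 3) // 2
    tail = head = None
    for _ in range(60):
        tail_total = n_total - head_total_guess
        if tail_total < n_tail:
            raise ValueError(
                "infeasible design: planted head leaves too few sequences for the tail"
            )
        rng.bit_generator.state = state
        tail = _tail_counts(rng, design, n_tail, tail_total, d_cap)
        head = tail[0] + g * np.arange(n_head, 0, -1)
        head_total = int(head.sum())
        if head_total == head_total_guess:
            return head, tail
        head_total_guess = head_total
    # the fixed point can cycle by a few counts; patch the residual into the
    # tail without touching its maximum (so the head stays aligned)
    residual = n_total - int(head.sum()) - int(tail.sum())
    if residual < 0:
        # remove from the largest entries: sorted-multiset diffs cannot grow
        for _ in range(-residual):
            if tail[0] <= 1:
                raise ValueError("infeasible design: head/tail allocation failed")
            tail[0] -= 1
            tail = np.sort(tail)[::-1]
    elif residual > 0:
        below = np.nonzero(tail < tail[0])[0]
        if len(below) < residual:
            raise ValueError("infeasible design: head/tail allocation failed")
        tail[below[-residual:]] += 1  # smallest entries, never creating a new max
        tail = np.sort(tail)[::-1]
    return head, tail


def _mutate(
    rng: np.random.Generator, seq: np.ndarray, n_mut: int
) -> np.ndarray:
    """Mutate ``n_mut`` distinct positions of a uint8 sequence to a different base."""
    if n_mut == 0:
        return seq
    out = seq.copy()
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    shift = rng.integers(1, 4, size=n_mut)
    idx = np.searchsorted(_BASES, out[pos])
    out[pos] = _BASES[(idx + shift) % 4]
    return out


def simulate(design: SimulationDesign) -> SimulatedRepertoire:
    """Generate a repertoire under ``design``; byte-identical per seed."""
    rng = np.random.default_rng(design.seed)
    pops = list(design.populations)
    subjects = [f"S{i + 1}" for i in range(design.n_subjects)]

    germline = {
        v: bytes(_BASES[rng.integers(0, 4, size=design.v_region_length)]).decode()
        for v in design.v_gene_pool
    }

    rows: list[dict] = []
    truth_clone: dict[str, str] = {}
    truth_sharing: dict[str, tuple[str, ...]] = {}
    truth_expanded: dict[tuple[str, str], tuple[str, ...]] = {}
    truth_shm: dict[str, int] = {}
    truth_sizes: dict[tuple[str, str], dict[str, int]] = {}

    for subject in subjects:
        # --- founders ---------------------------------------------------
        founders: dict[str, dict] = {}
        by_partition: dict[tuple, list[str]] = {}
        for c in range(design.n_clones):
            clone = f"{subject}:C{c:04d}"
            v = design.v_gene_pool[rng.integers(len(design.v_gene_pool))]
            j = design.j_gene_pool[rng.integers(len(design.j_gene_pool))]
            lo, hi = design.junction_length_range
            length = int(rng.choice(np.arange(lo, hi + 1, 3)))
            key = (v, j, length)
            for attempt in range(200):
                junc = _random_junction(rng, length)
                if all(
                    _identity(junc, founders[o]["junction"]) < design.max_founder_identity
                    for o in by_partition.get(key, [])
                ):
                    break
            else:
                raise ValueError(
                    "infeasible design: could not place distinct founders "
                    f"in partition {key}"
                )
            isotype = rng.choice(
                list(design.isotype_probs), p=list(design.isotype_probs.values())
            )
            founders[clone] = {"v": v, "j": j, "junction": junc, "isotype": str(isotype)}
            by_partition.setdefault(key, []).append(clone)

        clone_names = sorted(founders)
        head_clones = clone_names[: design.n_planted_expanded]
        tail_clones = clone_names[design.n_planted_expanded:]

        # --- sharing design ---------------------------------------------
        seeded: dict[str, list[str]] = {}
        for clone in head_clones:
            seeded[clone] = list(pops)  # dominant clones appear everywhere
        for clone in tail_clones:
            home = pops[rng.integers(len(pops))]
            where = [home]
            for other in pops:
                if other != home and rng.random() < design.sharing(home, other):
                    where.append(other)
            seeded[clone] = sorted(where, key=pops.index)
        truth_sharing.update({c: tuple(sorted(v)) for c, v in seeded.items()})

        # --- per-population counts and sequences ------------------------
        v_len = design.v_region_length
        for pop in pops:
            pop_tail = [c for c in tail_clones if pop in seeded[c]]
            if not pop_tail:
                raise ValueError(f"infeasible design: no tail clones seeded in {pop}")
            head, tail = _population_counts(
                rng, design, design.n_sequences_per_population,
                len(head_clones), len(pop_tail),
            )
            counts: dict[str, int] = {}
            for clone, c in zip(head_clones, head.tolist()):
                counts[clone] = c
            order = rng.permutation(len(pop_tail))
            for rank, ci in enumerate(order):
                counts[pop_tail[ci]] = int(tail[rank])
            truth_sizes[(subject, pop)] = dict(sorted(counts.items()))
            truth_expanded[(subject, pop)] = tuple(head_clones)

            idx = 0
            for clone in sorted(counts):
                f = founders[clone]
                jl = len(f["junction"])
                founder_arr = np.frombuffer(f["junction"].encode(), dtype=np.uint8)
                germ = germline[f["v"]]
                germ_arr = np.frombuffer(germ.encode(), dtype=np.uint8)
                cap = int(design.max_intra_divergence * jl)
                for _ in range(counts[clone]):
                    sid = f"{subject}_{pop}_{idx:06d}"
                    idx += 1
                    n_mut = min(
                        int(rng.binomial(jl, design.intra_clone_mut_rate)), cap
                    )
                    junc = bytes(_mutate(rng, founder_arr, n_mut)).decode()
                    # truncated-normal SHM percent, realized as integer mutations
                    shm = -1.0
                    while shm < 0:
                        shm = rng.normal(design.shm_mean, design.shm_sd)
                    n_v_mut = min(int(round(shm / 100.0 * v_len)), v_len)
                    v_obs = bytes(_mutate(rng, germ_arr, n_v_mut)).decode()
                    rows.append(
                        {
                            "sequence_id": sid,
                            "subject_id": subject,
                            "population": pop,
                            "v_call": f["v"],
                            "j_call": f["j"],
                            "junction": junc,
                            "junction_length": jl,
                            "duplicate_count": 1,
                            "c_call": _C_CALL[f["isotype"]],
                            "isotype": f["isotype"],
                            "v_sequence_alignment": v_obs,
                            "v_germline_alignment": germ,
                        }
                    )
                    truth_clone[sid] = clone
                    truth_shm[sid] = n_v_mut

    table = pd.DataFrame(rows, columns=aio.CANONICAL_COLUMNS)
    return SimulatedRepertoire(
        design=design,
        rearrangements=table,
        germline=germline,
        truth_clone=truth_clone,
        truth_sharing=truth_sharing,
        truth_expanded=truth_expanded,
        truth_shm=truth_shm,
        truth_sizes=truth_sizes,
    )


def score_recovery(
    sim: SimulatedRepertoire,
    annotated: pd.DataFrame,
    shm: pd.DataFrame | None = None,
    delta: float | None = None,
    Ns: tuple[int, ...] = (5, 10, 25, 50, 100),
) -> dict:
    """Score pipeline outputs against the planted truth.

    Returns a report with:

    * ``clone_ari`` — adjusted Rand index between the true clone labels and
      the assigned ``clone_id`` partition over all sequences;
    * ``expanded_precision`` / ``expanded_recall`` — micro-averaged over
      (subject, population) for the gap-rule expanded set versus the
      planted head (an assigned clone counts as a truth clone when all its
      members carry one true label);
    * ``sharing_curve_error`` — maximum absolute difference, over ordered
      population pairs and top-N cutoffs, between the pipeline sharing
      percentage and the same quantity computed from the planted seeding;
    * ``shm_bias`` — estimated minus planted mean V-mutation percent (and
      ``shm_design_bias`` against the design's nominal mean);
    * ``size_consistency`` — True when realized per-population clone sizes
      match the planted counts exactly under the truth-label mapping.
    """
    from sklearn.metrics import adjusted_rand_score

    from .metrics import (
        DEFAULT_EXPANSION_DELTA,
        detect_expanded,
        rank_from_sizes,
        sharing_curve,
    )

    truth = sim.truth_clone
    ids = annotated["sequence_id"]
    missing = set(truth) ^ set(ids)
    if missing:
        raise ValueError(f"sequence_ids do not match the simulation ({len(missing)} mismatches)")
    y_true = [truth[s] for s in ids]
    y_pred = annotated["clone_id"].tolist()
    ari = float(adjusted_rand_score(y_true, y_pred))

    # map assigned clones to truth labels where members are unanimous
    pair = pd.DataFrame({"assigned": y_pred, "truth": y_true})
    label_sets = pair.groupby("assigned")["truth"].agg(set)
    to_truth = {a: next(iter(s)) for a, s in label_sets.items() if len(s) == 1}

    tp = fp = fn = 0
    share_err = 0.0
    sizes_ok = True
    delta = DEFAULT_EXPANSION_DELTA if delta is None else delta
    for (subject, pop), truth_sizes in sim.truth_sizes.items():
        sel = annotated[
            (annotated["subject_id"] == subject) & (annotated["population"] == pop)
        ]
        sizes = sel.groupby("clone_id")["duplicate_count"].sum().to_dict()
        ranked = rank_from_sizes(sizes, subject, pop)
        detect_expanded(ranked, delta)
        pred = {
            to_truth.get(c, f"!{c}") for c in ranked.clone_ids[ranked.expanded_flags]
        }
        planted = set(sim.truth_expanded[(subject, pop)])
        tp += len(pred & planted)
        fp += len(pred - planted)
        fn += len(planted - pred)
        mapped = {to_truth.get(c, f"!{c}"): s for c, s in sizes.items()}
        if mapped != truth_sizes:
            sizes_ok = False
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")

    # sharing curves: pipeline vs planted seeding, same subject, all ordered pairs
    for subject in annotated["subject_id"].unique():
        pops = sorted(annotated.loc[annotated["subject_id"] == subject, "population"].unique())
        ranked_by_pop = {}
        for pop in pops:
            sel = annotated[
                (annotated["subject_id"] == subject) & (annotated["population"] == pop)
            ]
            sizes = sel.groupby("clone_id")["duplicate_count"].sum().to_dict()
            ranked_by_pop[pop] = rank_from_sizes(sizes, subject, pop)
        for ref in pops:
            for tgt in pops:
                if ref == tgt:
                    continue
                curve = sharing_curve(ranked_by_pop[ref], ranked_by_pop[tgt], Ns)
                for N, pct in curve.items():
                    n_eff = min(N, len(ranked_by_pop[ref]))
                    top = ranked_by_pop[ref].clone_ids[:n_eff]
                    shared = sum(
                        1
                        for c in top
                        if tgt in sim.truth_sharing.get(to_truth.get(c, ""), ())
                    )
                    share_err = max(share_err, abs(pct - 100.0 * shared / n_eff))

    report = {
        "clone_ari": ari,
        "expanded_precision": precision,
        "expanded_recall": recall,
        "sharing_curve_error": share_err,
        "size_consistency": sizes_ok,
    }
    if shm is not None and not shm.empty:
        est_mean = float(shm["shm_pct"].mean())
        v_len = sim.design.v_region_length
        planted_mean = 100.0 * float(np.mean(list(sim.truth_shm.values()))) / v_len
        report["shm_estimated_mean"] = est_mean
        report["shm_bias"] = est_mean - planted_mean
        report["shm_design_bias"] = est_mean - sim.design.shm_mean
    return report
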