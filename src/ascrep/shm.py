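"""Somatic hypermutation (SHM) quantification and intraclonal divergence.

SHM load is the percent of compared V-region positions at which an
observed sequence differs from its germline gene.  The junction is never
part of the denominator: junction diversity defines the clone, it is not
mutation.  Positions where either string carries a gap or an ``N`` are
excluded from both numerator and denominator.

Two comparison routes exist per record, in order of preference:

1. a pre-aligned (observed, germline) pair carried on the record
   (``v_sequence_alignment`` / ``v_germline_alignment``), as produced by
   IMGT-style alignment upstream;
2. an ungapped germline looked up by V gene, compared over the leading
   ``min(length)`` positions — an approximation, flagged as such in the
   output, for tables that carry only the observed V.

Intraclonal divergence summarises how far clone members have drifted from
one another: mean pairwise junction Hamming distance plus the number of
distinct V-mutation counts, and a rank correlation between each member's
mutation load and its mean distance to clone-mates (a ladder of sequential
mutation gives a positive correlation; a star around one founder does not).
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

_GAP_CHARS = frozenset(".-")


def _compare_alignment(observed: str, germline: str) -> tuple[int, int]:
    """(mutations, compared positions) over a same-length aligned pair."""
    x = np.frombuffer(observed.upper().encode("ascii"), dtype=np.uint8)
    y = np.frombuffer(germline.upper().encode("ascii"), dtype=np.uint8)
    skip = np.zeros(len(x), dtype=bool)
    for ch in (".", "-", "N"):
        b = ord(ch)
        skip |= (x == b) | (y == b)
    compared = int((~skip).sum())
    mutations = int(((x != y) & ~skip).sum())
    return mutations, compared


def v_mutation_frequency(
    records: pd.DataFrame,
    germline: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-sequence V-region mutation counts and percent SHM.

    Returns a table (sequence_id, subject_id, population, isotype, clone_id
    if present, mutation_count, aligned_length, shm_pct, approximate) and a
    QC dict counting records skipped for want of any germline comparison.
    ``approximate`` marks rows scored by the ungapped-germline fallback.
    """
    rows = []
    n_skipped = 0
    has_clone = "clone_id" in records.columns
    if "v_sequence" in records.columns:
        v_obs_fallback = records["v_sequence"]
    else:
        v_obs_fallback = records["v_sequence_alignment"]
    for i, rec in enumerate(records.itertuples(index=False)):
        obs = rec.v_sequence_alignment
        germ = rec.v_germline_alignment
        approximate = False
        if obs and germ:
            mut, length = _compare_alignment(obs, germ)
        elif germline is not None and rec.v_call in germline:
            obs = v_obs_fallback.iloc[i]
            if not obs:
                n_skipped += 1
                continue
            ref = germline[rec.v_call]
            L = min(len(obs), len(ref))
            mut, length = _compare_alignment(obs[:L], ref[:L])
            approximate = True
        else:
            n_skipped += 1
            continue
        if length == 0:
            n_skipped += 1
            continue
        rows.append(
            {
                "sequence_id": rec.sequence_id,
                "subject_id": rec.subject_id,
                "population": rec.population,
                "isotype": rec.isotype,
                **({"clone_id": rec.clone_id} if has_clone else {}),
                "mutation_count": mut,
                "aligned_length": length,
                "shm_pct": 100.0 * mut / length,
                "approximate": approximate,
            }
        )
    if n_skipped:
        logger.info("v_mutation_frequency: skipped %d records with no germline comparison", n_skipped)
    shm = pd.DataFrame(rows)
    qc = {"n_scored": len(shm), "n_skipped": n_skipped}
    return shm, qc


def shm_summary(
    shm: pd.DataFrame,
    by: tuple[str, ...] = ("population", "isotype"),
    below_pct: float = 5.0,
) -> pd.DataFrame:
    """Mean/median SHM and the fraction of sequences below a cutoff, per group.

    Weighted by sequence (each scored read counts once, regardless of
    duplicate_count).  Groups are emitted in sorted order; the default
    cutoff of 5% captures the unmutated / lightly-mutated tail.
    """
    if shm.empty:
        return pd.DataFrame(
            columns=list(by) + ["n", "mean_shm_pct", "median_shm_pct", "frac_below"]
        )
    grp = shm.groupby(list(by), sort=True)["shm_pct"]
    out = grp.agg(
        n="size", mean_shm_pct="mean", median_shm_pct="median"
    )
    out["frac_below"] = grp.apply(lambda s: float((s < below_pct).mean()))
    return out.reset_index()


def _mean_pairwise_hamming(junctions: list[str]) -> float:
    """Mean pairwise Hamming distance over equal-length strings.

    Computed per position from character counts (O(m*L)), exact: the sum of
    pairwise mismatches at a position is (m^2 - sum_c n_c^2) / 2.
    """
    m = len(junctions)
    if m < 2:
        return 0.0
    mat = np.frombuffer("".join(junctions).encode("ascii"), dtype=np.uint8).reshape(m, -1)
    total = 0.0
    for col in mat.T:
        counts = np.bincount(col)
        total += (m * m - int((counts.astype(np.int64) ** 2).sum())) / 2.0
    return total / (m * (m - 1) / 2.0)


def intraclonal_divergence(
    annotated: pd.DataFrame,
    shm: pd.DataFrame | None = None,
    min_members_for_rho: int = 3,
) -> pd.DataFrame:
    """Per-clone divergence statistics.

    One row per clone: member count, mean pairwise junction Hamming
    distance (members share a junction length by construction), the number
    of distinct V-mutation counts among members (a proxy for distinct
    mutation patterns), and ``mutation_distance_rho`` — the Spearman
    correlation between each member's V-mutation count and its junction
    distance to the clone's least-mutated member (a root proxy).
    Sequential accumulation of mutation (a ladder) drives this correlation
    positive; a star of independent variants around a common founder does
    not.  Singletons are exactly (distance 0, 1 pattern) and clones too
    small or too uniform for a rank correlation report NaN for rho.
    """
    mut_by_seq: Mapping[str, int] = {}
    if shm is not None and not shm.empty:
        mut_by_seq = shm.set_index("sequence_id")["mutation_count"].to_dict()
    rows = []
    for clone_id, sub in annotated.groupby("clone_id", sort=True):
        junctions = sub["junction"].tolist()
        m = len(junctions)
        mpd = _mean_pairwise_hamming(junctions)
        muts = [mut_by_seq[s] for s in sub["sequence_id"] if s in mut_by_seq]
        n_patterns = len(set(muts)) if muts else 1
        rho = float("nan")
        if len(muts) == m and m >= min_members_for_rho and len(set(muts)) > 1:
            mat = np.frombuffer(
                "".join(junctions).encode("ascii"), dtype=np.uint8
            ).reshape(m, -1)
            sids = sub["sequence_id"].tolist()
            root = min(range(m), key=lambda i: (muts[i], sids[i]))
            dists = (mat != mat[root]).sum(axis=1).astype(float)
            if np.ptp(dists) > 0:
                rho = float(spearmanr(muts, dists).statistic)
        rows.append(
            {
                "clone_id": clone_id,
                "n_members": m,
                "mean_pairwise_distance": mpd,
                "n_distinct_mutation_patterns": n_patterns,
                "mutation_distance_rho": rho,
            }
        )
    return pd.DataFrame(rows)


def isotype_fractions(
    records: pd.DataFrame, by: str = "population"
) -> pd.DataFrame:
    """Isotype composition per group with IgG/IgA and IgG/IgM ratios.

    Proportions are over sequences with a known isotype and sum to 1;
    unknowns are reported separately.  A ratio with a zero denominator is
    NA, never infinity.
    """
    rows = []
    for key, sub in records.groupby(by, sort=True):
        counts = sub["isotype"].value_counts()
        known = {iso: int(counts.get(iso, 0)) for iso in ("IgM", "IgG", "IgA")}
        total = sum(known.values())
        row = {by: key, "n_known": total, "n_unknown": int(counts.get("unknown", 0))}
        for iso, c in known.items():
            row[f"prop_{iso}"] = c / total if total else float("nan")
        row["ratio_IgG_IgA"] = (
            known["IgG"] / known["IgA"] if known["IgA"] else float("nan")
        )
        row["ratio_IgG_IgM"] = (
            known["IgG"] / known["IgM"] if known["IgM"] else float("nan")
        )
        rows.append(row)
    return pd.DataFrame(rows)
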