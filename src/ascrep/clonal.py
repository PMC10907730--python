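"""Clonal lineage inference for heavy-chain repertoires.

A clonal lineage groups sequences presumed to descend from one V(D)J
recombination event.  Membership requires, within a subject: the same V
gene, the same J gene, the same junction (CDR3) length, and junction
nucleotide identity at or above a homology threshold (default 85%).
Within each (subject, V, J, length) partition, lineages are the connected
components of the pairwise-identity graph (single linkage), so a chain
A~B~C is one lineage even when A and C fall below the threshold.

Identity is counted over nucleotide positions; an ``N`` never matches
anything, including another ``N`` — ambiguous positions are evidence of
nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

DEFAULT_THRESHOLD = 0.85

_N_BYTE = ord("N")


@dataclass(frozen=True)
class ClonePartitionKey:
    """The fields a lineage can never span."""

    subject_id: str
    v_gene: str
    j_gene: str
    junction_length: int


@dataclass
class CloneLineage:
    """An inferred clonal family within one subject."""

    clone_id: str
    key: ClonePartitionKey
    member_ids: frozenset[str]
    size_by_population: dict[str, int] = field(default_factory=dict)
    exemplar_junction: str = ""

    @property
    def total_size(self) -> int:
        return sum(self.size_by_population.values())


def cdr3_identity(a: str, b: str) -> float:
    """Fraction of matching positions between two equal-length junctions.

    Symmetric; ``N`` vs anything (including ``N``) counts as a mismatch.
    Raises ``ValueError`` on unequal or zero lengths — callers must partition
    by junction length first.
    """
    if len(a) != len(b) or len(a) == 0:
        raise ValueError(
            f"junction identity requires equal nonzero lengths, got {len(a)} and {len(b)}"
        )
    x = np.frombuffer(a.upper().encode("ascii"), dtype=np.uint8)
    y = np.frombuffer(b.upper().encode("ascii"), dtype=np.uint8)
    matches = int(((x == y) & (x != _N_BYTE) & (y != _N_BYTE)).sum())
    return matches / len(a)


def _encode(junctions: Sequence[str]) -> np.ndarray:
    """Stack equal-length junction strings into a (n, L) uint8 matrix."""
    return np.frombuffer(
        "".join(junctions).encode("ascii"), dtype=np.uint8
    ).reshape(len(junctions), -1)


def _identity_components(
    junctions: Sequence[str], threshold: float, chunk: int = 512
) -> np.ndarray:
    """Connected-component label per junction under the identity threshold.

    All-pairs match counts are computed in row chunks on a byte matrix; the
    threshold is applied as an integer minimum-match count so the boundary
    case (e.g. 17/20 at 85%) is included without floating-point surprises.
    """
    n = len(junctions)
    if n == 1:
        return np.zeros(1, dtype=int)
    m = _encode(junctions)
    L = m.shape[1]
    min_matches = int(np.ceil(threshold * L - 1e-9))
    valid = m != _N_BYTE
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = (
            (m[start:stop, None, :] == m[None, :, :])
            & valid[start:stop, None, :]
            & valid[None, :, :]
        ).sum(axis=2)
        r, c = np.nonzero(block >= min_matches)
        rows.append(r + start)
        cols.append(c)
    adj = coo_matrix(
        (np.ones(sum(len(r) for r in rows), dtype=bool),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    _, labels = connected_components(adj, directed=False)
    return labels


def cluster_partition(
    junctions: Sequence[str],
    sequence_ids: Sequence[str],
    threshold: float = DEFAULT_THRESHOLD,
) -> dict[str, str]:
    """Cluster the members of one partition into lineages.

    All inputs must share a V gene, J gene and junction length (enforced
    upstream).  Returns ``sequence_id -> clone label`` where each label is
    the lexicographically smallest member sequence_id of its connected
    component, making labels deterministic and order-invariant.
    """
    if len(junctions) == 0:
        return {}
    if len(junctions) != len(sequence_ids):
        raise ValueError("junctions and sequence_ids must align")
    order = np.argsort(np.asarray(junctions, dtype=object))
    uniq: list[str] = []
    uniq_members: list[list[str]] = []
    for i in order:
        j = junctions[i]
        if uniq and uniq[-1] == j:
            uniq_members[-1].append(sequence_ids[i])
        else:
            uniq.append(j)
            uniq_members.append([sequence_ids[i]])
    labels = _identity_components(uniq, threshold)
    label_min: dict[int, str] = {}
    for lab, members in zip(labels, uniq_members):
        smallest = min(members)
        if lab not in label_min or smallest < label_min[lab]:
            label_min[lab] = smallest
    out: dict[str, str] = {}
    for lab, members in zip(labels, uniq_members):
        for sid in members:
            out[sid] = label_min[lab]
    return out


def assign_clones(
    records: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign every rearrangement to a clonal lineage.

    Parameters
    ----------
    records
        Validated rearrangement table (see :mod:`ascrep.io`).
    threshold
        Minimum junction identity joining a pair (inclusive).

    Returns
    -------
    (annotated, clones)
        ``annotated`` is the input with a ``clone_id`` column
        (``<subject>|<smallest member sequence_id>``).  ``clones`` has one
        row per lineage: partition-key fields, member count, weighted
        per-population sizes (``size_<population>``), total size and an
        exemplar junction.  Lineages never span subjects or partition keys,
        and the result is invariant to input row order.
    """
    if records.empty:
        annotated = records.copy()
        annotated["clone_id"] = pd.Series(dtype=str)
        return annotated, pd.DataFrame(
            columns=["clone_id", "subject_id", "v_gene", "j_gene",
                     "junction_length", "n_members", "total_size",
                     "exemplar_junction"]
        )
    df = records
    clone_ids = pd.Series(index=df.index, dtype=object)
    for (subject, _v, _j, _ln), idx in df.groupby(
        ["subject_id", "v_call", "j_call", "junction_length"], sort=True
    ).groups.items():
        sub = df.loc[idx]
        labels = cluster_partition(
            sub["junction"].tolist(), sub["sequence_id"].tolist(), threshold
        )
        clone_ids.loc[idx] = [
            f"{subject}|{labels[sid]}" for sid in sub["sequence_id"]
        ]
    annotated = df.copy()
    annotated["clone_id"] = clone_ids.astype(str)

    clones = _summarize_clones(annotated)
    return annotated, clones


def _summarize_clones(annotated: pd.DataFrame) -> pd.DataFrame:
    grp = annotated.groupby("clone_id", sort=True)
    base = grp.agg(
        subject_id=("subject_id", "first"),
        v_gene=("v_call", "first"),
        j_gene=("j_call", "first"),
        junction_length=("junction_length", "first"),
        n_members=("sequence_id", "size"),
        total_size=("duplicate_count", "sum"),
    )
    # exemplar: junction of the smallest member sequence_id (the label seed)
    seed = annotated.loc[
        annotated.groupby("clone_id")["sequence_id"].idxmin(),
        ["clone_id", "junction"],
    ].set_index("clone_id")["junction"]
    base["exemplar_junction"] = seed
    sizes = (
        annotated.pivot_table(
            index="clone_id",
            columns="population",
            values="duplicate_count",
            aggfunc="sum",
            fill_value=0,
        )
        .add_prefix("size_")
        .astype(int)
    )
    out = base.join(sizes).reset_index()
    return out


def clone_sizes_by_population(
    annotated: pd.DataFrame, weighting: str = "duplicate_count"
) -> pd.DataFrame:
    """Weighted clone x population size matrix for one or more subjects.

    ``weighting`` is ``duplicate_count`` (sum of read-duplicate counts, the
    default) or ``unique_sequences`` (each row counts once).
    """
    w = (
        annotated["duplicate_count"]
        if weighting == "duplicate_count"
        else pd.Series(1, index=annotated.index)
    )
    tmp = annotated[["subject_id", "population", "clone_id"]].copy()
    tmp["w"] = w.values
    return (
        tmp.pivot_table(
            index=["subject_id", "clone_id"],
            columns="population",
            values="w",
            aggfunc="sum",
            fill_value=0,
        )
        .astype(int)
    )
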