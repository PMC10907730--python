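"""Clonality, expansion, overlap and connectivity statistics.

These are the per-subject repertoire summaries used to compare ASC
populations: descending rank-abundance curves, the 0.1-percentage-point
gap rule for flagging abnormally expanded clones, the Morisita-Horn
overlap index between population pairs, top-N clone-sharing curves, and
global connectivity (the fraction of one population's clones also seen in
another).  Clones are identified jointly per subject — populations are
never re-clustered separately — so a shared ``clone_id`` means a shared
lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .clonal import clone_sizes_by_population

DEFAULT_EXPANSION_DELTA = 0.1  # percentage points between consecutive ranked clones


@dataclass
class RankedRepertoire:
    """Descending clone-frequency vector for one (subject, population)."""

    subject_id: str
    population: str
    clone_ids: np.ndarray          # ranked by descending frequency
    frequencies: np.ndarray        # fractions summing to 1
    cumulative: np.ndarray = field(default=None)  # type: ignore[assignment]
    expanded_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.clone_ids = np.asarray(self.clone_ids, dtype=object)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.cumulative is None:
            self.cumulative = np.cumsum(self.frequencies)
        if self.expanded_flags is None:
            self.expanded_flags = np.zeros(len(self.frequencies), dtype=bool)

    @property
    def frequencies_pct(self) -> np.ndarray:
        return self.frequencies * 100.0

    def __len__(self) -> int:
        return len(self.clone_ids)


@dataclass
class OverlapResult:
    """Directional overlap summary for one ordered population pair."""

    subject_id: str
    reference: str
    target: str
    morisita: float
    shared_clone_ids: frozenset[str]
    sharing_curve: dict[int, float]         # N -> percent of ref top-N in target
    global_connectivity_pct: float          # all reference clones
    expanded_connectivity_pct: float        # expanded reference clones (NaN if none)
    edge_list: pd.DataFrame                 # clone_id, size_ref, size_target


def rank_repertoire(
    annotated: pd.DataFrame,
    subject_id: str,
    population: str,
    weighting: str = "duplicate_count",
) -> RankedRepertoire:
    """Rank a population's clones by descending weighted frequency.

    Frequencies are clone weighted size over total weighted size; ties are
    broken by ``clone_id`` so reruns are identical.  Raises ``ValueError``
    for an empty (subject, population).
    """
    sel = annotated[
        (annotated["subject_id"] == subject_id)
        & (annotated["population"] == population)
    ]
    if sel.empty:
        raise ValueError(f"no sequences for subject {subject_id!r} population {population!r}")
    w = (
        sel.groupby("clone_id")["duplicate_count"].sum()
        if weighting == "duplicate_count"
        else sel.groupby("clone_id")["sequence_id"].size()
    )
    return rank_from_sizes(w.to_dict(), subject_id, population)


def rank_from_sizes(
    sizes: Mapping[str, float], subject_id: str, population: str
) -> RankedRepertoire:
    """Build a :class:`RankedRepertoire` from a clone -> weighted size map."""
    items = [(cid, s) for cid, s in sizes.items() if s > 0]
    if not items:
        raise ValueError(f"no nonzero clone sizes for subject {subject_id!r} population {population!r}")
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    ids = np.array([cid for cid, _ in items], dtype=object)
    counts = np.array([s for _, s in items], dtype=float)
    freqs = counts / counts.sum()
    return RankedRepertoire(subject_id, population, ids, freqs)


def detect_expanded(
    ranked: RankedRepertoire, delta: float = DEFAULT_EXPANSION_DELTA
) -> np.ndarray:
    """Flag abnormally expanded clones by the consecutive-gap rule.

    A clone rank ``i`` qualifies when its frequency exceeds the next-ranked
    clone's by at least ``delta`` percentage points; the expanded set is the
    contiguous prefix up to the LAST qualifying gap.  The gap past the final
    clone (to a nonexistent successor) never counts, so a repertoire with no
    internal gap >= ``delta`` has no expanded clones.  Flags are also set on
    ``ranked`` in place.
    """
    f = ranked.frequencies_pct
    flags = np.zeros(len(f), dtype=bool)
    n_eff = int(np.count_nonzero(f))  # zero-frequency clones are absent clones
    if n_eff >= 2:
        g = f[:n_eff]
        gaps = g[:-1] - g[1:]
        qualifying = np.nonzero(gaps >= delta - 1e-12)[0]
        if qualifying.size:
            flags[: qualifying[-1] + 1] = True
    ranked.expanded_flags = flags
    return flags


def morisita_horn(
    x: Mapping[str, float], y: Mapping[str, float], variant: str = "morisita-horn"
) -> float:
    """Abundance-weighted overlap between two clone-size distributions.

    The Morisita-Horn form (default) uses squared proportions and is exact
    on weighted (non-integer) sizes::

        C = 2 * sum(x_i * y_i) * X * Y / (sum(x_i^2) * Y^2 + sum(y_i^2) * X^2)

    with X, Y the totals.  Returns exactly 1 for identical distributions
    and exactly 0 for disjoint clone sets; clamped to [0, 1] against
    floating-point overshoot.  ``variant="morisita"`` gives the classical
    index with the unbiased Simpson term ``sum(x(x-1)) / (X(X-1))``, valid
    for integer counts only (it can slightly exceed 1 by construction).
    """
    if not x or not y:
        raise ValueError("Morisita overlap requires two nonempty repertoires")
    keys = sorted(set(x) | set(y))
    xv = np.array([x.get(k, 0.0) for k in keys], dtype=float)
    yv = np.array([y.get(k, 0.0) for k in keys], dtype=float)
    X = xv.sum()
    Y = yv.sum()
    if X <= 0 or Y <= 0:
        raise ValueError("Morisita overlap requires positive total abundance")
    cross = float(xv @ yv)
    if cross == 0.0:
        return 0.0
    if variant == "morisita-horn":
        # X*Y grouped so the index is bitwise symmetric under argument swap
        num = 2.0 * cross * (X * Y)
        den = float(xv @ xv) * (Y * Y) + float(yv @ yv) * (X * X)
    elif variant == "morisita":
        if X < 2 or Y < 2:
            raise ValueError("classical Morisita needs total counts >= 2")
        lx = float((xv * (xv - 1)).sum()) / (X * (X - 1))
        ly = float((yv * (yv - 1)).sum()) / (Y * (Y - 1))
        num = 2.0 * cross
        den = (lx + ly) * (X * Y)
    else:
        raise ValueError(f"unknown Morisita variant {variant!r}")
    val = num / den
    if variant == "morisita-horn":
        val = min(max(val, 0.0), 1.0)
    return val


def sharing_curve(
    reference: RankedRepertoire,
    target: RankedRepertoire,
    Ns: Iterable[int] = range(1, 201),
) -> dict[int, float]:
    """Percent of the reference's top-N clones present in the target.

    Both repertoires must come from the same subject (clones identified
    jointly); N is capped at the reference clone count and the capped value
    is the denominator.
    """
    if reference.subject_id != target.subject_id:
        raise ValueError(
            f"sharing curve across subjects ({reference.subject_id!r} vs "
            f"{target.subject_id!r}) is undefined"
        )
    present = set(target.clone_ids.tolist())
    out: dict[int, float] = {}
    n_ref = len(reference)
    for N in Ns:
        n_eff = min(int(N), n_ref)
        if n_eff <= 0:
            continue
        top = reference.clone_ids[:n_eff]
        shared = sum(1 for cid in top if cid in present)
        out[int(N)] = 100.0 * shared / n_eff
    return out


def global_connectivity(
    reference: RankedRepertoire,
    target: RankedRepertoire,
    expanded_only: bool = False,
) -> float:
    """Percent of reference clones also present in the target population.

    With ``expanded_only`` the denominator is the expanded prefix of the
    reference (``detect_expanded`` must have run); an empty expanded set
    yields NaN (reported downstream as NA, not 0).
    """
    if reference.subject_id != target.subject_id:
        raise ValueError("connectivity across subjects is undefined")
    ids = reference.clone_ids
    if expanded_only:
        ids = ids[reference.expanded_flags]
        if len(ids) == 0:
            return float("nan")
    present = set(target.clone_ids.tolist())
    shared = sum(1 for cid in ids if cid in present)
    return 100.0 * shared / len(ids)


def overlap_matrix(
    annotated: pd.DataFrame,
    subject_id: str,
    populations: Iterable[str] | None = None,
    weighting: str = "duplicate_count",
    delta: float = DEFAULT_EXPANSION_DELTA,
    Ns: Iterable[int] = range(1, 201),
    variant: str = "morisita-horn",
) -> tuple[pd.DataFrame, dict[tuple[str, str], OverlapResult]]:
    """All pairwise overlap statistics for one subject.

    Returns the square, symmetric Morisita matrix (unit diagonal) over the
    requested populations, plus an :class:`OverlapResult` per ordered pair
    (reference, target) carrying the directional statistics.
    """
    sub = annotated[annotated["subject_id"] == subject_id]
    if populations is None:
        populations = sorted(sub["population"].unique())
    populations = list(populations)
    sizes = clone_sizes_by_population(sub, weighting=weighting)
    if not sizes.empty:
        sizes = sizes.droplevel("subject_id")
    vectors: dict[str, dict[str, int]] = {}
    ranked: dict[str, RankedRepertoire] = {}
    for pop in populations:
        if pop not in sizes.columns:
            raise ValueError(f"population {pop!r} has no sequences for subject {subject_id!r}")
        v = sizes[pop]
        vectors[pop] = v[v > 0].to_dict()
        ranked[pop] = rank_from_sizes(vectors[pop], subject_id, pop)
        detect_expanded(ranked[pop], delta)

    mat = pd.DataFrame(1.0, index=populations, columns=populations)
    results: dict[tuple[str, str], OverlapResult] = {}
    for a in populations:
        for b in populations:
            if a == b:
                continue
            mh = morisita_horn(vectors[a], vectors[b], variant=variant)
            mat.loc[a, b] = mh
            shared = frozenset(vectors[a]) & frozenset(vectors[b])
            edges = pd.DataFrame(
                {
                    "clone_id": sorted(shared),
                    "size_ref": [vectors[a][c] for c in sorted(shared)],
                    "size_target": [vectors[b][c] for c in sorted(shared)],
                }
            )
            results[(a, b)] = OverlapResult(
                subject_id=subject_id,
                reference=a,
                target=b,
                morisita=mh,
                shared_clone_ids=shared,
                sharing_curve=sharing_curve(ranked[a], ranked[b], Ns),
                global_connectivity_pct=global_connectivity(ranked[a], ranked[b], False),
                expanded_connectivity_pct=global_connectivity(ranked[a], ranked[b], True),
                edge_list=edges,
            )
    return mat, results
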