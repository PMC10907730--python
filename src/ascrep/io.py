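"""Reading, validating and writing AIRR rearrangement tables and germline FASTA.

The canonical in-memory container is a :class:`pandas.DataFrame` with
AIRR-standard column names (one row per rearranged heavy-chain sequence).
Validation normalises gene calls to gene level, derives isotype labels from
the constant-region call, fills documented defaults, and drops rows that
cannot satisfy the record invariants, reporting every drop reason in a QC
summary.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Default population labels (CD19/CD138-defined ASC subsets).
POPULATIONS = ("Pop2", "Pop3", "Pop4", "Pop5")

#: Columns every validated rearrangement table carries, in output order.
CANONICAL_COLUMNS = [
    "sequence_id",
    "subject_id",
    "population",
    "v_call",
    "j_call",
    "junction",
    "junction_length",
    "duplicate_count",
    "c_call",
    "isotype",
    "v_sequence_alignment",
    "v_germline_alignment",
]

_MANDATORY = {
    "airr_tsv": ["sequence_id", "v_call", "j_call", "junction"],
    "minimal_csv": ["sequence_id", "v_call", "j_call", "junction"],
}

_NT_RE = re.compile(r"^[ACGTN]+$")


def normalize_gene_call(call: str) -> str:
    """Reduce a V/J call to gene level.

    Takes the first gene of a comma-separated ambiguous call and strips the
    allele suffix at ``*`` (``IGHV3-23*01`` -> ``IGHV3-23``).  Deterministic by
    construction, so reruns and row shuffles cannot change the result.
    """
    if not isinstance(call, str) or not call.strip():
        return ""
    first = call.split(",")[0].strip()
    return first.split("*")[0].strip()


def isotype_from_c_call(c_call: str) -> str:
    """Map a constant-region call to an isotype label.

    ``IGHM`` -> IgM, ``IGHG*`` -> IgG, ``IGHA*`` -> IgA; anything else
    (including missing) -> ``unknown``.
    """
    if not isinstance(c_call, str):
        return "unknown"
    c = c_call.strip().upper()
    if c.startswith("IGHM"):
        return "IgM"
    if c.startswith("IGHG"):
        return "IgG"
    if c.startswith("IGHA"):
        return "IgA"
    return "unknown"


def read_rearrangements(
    path: str | Path, dialect: str = "airr_tsv"
) -> tuple[pd.DataFrame, dict]:
    """Read a rearrangement table and validate every row.

    Parameters
    ----------
    path
        AIRR TSV (``airr_tsv``, tab-delimited) or a reduced comma-delimited
        table (``minimal_csv``) with at least ``sequence_id``, ``v_call``,
        ``j_call`` and ``junction`` columns.
    dialect
        One of ``airr_tsv`` or ``minimal_csv``.

    Returns
    -------
    (table, qc)
        ``table`` holds only rows passing validation, with normalised gene
        calls, derived ``junction_length`` and ``isotype``, and defaults
        filled (``duplicate_count`` 1 when absent).  ``qc`` reports
        ``n_read``, ``n_kept`` and per-reason drop counts.

    Raises
    ------
    ValueError
        If the file is empty or a mandatory column is missing (named in the
        message).
    """
    if dialect not in _MANDATORY:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    sep = "\t" if dialect == "airr_tsv" else ","
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty rearrangement file: {path}") from None
    if raw.empty and raw.columns.empty:
        raise ValueError(f"empty rearrangement file: {path}")
    for col in _MANDATORY[dialect]:
        if col not in raw.columns:
            raise ValueError(f"mandatory column missing: {col!r} in {path}")

    n_read = len(raw)
    drops: dict[str, int] = {}

    def _drop(mask: pd.Series, reason: str) -> pd.Series:
        n = int(mask.sum())
        if n:
            drops[reason] = drops.get(reason, 0) + n
        return ~mask

    df = raw.copy()
    # optional columns with documented defaults
    if "subject_id" not in df.columns:
        df["subject_id"] = "subject"
    if "population" not in df.columns:
        df["population"] = "unlabeled"
    if "duplicate_count" not in df.columns:
        df["duplicate_count"] = "1"
    if "c_call" not in df.columns:
        df["c_call"] = ""
    for col in ("v_sequence_alignment", "v_germline_alignment"):
        if col not in df.columns:
            df[col] = ""

    df["duplicate_count"] = df["duplicate_count"].replace("", "1")
    df["junction"] = df["junction"].str.strip().str.upper()
    df["v_call"] = df["v_call"].map(normalize_gene_call)
    df["j_call"] = df["j_call"].map(normalize_gene_call)

    keep = pd.Series(True, index=df.index)
    keep &= _drop(keep & (df["sequence_id"].str.strip() == ""), "missing_sequence_id")
    keep &= _drop(keep & (df["v_call"] == ""), "missing_v_call")
    keep &= _drop(keep & (df["j_call"] == ""), "missing_j_call")
    keep &= _drop(keep & (df["junction"] == ""), "missing_junction")
    bad_nt = keep & ~df["junction"].map(lambda s: bool(_NT_RE.match(s)) if s else False)
    keep &= _drop(bad_nt, "invalid_junction_chars")

    dup = pd.to_numeric(df["duplicate_count"], errors="coerce")
    bad_dup = keep & (dup.isna() | (dup < 1) | (dup != dup.round()))
    keep &= _drop(bad_dup, "invalid_duplicate_count")

    aln_a = df["v_sequence_alignment"].str.strip().str.upper()
    aln_b = df["v_germline_alignment"].str.strip().str.upper()
    has_pair = (aln_a != "") & (aln_b != "")
    bad_aln = keep & has_pair & (aln_a.str.len() != aln_b.str.len())
    keep &= _drop(bad_aln, "alignment_length_mismatch")
    # a lone half of an alignment pair is unusable; keep the row, void the pair
    half = (aln_a != "") ^ (aln_b != "")
    aln_a = aln_a.where(~half, "")
    aln_b = aln_b.where(~half, "")

    out = df.loc[keep].copy()
    out["duplicate_count"] = dup.loc[keep].astype(int)
    out["junction_length"] = out["junction"].str.len().astype(int)
    if "isotype" in out.columns and dialect == "minimal_csv":
        out["isotype"] = out["isotype"].where(
            out["isotype"].isin(["IgM", "IgG", "IgA"]), "unknown"
        )
    else:
        out["isotype"] = out["c_call"].map(isotype_from_c_call)
    out["v_sequence_alignment"] = aln_a.loc[keep]
    out["v_germline_alignment"] = aln_b.loc[keep]

    cols = CANONICAL_COLUMNS + [c for c in ("clone_id",) if c in out.columns]
    out = out[cols].reset_index(drop=True)
    qc = {"n_read": n_read, "n_kept": int(len(out)), "drop_reasons": drops}
    return out, qc


def read_germline_fasta(path: str | Path) -> dict[str, str]:
    """Read a germline V-gene FASTA into a gene-level identifier -> sequence map.

    Headers are reduced to the first whitespace token with the allele suffix
    stripped; when two records collapse onto one gene the first wins and a
    warning is logged.
    """
    path = Path(path)
    ref: dict[str, str] = {}
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        gene = normalize_gene_call(rec.id.split()[0])
        seq = str(rec.seq).upper()
        if not gene or not seq or not _NT_RE.match(seq):
            raise ValueError(f"unparsable germline record {rec.id!r} in {path}")
        if gene in ref:
            logger.warning("duplicate germline gene %s: keeping first record", gene)
            continue
        ref[gene] = seq
    if n == 0:
        raise ValueError(f"no FASTA records found in {path}")
    return ref


def write_rearrangements(records: pd.DataFrame, path: str | Path) -> None:
    """Write a validated rearrangement table as AIRR TSV.

    Round-trips through :func:`read_rearrangements` with field identity on
    all modeled columns; a ``clone_id`` column is appended when clonal
    assignments exist.
    """
    path = Path(path)
    cols = [c for c in CANONICAL_COLUMNS if c in records.columns]
    cols += [c for c in ("clone_id",) if c in records.columns]
    records[cols].to_csv(path, sep="\t", index=False)


def write_germline_fasta(ref: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in ref:
            fh.write(f">{gene}\n{ref[gene]}\n")


def validate_invariants(df: pd.DataFrame) -> None:
    """Assert the record invariants on a validated table (cheap, vectorised)."""
    assert (df["junction"].str.len() == df["junction_length"]).all()
    assert (df["duplicate_count"] >= 1).all()
    pair = (df["v_sequence_alignment"] != "") & (df["v_germline_alignment"] != "")
    assert (
        df.loc[pair, "v_sequence_alignment"].str.len()
        == df.loc[pair, "v_germline_alignment"].str.len()
    ).all()
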