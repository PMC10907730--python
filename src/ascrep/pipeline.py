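"""End-to-end repertoire analysis with file exports and a run manifest.

``run_pipeline`` chains validation, clonal assignment, rank/expansion
metrics, overlap/connectivity and SHM summaries, writing figure-ready
tables (TSV/CSV) plus a JSON manifest whose content hash is identical
across reruns of the same config and inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as aio
from .clonal import assign_clones, DEFAULT_THRESHOLD
from .metrics import (
    DEFAULT_EXPANSION_DELTA,
    detect_expanded,
    overlap_matrix,
    rank_repertoire,
)
from .shm import (
    intraclonal_divergence,
    isotype_fractions,
    shm_summary,
    v_mutation_frequency,
)

logger = logging.getLogger(__name__)

OUTPUT_FILES = (
    "rearrangements_annotated.tsv",
    "clones.tsv",
    "rank_abundance.tsv",
    "expanded.tsv",
    "morisita_matrix.csv",
    "sharing_curves.tsv",
    "connectivity_edges.tsv",
    "connectivity_summary.tsv",
    "shm_sequences.tsv",
    "shm_summary.tsv",
    "divergence.tsv",
    "isotype_fractions.tsv",
    "qc.json",
    "run_manifest.json",
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serialisable)."""

    input_rearrangements: str
    outdir: str
    input_germline: str | None = None
    dialect: str = "airr_tsv"
    population_labels: dict | None = None   # raw label -> canonical label
    threshold: float = DEFAULT_THRESHOLD
    expansion_delta: float = DEFAULT_EXPANSION_DELTA
    weighting: str = "duplicate_count"
    top_n_min: int = 1
    top_n_max: int = 200
    morisita_variant: str = "morisita-horn"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        if self.expansion_delta < 0:
            raise ValueError("expansion_delta must be non-negative")
        if self.weighting not in ("duplicate_count", "unique_sequences"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.top_n_min < 1 or self.top_n_max < self.top_n_min:
            raise ValueError("top-N grid invalid")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to disk)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    stage = "read"
    try:
        records, qc = aio.read_rearrangements(
            config.input_rearrangements, dialect=config.dialect
        )
        if config.population_labels is not None:
            missing = set(records["population"]) - set(config.population_labels)
            if missing:
                raise ValueError(
                    f"population labels without a mapping: {sorted(missing)}"
                )
            records["population"] = records["population"].map(config.population_labels)
        if records.empty:
            raise ValueError("no valid rearrangements after QC")
        germline = (
            aio.read_germline_fasta(config.input_germline)
            if config.input_germline
            else None
        )
        logger.info("read: %d/%d records kept (%.2fs)", qc["n_kept"], qc["n_read"],
                    time.perf_counter() - t0)

        stage = "assign_clones"
        annotated, clones = assign_clones(records, threshold=config.threshold)
        aio.write_rearrangements(annotated, outdir / "rearrangements_annotated.tsv")
        clones.to_csv(outdir / "clones.tsv", sep="\t", index=False)

        stage = "metrics"
        Ns = range(config.top_n_min, config.top_n_max + 1)
        rank_rows, expanded_rows, mh_rows = [], [], []
        share_rows, edge_rows, conn_rows = [], [], []
        for subject in sorted(annotated["subject_id"].unique()):
            sub = annotated[annotated["subject_id"] == subject]
            pops = sorted(sub["population"].unique())
            for pop in pops:
                ranked = rank_repertoire(sub, subject, pop, weighting=config.weighting)
                detect_expanded(ranked, config.expansion_delta)
                for r in range(len(ranked)):
                    rank_rows.append(
                        {
                            "subject_id": subject,
                            "population": pop,
                            "rank": r + 1,
                            "clone_id": ranked.clone_ids[r],
                            "frequency": ranked.frequencies[r],
                            "cumulative": ranked.cumulative[r],
                            "expanded": bool(ranked.expanded_flags[r]),
                        }
                    )
                    if ranked.expanded_flags[r]:
                        expanded_rows.append(rank_rows[-1])
            if len(pops) >= 2:
                mat, results = overlap_matrix(
                    sub, subject, pops,
                    weighting=config.weighting,
                    delta=config.expansion_delta,
                    Ns=Ns,
                    variant=config.morisita_variant,
                )
                for a in pops:
                    for b in pops:
                        mh_rows.append(
                            {"subject_id": subject, "pop_a": a, "pop_b": b,
                             "morisita": mat.loc[a, b]}
                        )
                for (a, b), res in sorted(results.items()):
                    for N, pct in res.sharing_curve.items():
                        share_rows.append(
                            {"subject_id": subject, "ref_pop": a, "target_pop": b,
                             "N": N, "percent_shared": pct}
                        )
                    for e in res.edge_list.itertuples(index=False):
                        edge_rows.append(
                            {"subject_id": subject, "ref_pop": a, "target_pop": b,
                             "clone_id": e.clone_id, "size_ref": e.size_ref,
                             "size_target": e.size_target}
                        )
                    conn_rows.append(
                        {"subject_id": subject, "ref_pop": a, "target_pop": b,
                         "global_connectivity_pct": res.global_connectivity_pct,
                         "expanded_connectivity_pct": res.expanded_connectivity_pct}
                    )
        pd.DataFrame(rank_rows).to_csv(outdir / "rank_abundance.tsv", sep="\t", index=False)
        pd.DataFrame(expanded_rows).to_csv(outdir / "expanded.tsv", sep="\t", index=False)
        pd.DataFrame(mh_rows).to_csv(outdir / "morisita_matrix.csv", index=False)
        pd.DataFrame(share_rows).to_csv(outdir / "sharing_curves.tsv", sep="\t", index=False)
        pd.DataFrame(edge_rows).to_csv(outdir / "connectivity_edges.tsv", sep="\t", index=False)
        pd.DataFrame(conn_rows).to_csv(outdir / "connectivity_summary.tsv", sep="\t", index=False)

        stage = "shm"
        shm, shm_qc = v_mutation_frequency(annotated, germline)
        shm.to_csv(outdir / "shm_sequences.tsv", sep="\t", index=False)
        shm_summary(shm).to_csv(outdir / "shm_summary.tsv", sep="\t", index=False)
        intraclonal_divergence(annotated, shm).to_csv(
            outdir / "divergence.tsv", sep="\t", index=False
        )
        isotype_fractions(annotated).to_csv(
            outdir / "isotype_fractions.tsv", sep="\t", index=False
        )
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    qc_all = {"read": qc, "shm": shm_qc}
    with open(outdir / "qc.json", "w") as fh:
        json.dump(qc_all, fh, indent=1, sort_keys=True)

    config_yaml = RunConfig(**asdict(config)).to_yaml()
    manifest = {
        "inputs": {
            "rearrangements": str(config.input_rearrangements),
            "germline": str(config.input_germline) if config.input_germline else None,
        },
        "config": asdict(config),
        "config_sha256": _sha256(config_yaml),
        "counts": {
            "n_records": int(len(annotated)),
            "n_clones": int(len(clones)),
            "n_rank_rows": len(rank_rows),
            "n_expanded_rows": len(expanded_rows),
            "n_shm_scored": shm_qc["n_scored"],
        },
        "qc": qc_all,
    }
    manifest["manifest_sha256"] = _sha256(json.dumps(manifest, sort_keys=True))
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete in %.2fs", time.perf_counter() - t0)
    return manifest
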