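import numpy as np
import pandas as pd
import pytest

import ascrep


TOY_AIRR_ROWS = [
    # sequence_id, v_call, j_call, junction, duplicate_count, c_call
    ("seq1", "IGHV3-23*01", "IGHJ4*02", "TGTGCGAGAGATACGTACGACTGG", "3", "IGHG1"),
    ("seq2", "IGHV3-23*01", "IGHJ4*02", "TGTGCGAGAGATACGTACGACTGG", "1", "IGHG1"),
    ("seq3", "IGHV1-2*02", "IGHJ6*01", "TGTGCGAGACCCGGGTTTGACTGG", "2", "IGHM"),
    ("seq4", "IGHV1-2*02", "IGHJ6*01", "", "1", "IGHM"),  # dropped: no junction
    ("seq5", "IGHV4-34*01", "IGHJ4*02", "TGTGCGAGATTTACGTACGACTGG", "1", "IGHA1"),
    ("seq6", "IGHV4-34*01,IGHV4-59*01", "IGHJ4*02", "TGTGCGAGATTTACGTACGATTGG", "1", ""),
]


@pytest.fixture
def toy_airr_tsv(tmp_path):
    """Six-row AIRR TSV, one row lacking a junction."""
    path = tmp_path / "toy.tsv"
    header = "sequence_id\tv_call\tj_call\tjunction\tduplicate_count\tc_call\n"
    body = "".join("\t".join(r) + "\n" for r in TOY_AIRR_ROWS)
    path.write_text(header + body)
    return path


@pytest.fixture(scope="session")
def small_sim():
    """Well-separated desk-scale simulation shared across tests."""
    design = ascrep.SimulationDesign(
        seed=11, n_sequences_per_population=1500, n_clones=60
    )
    return ascrep.simulate(design)


@pytest.fixture(scope="session")
def small_annotated(small_sim):
    annotated, clones = ascrep.assign_clones(small_sim.rearrangements)
    return annotated, clones


@pytest.fixture(scope="session")
def recovery_sim():
    """The parameter-recovery design: 4 populations x 5,000 sequences."""
    design = ascrep.SimulationDesign(
        seed=29, n_sequences_per_population=5000, n_clones=200
    )
    return ascrep.simulate(design)


@pytest.fixture(scope="session")
def recovery_outputs(recovery_sim):
    annotated, clones = ascrep.assign_clones(recovery_sim.rearrangements)
    shm, _ = ascrep.v_mutation_frequency(annotated)
    return annotated, clones, shm


def make_table(rows: list[dict]) -> pd.DataFrame:
    """Build a validated-shape rearrangement table from sparse row dicts."""
    defaults = {
        "subject_id": "S1",
        "population": "Pop2",
        "v_call": "IGHV3-23",
        "j_call": "IGHJ4",
        "duplicate_count": 1,
        "c_call": "IGHG1",
        "isotype": "IgG",
        "v_sequence_alignment": "",
        "v_germline_alignment": "",
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["sequence_id"] = f"q{i:03d}"
        rec.update(row)
        rec["junction_length"] = len(rec["junction"])
        out.append(rec)
    return pd.DataFrame(out, columns=ascrep.io.CANONICAL_COLUMNS)


@pytest.fixture
def table_builder():
    return make_table


def random_partition_instance(rng: np.random.Generator, n: int, length: int = 24):
    """Random equal-length junctions with planted relatedness for oracle tests.

    Junctions are generated by mutating a few seeds at random rates, so the
    pairwise-identity graph has nontrivial components including borderline
    pairs around the 85% threshold.
    """
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    n_seeds = int(rng.integers(2, 8))
    seeds = [bases[rng.integers(0, 4, size=length)] for _ in range(n_seeds)]
    junctions = []
    for _ in range(n):
        seed = seeds[rng.integers(n_seeds)]
        k = int(rng.integers(0, length // 2))
        arr = seed.copy()
        pos = rng.choice(length, size=k, replace=False)
        arr[pos] = bases[rng.integers(0, 4, size=k)]
        junctions.append(bytes(arr).decode())
    ids = [f"r{i:04d}" for i in range(n)]
    return junctions, ids
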