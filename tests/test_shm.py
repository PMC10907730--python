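"""V-region mutation quantification, SHM summaries, intraclonal divergence,
and isotype composition."""

import numpy as np
import pandas as pd
import pytest

import ascrep
from ascrep.shm import (
    _compare_alignment,
    intraclonal_divergence,
    isotype_fractions,
    shm_summary,
    v_mutation_frequency,
)


def shm_table(rows):
    return pd.DataFrame(
        [
            {
                "sequence_id": f"s{i}",
                "subject_id": "S1",
                "population": r.get("population", "Pop2"),
                "isotype": r.get("isotype", "IgG"),
                "mutation_count": r.get("mutation_count", 0),
                "aligned_length": r.get("aligned_length", 100),
                "shm_pct": r["shm_pct"],
                "approximate": False,
            }
            for i, r in enumerate(rows)
        ]
    )


class TestVMutationFrequency:
    def test_twelve_mismatches_over_240_positions_is_five_percent(self, table_builder):
        germ = "ACGT" * 60
        obs = "GTAC" * 3 + "ACGT" * 57  # first 12 positions all mismatch
        n_diff = sum(1 for a, b in zip(obs, germ) if a != b)
        assert n_diff == 12 and len(obs) == 240
        df = table_builder(
            [{"junction": "TGTGCGTGG",
              "v_sequence_alignment": obs, "v_germline_alignment": germ}]
        )
        shm, qc = v_mutation_frequency(df)
        assert qc == {"n_scored": 1, "n_skipped": 0}
        assert shm.loc[0, "mutation_count"] == 12
        assert shm.loc[0, "aligned_length"] == 240
        assert shm.loc[0, "shm_pct"] == pytest.approx(5.0)

    def test_identical_to_germline_is_zero_percent(self, table_builder):
        germ = "ACGT" * 50
        df = table_builder(
            [{"junction": "TGTGCGTGG",
              "v_sequence_alignment": germ, "v_germline_alignment": germ}]
        )
        shm, _ = v_mutation_frequency(df)
        assert shm.loc[0, "shm_pct"] == 0.0

    def test_gap_positions_excluded_from_both_counts(self):
        obs = "ACGTA--CGTACG.TT"
        grm = "TCGTAAACGTACGAG-"
        # positions with a gap on either side: 5, 6, 13, 15 -> 12 compared;
        # mismatches among compared positions: 0 (A/T) and 14 (T/G)
        mut, length = _compare_alignment(obs, grm)
        assert length == 12
        assert mut == 2

    def test_n_positions_excluded(self):
        mut, length = _compare_alignment("ANCG", "AACG")
        assert (mut, length) == (0, 3)

    def test_ungapped_fallback_over_min_length_flagged_approximate(self, table_builder):
        germline = {"IGHV3-23": "AAAA" * 30}
        obs = "AAAC" * 20  # shorter than germline; 20 mismatches / 80
        df = table_builder(
            [{"junction": "TGTGCGTGG", "v_sequence_alignment": "",
              "v_germline_alignment": ""}]
        )
        df["v_sequence"] = obs
        shm, _ = v_mutation_frequency(df, germline)
        assert shm.loc[0, "approximate"]
        assert shm.loc[0, "aligned_length"] == 80
        assert shm.loc[0, "shm_pct"] == pytest.approx(25.0)

    def test_no_germline_available_skips_with_count(self, table_builder):
        df = table_builder([{"junction": "TGTGCGTGG"}])
        shm, qc = v_mutation_frequency(df, germline=None)
        assert qc == {"n_scored": 0, "n_skipped": 1}
        assert shm.empty


class TestShmSummary:
    def test_mean_and_fraction_below_five(self):
        t = shm_table([{"shm_pct": 4.0}, {"shm_pct": 6.0}, {"shm_pct": 8.0}])
        out = shm_summary(t)
        assert len(out) == 1
        assert out.loc[0, "mean_shm_pct"] == pytest.approx(6.0)
        assert out.loc[0, "frac_below"] == pytest.approx(1 / 3)

    def test_all_zero_shm(self):
        t = shm_table([{"shm_pct": 0.0}] * 4)
        out = shm_summary(t)
        assert out.loc[0, "mean_shm_pct"] == 0.0
        assert out.loc[0, "frac_below"] == 1.0

    def test_groups_split_by_population_and_isotype(self):
        t = shm_table(
            [
                {"shm_pct": 2.0, "population": "Pop2", "isotype": "IgM"},
                {"shm_pct": 8.0, "population": "Pop5", "isotype": "IgG"},
            ]
        )
        out = shm_summary(t)
        assert len(out) == 2

    def test_planted_mean_recovered_on_simulation(self, recovery_sim, recovery_outputs):
        """Planted truncated-Normal(7%, 2%) SHM is recovered within 0.3 points."""
        _, _, shm = recovery_outputs
        est = shm["shm_pct"].mean()
        assert abs(est - recovery_sim.design.shm_mean) <= 0.3


class TestIntraclonalDivergence:
    def test_singleton_is_exactly_zero_distance_one_pattern(self, table_builder):
        df = table_builder([{"junction": "TGTGCGTGG"}])
        df["clone_id"] = "c1"
        out = intraclonal_divergence(df)
        row = out.iloc[0]
        assert row["n_members"] == 1
        assert row["mean_pairwise_distance"] == 0.0
        assert row["n_distinct_mutation_patterns"] == 1

    def test_two_members_two_junction_differences(self, table_builder):
        df = table_builder(
            [{"junction": "TGTGCGTGGACT"}, {"junction": "TGTGCGTGGTCA"}]
        )
        df["clone_id"] = "c1"
        out = intraclonal_divergence(df)
        assert out.iloc[0]["mean_pairwise_distance"] == pytest.approx(2.0)

    def test_identical_members_equal_mutations(self, table_builder):
        df = table_builder([{"junction": "TGTGCGTGG"}] * 3)
        df["clone_id"] = "c1"
        shm = shm_table([{"shm_pct": 5.0, "mutation_count": 5}] * 3)
        shm["sequence_id"] = df["sequence_id"].values
        out = intraclonal_divergence(df, shm)
        row = out.iloc[0]
        assert row["mean_pairwise_distance"] == 0.0
        assert row["n_distinct_mutation_patterns"] == 1

    def test_ladder_topology_shows_mutation_distance_gradient(self, table_builder):
        """Sequential mutation accumulation (ladder) couples a member's
        mutation load to its junction distance from clone-mates; a star
        around one founder does not."""
        rng = np.random.default_rng(42)
        bases = "ACGT"
        L = 30

        def mutate(s, k):
            s = list(s)
            for p in rng.choice(L, size=k, replace=False):
                s[p] = bases[(bases.index(s[p]) + 1) % 4]
            return "".join(s)

        founder = "".join(rng.choice(list(bases), size=L))
        ladder, muts_ladder = [], []
        cur = founder
        for step in range(12):
            cur = mutate(cur, 1)
            ladder.append(cur)
            muts_ladder.append(step + 1)
        star = [mutate(founder, 1) for _ in range(12)]
        muts_star = [int(rng.integers(1, 13)) for _ in range(12)]

        def rho(junctions, muts):
            df = table_builder([{"junction": j} for j in junctions])
            df["clone_id"] = "c1"
            shm = shm_table(
                [{"shm_pct": m, "mutation_count": m} for m in muts]
            )
            shm["sequence_id"] = df["sequence_id"].values
            return intraclonal_divergence(df, shm).iloc[0]["mutation_distance_rho"]

        r_ladder = rho(ladder, muts_ladder)
        r_star = rho(star, muts_star)
        assert r_ladder > 0
        assert r_ladder > r_star


class TestIsotypeFractions:
    def test_ratio_igg_over_iga(self, table_builder):
        rows = (
            [{"junction": "TGT", "isotype": "IgG"}] * 60
            + [{"junction": "TGT", "isotype": "IgA"}] * 30
            + [{"junction": "TGT", "isotype": "IgM"}] * 10
        )
        out = isotype_fractions(table_builder(rows))
        row = out.iloc[0]
        assert row["ratio_IgG_IgA"] == pytest.approx(2.0)
        assert row["ratio_IgG_IgM"] == pytest.approx(6.0)
        assert row["prop_IgG"] + row["prop_IgA"] + row["prop_IgM"] == pytest.approx(1.0)

    def test_zero_denominator_gives_na_not_infinity(self, table_builder):
        rows = [{"junction": "TGT", "isotype": "IgG"}] * 5
        out = isotype_fractions(table_builder(rows))
        assert np.isnan(out.iloc[0]["ratio_IgG_IgA"])

    def test_row_order_invariance(self, table_builder):
        rows = [
            {"junction": "TGT", "isotype": iso, "population": pop}
            for iso in ("IgG", "IgA", "IgM")
            for pop in ("Pop2", "Pop5")
        ] * 3
        df = table_builder(rows)
        rng = np.random.default_rng(1)
        shuffled = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
        pd.testing.assert_frame_equal(isotype_fractions(df), isotype_fractions(shuffled))
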