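"""Rank-abundance, expansion gap rule, Morisita-Horn overlap, sharing
curves and connectivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ascrep
from ascrep.metrics import (
    RankedRepertoire,
    detect_expanded,
    global_connectivity,
    morisita_horn,
    overlap_matrix,
    rank_from_sizes,
    rank_repertoire,
    sharing_curve,
)


def ranked(freq_pct, subject="S1", pop="Pop2", ids=None):
    f = np.asarray(freq_pct, dtype=float)
    ids = ids or [f"c{i:03d}" for i in range(len(f))]
    return RankedRepertoire(subject, pop, np.array(ids, dtype=object), f / f.sum())


class TestRankRepertoire:
    def test_single_clone(self, table_builder):
        df = table_builder([{"junction": "TGTGCGTGG"}])
        df["clone_id"] = "S1|q000"
        r = rank_repertoire(df, "S1", "Pop2")
        assert r.frequencies.tolist() == [1.0]
        assert r.cumulative.tolist() == [1.0]

    def test_sizes_three_and_one(self, table_builder):
        df = table_builder(
            [
                {"junction": "TGTGCGTGG", "duplicate_count": 3},
                {"junction": "AAAAAAAAA", "duplicate_count": 1},
            ]
        )
        df["clone_id"] = ["A", "B"]
        r = rank_repertoire(df, "S1", "Pop2")
        assert r.frequencies.tolist() == [0.75, 0.25]

    def test_unique_sequence_weighting_ignores_duplicates(self, table_builder):
        df = table_builder(
            [
                {"junction": "TGTGCGTGG", "duplicate_count": 30},
                {"junction": "AAAAAAAAA", "duplicate_count": 1},
            ]
        )
        df["clone_id"] = ["A", "B"]
        r = rank_repertoire(df, "S1", "Pop2", weighting="unique_sequences")
        assert r.frequencies.tolist() == [0.5, 0.5]

    def test_ties_break_by_clone_id_deterministically(self):
        r1 = rank_from_sizes({"z": 5, "a": 5, "m": 5}, "S1", "Pop2")
        r2 = rank_from_sizes({"m": 5, "z": 5, "a": 5}, "S1", "Pop2")
        assert r1.clone_ids.tolist() == ["a", "m", "z"]
        assert r1.clone_ids.tolist() == r2.clone_ids.tolist()

    def test_empty_population_is_hard_error_naming_it(self, table_builder):
        df = table_builder([{"junction": "TGTGCGTGG"}])
        df["clone_id"] = "x"
        with pytest.raises(ValueError, match="Pop5"):
            rank_repertoire(df, "S1", "Pop5")


class TestDetectExpanded:
    def test_prefix_runs_to_last_qualifying_gap(self):
        # top clones at 2.50, 1.20, 1.05, 1.00, 0.20, 0.15, 0.10 percent over a
        # flat 0.10%-per-clone background; the last qualifying gap is 1.00 -> 0.20
        head = [2.50, 1.20, 1.05, 1.00, 0.20, 0.15, 0.10]
        r = ranked(head + [0.10] * 938)
        flags = detect_expanded(r)
        assert flags[:7].tolist() == [True, True, True, True, False, False, False]
        assert not flags[7:].any()

    def test_flat_repertoire_has_no_expanded_clones(self):
        r = ranked([1.0] * 50)
        assert not detect_expanded(r).any()

    def test_single_qualifying_gap_at_rank_one(self):
        r = ranked([5.0] + [0.1] * 950)
        flags = detect_expanded(r)
        assert flags[0] and flags.sum() == 1

    def test_gap_to_nonexistent_next_clone_never_counts(self):
        # one clone at 100%: no internal gap, so nothing is expanded
        r = ranked([100.0])
        assert not detect_expanded(r).any()

    def test_appending_zero_frequency_clones_changes_nothing(self):
        base = ranked([5.0, 3.0, 0.5, 0.5])
        flags1 = detect_expanded(base).copy()
        f = np.concatenate([base.frequencies, [0.0, 0.0]])
        padded = RankedRepertoire(
            "S1", "Pop2", np.array([f"c{i}" for i in range(len(f))], dtype=object), f
        )
        # frequencies of zero cannot create a qualifying gap past the old tail
        flags2 = detect_expanded(padded)
        assert flags2[: len(flags1)].tolist() == flags1.tolist()
        assert not flags2[len(flags1):].any()


class TestMorisitaHorn:
    def test_worked_example_six_sevenths(self):
        assert morisita_horn({"A": 2, "B": 1}, {"A": 1}) == pytest.approx(6 / 7, abs=1e-12)

    def test_worked_example_one_half(self):
        assert morisita_horn({"A": 1, "B": 1}, {"B": 1, "C": 1}) == pytest.approx(0.5, abs=1e-12)

    def test_identical_repertoire_is_exactly_one(self):
        x = {"A": 17, "B": 3, "C": 1}
        assert morisita_horn(x, x) == 1.0

    def test_disjoint_repertoires_are_exactly_zero(self):
        assert morisita_horn({"A": 5, "B": 2}, {"C": 9, "D": 1}) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.dictionaries(
            st.text(alphabet="abcdef", min_size=1, max_size=3),
            st.floats(min_value=0.01, max_value=1e6),
            min_size=1,
            max_size=20,
        )
    )
    def test_self_overlap_exactly_one_for_any_abundances(self, x):
        assert morisita_horn(x, x) == 1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.dictionaries(st.sampled_from("abcdefgh"), st.integers(1, 1000), min_size=1),
        st.dictionaries(st.sampled_from("abcdefgh"), st.integers(1, 1000), min_size=1),
    )
    def test_symmetric_and_bounded(self, x, y):
        v = morisita_horn(x, y)
        assert v == morisita_horn(y, x)
        assert 0.0 <= v <= 1.0

    def test_empty_repertoire_is_error(self):
        with pytest.raises(ValueError):
            morisita_horn({}, {"A": 1})

    def test_classical_variant_on_integer_counts(self):
        # x == y with counts {A: 2}: unbiased Simpson terms are 2/2 = 1 each
        assert morisita_horn({"A": 2}, {"A": 2}, variant="morisita") == pytest.approx(1.0)


class TestSharingCurve:
    def test_ten_of_top_twentyfive_is_forty_percent(self):
        ref = ranked([10.0] * 25 + [1.0] * 10)
        shared_ids = ref.clone_ids[:10].tolist()
        tgt = ranked([1.0] * 10, ids=shared_ids)
        curve = sharing_curve(ref, tgt, [25])
        assert curve[25] == pytest.approx(40.0)

    def test_identical_repertoire_shares_everything(self):
        ref = ranked([5.0, 3.0, 2.0])
        curve = sharing_curve(ref, ref, [1, 2, 3, 50])
        assert all(v == 100.0 for v in curve.values())

    def test_disjoint_repertoires_share_nothing(self):
        ref = ranked([5.0, 3.0], ids=["a", "b"])
        tgt = ranked([5.0, 3.0], ids=["c", "d"])
        assert set(sharing_curve(ref, tgt, [1, 2]).values()) == {0.0}

    def test_cross_subject_comparison_is_error(self):
        ref = ranked([1.0], subject="S1")
        tgt = ranked([1.0], subject="S2")
        with pytest.raises(ValueError):
            sharing_curve(ref, tgt, [1])

    def test_matches_brute_force_set_intersection(self, recovery_outputs):
        annotated, _, _ = recovery_outputs
        ref = rank_repertoire(annotated, "S1", "Pop5")
        tgt = rank_repertoire(annotated, "S1", "Pop2")
        curve = sharing_curve(ref, tgt, range(1, 120, 7))
        target_set = set(tgt.clone_ids.tolist())
        for N, pct in curve.items():
            n_eff = min(N, len(ref))
            top = set(ref.clone_ids[:n_eff].tolist())
            assert pct == pytest.approx(100.0 * len(top & target_set) / n_eff)
            assert 0.0 <= pct <= 100.0


class TestGlobalConnectivity:
    def test_two_of_fourteen_expanded(self):
        ref = ranked([10.0] * 14 + [0.1] * 20)
        ref.expanded_flags = np.array([True] * 14 + [False] * 20)
        tgt = ranked([1.0, 1.0], ids=ref.clone_ids[:2].tolist())
        pct = global_connectivity(ref, tgt, expanded_only=True)
        assert pct == pytest.approx(100 * 2 / 14)

    def test_all_clones_shared_is_hundred_percent(self):
        ref = ranked([5.0, 3.0, 2.0])
        assert global_connectivity(ref, ref) == 100.0

    def test_no_shared_clones_is_zero(self):
        ref = ranked([5.0], ids=["a"])
        tgt = ranked([5.0], ids=["b"])
        assert global_connectivity(ref, tgt) == 0.0

    def test_empty_expanded_set_reports_na_not_zero(self):
        ref = ranked([1.0] * 10)  # flat: nothing expanded
        detect_expanded(ref)
        assert np.isnan(global_connectivity(ref, ref, expanded_only=True))


class TestOverlapMatrix:
    def test_square_symmetric_unit_diagonal(self, recovery_outputs):
        annotated, _, _ = recovery_outputs
        mat, _ = overlap_matrix(annotated, "S1")
        assert mat.shape == (4, 4)
        assert (np.diag(mat.values) == 1.0).all()
        assert (mat.values == mat.values.T).all()

    def test_population_order_permutes_consistently(self, recovery_outputs):
        annotated, _, _ = recovery_outputs
        pops = ["Pop2", "Pop3", "Pop4", "Pop5"]
        m1, _ = overlap_matrix(annotated, "S1", pops)
        perm = ["Pop5", "Pop3", "Pop2", "Pop4"]
        m2, _ = overlap_matrix(annotated, "S1", perm)
        pd.testing.assert_frame_equal(m1.loc[perm, perm], m2)

    def test_pipeline_morisita_equals_direct_formula_on_planted_abundances(
        self, recovery_sim, recovery_outputs
    ):
        annotated, _, _ = recovery_outputs
        mat, _ = overlap_matrix(annotated, "S1")
        # oracle: the closed form applied to the planted per-population counts
        for a in mat.index:
            for b in mat.columns:
                if a == b:
                    continue
                x = recovery_sim.truth_sizes[("S1", a)]
                y = recovery_sim.truth_sizes[("S1", b)]
                assert mat.loc[a, b] == pytest.approx(morisita_horn(x, y), abs=1e-12)

    def test_subsampling_stability_of_morisita(self, recovery_sim):
        """A 50% multinomial subsample moves the index by less than 0.05."""
        rng = np.random.default_rng(17)
        x = recovery_sim.truth_sizes[("S1", "Pop2")]
        y = recovery_sim.truth_sizes[("S1", "Pop5")]
        full = morisita_horn(x, y)

        def subsample(v):
            keys = sorted(v)
            counts = np.array([v[k] for k in keys])
            sub = rng.multinomial(counts.sum() // 2, counts / counts.sum())
            return {k: int(c) for k, c in zip(keys, sub) if c > 0}

        half = morisita_horn(subsample(x), subsample(y))
        assert abs(full - half) < 0.05
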