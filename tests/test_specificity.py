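"""Conservation scoring, mR scores vs exhaustive pair enumeration, the
permutation z-test, disjunctness filtering and query calls."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trpscan as t
from trpscan.specificity import (
    PROPERTY_TABLE,
    SpecificityError,
    conservation_score_column,
)


class TestConservation:
    def test_identical_gapfree_column_scores_11(self):
        for res in "KAW":
            assert conservation_score_column(res * 6) == 11

    def test_column_with_no_uniform_property_scores_0(self):
        # K,D,P,I,W,G disagree on every property's all-have/none-have status
        column = "KDPIWG"
        for members in PROPERTY_TABLE.values():
            have = [r in members for r in column]
            assert any(have) and not all(have)
        assert conservation_score_column(column) == 0

    def test_aliphatic_column_matches_property_table_enumeration(self):
        """{I,L,V}: the score equals a direct enumeration of the 10-property
        table (independent oracle)."""
        column = "ILV"
        expected = 0
        for members in PROPERTY_TABLE.values():
            have = [r in members for r in column]
            if all(have) or not any(have):
                expected += 1
        # I, L, V share hydrophobic+aliphatic (all-have) and uniformly lack
        # polar, tiny, aromatic, positive, negative, charged and proline;
        # "small" splits the column (V is small, I and L are not) -> 9
        assert expected == 9
        assert conservation_score_column(column) == expected

    def test_gap_breaks_identity_and_all_have_statuses(self):
        assert conservation_score_column("KKK-") != 11
        # gap carries no properties: 'positive' is no longer all-have, but
        # none-have properties (e.g. negative, proline) still count
        s = conservation_score_column("KKK-")
        assert 0 < s < 11

    def test_all_gap_column_has_no_score(self):
        assert conservation_score_column("---") is None

    def test_scores_per_alignment_column(self):
        aln = t.Alignment(["a", "b"], ["KA", "KG"])
        assert t.conservation_scores(aln) == [11, conservation_score_column("AG")]


def brute_force_mr(columns_push, columns_pull):
    """Exhaustive pair enumeration oracle for one column."""
    d_between = np.mean([a != b for a in columns_push for b in columns_pull])
    within = [
        a != b for a, b in itertools.combinations(columns_push, 2)
    ] + [a != b for a, b in itertools.combinations(columns_pull, 2)]
    d_within = np.mean(within) if within else 0.0
    return d_between - d_within


class TestMrScores:
    def _aln(self, push_rows, pull_rows):
        ids = [f"p{i}" for i in range(len(push_rows))] + [
            f"l{i}" for i in range(len(pull_rows))
        ]
        labels = {f"p{i}": "push" for i in range(len(push_rows))} | {
            f"l{i}": "pull" for i in range(len(pull_rows))
        }
        return t.Alignment(ids, push_rows + pull_rows), labels

    def test_constant_column_scores_zero(self):
        aln, labels = self._aln(["A", "A"], ["A", "A"])
        assert t.mr_scores(aln, labels)[0] == 0.0

    def test_perfectly_separated_column_scores_one(self):
        aln, labels = self._aln(["A", "A", "A"], ["G", "G", "G"])
        assert t.mr_scores(aln, labels)[0] == 1.0

    def test_hand_enumerated_mixed_column(self):
        aln, labels = self._aln(["A", "A", "S"], ["G", "G", "G"])
        expected = brute_force_mr("AAS", "GGG")
        assert t.mr_scores(aln, labels)[0] == pytest.approx(expected)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_exhaustive_pair_enumeration(self, data):
        """mR equals brute-force pair enumeration on alignments of <=8 rows,
        including gapped columns (gap = 21st symbol)."""
        n_push = data.draw(st.integers(1, 4))
        n_pull = data.draw(st.integers(1, 4))
        n_cols = data.draw(st.integers(1, 5))
        sym = "AGKD-"
        rows = [
            "".join(data.draw(st.sampled_from(sym)) for _ in range(n_cols))
            for _ in range(n_push + n_pull)
        ]
        aln, labels = self._aln(rows[:n_push], rows[n_push:])
        mr = t.mr_scores(aln, labels)
        for c in range(n_cols):
            col = aln.column(c)
            expected = brute_force_mr(col[:n_push], col[n_push:])
            assert mr[c] == pytest.approx(expected, abs=1e-12)
        assert np.all(mr >= -1 - 1e-12) and np.all(mr <= 1 + 1e-12)

    def test_empty_group_rejected(self):
        aln = t.Alignment(["a", "b"], ["AG", "AG"])
        with pytest.raises(SpecificityError):
            t.mr_scores(aln, {"a": "push", "b": "push"})


class TestPermutationZ:
    def test_constant_column_never_significant(self):
        rng = np.random.default_rng(0)
        rows = ["A" + "".join(rng.choice(list("AGKD"), size=9)) for _ in range(12)]
        ids = [f"s{i}" for i in range(12)]
        labels = {f"s{i}": "push" if i < 6 else "pull" for i in range(12)}
        z, sig = t.permutation_z(t.Alignment(ids, rows), labels,
                                 n_permutations=200, rng_seed=1)
        assert math.isnan(z[0])
        assert 0 not in sig

    def test_planted_disjunct_column_is_significant(self):
        aln, truth = t.generate_pushpull_alignment(10, 10, 0, 40, 1, 0.1, rng_seed=5)
        z, sig = t.permutation_z(aln, truth.group_of, n_permutations=1000, rng_seed=2)
        (c,) = [c for c, _, _ in truth.disjunct_columns]
        assert z[c] > 3
        assert c in sig

    def test_threshold_is_strict_and_one_sided(self):
        aln, truth = t.generate_pushpull_alignment(10, 10, 0, 40, 1, 0.1, rng_seed=5)
        (c,) = [c for c, _, _ in truth.disjunct_columns]
        z, sig_above = t.permutation_z(
            aln, truth.group_of, n_permutations=500, z_threshold=float(10**9), rng_seed=2
        )
        assert sig_above == set()  # z just below threshold -> discarded
        _, sig_at = t.permutation_z(
            aln, truth.group_of, n_permutations=500, z_threshold=float(z[c]), rng_seed=2
        )
        assert c not in sig_at  # strictly-greater comparison

    def test_false_site_rate_under_pure_noise(self):
        """Across 10 seeds x 50 noise-only columns (500 columns), at most 2
        survive the full z>3 + disjunctness filter."""
        false_sites = 0
        for seed in range(10):
            aln, truth = t.generate_pushpull_alignment(8, 8, 0, 50, 0, 0.1, rng_seed=seed)
            z, sig = t.permutation_z(aln, truth.group_of, n_permutations=300,
                                     rng_seed=seed + 100)
            disjunct, _ = t.disjunct_sites(aln, truth.group_of, sig)
            false_sites += len(disjunct)
        assert false_sites <= 2


class TestDisjunctness:
    def _aln(self):
        ids = ["p0", "p1", "p2", "l0", "l1", "l2"]
        #          col0: {A,S} vs {G,T}; col1: {A,S} vs {A,T}
        rows = ["AA", "AS", "SA", "GA", "GT", "TA"]
        labels = {i: ("push" if i.startswith("p") else "pull") for i in ids}
        return t.Alignment(ids, rows), labels

    def test_disjoint_and_shared_residue_columns(self):
        aln, labels = self._aln()
        disjunct, sets = t.disjunct_sites(aln, labels, {0, 1})
        assert disjunct == {0}
        assert sets[0] == (frozenset("AS"), frozenset("GT"))

    def test_only_significant_columns_considered(self):
        aln, labels = self._aln()
        disjunct, _ = t.disjunct_sites(aln, labels, set())
        assert disjunct == set()

    def test_gap_counts_as_symbol_for_disjointness(self):
        aln = t.Alignment(["p0", "p1", "l0", "l1"], ["A", "-", "G", "G"])
        labels = {"p0": "push", "p1": "push", "l0": "pull", "l1": "pull"}
        disjunct, sets = t.disjunct_sites(aln, labels, {0})
        assert disjunct == {0} and sets[0][0] == frozenset("A-")


class TestQueryCalls:
    def test_pull_query_and_unknown_residue(self, pushpull_default):
        aln, truth = pushpull_default
        report = t.analyse(aln, truth.group_of, n_permutations=300, rng_seed=4)
        assert report.query_calls
        assert all(q.call == "pull" for q in report.query_calls.values())
        for q in report.query_calls.values():
            assert set(q.votes.values()) == {"pull"}

    def test_residue_outside_both_sets_votes_neither(self):
        sets = {0: (frozenset("A"), frozenset("G"))}
        aln = t.Alignment(["q"], ["W"])
        calls = t.classify_queries(aln, {}, {0}, sets, ["q"])
        assert calls["q"].votes[0] == "neither"
        assert calls["q"].call == "ambiguous"

    def test_gap_at_disjunct_site_votes_neither(self):
        sets = {0: (frozenset("A"), frozenset("G"))}
        aln = t.Alignment(["q"], ["-"])
        calls = t.classify_queries(aln, {}, {0}, sets, ["q"])
        assert calls["q"].votes[0] == "neither"


def test_label_swap_antisymmetry(pushpull_default):
    """Swapping push/pull labels leaves mr, z, and site sets unchanged and
    swaps the query calls."""
    aln, truth = pushpull_default
    swapped = {
        k: {"push": "pull", "pull": "push"}.get(v, v) for k, v in truth.group_of.items()
    }
    r1 = t.analyse(aln, truth.group_of, n_permutations=300, rng_seed=7)
    r2 = t.analyse(aln, swapped, n_permutations=300, rng_seed=7)
    np.testing.assert_allclose(
        [c.mr_score for c in r1.columns], [c.mr_score for c in r2.columns], atol=1e-12
    )
    assert r1.disjunct_sites == r2.disjunct_sites
    assert r1.significant_sites == r2.significant_sites
    swap = {"push": "pull", "pull": "push", "ambiguous": "ambiguous"}
    for qid, call in r1.query_calls.items():
        assert r2.query_calls[qid].call == swap[call.call]


def test_planted_sites_recovered_with_full_precision(pushpull_default):
    aln, truth = pushpull_default
    report = t.analyse(aln, truth.group_of, n_permutations=1000, rng_seed=3)
    planted = {c for c, _, _ in truth.disjunct_columns}
    assert set(report.disjunct_sites) == planted
    assert len(report.disjunct_sites) == 17
    assert set(report.disjunct_sites) <= set(report.significant_sites)


def test_report_tsv_round_trip(tmp_path, pushpull_default):
    aln, truth = pushpull_default
    report = t.analyse(aln, truth.group_of, n_permutations=200, rng_seed=3)
    report.to_tsv(tmp_path / "spec.tsv")
    report.calls_to_tsv(tmp_path / "calls.tsv")
    lines = (tmp_path / "spec.tsv").read_text().splitlines()
    assert len(lines) == aln.n_cols + 2  # metadata + header + columns
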