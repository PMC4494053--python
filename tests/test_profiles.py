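"""Profile building, Viterbi scoring vs exhaustive enumeration, Gumbel
calibration, E-values, iterative search and TM seed extraction."""
import math

import numpy as np
import pytest

import trpscan as t
from trpscan.profiles import (
    CalibrationError,
    ProfileError,
    _encode_ungapped,
    _log_odds_tables,
    M, I, D,
    predict_tm_helices,
    score_only,
)


def brute_force_score(model, seq):
    """Independent oracle: enumerate every local path (entry at any match
    state, exit at any match state) and return the best bit score."""
    idx = _encode_ungapped(seq, "oracle")
    lm, li, lt = _log_odds_tables(model)
    L, n = model.consensus_length, len(seq)
    best = [-math.inf]

    def extend(score, i, j, state):
        if state == "M":
            best[0] = max(best[0], score)
        tr = lt[j]
        if state in ("M", "I"):
            s = M if state == "M" else I
            if j < L and i < n:
                extend(score + tr[s, M] + lm[j, idx[i]], i + 1, j + 1, "M")
            if state == "M" and j < L:
                extend(score + tr[M, D], i, j + 1, "D")
            if i < n:
                extend(score + tr[s, I] + li[idx[i]], i + 1, j, "I")
        else:
            if j < L and i < n:
                extend(score + tr[D, M] + lm[j, idx[i]], i + 1, j + 1, "M")
            if j < L:
                extend(score + tr[D, D], i, j + 1, "D")

    for s in range(n):
        for c in range(L):
            extend(lm[c, idx[s]], s + 1, c + 1, "M")
    return best[0]


def test_pseudocount_emission_hand_value():
    aln = t.Alignment(["a", "b", "c"], ["A", "A", "A"])
    model = t.build_profile(aln, pseudocount_weight=2.0)
    assert model.match_emissions[0, 0] == pytest.approx((3 + 2 * 0.05) / 5)  # 0.62


def test_zero_pseudocount_identical_column_is_certain():
    aln = t.Alignment(["a", "b"], ["AC", "AC"])
    model = t.build_profile(aln, pseudocount_weight=0.0)
    assert model.match_emissions[0, 0] == 1.0
    assert model.match_emissions[1, 1] == 1.0


def test_consensus_length_counts_low_gap_columns():
    aln = t.Alignment(["a", "b"], ["ACDEFGHIKL", "ACDEFGHIKL"])
    assert t.build_profile(aln).consensus_length == 10
    gappy = t.Alignment(["a", "b", "c"], ["AC-", "A--", "AC-"])  # col3 all gap
    assert t.build_profile(gappy).consensus_length == 2


def test_empty_or_all_gap_alignment_rejected():
    with pytest.raises(Exception):
        t.build_profile(t.Alignment([], []))
    with pytest.raises(ProfileError):
        t.build_profile(t.Alignment(["a", "b", "c"], ["-", "-", "A"]))


def test_emissions_normalised_after_build(default_superfamily):
    cfg, records, truth = default_superfamily
    aln = t.channel_alignment(records, truth)
    model = t.build_profile(aln)
    model.check_normalised()


def test_viterbi_matches_exhaustive_enumeration():
    """Score symmetry oracle: on models with <=3 match columns and sequences
    of length <=4, the DP equals brute-force path enumeration."""
    rng = np.random.default_rng(42)
    aas = list(t.AMINO_ACIDS)
    for _ in range(40):
        L = int(rng.integers(1, 4))
        n = int(rng.integers(1, 5))
        rows = ["".join(rng.choice(aas, size=L)) for _ in range(3)]
        model = t.build_profile(t.Alignment(["a", "b", "c"], rows), pseudocount_weight=2.0)
        seq = "".join(rng.choice(aas, size=n))
        hit = t.score_sequence(model, seq)
        assert hit.bit_score == pytest.approx(brute_force_score(model, seq), abs=1e-9)


def test_two_column_toy_model_hand_score():
    """2-match-column model, gapless 2-residue sequence: the optimal path is
    M1->M2 and its log-odds is checkable by hand."""
    aln = t.Alignment(["a", "b"], ["AC", "AC"])
    model = t.build_profile(aln, pseudocount_weight=2.0)
    # emissions: (2 + 2*0.05)/(2+2) = 0.525 for the consensus residue
    e = (2 + 2 * 0.05) / 4
    # transitions observed: begin->M (2), M->M (2), M->end (2); w/3 pseudo
    tmm = (2 + 2 / 3) / 4
    expected = math.log2(e / 0.05) * 2 + math.log2(tmm)
    hit = t.score_sequence(model, "AC")
    assert hit.bit_score == pytest.approx(expected, abs=1e-12)
    assert (hit.envelope_start, hit.envelope_end) == (1, 2)
    assert hit.model_cols_matched == 2


def test_consensus_scores_positive_and_beats_reversal(default_superfamily):
    cfg, records, truth = default_superfamily
    aln = t.channel_alignment(records, truth)
    model = t.build_profile(aln.subset(range(10)))
    consensus = model.consensus
    s_fwd = t.score_sequence(model, consensus).bit_score
    s_rev = t.score_sequence(model, consensus[::-1]).bit_score
    assert s_fwd > 0
    assert s_fwd > s_rev


def test_score_rejects_non_amino_acid_symbols():
    model = t.build_profile(t.Alignment(["a"], ["ACDE"]))
    with pytest.raises(ProfileError, match="X"):
        t.score_sequence(model, "ACXDE")


def test_calibration_recovers_known_gumbel():
    """Method-of-moments fit on samples drawn from Gumbel(mu=5, lambda=0.7)."""
    rng = np.random.default_rng(7)
    sample = rng.gumbel(loc=5.0, scale=1 / 0.7, size=5000)
    sd = sample.std(ddof=1)
    lam = math.pi / (sd * math.sqrt(6))
    mu = sample.mean() - np.euler_gamma / lam
    assert lam == pytest.approx(0.7, rel=0.10)
    assert mu == pytest.approx(5.0, rel=0.10)


@pytest.fixture()
def toy_model():
    aln = t.Alignment(["a", "b", "c"], ["ACDEFGHIKL", "ACDEFGHIKL", "ACDEWGHIKL"])
    return t.build_profile(aln, name="toy")


def test_calibration_is_seed_deterministic(toy_model):
    c1 = t.calibrate(toy_model, n_samples=150, rng_seed=5)
    c2 = t.calibrate(toy_model, n_samples=150, rng_seed=5)
    assert (c1.mu, c1.lam) == (c2.mu, c2.lam)


def test_more_samples_tighten_mu_spread(toy_model):
    spreads = {}
    for n in (100, 900):
        mus = [t.calibrate(toy_model, n_samples=n, rng_seed=s).mu for s in range(6)]
        spreads[n] = np.std(mus)
    assert spreads[900] < spreads[100]


def test_calibration_rejects_small_or_degenerate_samples(toy_model):
    with pytest.raises(CalibrationError):
        t.calibrate(toy_model, n_samples=50, rng_seed=1)


def test_evalue_linearity_and_location(toy_model):
    t.calibrate(toy_model, n_samples=200, rng_seed=11)
    mu = toy_model.calibration.mu
    assert t.evalue(toy_model, 30.0, 2000) == pytest.approx(
        2 * t.evalue(toy_model, 30.0, 1000)
    )
    assert t.evalue(toy_model, mu, 500) == pytest.approx(500.0)
    assert t.evalue(toy_model, 1e6, 500) == 0.0
    bits = np.linspace(0, 60, 7)
    evs = [t.evalue(toy_model, b, 100) for b in bits]
    assert all(a >= b for a, b in zip(evs, evs[1:]))


def test_evalue_requires_calibration():
    model = t.build_profile(t.Alignment(["a"], ["ACDE"]))
    with pytest.raises(CalibrationError):
        t.evalue(model, 10.0, 100)


@pytest.fixture(scope="module")
def family_db():
    cfg = t.SyntheticConfig(
        rng_seed=7, n_subfamilies=1, seqs_per_subfamily=30,
        n_decoys=300, ankyrin_repeat_count={},
    )
    records, truth = t.generate_superfamily(cfg)
    fam = [r for r in records if truth.family_of[r.id] != "decoy"]
    return records, {r.id for r in fam}, fam[0]


class TestIterativeSearch:
    def test_planted_family_recovered_without_decoys(self, family_db):
        records, fam_ids, query = family_db
        included, model = t.iterative_search(records[0], records, rng_seed=3)
        assert included == fam_ids
        model.check_normalised()

    def test_query_always_included_even_at_impossible_threshold(self, family_db):
        records, _, query = family_db
        included, _ = t.iterative_search(
            query, records[:40], max_iterations=1, inclusion_evalue=0.0, rng_seed=3
        )
        assert included == {query.id}

    def test_shrinking_threshold_never_grows_iteration_one(self, family_db):
        records, _, query = family_db
        sizes = []
        for thr in (1e-5, 1e-20, 1e-40):
            inc, _ = t.iterative_search(
                query, records[:60], max_iterations=1, inclusion_evalue=thr, rng_seed=3
            )
            sizes.append(len(inc))
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_database_rejected(self, family_db):
        _, _, query = family_db
        with pytest.raises(ProfileError):
            t.iterative_search(query, [], rng_seed=0)


class TestTmExtraction:
    def test_flank_arithmetic_and_clipping(self):
        rng = np.random.default_rng(3)
        polar = "".join(rng.choice(list("DENQKRST"), size=300))
        seq = polar[:99] + "I" * 61 + polar[160:]
        region = t.extract_tm_region(seq, flank=20)
        helices = predict_tm_helices(seq)
        assert helices, "expected a helix in the hydrophobic stretch"
        assert region.start == max(1, helices[0][0] - 20)
        assert region.end == min(len(seq), helices[-1][1] + 20)
        # helix near the N-terminus clips to 1
        seq2 = "I" * 40 + polar[:200]
        region2 = t.extract_tm_region(seq2, flank=20)
        assert region2.start == 1

    def test_hydrophobic_stretch_detected_all_polar_is_not(self):
        rng = np.random.default_rng(4)
        polar = "".join(rng.choice(list("DENQKRST"), size=120))
        with_tm = polar[:50] + "I" * 30 + polar[50:]
        assert predict_tm_helices(with_tm) != []
        assert t.extract_tm_region("D" * 100) is None  # "no TM region" signal

    def test_flank_25_variant_available(self):
        seq = "D" * 60 + "L" * 30 + "D" * 60
        r20 = t.extract_tm_region(seq, flank=20)
        r25 = t.extract_tm_region(seq, flank=25)
        assert r25.start == r20.start - 5 and r25.end == r20.end + 5


def test_model_serialisation_round_trip(tmp_path, unit_model):
    p = tmp_path / "models.jsonl"
    t.save_models([unit_model], p)
    loaded = t.load_models(p)[0]
    assert loaded.name == unit_model.name
    np.testing.assert_allclose(loaded.match_emissions, unit_model.match_emissions)
    np.testing.assert_allclose(loaded.transitions, unit_model.transitions)
    assert loaded.calibration.mu == unit_model.calibration.mu
    s1 = t.score_sequence(unit_model, "ACDEFGHIKLMNPQRSTVWY").bit_score
    s2 = t.score_sequence(loaded, "ACDEFGHIKLMNPQRSTVWY").bit_score
    assert s1 == pytest.approx(s2)
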