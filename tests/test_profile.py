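"""Profile construction, local DP scoring and Gumbel E-value calibration."""
import numpy as np
import pytest

from pqloop.composition import AA_INDEX, BACKGROUND_FREQS
from pqloop.profile import (
    Profile,
    ProfileError,
    align_profiles,
    background_sequence_sampler,
    build_profile,
    calibrate,
    evalue,
    profile_from_json,
    profile_to_json,
    score_sequence,
)
from pqloop.seq_io import Alignment, SequenceRecord
from pqloop.synthetic import FamilySpec, make_ancestor


def test_single_sequence_zero_pseudocount_gives_unit_columns():
    p = build_profile(Alignment([SequenceRecord("a", "ACD")]), pseudocount_weight=0.0)
    expected = np.zeros((3, 20))
    for i, c in enumerate("ACD"):
        expected[i, AA_INDEX[c]] = 1.0
    assert np.allclose(p.emissions, expected)


def test_duplicated_row_equals_single_row_profile():
    one = build_profile(Alignment([SequenceRecord("a", "ACDKL")]))
    two = build_profile(Alignment([SequenceRecord("a", "ACDKL"),
                                   SequenceRecord("b", "ACDKL")]))
    assert np.allclose(one.emissions, two.emissions)


def test_three_row_toy_emission_matches_hand_count():
    """AAC / A-C / AGC with pseudocount 1: column 1 re-derived by hand.

    Position-based weights over match columns (col0: A×3 -> 1/3 each;
    col1: A,-,G -> 1/2, 0, 1/2; col2: C×3 -> 1/3 each) give raw weights
    (7/6, 2/3, 7/6), normalised to (7/18, 4/18, 7/18).  Column 1 residues:
    A (7/18), G (7/18) -> frequencies 1/2 each; with n_eff = 3 distinct
    rows and background pseudocount weight 1 the emission is
    (3·freq + bg) / 4.
    """
    msa = Alignment([SequenceRecord("r1", "AAC"), SequenceRecord("r2", "A-C"),
                     SequenceRecord("r3", "AGC")])
    p = build_profile(msa, pseudocount_weight=1.0)
    expected = (3.0 * 0.5 + BACKGROUND_FREQS[AA_INDEX["A"]]) / 4.0
    assert p.emissions[1, AA_INDEX["A"]] == pytest.approx(expected, abs=1e-12)
    expected_g = (3.0 * 0.5 + BACKGROUND_FREQS[AA_INDEX["G"]]) / 4.0
    assert p.emissions[1, AA_INDEX["G"]] == pytest.approx(expected_g, abs=1e-12)
    assert np.allclose(p.emissions.sum(axis=1), 1.0, atol=1e-9)


def test_all_gappy_alignment_is_an_error():
    msa = Alignment([SequenceRecord("a", "A---"), SequenceRecord("b", "-C--"),
                     SequenceRecord("c", "--D-"), SequenceRecord("d", "---E")])
    with pytest.raises(ProfileError, match="no match columns"):
        build_profile(msa)


def test_tm_annotation_maps_through_match_columns():
    msa = Alignment([SequenceRecord("a", "AAC-DEF"), SequenceRecord("b", "AAC-DEF"),
                     SequenceRecord("c", "AACKDEF")])
    p = build_profile(msa, tm_annotation=[(0, 3), (4, 7)])
    # column 3 is 2/3 gaps -> dropped; spans re-indexed over 6 match columns
    assert p.ncols == 6
    assert p.tm_segments == [(0, 3), (3, 6)]


def test_self_score_equals_log_odds_sum():
    anc, _ = make_ancestor(FamilySpec(seed=2))
    p = build_profile(Alignment([anc]))
    res = score_sequence(p, anc)
    expected = sum(p.log_odds[i, AA_INDEX[c]] for i, c in enumerate(anc.residues))
    assert res.score_bits == pytest.approx(expected, abs=1e-6)
    assert res.query_span == (0, p.ncols)
    assert res.target_span == (0, len(anc.residues))


def test_all_x_sequence_scores_zero_with_empty_span():
    p = build_profile(Alignment([SequenceRecord("a", "ACDEFGHIKL")]))
    res = score_sequence(p, SequenceRecord("x", "XXXXXX"))
    assert res.score_bits == 0.0
    assert res.pairs == []


def test_shuffled_sequence_scores_below_intact():
    anc, _ = make_ancestor(FamilySpec(seed=3))
    p = build_profile(Alignment([anc]))
    base = score_sequence(p, anc).score_bits
    rng = np.random.default_rng(0)
    worse = sum(
        score_sequence(p, SequenceRecord("s", "".join(rng.permutation(list(anc.residues))))).score_bits < base
        for _ in range(100)
    )
    assert worse >= 99


def test_profile_self_alignment_is_identity_pairing():
    anc, _ = make_ancestor(FamilySpec(seed=4))
    p = build_profile(Alignment([anc]))
    res = align_profiles(p, p)
    assert res.pairs == [(i, i) for i in range(p.ncols)]


def test_disjoint_profiles_align_degenerately():
    a = build_profile(Alignment([SequenceRecord("x", "AAAA")]), 0.0)
    b = build_profile(Alignment([SequenceRecord("y", "CCCC")]), 0.0)
    res = align_profiles(a, b)
    assert res.score_bits <= 0.0
    assert res.pairs == []


@pytest.mark.parametrize("seed_pair", [(5, 6), (7, 8), (9, 10)])
def test_profile_alignment_score_symmetry(seed_pair):
    profiles = []
    for s in seed_pair:
        anc, _ = make_ancestor(FamilySpec(seed=s))
        profiles.append(build_profile(Alignment([anc])))
    ab = align_profiles(profiles[0], profiles[1]).score_bits
    ba = align_profiles(profiles[1], profiles[0]).score_bits
    assert ab == pytest.approx(ba, abs=1e-6)


def test_calibration_determinism_and_evalue_monotonicity():
    anc, _ = make_ancestor(FamilySpec(seed=5))
    p = build_profile(Alignment([anc]))
    sampler = background_sequence_sampler([120, 150, 180])
    c1 = calibrate(p, sampler, n_null=120, database_size=200, seed=42)
    c2 = calibrate(p, sampler, n_null=120, database_size=200, seed=42)
    assert (c1.mu, c1.lam) == (c2.mu, c2.lam)
    scores = np.linspace(c1.mu - 5, c1.mu + 60, 30)
    es = [evalue(c1, s) for s in scores]
    assert all(a >= b for a, b in zip(es, es[1:]))
    assert evalue(c1, c1.mu) == pytest.approx(200.0)
    assert evalue(c1, 1e4) == pytest.approx(0.0)


def test_evalue_calibration_matches_fresh_null_frequencies():
    """P(E <= e0) on fresh null draws ~= e0/N within 3-sigma binomial."""
    rng_profile, _ = make_ancestor(FamilySpec(seed=6, n_helices=2, c_term_len=5,
                                              loop_len_range=(3, 8),
                                              duplication=False, motif_spec=(),
                                              conserved_cols=()))
    p = build_profile(Alignment([rng_profile]))
    sampler = background_sequence_sampler([60, 80])
    cal = calibrate(p, sampler, n_null=400, database_size=100, seed=1)
    from pqloop.profile import _score_only, encode_sequence
    rng = np.random.default_rng(99)
    n = 2000
    fresh = np.array([
        _score_only(p.log_odds[:, encode_sequence(sampler(rng).residues)],
                    p.gap_open, p.gap_extend)
        for _ in range(n)
    ])
    for e0_over_n in (0.02, 0.05, 0.1):
        e0 = e0_over_n * cal.database_size
        threshold = cal.mu - np.log(e0 / cal.database_size) / cal.lam
        observed = float((fresh >= threshold).mean())
        sigma = np.sqrt(e0_over_n * (1 - e0_over_n) / n)
        assert abs(observed - e0_over_n) <= 3 * sigma + 1e-9


def test_profile_json_round_trip():
    anc, truth = make_ancestor(FamilySpec(seed=7))
    p = build_profile(Alignment([anc]), tm_annotation=truth.tm_spans)
    q = profile_from_json(profile_to_json(p))
    assert np.allclose(p.emissions, q.emissions)
    assert q.tm_segments == p.tm_segments
    assert q.gap_open == p.gap_open
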