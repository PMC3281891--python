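"""Generator correctness: architecture, truth bookkeeping, divergence behavior."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pqloop.composition import KYTE_DOOLITTLE
from pqloop.synthetic import (
    FamilySpec,
    SpecError,
    evolve_family,
    make_ancestor,
    make_decoys,
    make_family,
    make_half_proteins,
    make_proteome,
)


def mean_kd(seq: str) -> float:
    return float(np.mean([KYTE_DOOLITTLE[c] for c in seq]))


def test_ancestor_architecture_and_planted_features():
    anc, truth = make_ancestor(FamilySpec(seed=1))
    assert len(truth.tm_spans) == 7
    ends = [e for _, e in truth.tm_spans]
    starts = [s for s, _ in truth.tm_spans]
    assert all(e <= s2 for e, s2 in zip(ends, starts[1:]))
    for s, e in truth.motif_spans:
        assert anc.residues[s:e] == "PQ"
    classes = {c for _, c in truth.conserved_positions}
    assert classes == {"basic", "serine"}
    for p, klass in truth.conserved_positions:
        assert anc.residues[p] == {"basic": "R", "serine": "S"}[klass]


def test_zero_divergence_duplication_halves_identical():
    spec = FamilySpec(divergence=0.0, duplication=True, seed=3)
    anc, truth = make_ancestor(spec)
    n_region = (truth.tm_spans[0][0], truth.tm_spans[2][1])
    c_region = (truth.tm_spans[4][0], truth.tm_spans[6][1])
    planted = {p for p, _ in truth.conserved_positions}
    for span in truth.motif_spans:
        planted |= set(range(*span))
    n_seq = anc.residues[n_region[0]:n_region[1]]
    c_seq = anc.residues[c_region[0]:c_region[1]]
    assert len(n_seq) == len(c_seq)
    for k, (x, y) in enumerate(zip(n_seq, c_seq)):
        if (n_region[0] + k) in planted or (c_region[0] + k) in planted:
            continue
        assert x == y


def test_helices_more_hydrophobic_than_loops_over_seeds():
    diffs = []
    for s in range(1, 101):
        anc, truth = make_ancestor(FamilySpec(seed=s))
        tm = "".join(anc.residues[a:b] for a, b in truth.tm_spans)
        loops = "".join(anc.residues[a:b] for a, b in truth.loop_spans)
        diffs.append(mean_kd(tm) - mean_kd(loops))
    assert np.mean(diffs) > 1.5
    assert min(diffs) > 0


def test_zero_divergence_members_identical_to_ancestor():
    spec = FamilySpec(divergence=0.0, seed=5, n_members=5)
    anc, truth = make_ancestor(spec)
    members, _ = evolve_family(anc, truth, spec)
    assert all(m.residues == anc.residues for m in members)


def test_helix_identity_exceeds_loop_identity():
    spec = FamilySpec(seed=7)
    anc, members, truth = make_family(spec)
    helix = np.zeros(truth.ancestor_length, dtype=bool)
    for a, b in truth.tm_spans:
        helix[a:b] = True
    loop = ~helix
    h_match = h_tot = l_match = l_tot = 0
    ids = [m.id for m in members]
    res = {m.id: m.residues for m in members}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            mi, mj = truth.members[ids[i]], truth.members[ids[j]]
            both = (mi.coord_map >= 0) & (mj.coord_map >= 0)
            ri = np.array(list(res[ids[i]]))
            rj = np.array(list(res[ids[j]]))
            eq = ri[mi.coord_map[both]] == rj[mj.coord_map[both]]
            h_match += eq[helix[both]].sum(); h_tot += helix[both].sum()
            l_match += eq[loop[both]].sum(); l_tot += loop[both].sum()
    assert h_match / h_tot > l_match / l_tot


def test_planted_pq_verbatim_in_most_members():
    carried = total = 0
    for s in range(1, 101):
        anc, members, truth = make_family(FamilySpec(seed=s, n_members=10))
        for m in members:
            for span in truth.motif_spans:
                ms = truth.member_span(m.id, span)
                total += 1
                carried += m.residues[ms[0]:ms[1]] == "PQ"
    assert carried / total >= 0.9


def test_divergence_monotonicity_of_identity():
    def mean_identity(divergence):
        vals = []
        for s in range(1, 21):
            spec = FamilySpec(seed=s, divergence=divergence, n_members=6)
            anc, members, truth = make_family(spec)
            ident = []
            for m in members:
                cm = truth.members[m.id].coord_map
                kept = cm >= 0
                arr = np.array(list(m.residues))
                anc_arr = np.array(list(anc.residues))
                ident.append(float((arr[cm[kept]] == anc_arr[kept]).mean()))
            vals.append(np.mean(ident))
        return np.mean(vals)

    i02, i05, i08 = (mean_identity(d) for d in (0.2, 0.5, 0.8))
    assert i02 > i05 > i08


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10**6))
def test_truth_spans_consistent_with_members(seed):
    anc, members, truth = make_family(FamilySpec(seed=seed, n_members=4))
    for m in members:
        spans = truth.member_tm_spans(m.id)
        assert len(spans) == 7
        prev_end = 0
        for s, e in spans:
            assert 0 <= s < e <= len(m.residues)
            assert s >= prev_end
            prev_end = e


def test_motif_longer_than_loop_is_spec_error():
    with pytest.raises(SpecError, match="motif"):
        FamilySpec(motif_spec=((1, "PQRSTVW"),), loop_len_range=(3, 19))


def test_decoys_counts_lengths_and_empty():
    decoys = make_decoys(100, (150, 300), kind="random", seed=2)
    assert len(decoys) == 100
    assert all(150 <= len(d.residues) <= 300 for d in decoys)
    assert make_decoys(0, (100, 200)) == []


def test_half_proteins_truth_and_length():
    spec = FamilySpec(seed=4)
    anc, _ = make_ancestor(spec)
    members, truth = make_half_proteins(spec, 8, seed=9)
    assert len(members) == 8
    for m in members:
        assert len(truth.member_tm_spans(m.id)) == 3
        assert len(m.residues) < len(anc.residues)


def test_proteome_partition_and_determinism():
    specs = [FamilySpec(seed=0)]
    records, truth = make_proteome(specs, n_decoys=200, n_half_proteins=0, seed=3)
    assert len(records) == 220
    fams = truth.ids_in("family:fam0")
    decs = truth.ids_in("decoy")
    assert len(fams) == 20 and len(decs) == 200
    assert fams | decs == {r.id for r in records}
    assert not (fams & decs)
    records2, _ = make_proteome(specs, n_decoys=200, n_half_proteins=0, seed=3)
    assert [(r.id, r.residues) for r in records] == [(r.id, r.residues) for r in records2]
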