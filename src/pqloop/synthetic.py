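"""Synthetic membrane-protein family generator with complete ground truth.

Families emulate the architecture of 7-TM cargo-receptor-like proteins: a
single-residue lumenal N-terminus, seven hydrophobic helices of 21 residues
joined by short loops (< 20 residues), and a ~15-residue cytoplasmic
C-terminus.  The C-terminal three-helix block can be generated as a diverged
copy of the N-terminal block (internal duplication), PQ doublets are planted
in the loops after helices 1 and 5, and near-invariant basic/serine columns
are planted inside helices.  Members of a family evolve from the ancestor by
star-phylogeny substitutions (hydrophobicity-preserving inside helices) and
loop-only indels; every feature coordinate is recorded in a FamilyTruth
object so that downstream stages can be scored against known truth.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .composition import AA_INDEX, AMINO_ACIDS, BACKGROUND_FREQS, HELIX_FREQS, KD_VECTOR
from .seq_io import Alignment, SequenceRecord

logger = logging.getLogger(__name__)

_AA = np.array(list(AMINO_ACIDS))

CLASS_RESIDUE = {"basic": "R", "serine": "S"}


class SpecError(ValueError):
    """Inconsistent family specification (e.g. motif longer than its loop)."""


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic family.

    ``motif_spec`` entries are ``(loop_index, motif)`` or
    ``(loop_index, motif, rate_multiplier)`` where loop *i* is the loop
    following helix *i* (1-based).  ``conserved_cols`` entries are
    ``(region, index, residue_class)`` with region ``"helix"`` (planted at
    the helix midpoint) or ``"loop"`` (planted at the last loop position,
    i.e. the membrane interface, where conserved charged residues sit in
    real polytopic membrane proteins); classes are ``basic`` (R) and
    ``serine`` (S).
    """

    n_helices: int = 7
    helix_len: int = 21
    loop_len_range: tuple[int, int] = (3, 19)
    n_term_len: int = 1
    c_term_len: int = 15
    duplication: bool = True
    motif_spec: tuple = ((1, "PQ"), (5, "PQ"))
    conserved_cols: tuple = (("loop", 1, "basic"), ("loop", 5, "basic"),
                             ("helix", 4, "serine"))
    n_members: int = 20
    divergence: float = 0.5
    loop_rate_factor: float = 1.5
    conserved_rate_factor: float = 0.05
    indel_rate: float = 0.01
    min_helix_kd: float = 3.0   # mean Kyte-Doolittle floor for ancestral helices
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_helices < 1:
            raise SpecError("n_helices must be >= 1")
        if self.divergence < 0:
            raise SpecError("divergence must be >= 0")
        if self.loop_len_range[0] < 1 or self.loop_len_range[1] < self.loop_len_range[0]:
            raise SpecError("invalid loop_len_range")
        for entry in self.motif_spec:
            loop_idx, motif = entry[0], entry[1]
            if not 1 <= loop_idx <= self.n_helices - 1:
                raise SpecError(f"motif loop index {loop_idx} out of range")
            if len(motif) > self.loop_len_range[0]:
                raise SpecError(
                    f"motif {motif!r} may exceed the shortest allowed loop "
                    f"({self.loop_len_range[0]} residues)"
                )
        for region, idx, klass in self.conserved_cols:
            if region not in ("helix", "loop"):
                raise SpecError(f"unknown conserved-column region {region!r}")
            upper = self.n_helices if region == "helix" else self.n_helices - 1
            if not 1 <= idx <= upper:
                raise SpecError(f"conserved column {region} index {idx} out of range")
            if klass not in CLASS_RESIDUE:
                raise SpecError(f"unknown residue class {klass!r}")


@dataclass
class MemberTruth:
    """Mapping from the ancestral coordinate frame to one member."""

    coord_map: np.ndarray           # ancestral position -> member position (-1 deleted)
    insertions: dict[int, str]      # junction j (before ancestral pos j) -> residues
    length: int


@dataclass
class FamilyTruth:
    """Generator-emitted ground truth for one family."""

    family_id: str
    ancestor_length: int
    tm_spans: list[tuple[int, int]]
    loop_spans: list[tuple[int, int]]            # loop i (after helix i+1... 0-based list)
    term_spans: tuple[tuple[int, int], tuple[int, int]]
    motif_spans: list[tuple[int, int]]
    conserved_positions: list[tuple[int, str]]   # (ancestral position, residue class)
    duplication: bool
    n_side: str = "lumen"
    members: dict[str, MemberTruth] = field(default_factory=dict)

    def member_span(self, member_id: str, span: tuple[int, int]) -> tuple[int, int] | None:
        """Map an ancestral (start, end) span into member coordinates."""
        cm = self.members[member_id].coord_map[span[0] : span[1]]
        kept = cm[cm >= 0]
        if kept.size == 0:
            return None
        return int(kept[0]), int(kept[-1]) + 1

    def member_tm_spans(self, member_id: str) -> list[tuple[int, int]]:
        out = []
        for span in self.tm_spans:
            m = self.member_span(member_id, span)
            if m is not None:
                out.append(m)
        return out

    def induced_alignment(self, records: Sequence[SequenceRecord]) -> Alignment:
        """Build the by-construction alignment of ``records`` (a subset of the
        family members), with insert columns for member-specific insertions and
        ``tm_segments`` set in alignment-column coordinates."""
        members = [self.members[r.id] for r in records]
        L = self.ancestor_length
        widths = np.zeros(L + 1, dtype=int)
        for mt in members:
            for j, ins in mt.insertions.items():
                widths[j] = max(widths[j], len(ins))
        # column index of ancestral position p
        col_of = np.cumsum(widths[:-1]) + np.arange(L)
        rows = []
        for rec, mt in zip(records, members):
            parts = []
            for j in range(L):
                ins = mt.insertions.get(j, "")
                parts.append(ins.ljust(widths[j], "-"))
                p = mt.coord_map[j]
                parts.append(rec.residues[p] if p >= 0 else "-")
            parts.append(mt.insertions.get(L, "").ljust(widths[L], "-"))
            rows.append(SequenceRecord(rec.id, "".join(parts), rec.description))
        tm_cols = [(int(col_of[s]), int(col_of[e - 1]) + 1) for s, e in self.tm_spans]
        return Alignment(rows, tm_segments=tm_cols)


# ---------------------------------------------------------------------------
# Ancestor construction
# ---------------------------------------------------------------------------

def _draw(rng: np.random.Generator, n: int, freqs: np.ndarray) -> str:
    return "".join(_AA[rng.choice(len(_AA), size=n, p=freqs)])


def _draw_helix(rng: np.random.Generator, n: int, min_kd: float) -> str:
    """Draw a helix from the hydrophobic composition, resampling until its
    mean Kyte-Doolittle value reaches ``min_kd``: a transmembrane helix must
    be hydrophobic enough to insert into the bilayer, so annotated TM
    segments do not carry the weak lower tail of a random composition."""
    seq = _draw(rng, n, HELIX_FREQS)
    for _ in range(500):
        if float(np.mean([KD_VECTOR[AA_INDEX[c]] for c in seq])) >= min_kd:
            return seq
        seq = _draw(rng, n, HELIX_FREQS)
    return seq


def _mutate_region(rng: np.random.Generator, seq: str, helix_mask: np.ndarray,
                   rate: float) -> str:
    """Apply expected ``rate`` substitutions/site with category-aware
    proposals (proposals may silently redraw the current residue, so the
    realised change rate is slightly below nominal)."""
    if rate <= 0:
        return seq
    chars = np.array(list(seq))
    hit = rng.random(len(seq)) < 1.0 - np.exp(-rate)
    for i in np.nonzero(hit)[0]:
        freqs = HELIX_FREQS if helix_mask[i] else BACKGROUND_FREQS
        chars[i] = _AA[rng.choice(len(_AA), p=freqs)]
    return "".join(chars)


def make_ancestor(spec: FamilySpec, family_id: str = "fam") -> tuple[SequenceRecord, FamilyTruth]:
    """Draw the family ancestor and its feature truth.

    Helices come from the hydrophobic-biased composition, loops and termini
    from background.  With ``spec.duplication`` the C-terminal half (helices
    n-k+1..n and their internal loops, k = n//2) is a diverged copy of the
    N-terminal half; motifs and conserved columns are overwritten afterwards.
    """
    rng = np.random.default_rng([spec.seed, 7])
    n = spec.n_helices
    k = n // 2
    lo, hi = spec.loop_len_range
    loop_lens = rng.integers(lo, hi + 1, size=max(n - 1, 0)).astype(int)
    if spec.duplication and n >= 4:
        # internal loops of the C block mirror those of the N block
        first_c_loop = n - k + 1      # 1-based loop index following helix n-k+1
        for offset in range(k - 1):
            loop_lens[first_c_loop - 1 + offset] = loop_lens[offset]

    # lay out segments
    segments: list[tuple[str, int, int]] = [("term", 0, spec.n_term_len)]
    for h in range(1, n + 1):
        segments.append(("helix", h, spec.helix_len))
        if h < n:
            segments.append(("loop", h, int(loop_lens[h - 1])))
    segments.append(("term", 1, spec.c_term_len))

    spans: dict[tuple[str, int], tuple[int, int]] = {}
    pos = 0
    for kind, idx, length in segments:
        spans[(kind, idx)] = (pos, pos + length)
        pos += length
    L = pos
    helix_mask = np.zeros(L, dtype=bool)
    for h in range(1, n + 1):
        s, e = spans[("helix", h)]
        helix_mask[s:e] = True

    chars = np.array(list(_draw(rng, L, BACKGROUND_FREQS)))
    for h in range(1, n + 1):
        s, e = spans[("helix", h)]
        chars[s:e] = list(_draw_helix(rng, e - s, spec.min_helix_kd))

    if spec.duplication and n >= 4:
        src = (spans[("helix", 1)][0], spans[("helix", k)][1])
        dst = (spans[("helix", n - k + 1)][0], spans[("helix", n)][1])
        assert dst[1] - dst[0] == src[1] - src[0]
        copied = _mutate_region(
            rng, "".join(chars[src[0] : src[1]]), helix_mask[src[0] : src[1]],
            spec.divergence,
        )
        chars[dst[0] : dst[1]] = list(copied)

    # plant motifs (loop-centred) and conserved columns (helix midpoints)
    motif_spans: list[tuple[int, int]] = []
    for entry in spec.motif_spec:
        loop_idx, motif = entry[0], entry[1]
        s, e = spans[("loop", loop_idx)]
        if e - s < len(motif):
            raise SpecError(f"motif {motif!r} longer than loop {loop_idx} ({e - s} aa)")
        start = s + (e - s - len(motif)) // 2
        chars[start : start + len(motif)] = list(motif)
        motif_spans.append((start, start + len(motif)))

    conserved_positions: list[tuple[int, str]] = []
    planted_cols = {c for span in motif_spans for c in range(*span)}
    for region, idx, klass in spec.conserved_cols:
        s, e = spans[(region, idx)]
        if region == "helix":
            p = (s + e) // 2
        else:
            # near the loop's C-terminal membrane interface, but kept a
            # couple of residues off the helix (a charged residue flush
            # against the helix would erode its hydropathy signal)
            p = e - 1
            for candidate in (e - 3, e - 2, e - 1):
                if s <= candidate < e and candidate not in planted_cols:
                    p = candidate
                    break
        if p in planted_cols:
            raise SpecError(f"conserved column at {p} collides with a motif")
        chars[p] = CLASS_RESIDUE[klass]
        conserved_positions.append((p, klass))
        planted_cols.add(p)

    truth = FamilyTruth(
        family_id=family_id,
        ancestor_length=L,
        tm_spans=[spans[("helix", h)] for h in range(1, n + 1)],
        loop_spans=[spans[("loop", h)] for h in range(1, n)],
        term_spans=(spans[("term", 0)], spans[("term", 1)]),
        motif_spans=motif_spans,
        conserved_positions=conserved_positions,
        duplication=bool(spec.duplication),
    )
    record = SequenceRecord(f"{family_id}_anc", "".join(chars), "synthetic ancestor")
    return record, truth


# ---------------------------------------------------------------------------
# Family evolution (star phylogeny)
# ---------------------------------------------------------------------------

def _site_rates(spec: FamilySpec, truth: FamilyTruth) -> np.ndarray:
    L = truth.ancestor_length
    helix = np.zeros(L, dtype=bool)
    for s, e in truth.tm_spans:
        helix[s:e] = True
    rate = np.where(helix, spec.divergence, spec.divergence * spec.loop_rate_factor)
    for i, entry in enumerate(spec.motif_spec):
        mult = entry[2] if len(entry) > 2 else spec.conserved_rate_factor
        if i < len(truth.motif_spans):
            s, e = truth.motif_spans[i]
            rate[s:e] = spec.divergence * spec.loop_rate_factor * mult
    for p, _klass in truth.conserved_positions:
        rate[p] = spec.divergence * spec.conserved_rate_factor
    return rate


def _protected_mask(truth: FamilyTruth) -> np.ndarray:
    """Sites excluded from indels: TM helices, motifs, conserved columns."""
    prot = np.zeros(truth.ancestor_length, dtype=bool)
    for s, e in truth.tm_spans:
        prot[s:e] = True
    for s, e in truth.motif_spans:
        prot[s:e] = True
    for p, _ in truth.conserved_positions:
        prot[p] = True
    return prot


def evolve_family(ancestor: SequenceRecord, truth: FamilyTruth, spec: FamilySpec,
                  seed: int | None = None) -> tuple[list[SequenceRecord], FamilyTruth]:
    """Evolve ``spec.n_members`` members from the ancestor on a star phylogeny.

    Helix sites substitute with a hydrophobicity-preserving proposal, loop and
    terminal sites with a background proposal; planted motif/conserved sites
    substitute at a reduced rate.  Indels (geometric length, mean 2) occur
    only outside helices and planted features, and only when divergence > 0.
    Per-member coordinate maps are recorded in the returned truth.
    """
    if spec.n_members < 1:
        raise SpecError("n_members must be >= 1")
    base = spec.seed if seed is None else seed
    L = truth.ancestor_length
    anc = np.array(list(ancestor.residues))
    rate = _site_rates(spec, truth)
    p_sub = 1.0 - np.exp(-rate)
    helix = np.zeros(L, dtype=bool)
    for s, e in truth.tm_spans:
        helix[s:e] = True
    eligible = ~_protected_mask(truth)
    elig_idx = np.nonzero(eligible)[0]
    indel_rate = spec.indel_rate if spec.divergence > 0 else 0.0

    members: list[SequenceRecord] = []
    truth.members = {}
    for m in range(spec.n_members):
        rng = np.random.default_rng([base, 101, m])
        chars = anc.copy()
        hit = rng.random(L) < p_sub
        hx = np.nonzero(hit & helix)[0]
        lx = np.nonzero(hit & ~helix)[0]
        if hx.size:
            chars[hx] = _AA[rng.choice(len(_AA), size=hx.size, p=HELIX_FREQS)]
        if lx.size:
            chars[lx] = _AA[rng.choice(len(_AA), size=lx.size, p=BACKGROUND_FREQS)]

        deleted = np.zeros(L, dtype=bool)
        insertions: dict[int, str] = {}
        if indel_rate > 0 and elig_idx.size:
            u = rng.random(elig_idx.size)
            for j in np.nonzero(u < indel_rate)[0]:
                pos = int(elig_idx[j])
                length = int(rng.geometric(0.5))
                if rng.random() < 0.5:
                    # deletion: stay inside the contiguous eligible block
                    q = pos
                    while q < L and q - pos < length and eligible[q]:
                        deleted[q] = True
                        q += 1
                else:
                    ins = _draw(rng, length, BACKGROUND_FREQS)
                    insertions[pos] = insertions.get(pos, "") + ins

        coord_map = np.full(L, -1, dtype=int)
        parts: list[str] = []
        cursor = 0
        for j in range(L):
            ins = insertions.get(j, "")
            if ins:
                parts.append(ins)
                cursor += len(ins)
            if not deleted[j]:
                parts.append(chars[j])
                coord_map[j] = cursor
                cursor += 1
        tail = insertions.get(L, "")
        if tail:
            parts.append(tail)
            cursor += len(tail)
        member_id = f"{truth.family_id}_m{m:02d}"
        members.append(SequenceRecord(member_id, "".join(parts), "synthetic member"))
        truth.members[member_id] = MemberTruth(coord_map, insertions, cursor)
    return members, truth


def make_family(spec: FamilySpec, family_id: str = "fam",
                seed: int | None = None) -> tuple[SequenceRecord, list[SequenceRecord], FamilyTruth]:
    """Convenience: ancestor + evolved members + truth."""
    anc, truth = make_ancestor(spec, family_id)
    members, truth = evolve_family(anc, truth, spec, seed=seed)
    return anc, members, truth


# ---------------------------------------------------------------------------
# Decoys and half-proteins
# ---------------------------------------------------------------------------

def make_decoys(n: int, length_range: tuple[int, int] = (150, 450),
                kind: str = "globular", k: int = 7, seed: int = 0) -> list[SequenceRecord]:
    """Negative set: ``globular`` (background composition), ``random``
    (uniform letters) or ``k_tm`` (same construction as families but drawn
    independently, hence no homology to any family)."""
    rng = np.random.default_rng([seed, 23])
    out: list[SequenceRecord] = []
    for i in range(n):
        name = f"decoy{i:03d}"
        if kind == "globular":
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            out.append(SequenceRecord(name, _draw(rng, length, BACKGROUND_FREQS), "decoy"))
        elif kind == "random":
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            uniform = np.full(len(_AA), 1.0 / len(_AA))
            out.append(SequenceRecord(name, _draw(rng, length, uniform), "decoy"))
        elif kind == "k_tm":
            sub = int(rng.integers(0, 2**31 - 1))
            dspec = FamilySpec(n_helices=k, duplication=False, motif_spec=(),
                               conserved_cols=(), n_members=1, seed=sub)
            anc, _ = make_ancestor(dspec, family_id=name)
            out.append(SequenceRecord(name, anc.residues, "tm decoy"))
        else:
            raise ValueError(f"unknown decoy kind {kind!r}")
    return out


def make_half_proteins(spec: FamilySpec, n: int, seed: int = 0, half: str = "N",
                       family_id: str = "half") -> tuple[list[SequenceRecord], FamilyTruth]:
    """Short proteins homologous to one half of the family architecture.

    The half-ancestor is the slice of the full family ancestor covering the
    k = n//2 N-terminal (or C-terminal) helices, cut at the midpoint of the
    flanking loop; members then evolve exactly like full families.  Truth
    lists k (= 3 for the default architecture) TM spans per member.
    """
    if spec.n_helices < 2:
        raise SpecError("half proteins need >= 2 helices")
    anc, truth = make_ancestor(spec, family_id=family_id)
    k = spec.n_helices // 2
    if half == "N":
        cut_loop = truth.loop_spans[k - 1]
        region = (0, (cut_loop[0] + cut_loop[1]) // 2)
        kept_helices = range(k)
    elif half == "C":
        cut_loop = truth.loop_spans[spec.n_helices - k - 1]
        region = ((cut_loop[0] + cut_loop[1]) // 2, truth.ancestor_length)
        kept_helices = range(spec.n_helices - k, spec.n_helices)
    else:
        raise ValueError("half must be 'N' or 'C'")
    s0, e0 = region

    def shift(span: tuple[int, int]) -> tuple[int, int] | None:
        s, e = max(span[0], s0), min(span[1], e0)
        if e <= s:
            return None
        return s - s0, e - s0

    half_truth = FamilyTruth(
        family_id=family_id,
        ancestor_length=e0 - s0,
        tm_spans=[shift(truth.tm_spans[h]) for h in kept_helices],
        loop_spans=[sp for sp in (shift(x) for x in truth.loop_spans) if sp is not None],
        term_spans=((0, 0), (0, 0)),
        motif_spans=[sp for sp in (shift(x) for x in truth.motif_spans) if sp is not None],
        conserved_positions=[(p - s0, c) for p, c in truth.conserved_positions
                             if s0 <= p < e0],
        duplication=False,
        n_side=truth.n_side,
    )
    half_anc = SequenceRecord(f"{family_id}_anc", anc.residues[s0:e0], "half ancestor")
    half_spec = replace(spec, n_members=n, duplication=False)
    members, half_truth = evolve_family(half_anc, half_truth, half_spec, seed=seed)
    return members, half_truth


# ---------------------------------------------------------------------------
# Proteome bundles
# ---------------------------------------------------------------------------

@dataclass
class ProteomeTruth:
    """Truth manifest for a shuffled synthetic proteome, keyed by record id."""

    membership: dict[str, str]                  # id -> "family:<fid>" | "half:<fid>" | "decoy"
    family_truths: dict[str, FamilyTruth]
    half_truths: dict[str, FamilyTruth]
    family_records: dict[str, list[SequenceRecord]]
    half_records: dict[str, list[SequenceRecord]]

    def ids_in(self, category: str) -> set[str]:
        return {i for i, c in self.membership.items() if c == category}


def make_proteome(families: Sequence[FamilySpec], n_decoys: int = 200,
                  n_half_proteins: int = 0, decoy_kind: str = "globular",
                  decoy_length_range: tuple[int, int] = (150, 450),
                  seed: int = 0) -> tuple[list[SequenceRecord], ProteomeTruth]:
    """Shuffled concatenation of family members, half-proteins (homologous to
    the first family) and decoys, with a truth manifest partitioning the ids."""
    records: list[SequenceRecord] = []
    membership: dict[str, str] = {}
    family_truths: dict[str, FamilyTruth] = {}
    half_truths: dict[str, FamilyTruth] = {}
    family_records: dict[str, list[SequenceRecord]] = {}
    half_records: dict[str, list[SequenceRecord]] = {}

    for fi, spec in enumerate(families):
        fid = f"fam{fi}"
        _, members, truth = make_family(spec, family_id=fid)
        records.extend(members)
        family_truths[fid] = truth
        family_records[fid] = members
        for r in members:
            membership[r.id] = f"family:{fid}"

    if n_half_proteins > 0:
        if not families:
            raise SpecError("half proteins require at least one family spec")
        hid = "half0"
        halves, htruth = make_half_proteins(
            families[0], n_half_proteins, seed=families[0].seed + 104729,
            family_id=hid,
        )
        records.extend(halves)
        half_truths[hid] = htruth
        half_records[hid] = halves
        for r in halves:
            membership[r.id] = f"half:{hid}"

    decoys = make_decoys(n_decoys, decoy_length_range, kind=decoy_kind, seed=seed)
    records.extend(decoys)
    for r in decoys:
        membership[r.id] = "decoy"

    rng = np.random.default_rng([seed, 991])
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    return records, ProteomeTruth(membership, family_truths, half_truths,
                                  family_records, half_records)
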