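"""Position-specific profiles, local alignment scoring and E-value calibration.

A Profile is a simplified per-column emission model built from a multiple
alignment (match columns at <= 50% gap occupancy, position-based sequence
weighting, fixed-weight background pseudocounts) with affine gap penalties in
bits.  Sequences are scored against a profile and profiles against profiles
with Smith-Waterman-style local dynamic programming; statistical significance
comes from a Gumbel (extreme-value) fit to scores of seeded null samples,
giving E = N * exp(-lambda * (score - mu)).

The DP inner loops are vectorised along the target axis.  For a fixed profile
row, the horizontal (target-side) affine gap state is computed exactly with a
cumulative-maximum scan: when gap-open >= gap-extend an optimal path never
opens a horizontal gap out of a cell whose best path itself ends in a
horizontal gap, so E[j] = max_k (Hne[k] - open - (j-1-k)*extend) over cells
Hne that exclude the horizontal state.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .composition import AA_INDEX, AMINO_ACIDS, BACKGROUND_FREQS, GAP
from .seq_io import Alignment, SequenceRecord

logger = logging.getLogger(__name__)

PROFILE_SCHEMA_VERSION = 1
_NEG = -1e30


class ProfileError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


@dataclass
class Profile:
    """Per-column amino-acid emission model with TM-segment annotation."""

    emissions: np.ndarray                    # (ncols, 20), rows sum to 1
    background: np.ndarray                   # (20,)
    gap_open: float = 11.0                   # bits
    gap_extend: float = 1.0                  # bits
    tm_segments: list[tuple[int, int]] = field(default_factory=list)
    n_effective: float = 1.0
    match_columns: np.ndarray | None = None  # source alignment column of each match column

    def __post_init__(self) -> None:
        self.emissions = np.asarray(self.emissions, dtype=float)
        if self.emissions.ndim != 2 or self.emissions.shape[1] != len(AMINO_ACIDS):
            raise ProfileError("emissions must be (ncols, 20)")
        if self.emissions.shape[0] < 1:
            raise ProfileError("profile needs at least one column")
        if not np.allclose(self.emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ProfileError("emission columns must sum to 1")
        self._log_odds: np.ndarray | None = None

    @property
    def ncols(self) -> int:
        return int(self.emissions.shape[0])

    @property
    def log_odds(self) -> np.ndarray:
        """(ncols, 21) log2 emission/background; last column (X) scores 0."""
        if self._log_odds is None:
            lo = np.log2(np.maximum(self.emissions, 1e-300) / self.background)
            self._log_odds = np.hstack([lo, np.zeros((self.ncols, 1))])
        return self._log_odds

    def slice(self, start: int, end: int) -> "Profile":
        """Sub-profile over columns [start, end); TM segments re-indexed."""
        segs = []
        for s, e in self.tm_segments:
            s2, e2 = max(s, start), min(e, end)
            if e2 > s2:
                segs.append((s2 - start, e2 - start))
        mc = self.match_columns[start:end] if self.match_columns is not None else None
        return Profile(self.emissions[start:end].copy(), self.background,
                       self.gap_open, self.gap_extend, segs, self.n_effective, mc)


def position_based_weights(rows: np.ndarray) -> np.ndarray:
    """Henikoff position-based sequence weights (normalised to sum 1).

    ``rows`` is an (nrows, ncols) character array; gaps contribute nothing.
    """
    nrows = rows.shape[0]
    w = np.zeros(nrows)
    for j in range(rows.shape[1]):
        col = rows[:, j]
        residues = col[(col != GAP) & (col != "X")]
        if residues.size == 0:
            continue
        uniq, counts = np.unique(residues, return_counts=True)
        r = len(uniq)
        count_of = dict(zip(uniq, counts))
        for i in range(nrows):
            a = col[i]
            if a != GAP and a != "X":
                w[i] += 1.0 / (r * count_of[a])
    if w.sum() == 0:
        w[:] = 1.0
    return w / w.sum()


def build_profile(msa: Alignment, pseudocount_weight: float = 1.0,
                  tm_annotation: Sequence[tuple[int, int]] | None = None,
                  gap_open: float = 11.0, gap_extend: float = 1.0,
                  background: np.ndarray = BACKGROUND_FREQS) -> Profile:
    """Build a profile from an alignment.

    Match columns are those with <= 50% gaps (ties count as match).  Emissions
    are (n_eff * weighted frequencies + pseudocount_weight * background)
    normalised, with n_eff the number of distinct rows, so duplicated rows do
    not sharpen the profile.  ``tm_annotation`` spans (alignment columns) are
    mapped through the match-column indexing; defaults to ``msa.tm_segments``.
    """
    rows = np.array([list(r.residues) for r in msa.records])
    nrows, ncols = rows.shape
    gap_frac = (rows == GAP).sum(axis=0) / nrows
    is_match = gap_frac <= 0.5
    if not is_match.any():
        raise ProfileError("no match columns: every column is more than 50% gaps")
    match_cols = np.nonzero(is_match)[0]

    weights = position_based_weights(rows[:, match_cols])
    n_eff = float(len({r.residues for r in msa.records}))

    emissions = np.zeros((len(match_cols), len(AMINO_ACIDS)))
    for out_j, j in enumerate(match_cols):
        col = rows[:, j]
        counts = np.zeros(len(AMINO_ACIDS))
        for i in range(nrows):
            a = col[i]
            if a != GAP and a != "X":
                counts[AA_INDEX[a]] += weights[i]
        total = counts.sum()
        freqs = counts / total if total > 0 else background
        emissions[out_j] = (n_eff * freqs + pseudocount_weight * background) / (
            n_eff + pseudocount_weight
        )
    emissions /= emissions.sum(axis=1, keepdims=True)

    if tm_annotation is None:
        tm_annotation = msa.tm_segments or []
    rank = np.cumsum(is_match)  # number of match columns in [0, j]
    segs = []
    for s, e in tm_annotation:
        ms = int(rank[s - 1]) if s > 0 else 0
        me = int(rank[e - 1]) if e > 0 else 0
        if me > ms:
            segs.append((ms, me))
    return Profile(emissions, np.asarray(background, dtype=float), gap_open,
                   gap_extend, segs, n_eff, match_cols)


# ---------------------------------------------------------------------------
# Local affine-gap dynamic programming
# ---------------------------------------------------------------------------

def encode_sequence(residues: str) -> np.ndarray:
    """Residues -> indices 0..19, with X (and anything unknown) as 20."""
    return np.array([AA_INDEX.get(c, 20) for c in residues], dtype=int)


def _dp_matrices(S: np.ndarray, open_: float, ext: float):
    """Full local-alignment DP on score matrix S (n query rows x m target cols).

    Returns (H, E, F, Hne) of shape (n+1, m+1); H[i, j] is the best local
    alignment score ending at query i, target j (1-based).
    """
    n, m = S.shape
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), _NEG)
    F = np.full((n + 1, m + 1), _NEG)
    Hne = np.zeros((n + 1, m + 1))
    ar = np.arange(m + 1) * ext
    for i in range(1, n + 1):
        diag = H[i - 1, :-1] + S[i - 1]
        F[i, 1:] = np.maximum(H[i - 1, 1:] - open_, F[i - 1, 1:] - ext)
        hne = np.maximum(0.0, np.maximum(diag, F[i, 1:]))
        Hne[i, 1:] = hne
        t = Hne[i] + ar                      # Hne[i, k] + k*ext
        cm = np.maximum.accumulate(t[:-1])   # over k = 0..j-1
        E[i, 1:] = cm - open_ - ar[1:] + ext
        H[i] = np.maximum(Hne[i], E[i])
    return H, E, F, Hne


def _score_only(S: np.ndarray, open_: float, ext: float) -> float:
    """Best local score without storing matrices (used for null calibration)."""
    n, m = S.shape
    Hprev = np.zeros(m + 1)
    Fprev = np.full(m + 1, _NEG)
    ar = np.arange(m + 1) * ext
    best = 0.0
    for i in range(n):
        F = np.maximum(Hprev - open_, Fprev - ext)
        hne = np.empty(m + 1)
        hne[0] = 0.0
        hne[1:] = np.maximum(0.0, np.maximum(Hprev[:-1] + S[i], F[1:]))
        t = hne + ar
        cm = np.maximum.accumulate(t[:-1])
        H = hne.copy()
        H[1:] = np.maximum(hne[1:], cm - open_ - ar[1:] + ext)
        b = H.max()
        if b > best:
            best = b
        Hprev, Fprev = H, F
    return float(best)


def _traceback(H, E, F, Hne, S, open_, ext, tol=1e-9):
    """Trace the best local alignment; returns (score, pairs) with 0-based
    (query, target) index pairs, ties broken toward the diagonal."""
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    score = float(H[i, j])
    pairs: list[tuple[int, int]] = []
    if score <= tol:
        return 0.0, []
    state = "H"
    while i > 0 and j > 0:
        if state in ("H", "Hne"):
            val = H[i, j] if state == "H" else Hne[i, j]
            if val <= tol:
                break
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            if abs(val - diag) <= tol:
                pairs.append((i - 1, j - 1))
                i, j = i - 1, j - 1
                state = "H"
            elif abs(val - F[i, j]) <= tol:
                state = "F"
            elif state == "H" and abs(val - E[i, j]) <= tol:
                state = "E"
            else:  # numerical corner: stop
                break
        elif state == "F":
            # vertical gap: query columns skipped
            if abs(F[i, j] - (H[i - 1, j] - open_)) <= tol:
                i -= 1
                state = "H"
            else:
                i -= 1
                state = "F"
        else:  # state == "E": horizontal gap, find the opening cell (shortest gap)
            target_val = E[i, j]
            k = j - 1
            while k >= 1:
                if abs(Hne[i, k] - open_ - (j - 1 - k) * ext - target_val) <= tol:
                    break
                k -= 1
            if k < 1:
                break
            j = k
            state = "Hne"
    pairs.reverse()
    return score, pairs


@dataclass
class AlignmentResult:
    """Outcome of one local alignment (profile vs sequence or vs profile)."""

    score_bits: float
    pairs: list[tuple[int, int]]         # (query column, target position/column)

    @property
    def query_span(self) -> tuple[int, int]:
        if not self.pairs:
            return (0, 0)
        return (self.pairs[0][0], self.pairs[-1][0] + 1)

    @property
    def target_span(self) -> tuple[int, int]:
        if not self.pairs:
            return (0, 0)
        return (self.pairs[0][1], self.pairs[-1][1] + 1)


def score_sequence(profile: Profile, seq: SequenceRecord) -> AlignmentResult:
    """Best local alignment of a sequence to the profile (log-odds, bits)."""
    enc = encode_sequence(seq.residues.replace(GAP, ""))
    if enc.size == 0 or np.all(enc == 20):
        return AlignmentResult(0.0, [])
    S = profile.log_odds[:, enc]
    H, E, F, Hne = _dp_matrices(S, profile.gap_open, profile.gap_extend)
    score, pairs = _traceback(H, E, F, Hne, S, profile.gap_open, profile.gap_extend)
    return AlignmentResult(score, pairs)


def _coemission(query: Profile, target: Profile) -> np.ndarray:
    """Column-column co-emission scores log2 sum_a p_a q_a / f_a."""
    ratio = query.emissions / query.background
    M = ratio @ target.emissions.T
    return np.log2(np.maximum(M, 1e-300))


def align_profiles(query: Profile, target: Profile) -> AlignmentResult:
    """Best local column pairing of two profiles under co-emission scoring."""
    S = _coemission(query, target)
    H, E, F, Hne = _dp_matrices(S, query.gap_open, query.gap_extend)
    score, pairs = _traceback(H, E, F, Hne, S, query.gap_open, query.gap_extend)
    return AlignmentResult(score, pairs)


def score_profile_fast(query: Profile, target: Profile) -> float:
    S = _coemission(query, target)
    return _score_only(S, query.gap_open, query.gap_extend)


# ---------------------------------------------------------------------------
# Gumbel calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Calibration:
    """Gumbel null model of local-alignment scores: E = N exp(-lambda (s - mu))."""

    mu: float
    lam: float
    n_null: int
    database_size: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise CalibrationError("lambda must be positive")
        if self.n_null < 100:
            raise CalibrationError("calibration needs at least 100 null samples")


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gumbel (right-skewed) fit; returns (mu, lambda)."""
    scores = np.asarray(scores, dtype=float)
    if scores.std() < 1e-12:
        raise CalibrationError("degenerate null score variance")
    loc, scale = stats.gumbel_r.fit(scores)
    if not np.isfinite(loc) or not np.isfinite(scale) or scale <= 0:
        raise CalibrationError("Gumbel fit failed")
    return float(loc), float(1.0 / scale)


def background_sequence_sampler(lengths: Sequence[int],
                                background: np.ndarray = BACKGROUND_FREQS) -> Callable:
    """Null sampler drawing i.i.d. background sequences with lengths matched
    to the target database's length distribution."""
    lengths = list(lengths)
    aa = np.array(list(AMINO_ACIDS))

    def sample(rng: np.random.Generator) -> SequenceRecord:
        n = int(lengths[rng.integers(0, len(lengths))])
        return SequenceRecord("null", "".join(aa[rng.choice(len(aa), size=n, p=background)]))

    return sample


def shuffled_profile_sampler(target: Profile, stratify_segments: bool = True) -> Callable:
    """Null sampler permuting the target profile's columns (profile mode).

    When the target carries TM segments (and ``stratify_segments`` is on),
    TM columns are permuted among TM columns and loop columns among loop
    columns with positions fixed.  This preserves the hydrophobic block
    architecture under the null: two unrelated TM-helix profiles align well
    purely by composition, so an unstratified shuffle — which destroys the
    blocks — would declare any pair of helix bundles homologous.  Stratified
    shuffling leaves only true column-to-column correspondence as signal.
    """
    tm = np.zeros(target.ncols, dtype=bool)
    for s, e in target.tm_segments:
        tm[s:e] = True
    tm_idx = np.nonzero(tm)[0]
    lp_idx = np.nonzero(~tm)[0]
    stratified = stratify_segments and tm_idx.size > 0

    def sample(rng: np.random.Generator) -> Profile:
        if stratified:
            perm = np.arange(target.ncols)
            perm[tm_idx] = tm_idx[rng.permutation(tm_idx.size)]
            perm[lp_idx] = lp_idx[rng.permutation(lp_idx.size)]
            segs = list(target.tm_segments)
        else:
            perm = rng.permutation(target.ncols)
            segs = []
        return Profile(target.emissions[perm], target.background,
                       target.gap_open, target.gap_extend, segs,
                       target.n_effective)

    return sample


def calibrate(profile: Profile, null_sampler: Callable, n_null: int = 200,
              database_size: int = 1, seed: int | Sequence[int] = 0) -> Calibration:
    """Score ``n_null`` seeded null samples against the profile and fit a
    Gumbel to the score distribution."""
    if n_null < 100:
        raise CalibrationError("n_null must be >= 100")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_null)
    for i in range(n_null):
        null = null_sampler(rng)
        if isinstance(null, Profile):
            scores[i] = score_profile_fast(profile, null)
        else:
            enc = encode_sequence(null.residues)
            scores[i] = _score_only(profile.log_odds[:, enc],
                                    profile.gap_open, profile.gap_extend)
    mu, lam = fit_gumbel(scores)
    return Calibration(mu, lam, n_null, database_size)


def evalue(calibration: Calibration, score: float) -> float:
    """Expected number of chance hits at >= score; clamped to [0, N]."""
    N = calibration.database_size
    with np.errstate(over="ignore"):
        e = N * np.exp(-calibration.lam * (score - calibration.mu))
    return float(np.clip(e, 0.0, N))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def profile_to_json(profile: Profile) -> str:
    return json.dumps({
        "schema_version": PROFILE_SCHEMA_VERSION,
        "alphabet": AMINO_ACIDS,
        "emissions": profile.emissions.tolist(),
        "background": profile.background.tolist(),
        "gap_open": profile.gap_open,
        "gap_extend": profile.gap_extend,
        "tm_segments": [list(s) for s in profile.tm_segments],
        "n_effective": profile.n_effective,
    })


def profile_from_json(text: str) -> Profile:
    d = json.loads(text)
    if d.get("schema_version") != PROFILE_SCHEMA_VERSION:
        raise ProfileError(f"unsupported profile schema {d.get('schema_version')}")
    return Profile(np.array(d["emissions"]), np.array(d["background"]),
                   d["gap_open"], d["gap_extend"],
                   [tuple(s) for s in d["tm_segments"]], d["n_effective"])
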