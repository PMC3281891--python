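"""Internal N-half/C-half duplication detection and half-protein classification.

Seven-helix family profiles are split into an N-terminal core (helices 1-3)
and a C-terminal core (helices 5-7), cut at the midpoints of the loops
flanking helix 4.  Significant local profile-profile alignment between the
two cores — judged against a column-shuffled null — is the signature that
the helix bundle arose by duplication (or fusion) of a three-helix ancestor.
Short proteins that pass the E-value threshold but cover only one half of
the full query are classified here rather than silently accepted.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

from .profile import (
    Calibration,
    Profile,
    align_profiles,
    calibrate,
    evalue,
    score_sequence,
    shuffled_profile_sampler,
)
from .search import SearchConfig, covered_segments, coverage_filter, Hit
from .seq_io import SequenceRecord

logger = logging.getLogger(__name__)

DUPLICATION_E_THRESHOLD = 1e-3


class DuplicationError(ValueError):
    pass


def split_profile(profile: Profile) -> tuple[Profile, Profile]:
    """Split a profile into N-half and C-half cores at the loop midpoints
    flanking the middle helix.

    For an odd helix count 2k+1 the N core holds helices 1..k and the C core
    helices k+2..2k+1; the middle helix belongs to neither core.  For an even
    count 2k the split is 1..k / k+1..2k at the central loop midpoint.
    """
    segs = profile.tm_segments
    n = len(segs)
    if n < 2:
        raise DuplicationError("profile needs at least 2 TM segments to split")
    k = n // 2
    if n % 2 == 1:
        n_end = (segs[k - 1][1] + segs[k][0]) // 2
        c_start = (segs[k][1] + segs[k + 1][0]) // 2
    else:
        n_end = c_start = (segs[k - 1][1] + segs[k][0]) // 2
    return profile.slice(0, n_end), profile.slice(c_start, profile.ncols)


def detect_duplication(profile: Profile, n_null: int = 500, seed: int = 0,
                       e_threshold: float = DUPLICATION_E_THRESHOLD,
                       min_segment_overlap: int = 5) -> dict:
    """Align the N-half profile against the C-half profile and judge
    significance against a column-shuffled null (Gumbel fit).

    Returns {score_bits, evalue, verdict, covered_segments, n_covered}; the
    verdict is ``duplicated`` iff E < e_threshold."""
    pn, pc = split_profile(profile)
    res = align_profiles(pn, pc)
    cal = calibrate(pn, shuffled_profile_sampler(pc), n_null=n_null,
                    database_size=1, seed=[seed, 31])
    e = evalue(cal, res.score_bits)
    covered = covered_segments(res.query_span, pn.tm_segments, min_segment_overlap)
    return {
        "score_bits": res.score_bits,
        "evalue": e,
        "verdict": "duplicated" if e < e_threshold else "not_duplicated",
        "covered_segments": covered,
        "n_covered": len(covered),
    }


def classify_half_protein(profile: Profile, seq: SequenceRecord,
                          config: SearchConfig, calibration: Calibration) -> dict:
    """Classify a sequence as a full member, an N-half or C-half homologue,
    or neither.

    A sequence is a half-protein when its hit is significant (E < e_accept)
    but its covered segments fall within one half of the query ({1..4} or
    {4..7} for seven helices, 1-based).  Short sequences homologous to both
    halves (alternative alignments against either core) are flagged
    ``both_halves`` and labelled with the better-covered half.
    """
    res = score_sequence(profile, seq)
    e = evalue(calibration, res.score_bits)
    covered = covered_segments(res.query_span, profile.tm_segments,
                               config.min_segment_overlap)
    out = {"half": "none", "covered_segments": covered, "both_halves": False,
           "evalue": e, "score_bits": res.score_bits}
    if e >= config.e_accept:
        return out
    hit = Hit(seq.id, res.score_bits, e, res.query_span, res.target_span,
              covered, accepted=False)
    full_config = SearchConfig(
        e_accept=config.e_accept, min_segment_overlap=config.min_segment_overlap,
        require_all_segments=True,
    )
    if coverage_filter(hit, profile, full_config):
        return out   # full coverage: a regular family member

    n = len(profile.tm_segments)
    k = n // 2
    n_set = set(range(0, k + 1))
    c_set = set(range(n - k - 1, n))
    in_n = set(covered) <= n_set
    in_c = set(covered) <= c_set

    pn, pc = split_profile(profile)
    res_n = score_sequence(pn, seq)
    res_c = score_sequence(pc, seq)
    cov_n = covered_segments(res_n.query_span, pn.tm_segments,
                             config.min_segment_overlap)
    cov_c = covered_segments(res_c.query_span, pc.tm_segments,
                             config.min_segment_overlap)
    out["both_halves"] = len(cov_n) >= 2 and len(cov_c) >= 2

    if in_n and not in_c:
        out["half"] = "N"
    elif in_c and not in_n:
        out["half"] = "C"
    elif in_n and in_c:
        out["half"] = "N" if (len(cov_n), res_n.score_bits) >= (len(cov_c), res_c.score_bits) else "C"
    return out
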