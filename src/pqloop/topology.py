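"""Transmembrane topology: per-sequence hydropathy prediction and
alignment-level consensus.

Per-sequence prediction is a transparent sliding-window rule on the
Kyte-Doolittle scale: residues whose 19-residue window mean exceeds 1.6 are
candidates, candidate runs of >= 15 residues become helices, and runs longer
than 35 are split recursively at their hydropathy minimum (which for
membrane proteins sits in the loop between two merged helices).  The
alignment-level consensus votes per column across members, which averages
out single-sequence boundary noise — the number and position of helices is
established more reliably from the family than from any individual sequence.

Sidedness (lumen vs cytoplasm) is an annotation, not a prediction: the
N-terminal side is supplied (default lumenal, as established experimentally
for KDEL receptors) and loop sides alternate from it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .composition import AA_INDEX, GAP, KD_UNKNOWN, KD_VECTOR
from .seq_io import Alignment, SequenceRecord

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 19
DEFAULT_THRESHOLD = 1.6
MIN_HELIX_RUN = 15
MAX_HELIX_RUN = 35
CONSENSUS_MIN_RUN = 12
CLOSE_GAP = 3


@dataclass(frozen=True)
class TopologyModel:
    """Ordered TM segments plus the membrane side of the N-terminus."""

    segments: tuple[tuple[int, int], ...]
    n_side: str | None = None   # "lumen" | "cytoplasm" | None (unoriented)

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e in self.segments:
            if s >= e or s < prev_end:
                raise ValueError("TM segments must be ordered and non-overlapping")
            prev_end = e

    @property
    def n_helices(self) -> int:
        return len(self.segments)

    def loop_sides(self) -> list[str]:
        """Sides of the n_helices + 1 non-membrane regions, N-terminal first."""
        if self.n_side is None:
            raise ValueError("topology is unoriented; call orient() first")
        other = {"lumen": "cytoplasm", "cytoplasm": "lumen"}
        sides = [self.n_side]
        for _ in range(self.n_helices):
            sides.append(other[sides[-1]])
        return sides

    @property
    def c_side(self) -> str:
        return self.loop_sides()[-1]


def orient(topology: TopologyModel, n_side: str) -> TopologyModel:
    if n_side not in ("lumen", "cytoplasm"):
        raise ValueError(f"unknown side {n_side!r}")
    return replace(topology, n_side=n_side)


def hydropathy(residues: str) -> np.ndarray:
    """Per-residue Kyte-Doolittle values; X/gaps at the background mean."""
    return np.array([KD_VECTOR[AA_INDEX[c]] if c in AA_INDEX else KD_UNKNOWN
                     for c in residues])


def _marked_runs(marked: np.ndarray, close_gap: int = 0) -> list[tuple[int, int]]:
    """Contiguous True runs, bridging gaps of at most ``close_gap``."""
    runs: list[list[int]] = []
    i, n = 0, len(marked)
    while i < n:
        if marked[i]:
            j = i
            while j < n and marked[j]:
                j += 1
            if runs and i - runs[-1][1] <= close_gap:
                runs[-1][1] = j
            else:
                runs.append([i, j])
            i = j
        else:
            i += 1
    return [tuple(r) for r in runs]


def _split_runs(runs: list[tuple[int, int]], valley: np.ndarray,
                min_run: int, max_run: int) -> list[tuple[int, int]]:
    """Recursively split runs longer than ``max_run`` at the interior minimum
    of ``valley`` (a per-position hydropathy signal); drop fragments shorter
    than ``min_run``.

    The split point is constrained to lie at least ``min_run`` positions from
    both run ends: hydropathy sags toward the run boundaries by construction,
    so an unconstrained minimum would erode the run edges instead of cutting
    at the loop between two merged helices."""
    out: list[tuple[int, int]] = []
    stack = list(runs)
    while stack:
        s, e = stack.pop()
        if e - s > max_run and e - s >= 2 * min_run + 1:
            interior = valley[s + min_run : e - min_run]
            m = s + min_run + int(np.argmin(interior))
            stack.append((s, m))
            stack.append((m + 1, e))
        elif e - s >= min_run:
            out.append((s, e))
    return sorted(out)


def predict_tm(seq: SequenceRecord, window: int = DEFAULT_WINDOW,
               threshold: float = DEFAULT_THRESHOLD, min_run: int = MIN_HELIX_RUN,
               max_run: int = MAX_HELIX_RUN, close_gap: int = CLOSE_GAP) -> TopologyModel:
    """Sliding-window Kyte-Doolittle TM-helix prediction for one sequence.

    Candidate runs separated by at most ``close_gap`` sub-threshold positions
    are bridged before the minimum-run rule: a single noisy window can dip a
    smoothed signal below threshold mid-helix, and without closing such dips
    split a genuine helix into two sub-minimum fragments."""
    residues = seq.residues.replace(GAP, "")
    if len(residues) < window:
        logger.warning("sequence %s shorter than window (%d < %d): no segments",
                       seq.id, len(residues), window)
        return TopologyModel(())
    kd = hydropathy(residues)
    # window mean assigned to the centre residue; windows are clipped at the
    # sequence ends so terminal helices (the N-tail is a single residue in
    # this architecture) are not lost for lack of a full window
    n = len(residues)
    half = window // 2
    cum = np.concatenate([[0.0], np.cumsum(kd)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    center_means = (cum[hi] - cum[lo]) / (hi - lo)
    marked = center_means > threshold

    runs = _marked_runs(marked, close_gap)
    segments = _split_runs(runs, center_means, min_run, max_run)
    return TopologyModel(tuple(segments))


def consensus_topology(msa: Alignment, per_seq: list[TopologyModel],
                       vote: float = 0.5, min_run: int = CONSENSUS_MIN_RUN,
                       max_run: int = MAX_HELIX_RUN) -> TopologyModel:
    """Column-level consensus: a column is TM when more than ``vote`` of the
    sequences with a residue there lie inside one of their predicted
    segments; consensus runs of >= ``min_run`` columns become segments, long
    runs split at the column-hydropathy minimum.  Returned coordinates are
    alignment columns.

    Only columns occupied by more than half of the rows participate in the
    run logic: sparse insert columns would otherwise stretch a helix run in
    column space and trigger spurious length-based splits."""
    if len(per_seq) != len(msa.records):
        raise ValueError("need one TopologyModel per alignment row")
    ncols = msa.column_count
    inside_count = np.zeros(ncols)
    voters = np.zeros(ncols)
    col_kd_sum = np.zeros(ncols)

    for rec, topo in zip(msa.records, per_seq):
        row = np.array(list(rec.residues))
        non_gap = row != GAP
        positions = np.cumsum(non_gap) - 1      # seq position per column
        seq_len = int(non_gap.sum())
        inside = np.zeros(seq_len, dtype=bool)
        for s, e in topo.segments:
            inside[s:e] = True
        vot = non_gap
        voters += vot
        inside_count[vot] += inside[positions[vot]]
        kd = hydropathy(rec.residues.replace(GAP, ""))
        col_kd_sum[vot] += kd[positions[vot]]

    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(voters > 0, inside_count / np.maximum(voters, 1), 0.0)
        col_kd = np.where(voters > 0, col_kd_sum / np.maximum(voters, 1), -10.0)
    nrows = len(msa.records)
    occupied = np.nonzero(voters > 0.5 * nrows)[0]
    if occupied.size == 0:
        occupied = np.nonzero(voters > 0)[0]
    is_tm = (frac[occupied] > vote) & (voters[occupied] > 0)
    runs = _marked_runs(is_tm)
    segments = [(int(occupied[s]), int(occupied[e - 1]) + 1)
                for s, e in _split_runs(runs, col_kd[occupied], min_run, max_run)]
    n_sides = {t.n_side for t in per_seq if t.n_side is not None}
    n_side = n_sides.pop() if len(n_sides) == 1 else None
    return TopologyModel(tuple(segments), n_side=n_side)


def topology_to_gff3(topology: TopologyModel, seq_id: str) -> str:
    """GFF3 rendering (1-based inclusive coordinates at this boundary)."""
    lines = ["##gff-version 3"]
    for i, (s, e) in enumerate(topology.segments, 1):
        lines.append("\t".join([
            seq_id, "pqloop", "transmembrane_helix", str(s + 1), str(e),
            ".", "+", ".", f"ID=tm{i}",
        ]))
    return "\n".join(lines) + "\n"
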