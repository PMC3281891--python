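"""Column conservation, motif detection and neighbor-joining phylogeny.

Conservation is measured per alignment column as the relative entropy (bits)
of the pseudocounted, sequence-weighted residue distribution against the
background composition; columns with more than 50% gaps are masked.  The PQ
doublet and other short motifs are located by scanning the ungapped member
sequences, optionally restricted to loop regions.  Distances for the tree
are simple p-distances over mutually ungapped columns (with an optional
Poisson correction hook), and the tree itself is classical neighbor joining.
"""
from __future__ import annotations

import io
import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .composition import AA_INDEX, AMINO_ACIDS, BACKGROUND_FREQS, GAP
from .profile import position_based_weights
from .seq_io import Alignment

logger = logging.getLogger(__name__)

RESIDUE_CLASSES = {"basic": {"K", "R", "H"}, "serine": {"S"}}


@dataclass
class ConservationTrack:
    """Per-column conservation: relative entropy (bits, NaN when masked),
    majority residue, its carrier fraction, and the gap fraction."""

    scores: np.ndarray
    majority: list[str | None]
    majority_fraction: np.ndarray
    gap_fraction: np.ndarray


def column_conservation(msa: Alignment, pseudocount_weight: float = 0.2,
                        background: np.ndarray = BACKGROUND_FREQS) -> ConservationTrack:
    """Sequence-weighted relative-entropy conservation per alignment column."""
    rows = np.array([list(r.residues) for r in msa.records])
    nrows, ncols = rows.shape
    weights = position_based_weights(rows)
    n_eff = float(len({r.residues for r in msa.records}))

    scores = np.full(ncols, np.nan)
    majority: list[str | None] = [None] * ncols
    majority_fraction = np.zeros(ncols)
    gap_fraction = np.zeros(ncols)
    for j in range(ncols):
        col = rows[:, j]
        gap_fraction[j] = (col == GAP).sum() / nrows
        if gap_fraction[j] > 0.5:
            continue
        counts = np.zeros(len(AMINO_ACIDS))
        raw = np.zeros(len(AMINO_ACIDS))
        for i in range(nrows):
            a = col[i]
            if a != GAP and a != "X":
                counts[AA_INDEX[a]] += weights[i]
                raw[AA_INDEX[a]] += 1.0
        total = counts.sum()
        if total == 0:
            continue
        freqs = counts / total
        # majority/carrier fraction from raw counts: the unweighted fraction
        # is the better-behaved invariance statistic, while the entropy score
        # stays sequence-weighted
        top = int(np.argmax(raw))
        majority[j] = AMINO_ACIDS[top]
        majority_fraction[j] = raw[top] / raw.sum()
        p = (n_eff * freqs + pseudocount_weight * background) / (n_eff + pseudocount_weight)
        scores[j] = float(np.sum(p * np.log2(p / background)))
    return ConservationTrack(scores, majority, majority_fraction, gap_fraction)


def find_motif(msa: Alignment, motif: str = "PQ",
               loop_regions: list[tuple[int, int]] | None = None,
               threshold: float = 0.5) -> list[tuple[tuple[int, int], float]]:
    """Column spans where >= ``threshold`` of the members carry ``motif``
    verbatim, scanning ungapped sequences (optionally loop-restricted)."""
    nrows = len(msa.records)
    counter: Counter[tuple[int, int]] = Counter()
    for rec in msa.records:
        row = rec.residues
        cols = [j for j, c in enumerate(row) if c != GAP]
        seq = "".join(row[j] for j in cols)
        start = seq.find(motif)
        seen: set[tuple[int, int]] = set()
        while start != -1:
            span = (cols[start], cols[start + len(motif) - 1] + 1)
            ok = True
            if loop_regions is not None:
                ok = any(span[0] >= s and span[1] <= e for s, e in loop_regions)
            if ok and span not in seen:
                counter[span] += 1
                seen.add(span)
            start = seq.find(motif, start + 1)
    out = [(span, count / nrows) for span, count in counter.items()
           if count / nrows >= threshold]
    out.sort()
    return out


def find_conserved_class_columns(track: ConservationTrack, msa: Alignment,
                                 classes: dict[str, set[str]] | None = None,
                                 min_score: float = 2.0,
                                 min_majority_fraction: float = 0.9) -> dict[str, list[int]]:
    """Columns above ``min_score`` bits whose majority residue belongs to the
    class and is carried by >= ``min_majority_fraction`` of the members.

    The carrier-fraction requirement separates planted near-invariant columns
    from ordinary columns that are moderately conserved merely because the
    family is shallow."""
    if classes is None:
        classes = RESIDUE_CLASSES
    out: dict[str, list[int]] = {k: [] for k in classes}
    for j, score in enumerate(track.scores):
        if not np.isfinite(score) or score < min_score:
            continue
        if track.majority_fraction[j] < min_majority_fraction:
            continue
        res = track.majority[j]
        for klass, members in classes.items():
            if res in members:
                out[klass].append(j)
    return out


# ---------------------------------------------------------------------------
# Distances and neighbor joining
# ---------------------------------------------------------------------------

def pairwise_distances(msa: Alignment, correction: str | None = None) -> tuple[list[str], np.ndarray]:
    """p-distances (1 - fractional identity over mutually ungapped columns).

    ``correction='poisson'`` applies -ln(1 - p), clipped below saturation.
    Pairs sharing no ungapped column get distance 1 with a warning."""
    rows = np.array([list(r.residues) for r in msa.records])
    n = rows.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (rows[i] != GAP) & (rows[j] != GAP)
            m = int(both.sum())
            if m == 0:
                logger.warning("rows %s and %s share no ungapped columns",
                               msa.records[i].id, msa.records[j].id)
                d = 1.0
            else:
                p = 1.0 - float((rows[i][both] == rows[j][both]).sum()) / m
                if correction == "poisson":
                    d = float(-np.log(max(1.0 - p, 1e-6)))
                else:
                    d = p
            D[i, j] = D[j, i] = d
    return msa.ids, D


@dataclass
class PhyloTree:
    """Unrooted tree over sequence ids with non-negative branch lengths."""

    tree: TreeNode
    ids: list[str]

    def newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf)
        return buf.getvalue().strip()

    def leaf_names(self) -> set[str]:
        return {t.name for t in self.tree.tips()}


def nj_tree(distances: np.ndarray, ids: list[str]) -> PhyloTree:
    """Classical neighbor joining; negative branch lengths clamped to zero.

    Two taxa yield the single-edge convention of two branches of length d/2.
    """
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        d = float(distances[0, 1])
        tree = TreeNode.read(io.StringIO(f"({ids[0]}:{d / 2:.6f},{ids[1]}:{d / 2:.6f});"))
        return PhyloTree(tree, list(ids))
    dm = DistanceMatrix(distances, ids)
    tree = nj(dm)
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            logger.warning("clamping negative branch length %.4f", node.length)
            node.length = 0.0
    return PhyloTree(tree, list(ids))
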