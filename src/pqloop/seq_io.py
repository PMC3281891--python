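"""Readers and writers for the formats the pipeline touches.

Unaligned and aligned FASTA, Stockholm 1.0 multiple alignments, and the
packaged tab-separated tables of the human and yeast PQ-loop family members
(including the three footnoted short homologues of the human table).

Coordinates everywhere in this package are 0-based, half-open.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .composition import AMINO_ACIDS, GAP

logger = logging.getLogger(__name__)

_ALLOWED = set(AMINO_ACIDS) | {"X", GAP}
# Ambiguity/rare codes collapse to X so every scoring model stays closed over
# the 20 standard letters; X scores as background everywhere downstream.
_NONSTANDARD = str.maketrans({c: "X" for c in "BZJUO*"})


class FormatError(ValueError):
    """Malformed input file (bad FASTA/Stockholm syntax, ragged alignment...)."""


def sanitize_residues(residues: str, record_id: str = "?") -> str:
    s = residues.upper().replace(".", GAP)
    t = s.translate(_NONSTANDARD)
    if t != s:
        logger.warning("record %s: non-standard residues mapped to X", record_id)
    bad = sorted(set(t) - _ALLOWED)
    if bad:
        raise FormatError(f"record {record_id}: illegal residue characters {bad!r}")
    return t


@dataclass(frozen=True)
class SequenceRecord:
    """One identified amino-acid sequence (possibly gapped when aligned)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id {self.id!r} is empty or contains whitespace")
        if not self.residues:
            raise ValueError(f"record {self.id}: empty residue string")

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> "SequenceRecord":
        return replace(self, residues=self.residues.replace(GAP, ""))


@dataclass
class Alignment:
    """Equal-length rows of gapped SequenceRecords.

    ``column_annotations`` keeps Stockholm #=GC lines; ``tm_segments`` is an
    optional ordered list of (start, end) column spans marking transmembrane
    helices in alignment coordinates.
    """

    records: list[SequenceRecord]
    column_annotations: dict[str, str] = field(default_factory=dict)
    tm_segments: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("alignment has no rows")
        width = len(self.records[0].residues)
        for rec in self.records:
            if len(rec.residues) != width:
                raise FormatError(
                    f"ragged alignment: row {rec.id} has length "
                    f"{len(rec.residues)}, expected {width}"
                )
            if set(rec.residues) <= {GAP}:
                raise FormatError(f"row {rec.id} is all gaps")
        ids = [r.id for r in self.records]
        dups = {i for i in ids if ids.count(i) > 1}
        if dups:
            raise FormatError(f"duplicate row ids: {sorted(dups)}")

    @property
    def column_count(self) -> int:
        return len(self.records[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, aligned: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file; order preserved, gaps stripped unless ``aligned``."""
    path = Path(path)
    records: list[SequenceRecord] = []
    current_id: str | None = None
    current_desc = ""
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        nonlocal current_id, chunks
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}:{line_no}: record {current_id} has no residues")
        records.append(
            SequenceRecord(current_id, sanitize_residues(seq, current_id), current_desc)
        )
        current_id, chunks = None, []

    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}:{line_no}: empty FASTA header")
                parts = header.split(None, 1)
                current_id = parts[0]
                current_desc = parts[1] if len(parts) > 1 else ""
            else:
                if current_id is None:
                    raise FormatError(
                        f"{path}:{line_no}: sequence data before first '>' header"
                    )
                chunks.append(line)
        flush(line_no if records or current_id else 0)
    if not records:
        raise FormatError(f"{path}:1: empty FASTA file")
    ids = [r.id for r in records]
    dups = sorted({i for i in ids if ids.count(i) > 1})
    if dups:
        raise FormatError(f"{path}: duplicate sequence ids {dups}")
    if not aligned:
        records = [r.ungapped() for r in records]
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Multiple sequence alignments
# ---------------------------------------------------------------------------

def read_msa(path: str | Path, dialect: str = "aligned_fasta") -> Alignment:
    """Read an MSA in ``aligned_fasta`` or ``stockholm`` dialect."""
    path = Path(path)
    if dialect == "aligned_fasta":
        return Alignment(read_fasta(path, aligned=True))
    if dialect == "stockholm":
        try:
            aln = AlignIO.read(str(path), "stockholm")
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        records = [
            SequenceRecord(r.id, sanitize_residues(str(r.seq), r.id),
                           r.description if r.description != "<unknown description>" else "")
            for r in aln
        ]
        annotations = dict(getattr(aln, "column_annotations", {}) or {})
        return Alignment(records, column_annotations=annotations)
    raise ValueError(f"unknown MSA dialect {dialect!r}")


def write_msa(alignment: Alignment, path: str | Path, dialect: str = "aligned_fasta") -> None:
    path = Path(path)
    if dialect == "aligned_fasta":
        write_fasta(alignment.records, path)
        return
    if dialect == "stockholm":
        bio = MultipleSeqAlignment(
            [_BioSeqRecord(Seq(r.residues), id=r.id, description=r.description or "")
             for r in alignment.records]
        )
        if alignment.column_annotations:
            bio.column_annotations = dict(alignment.column_annotations)
        AlignIO.write(bio, str(path), "stockholm")
        return
    raise ValueError(f"unknown MSA dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Packaged family tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyTableEntry:
    uniprot_id: str
    swissprot_id: str
    protein_name: str
    gene_name: str
    length: int
    short_half_flag: bool

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.uniprot_id}: non-positive length")


_TABLE_FILES = {"human": "human_pq_loop.tsv", "yeast": "yeast_pq_loop.tsv"}


def load_family_table(which: str) -> list[FamilyTableEntry]:
    """Load the packaged human (15 entries, 3 short-half flagged) or yeast
    (8 entries) PQ-loop family table."""
    if which not in _TABLE_FILES:
        raise ValueError(f"unknown family table {which!r}; expected 'human' or 'yeast'")
    text = resources.files("pqloop").joinpath(f"data/{_TABLE_FILES[which]}").read_text()
    entries = []
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        entries.append(
            FamilyTableEntry(
                uniprot_id=row["uniprot_id"],
                swissprot_id=row["swissprot_id"],
                protein_name=row["protein_name"],
                gene_name=row["gene_name"],
                length=int(row["length"]),
                short_half_flag=row["short_half_flag"].strip().lower() == "true",
            )
        )
    return entries
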