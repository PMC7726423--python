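"""Proteome FASTA input and bidirectional protein-homology tables.

Homology evidence is consumed as standard 12-column BLAST tabular
output (``-outfmt 6``): qseqid sseqid pident length mismatch gapopen
qstart qend sstart send evalue bitscore.  The tool never runs the
aligner itself; the tabular file is the contract, so results from any
BLASTp/DIAMOND-compatible search can be used.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "ProteinSet",
    "HomologyHit",
    "HomologyTable",
    "LengthSummary",
    "read_fasta",
    "length_summary",
    "read_homology_table",
    "write_homology_table",
    "BLAST_COLUMNS",
]

BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


@dataclass(frozen=True)
class ProteinRecord:
    """One peptide sequence; id is the first whitespace token of the header."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence or not self.sequence.isalpha():
            raise ValueError(f"protein {self.id!r}: sequence must be non-empty alphabetic")

    def __len__(self) -> int:
        return len(self.sequence)


class ProteinSet:
    """An ordered set of protein records with unique ids."""

    def __init__(self, records: list[ProteinRecord] | None = None):
        self._records: dict[str, ProteinRecord] = {}
        for rec in records or []:
            self.add(rec)

    def add(self, rec: ProteinRecord) -> None:
        if rec.id in self._records:
            raise ValueError(f"duplicate protein id {rec.id!r}")
        self._records[rec.id] = rec

    def __len__(self):
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._records

    def __getitem__(self, protein_id: str) -> ProteinRecord:
        return self._records[protein_id]

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def lengths(self) -> list[int]:
        return [len(rec) for rec in self._records.values()]


def read_fasta(path: str | Path, strip_version: bool = False) -> ProteinSet:
    """Read a proteome FASTA file into a :class:`ProteinSet`.

    The record id is the first whitespace-delimited token of the header.
    ``strip_version`` removes a trailing ``.N`` version suffix (versioned
    transcript ids need stable ids for mapping).  Duplicate ids raise.
    """
    proteins = ProteinSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if strip_version:
            head, dot, tail = pid.rpartition(".")
            if dot and tail.isdigit():
                pid = head
        proteins.add(ProteinRecord(id=pid, sequence=str(rec.seq)))
    if len(proteins) == 0:
        warnings.warn(f"FASTA file {path!s} contains no records")
    return proteins


@dataclass(frozen=True)
class LengthSummary:
    """Distribution summary of peptide sequence lengths."""

    n: int
    min: int
    q1: float
    median: float
    q3: float
    max: int
    mean: float
    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "min": self.min,
            "q1": self.q1,
            "median": self.median,
            "q3": self.q3,
            "max": self.max,
            "mean": self.mean,
            "histogram": {"bin_edges": list(self.bin_edges), "counts": list(self.counts)},
        }


def length_summary(proteins: ProteinSet, bin_width: int = 100) -> LengthSummary:
    """Summary statistics and a histogram of sequence lengths.

    Quartiles use linear interpolation between order statistics (the
    numpy default).  Histogram bins start at 0 with the given width;
    the last bin is extended to include the maximum length.
    """
    if len(proteins) == 0:
        raise ValueError("cannot summarize an empty protein set")
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    lengths = np.asarray(proteins.lengths())
    q1, med, q3 = np.quantile(lengths, [0.25, 0.5, 0.75])
    n_bins = int(lengths.max() // bin_width) + 1
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    return LengthSummary(
        n=int(lengths.size),
        min=int(lengths.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=int(lengths.max()),
        mean=float(statistics.fmean(lengths.tolist())),
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(int(c) for c in counts),
    )


@dataclass(frozen=True)
class HomologyHit:
    """One pairwise alignment record (one BLAST tabular line)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int = 0
    gap_opens: int = 0
    q_start: int = 1
    q_end: int = 1
    s_start: int = 1
    s_end: int = 1
    e_value: float = 0.0
    bit_score: float = 0.0

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity must be in [0, 100]")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")


TARGET_TO_TEMPLATE = "target_to_template"
TEMPLATE_TO_TARGET = "template_to_target"


@dataclass
class HomologyTable:
    """All hits of one search direction, in file order.

    Multiple high-scoring pairs per (query, subject) are retained here;
    collapsing to one representative per pair happens downstream.
    """

    direction: str
    hits: list[HomologyHit] = field(default_factory=list)

    def __post_init__(self):
        if self.direction not in (TARGET_TO_TEMPLATE, TEMPLATE_TO_TARGET):
            raise ValueError(
                f"direction must be {TARGET_TO_TEMPLATE!r} or {TEMPLATE_TO_TARGET!r}"
            )

    def __len__(self):
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)


def read_homology_table(path: str | Path, direction: str) -> HomologyTable:
    """Parse a 12-column BLAST tabular file ('outfmt 6').

    Lines beginning with ``#`` are ignored.  A wrong column count or an
    unparseable numeric field raises with the offending line number.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                hits.append(
                    HomologyHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        percent_identity=float(fields[2]),
                        alignment_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        e_value=float(fields[10]),
                        bit_score=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return HomologyTable(direction=direction, hits=hits)


def write_homology_table(table: HomologyTable, path: str | Path) -> None:
    """Write a table back to the 12-column tabular dialect (read∘write = id)."""
    with open(path, "w") as fh:
        for h in table.hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id,
                        h.subject_id,
                        repr(h.percent_identity),
                        h.alignment_length,
                        h.mismatches,
                        h.gap_opens,
                        h.q_start,
                        h.q_end,
                        h.s_start,
                        h.s_end,
                        repr(h.e_value),
                        repr(h.bit_score),
                    )
                )
                + "\n"
            )
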