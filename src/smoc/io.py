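"""Sequence and annotation I/O plus basic sequence utilities.

All coordinates inside the package are 0-based, half-open.  Conversion to the
1-based inclusive convention happens only when serializing GFF3.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY*X")

FEATURE_TYPES = {
    "n_terminal_domain",
    "c_terminal_domain",
    "repeat_unit",
    "linker",
    "intron",
    "exon",
    "motif",
    "gene",
}


class ParseError(ValueError):
    """Raised on malformed FASTA/FASTQ/GFF3 input."""


@dataclass
class SeqRecord:
    """A named sequence, optionally with per-base Phred quality scores."""

    id: str
    sequence: str
    qualities: Optional[list[int]] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: {len(self.qualities)} quality values for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Annotation:
    """A feature interval on a named sequence (0-based, half-open)."""

    seq_id: str
    start: int
    end: int
    feature_type: str
    label: str = ""
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def shift(self, offset: int) -> "Annotation":
        return Annotation(
            self.seq_id, self.start + offset, self.end + offset,
            self.feature_type, self.label, self.strand,
        )


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords (uppercased, file order)."""
    records = []
    # scan manually first so malformed input yields a line-numbered error
    with open(path) as fh:
        lineno = 0
        current_header = None
        seen_seq = False
        for line in fh:
            lineno += 1
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current_header is not None and not seen_seq:
                    raise ParseError(f"line {lineno}: record {current_header!r} has no sequence")
                if line == ">":
                    raise ParseError(f"line {lineno}: empty FASTA header")
                current_header = line[1:].split()[0]
                seen_seq = False
            else:
                if current_header is None:
                    raise ParseError(f"line {lineno}: sequence before any header")
                seen_seq = True
        if current_header is not None and not seen_seq:
            raise ParseError(f"line {lineno}: record {current_header!r} has no sequence")
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SeqRecord(id=rec.id, sequence=str(rec.seq)))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Read Phred+33 FASTQ; qualities decoded to integers."""
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            records.append(
                SeqRecord(
                    id=rec.id,
                    sequence=str(rec.seq),
                    qualities=list(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:
        raise ParseError(str(exc)) from exc
    return records


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            quals = rec.qualities
            if quals is None:
                quals = [40] * len(rec.sequence)
            qline = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qline}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(annotations: Sequence[Annotation], path: str | Path,
               source: str = "smoc") -> None:
    """Write annotations as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            attrs = f"Name={ann.label}" if ann.label else "."
            fh.write(
                "\t".join([
                    ann.seq_id, source, ann.feature_type,
                    str(ann.start + 1), str(ann.end), ".",
                    ann.strand, ".", attrs,
                ]) + "\n"
            )


def read_gff3(path: str | Path) -> list[Annotation]:
    annotations = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"line {lineno}: expected 9 columns, got {len(fields)}")
            seq_id, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            label = ""
            m = re.search(r"Name=([^;]+)", attrs)
            if m:
                label = m.group(1)
            annotations.append(
                Annotation(seq_id, int(start) - 1, int(end), ftype, label, strand)
            )
    return annotations


# ---------------------------------------------------------------------------
# Sequence utilities
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    if not set(seq) <= DNA_ALPHABET:
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise ValueError(f"non-DNA characters: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, frame: int = 0) -> str:
    """Translate DNA in the given frame; stops are '*', trailing partial codon dropped."""
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    sub = seq[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate())
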