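"""Sequence I/O: FASTA/FASTQ reading and writing, translation, reference pooling.

Records are lightweight and in-memory; parsing is delegated to Biopython's
``SeqIO`` so that header conventions, line wrapping and edge cases follow the
standard behaviour. All readers transparently handle gzip-compressed files.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

NUCLEOTIDE = "nucleotide"
AMINO_ACID = "amino_acid"

#: The 20 standard residues; everything else produced by translation is
#: normalised to 'X' (or kept as '*' for stops).
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_AA = frozenset("BJXZ")


class SeqFormatError(ValueError):
    """Raised for malformed or inconsistent sequence files."""


@dataclass
class SeqRecord:
    """A named sequence.

    ``id`` is the first whitespace-delimited token of the header;
    ``description`` is the remainder (may be empty). ``alphabet`` is either
    ``"nucleotide"`` or ``"amino_acid"`` and is a tag, not an enforced
    constraint on every character (IUPAC ambiguity codes are allowed).
    """

    id: str
    seq: str
    description: str = ""
    alphabet: str = NUCLEOTIDE

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqFormatError("sequence record with empty id")

    def __len__(self) -> int:
        return len(self.seq)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path, alphabet: str = NUCLEOTIDE) -> list[SeqRecord]:
    """Read a (possibly gzipped) FASTA file into a list of records.

    Raises :class:`SeqFormatError` on duplicate ids or empty sequences; a
    missing file raises the usual ``FileNotFoundError``.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq)
            if not seq:
                raise SeqFormatError(f"record {rec.id!r} in {path} has an empty sequence")
            if rec.id in seen:
                raise SeqFormatError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
            records.append(SeqRecord(id=rec.id, seq=seq, description=desc, alphabet=alphabet))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 80) -> Path:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as handle:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i : i + width] + "\n")
    return path


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Read a (possibly gzipped) 4-line-per-record FASTQ file.

    Quality strings are discarded; records come back as nucleotide
    :class:`SeqRecord` objects in file order.
    """
    records: list[SeqRecord] = []
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
                records.append(SeqRecord(id=rec.id, seq=str(rec.seq), description=desc, alphabet=NUCLEOTIDE))
        except ValueError as exc:
            raise SeqFormatError(f"truncated or malformed FASTQ record ~#{len(records) + 1} in {path}: {exc}") from exc
    return records


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> Path:
    """Write records as FASTQ with uniform placeholder qualities."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as handle:
        for rec in records:
            handle.write(f"@{rec.id}\n{rec.seq}\n+\n{'I' * len(rec.seq)}\n")
    return path


def pool_references(paths: Sequence[str | Path], out_path: str | Path) -> tuple[Path, list[SeqRecord]]:
    """Pool one or more amino-acid FASTA files into a single file.

    Reference proteins may be spread over many files; downstream stages want
    one pooled database. Ids must be unique across the whole pool.
    """
    if not paths:
        raise ValueError("pool_references requires at least one input path")
    pooled: list[SeqRecord] = []
    origin: dict[str, str] = {}
    for p in paths:
        for rec in read_fasta(p, alphabet=AMINO_ACID):
            if rec.id in origin:
                raise SeqFormatError(
                    f"reference id {rec.id!r} occurs in both {origin[rec.id]} and {p}"
                )
            origin[rec.id] = str(p)
            pooled.append(rec)
    out = write_fasta(pooled, out_path)
    return out, pooled


def revcomp(nt: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return str(Seq(nt).reverse_complement())


def translate(nt: str, frame: int = 1) -> str:
    """Translate a nucleotide string in one of the six frames.

    ``frame`` is in {1, 2, 3, -1, -2, -3}: the sign selects the strand
    (negative = reverse complement), the magnitude the 0-, 1- or 2-base
    offset. Uses the standard genetic code; a trailing partial codon is
    dropped. Stop codons become ``*``. Codons with ambiguity codes translate
    to a single residue only when every resolution agrees (e.g. GCN -> A);
    otherwise they become ``X``.
    """
    if frame not in (1, 2, 3, -1, -2, -3):
        raise ValueError(f"frame must be in {{±1, ±2, ±3}}, got {frame}")
    s = nt if frame > 0 else revcomp(nt)
    offset = abs(frame) - 1
    s = s[offset:]
    s = s[: len(s) - len(s) % 3]
    if not s:
        return ""
    aa = str(Seq(s).translate())
    # Biopython resolves ambiguity codes to B/Z/J/etc. where possible; we
    # only keep resolutions that name one standard residue.
    return "".join(c if (c in STANDARD_AA or c == "*") else "X" for c in aa)
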