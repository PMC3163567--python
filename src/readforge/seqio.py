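"""Readers/writers and elementary sequence operations.

FASTA and FASTQ (PHRED+33) input/output plus reverse complementation.
Gzip-compressed files are handled transparently by the ``.gz`` extension.
Only uppercase ``A C G T N`` are accepted as bases (lowercase input is
uppercased on read); qualities are integer PHRED scores in ``[0, 60]``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

VALID_BASES = frozenset("ACGTN")
QUAL_MIN = 0
QUAL_MAX = 60

#: Illumina paired-end library adapter (identical for both mates); read into
#: the insert whenever the insert is shorter than the read length.
ILLUMINA_PE_ADAPTER = (
    "AGATCGGAAGAGCGGTTCAGCAGGAATGCCGAGACCGATCTCGTATGCCGTCTTCTGCTTG"
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of ``seq``; ``N`` maps to ``N``.

    Raises ``ValueError`` on characters outside ``{A,C,G,T,N}``.
    """
    if not set(seq) <= VALID_BASES:
        bad = sorted(set(seq) - VALID_BASES)
        raise ValueError(f"invalid base(s) {bad} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadRecord:
    """One sequencing read: identifier, bases and per-base PHRED qualities."""

    id: str
    seq: str
    qual: list[int] = field(repr=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read id must be non-empty")
        if not set(self.seq) <= VALID_BASES:
            bad = sorted(set(self.seq) - VALID_BASES)
            raise ValueError(f"read {self.id!r}: invalid base(s) {bad}")
        self.qual = list(self.qual)
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )
        if self.qual and not (QUAL_MIN <= min(self.qual) and max(self.qual) <= QUAL_MAX):
            raise ValueError(
                f"read {self.id!r}: quality outside [{QUAL_MIN}, {QUAL_MAX}]"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _mate_stem(read_id: str) -> str:
    stem = read_id.split()[0]
    if len(stem) > 2 and stem[-2] == "/" and stem[-1] in "12":
        stem = stem[:-2]
    return stem


@dataclass
class ReadPair:
    """A forward/reverse read pair from one cluster."""

    fwd: ReadRecord
    rev: ReadRecord

    def __post_init__(self) -> None:
        if _mate_stem(self.fwd.id) != _mate_stem(self.rev.id):
            raise ValueError(
                f"mate ids differ: {self.fwd.id!r} vs {self.rev.id!r}"
            )


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open a possibly gzip-compressed text file by extension."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream ``ReadRecord`` objects from a 4-line PHRED+33 FASTQ file.

    Malformed records raise ``ValueError`` naming the (0-based) record index.
    """
    with open_text(path) as handle:
        it = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual_str = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"FASTQ record {index} in {path}: {exc}") from exc
            quals = [ord(c) - 33 for c in qual_str]
            try:
                yield ReadRecord(id=title.split()[0], seq=seq.upper(), qual=quals)
            except ValueError as exc:
                raise ValueError(f"FASTQ record {index} in {path}: {exc}") from exc
            index += 1


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> int:
    """Write records as 4-line PHRED+33 FASTQ. Returns the record count."""
    n = 0
    with open_text(path, "wt") as handle:
        for rec in records:
            handle.write(format_fastq(rec))
            n += 1
    return n


def format_fastq(rec: ReadRecord) -> str:
    qual_str = "".join(chr(q + 33) for q in rec.qual)
    return f"@{rec.id}\n{rec.seq}\n+\n{qual_str}\n"


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Stream ``(name, sequence)`` tuples from a FASTA file.

    Sequences are uppercased; names are the first whitespace-delimited
    token. An empty file raises ``ValueError``.
    """
    empty = True
    with open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            empty = False
            yield record.id, str(record.seq).upper()
    if empty:
        raise ValueError(f"no FASTA records in {path}")
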