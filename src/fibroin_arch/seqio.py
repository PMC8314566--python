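"""FASTA/FASTQ reading and writing.

Thin wrappers over Biopython that fix the package's conventions: ids and
sequences round-trip unchanged, sequences are upper-cased on read, FASTA
wraps at 60 columns, FASTQ is the plain 4-line dialect with qualities
preserved verbatim, and ``.gz`` paths are handled transparently.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from .errors import ParseError
from .simulate import Read


@dataclass(frozen=True)
class FastaRecord:
    id: str
    sequence: str


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Parse FASTA; sequences are upper-cased, empty files give []."""
    import io

    with _open_text(path, "r") as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected '>' header, got {line.strip()[:20]!r}"
                )
            break
    try:
        return [
            FastaRecord(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(io.StringIO(text), "fasta")
        ]
    except ValueError as exc:  # pragma: no cover - malformed mid-file
        raise ParseError(f"{path}: {exc}") from exc


def write_fasta(records: Iterable[FastaRecord | tuple[str, str]], path: str | Path) -> None:
    """Write FASTA wrapped at 60 columns."""
    seq_records = []
    for rec in records:
        rid, seq = (rec.id, rec.sequence) if isinstance(rec, FastaRecord) else rec
        seq_records.append(SeqRecord(Seq(seq), id=rid, description=""))
    with _open_text(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def read_fastq(path: str | Path) -> list[Read]:
    """Parse 4-line FASTQ (optionally gzipped); qualities kept verbatim."""
    reads: list[Read] = []
    with _open_text(path, "r") as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                reads.append(Read(title.split()[0], seq.upper(), qual))
        except ValueError as exc:
            where = f" after read {reads[-1].read_id!r}" if reads else ""
            raise ParseError(f"{path}{where}: {exc}") from exc
    return reads


def write_fastq(reads: Sequence[Read], path: str | Path) -> None:
    with _open_text(path, "w") as fh:
        for read in reads:
            if len(read.sequence) != len(read.quality):
                raise ParseError(
                    f"read {read.read_id!r}: sequence and quality lengths differ"
                )
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{read.quality}\n")
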