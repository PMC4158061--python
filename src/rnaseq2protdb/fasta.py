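"""Ordered protein FASTA databases with provenance-tagged entries.

``FastaDatabase`` is the common output currency of every builder in this
package: an ordered list of ``(header, sequence)`` records where each record
additionally carries a provenance tag (``reference``, ``sap``, ``splice``,
``contaminant`` or ``decoy``).  Headers are unique within a database and
sequences are non-empty protein strings over the 20 amino acids plus ``X``
(unknown) and ``*`` (stop).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROVENANCE_TAGS = ("reference", "sap", "splice", "contaminant", "decoy")

_LINE_WIDTH = 60


@dataclass(frozen=True)
class FastaRecord:
    """One protein entry: full header line (without ``>``), sequence, tag."""

    header: str
    sequence: str
    tag: str = "reference"

    def __post_init__(self) -> None:
        if not self.header:
            raise ValueError("FASTA record header must be non-empty")
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.header!r}")
        if self.tag not in PROVENANCE_TAGS:
            raise ValueError(f"unknown provenance tag {self.tag!r}")

    @property
    def entry_id(self) -> str:
        """First whitespace-delimited token of the header."""
        return self.header.split()[0]


def _infer_tag(header: str) -> str:
    if header.startswith("rev_"):
        return "decoy"
    if header.startswith("sap|"):
        return "sap"
    if header.startswith("jnc|"):
        return "splice"
    return "reference"


class FastaDatabase:
    """Ordered collection of :class:`FastaRecord` with unique headers."""

    def __init__(self, records: Iterable[FastaRecord] = ()) -> None:
        self._records: list[FastaRecord] = []
        self._headers: set[str] = set()
        for rec in records:
            self.append(rec)

    def append(self, record: FastaRecord) -> None:
        if record.header in self._headers:
            raise ValueError(f"duplicate header in database: {record.header!r}")
        self._records.append(record)
        self._headers.add(record.header)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[FastaRecord]:
        return iter(self._records)

    def __getitem__(self, i: int) -> FastaRecord:
        return self._records[i]

    def __contains__(self, header: str) -> bool:
        return header in self._headers

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FastaDatabase):
            return NotImplemented
        return self._records == other._records

    @property
    def headers(self) -> list[str]:
        return [r.header for r in self._records]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self._records]

    @classmethod
    def from_fasta(cls, path: str | Path, tag: str | None = None) -> "FastaDatabase":
        """Read a protein FASTA file.

        When ``tag`` is None the per-record provenance is inferred from the
        header prefix (``sap|`` / ``jnc|`` / ``rev_``), defaulting to
        ``reference``.
        """
        db = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            header = rec.description
            db.append(
                FastaRecord(
                    header=header,
                    sequence=str(rec.seq).upper(),
                    tag=tag if tag is not None else _infer_tag(header),
                )
            )
        return db

    def to_fasta(self) -> str:
        """Serialize to FASTA text with fixed 60-column wrapping."""
        chunks: list[str] = []
        for rec in self._records:
            chunks.append(f">{rec.header}\n")
            for i in range(0, len(rec.sequence), _LINE_WIDTH):
                chunks.append(rec.sequence[i : i + _LINE_WIDTH] + "\n")
        return "".join(chunks)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_fasta())

    def to_seqrecords(self) -> list[SeqRecord]:
        return [
            SeqRecord(Seq(r.sequence), id=r.entry_id, description=r.header)
            for r in self._records
        ]
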