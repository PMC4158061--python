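"""Genome FASTA / GTF readers, coordinate mapping and DNA translation.

All internal genomic coordinates are 1-based inclusive (the GTF/VCF
convention); BED conversion happens at the file boundary in
:mod:`rnaseq2protdb.splice_db`.  The GTF frame/phase column is ignored:
reading frame is derived from the CDS concatenation starting at offset 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pyranges
from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable

__all__ = [
    "CODON_TABLE",
    "CoordinateError",
    "GenomeSequence",
    "TranscriptModel",
    "build_codon_table",
    "genomic_to_protein_position",
    "load_gene_models",
    "load_genome",
    "reverse_complement",
    "spliced_cds_sequence",
    "translate_dna",
]

_DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def build_codon_table() -> dict[str, str]:
    """Standard genetic code as a 64-entry codon → amino-acid mapping.

    Stops map to ``'*'``.  Derived from Biopython's table 1 so the standard
    code is never transcribed by hand here.
    """
    table = _BioCodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for codon in table.stop_codons:
        mapping[codon] = "*"
    assert len(mapping) == 64
    return mapping


CODON_TABLE: Mapping[str, str] = build_codon_table()


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class CoordinateError(ValueError):
    """A genomic position that cannot be mapped into a transcript's CDS.

    ``region`` is one of ``"intronic"``, ``"utr"`` or ``"outside"``.
    """

    def __init__(self, message: str, region: str):
        super().__init__(message)
        self.region = region


class GenomeSequence:
    """Chromosome-name → uppercase DNA sequence store."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r}")
            seq = seq.upper()
            bad = set(seq) - _DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )
            self._seqs[name] = seq

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __iter__(self):
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Extract ``chrom[start..end]``, 1-based inclusive, bounds-checked."""
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        n = len(self._seqs[chrom])
        if not (1 <= start <= end <= n):
            raise ValueError(
                f"interval [{start}..{end}] outside [1..{n}] on {chrom}"
            )
        return self._seqs[chrom][start - 1 : end]


def load_genome(path: str | Path) -> GenomeSequence:
    """Read a genome FASTA; sequences are uppercased, duplicate names error."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence name in {path}: {rec.id!r}")
        if len(rec.seq) == 0:
            raise ValueError(f"empty record in {path}: {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeSequence(seqs)


@dataclass
class TranscriptModel:
    """One transcript: exon/CDS intervals (1-based inclusive, ascending)."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    protein_id: str | None = None
    inconsistent: bool = False  # CDS feature without an enclosing exon

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        for intervals, what in ((self.exons, "exon"), (self.cds, "CDS")):
            prev_end = 0
            for start, end in intervals:
                if start > end:
                    raise ValueError(
                        f"{self.transcript_id}: inverted {what} interval {start}..{end}"
                    )
                if start <= prev_end:
                    raise ValueError(
                        f"{self.transcript_id}: {what} intervals overlap or are unsorted"
                    )
                prev_end = end

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds)

    @property
    def is_translatable(self) -> bool:
        """CDS present, length divisible by 3, and model internally consistent."""
        return (
            bool(self.cds) and self.cds_length % 3 == 0 and not self.inconsistent
        )

    @property
    def span(self) -> tuple[int, int]:
        intervals = self.exons or self.cds
        return intervals[0][0], intervals[-1][1]


def _contained(inner: tuple[int, int], outer: list[tuple[int, int]]) -> bool:
    return any(s <= inner[0] and inner[1] <= e for s, e in outer)


def load_gene_models(path: str | Path) -> dict[str, TranscriptModel]:
    """Read exon/CDS features from a GTF into transcript models.

    Returns a mapping transcript_id → :class:`TranscriptModel`.  Exon and CDS
    lists are sorted ascending by genomic start regardless of strand.  A CDS
    interval not contained in any exon flags the model ``inconsistent`` (with
    a warning) rather than raising.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pyranges.read_gtf(str(path), as_df=True)
    df = df[df["Feature"].isin(["exon", "CDS"])]
    if "transcript_id" not in df.columns:
        raise ValueError(f"{path}: no transcript_id attributes found")

    models: dict[str, TranscriptModel] = {}
    for (tid,), grp in df.groupby(["transcript_id"], sort=True):
        strands = set(grp["Strand"])
        if not strands <= {"+", "-"}:
            raise ValueError(
                f"transcript {tid}: unsupported strand value(s) {strands - {'+', '-'}}"
            )
        if len(strands) != 1 or grp["Chromosome"].nunique() != 1:
            raise ValueError(f"transcript {tid}: features span strands/chromosomes")
        gene_id = str(grp["gene_id"].iloc[0])
        protein_id = None
        if "protein_id" in grp.columns:
            pids = grp["protein_id"].dropna()
            if len(pids):
                protein_id = str(pids.iloc[0])
        exons, cds = [], []
        for row in grp.itertuples(index=False):
            # pyranges converts to 0-based half-open; restore 1-based inclusive
            iv = (int(row.Start) + 1, int(row.End))
            (exons if row.Feature == "exon" else cds).append(iv)
        exons.sort()
        cds.sort()
        inconsistent = False
        for iv in cds:
            if exons and not _contained(iv, exons):
                warnings.warn(
                    f"transcript {tid}: CDS {iv[0]}..{iv[1]} has no enclosing exon; "
                    "model flagged inconsistent"
                )
                inconsistent = True
        models[str(tid)] = TranscriptModel(
            transcript_id=str(tid),
            gene_id=gene_id,
            chrom=str(grp["Chromosome"].iloc[0]),
            strand=strands.pop(),
            exons=exons,
            cds=cds,
            protein_id=protein_id,
            inconsistent=inconsistent,
        )
    return models


def spliced_cds_sequence(t: TranscriptModel, genome: GenomeSequence) -> str:
    """Concatenated CDS sequence in transcript (5'→3') orientation."""
    if not t.cds:
        raise ValueError(f"transcript {t.transcript_id} has no CDS")
    seq = "".join(genome.fetch(t.chrom, s, e) for s, e in t.cds)
    return reverse_complement(seq) if t.strand == "-" else seq


def translate_dna(seq: str, frame: int = 0) -> str:
    """Translate DNA from codon offset ``frame`` (0..2).

    Trailing 1-2 nt are dropped; stops are emitted as ``'*'`` (never
    truncated here — stop handling is the caller's policy); codons containing
    ``N`` become ``'X'``.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    seq = seq.upper()
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    out = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append("X" if "N" in codon else CODON_TABLE[codon])
    return "".join(out)


def genomic_to_protein_position(
    t: TranscriptModel, genomic_pos: int
) -> tuple[int, int, int]:
    """Map a genomic position inside the CDS to transcript coordinates.

    Returns ``(cds_pos, protein_pos, codon_offset)`` where ``cds_pos`` counts
    transcript-oriented coding bases from 1, ``protein_pos = ceil(cds_pos/3)``
    and ``codon_offset = (cds_pos - 1) % 3``.  On the '-' strand the mapping
    runs antiparallel to genomic coordinates.

    Raises :class:`CoordinateError` with ``region`` distinguishing intronic,
    UTR and outside-transcript positions.
    """
    offset = 0
    for start, end in t.cds:
        if start <= genomic_pos <= end:
            if t.strand == "+":
                cds_pos = offset + (genomic_pos - start) + 1
            else:
                # antiparallel: count from the 3'-most genomic base
                tail = sum(
                    e - s + 1 for s, e in t.cds if s > end
                )
                cds_pos = tail + (end - genomic_pos) + 1
            protein_pos = (cds_pos + 2) // 3
            return cds_pos, protein_pos, (cds_pos - 1) % 3
        offset += end - start + 1

    span = t.span
    if genomic_pos < span[0] or genomic_pos > span[1]:
        region = "outside"
    elif any(s <= genomic_pos <= e for s, e in t.exons):
        region = "utr"
    else:
        region = "intronic"
    raise CoordinateError(
        f"position {t.chrom}:{genomic_pos} is outside the CDS of "
        f"{t.transcript_id} ({region})",
        region=region,
    )
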