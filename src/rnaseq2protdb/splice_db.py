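"""Novel splice-junction detection and three-frame translated database.

Junctions are described by their intron interval (1-based inclusive).  Two
BED dialects are read: the TopHat ``junctions.bed`` BED12 two-block dialect,
where the inner block boundaries define the intron, and a plain 6-column BED
whose interval IS the intron (0-based half-open, as BED always is).

Entry header grammar:
``jnc|<chrom>:<intron_start>-<intron_end>|s.<strand>|f.<frame><orientation>|d.<depth>|o.<junction_offset_aa>``
where ``orientation`` is ``+`` for translations of the orientation-corrected
junction sequence and ``-`` for its reverse complement (only produced for
unstranded ``.`` junctions, which are translated in six frames).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from rnaseq2protdb.fasta import FastaDatabase, FastaRecord
from rnaseq2protdb.seq_model import (
    GenomeSequence,
    TranscriptModel,
    reverse_complement,
    translate_dna,
)

__all__ = [
    "Junction",
    "SpliceEntry",
    "SpliceBuildReport",
    "SpliceParams",
    "parse_junction_bed",
    "known_junctions_from_models",
    "novel_junctions",
    "junction_flanking_sequence",
    "translate_junction",
    "build_splice_database",
]


@dataclass(frozen=True)
class Junction:
    """One splice junction: intron interval, strand, read depth, overhangs."""

    chrom: str
    intron_start: int  # first intronic base, 1-based
    intron_end: int  # last intronic base, 1-based
    strand: str = "."
    depth: int = 0
    left_overhang: int = 0
    right_overhang: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise ValueError(
                f"junction {self.name or self.chrom}: intron_start > intron_end"
            )
        if self.depth < 0:
            raise ValueError("junction depth must be non-negative")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid junction strand {self.strand!r}")

    def key(self, strand_aware: bool = False) -> tuple:
        if strand_aware:
            return (self.chrom, self.intron_start, self.intron_end, self.strand)
        return (self.chrom, self.intron_start, self.intron_end)


@dataclass(frozen=True)
class SpliceEntry:
    header: str
    sequence: str
    frame: int
    orientation: str
    junction_offset_aa: int
    depth: int


def parse_junction_bed(path: str | Path) -> list[Junction]:
    """Read junctions from BED12 (TopHat dialect) or 6-column intron BED.

    The dialect is auto-detected per line by column count.  BED12 records
    must have exactly two blocks; others are rejected with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    junctions: list[Junction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) >= 12:
                jct = _parse_bed12(cols, lineno)
                if jct is not None:
                    junctions.append(jct)
            elif len(cols) >= 6:
                chrom_start, chrom_end = int(cols[1]), int(cols[2])
                junctions.append(
                    Junction(
                        chrom=cols[0],
                        intron_start=chrom_start + 1,  # half-open → 1-based
                        intron_end=chrom_end,
                        strand=cols[5],
                        depth=int(float(cols[4])),
                        name=cols[3],
                    )
                )
            else:
                warnings.warn(f"{path}:{lineno}: fewer than 6 BED columns; skipped")
    return junctions


def _parse_bed12(cols: list[str], lineno: int) -> Junction | None:
    block_count = int(cols[9])
    if block_count != 2:
        warnings.warn(
            f"BED12 line {lineno}: {block_count} blocks (expected 2); rejected"
        )
        return None
    chrom_start = int(cols[1])
    sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
    starts = [int(x) for x in cols[11].rstrip(",").split(",")]
    return Junction(
        chrom=cols[0],
        intron_start=chrom_start + sizes[0] + 1,
        intron_end=chrom_start + starts[1],
        strand=cols[5],
        depth=int(float(cols[4])),
        left_overhang=sizes[0],
        right_overhang=sizes[1],
        name=cols[3],
    )


def known_junctions_from_models(
    models: dict[str, TranscriptModel] | list[TranscriptModel],
) -> set[tuple[str, int, int, str]]:
    """Introns between consecutive exons of each multi-exon transcript.

    Returned as a set of ``(chrom, intron_start, intron_end, strand)`` keys,
    deduplicated across transcripts sharing an intron.
    """
    if isinstance(models, dict):
        models = list(models.values())
    known: set[tuple[str, int, int, str]] = set()
    for t in models:
        for (s1, e1), (s2, e2) in zip(t.exons, t.exons[1:]):
            known.add((t.chrom, e1 + 1, s2 - 1, t.strand))
    return known


def novel_junctions(
    observed: list[Junction],
    known: set[tuple],
    strand_aware: bool = False,
) -> list[Junction]:
    """Observed junctions whose intron key is absent from ``known``.

    ``known`` may contain 3-tuples or 4-tuples (with strand); keys are
    normalized to the requested ``strand_aware`` arity.  Input order is
    preserved.
    """
    norm = {k[:4] if strand_aware else k[:3] for k in known}
    return [j for j in observed if j.key(strand_aware) not in norm]


def junction_flanking_sequence(
    j: Junction, genome: GenomeSequence, flank_nt: int = 66
) -> tuple[str, int] | None:
    """Exonic sequence flanking the intron, intron excised.

    Returns ``(dna, junction_offset_nt)`` where the splice boundary lies
    between positions ``junction_offset_nt`` and ``junction_offset_nt + 1``
    of ``dna`` (1-based).  Flanks are truncated at chromosome ends; a
    junction with zero flank on either side is skipped (returns None with a
    warning).  For '-' strand junctions the reverse complement is returned
    and the offset adjusted.
    """
    if flank_nt < 3:
        raise ValueError("flank_nt must be >= 3")
    chrom_len = genome.length(j.chrom)
    left_start = max(1, j.intron_start - flank_nt)
    right_end = min(chrom_len, j.intron_end + flank_nt)
    if j.intron_start - 1 < 1 or j.intron_end + 1 > chrom_len:
        warnings.warn(
            f"junction {j.chrom}:{j.intron_start}-{j.intron_end} at chromosome "
            "edge leaves no flank on one side; skipped"
        )
        return None
    left = genome.fetch(j.chrom, left_start, j.intron_start - 1)
    right = genome.fetch(j.chrom, j.intron_end + 1, right_end)
    dna = left + right
    if j.strand == "-":
        return reverse_complement(dna), len(right)
    return dna, len(left)


def _junction_codon(offset_nt: int, frame: int, protein_len: int) -> int | None:
    """1-based residue whose codon contains the splice boundary.

    The boundary sits between nucleotides ``offset_nt`` and ``offset_nt+1``;
    the codon containing the first nucleotide after the boundary is used when
    the boundary falls exactly between codons.  None when that codon is not
    fully inside the translation.
    """
    if offset_nt < frame:  # boundary precedes the first full codon
        aa = 1
    else:
        aa = (offset_nt - frame) // 3 + 1
    if aa > protein_len:
        return None
    return aa


def translate_junction(
    dna: str, strand: str = "."
) -> list[tuple[int, str, str]]:
    """Three-frame (stranded) or six-frame (unstranded) translations.

    Returns a list of ``(frame, orientation, protein)`` tuples where
    orientation ``'+'`` marks translations of ``dna`` as given and ``'-'``
    translations of its reverse complement (unstranded junctions only).
    """
    if len(dna) < 3:
        return []
    out = [(f, "+", translate_dna(dna, f)) for f in range(3)]
    if strand == ".":
        rc = reverse_complement(dna)
        out += [(f, "-", translate_dna(rc, f)) for f in range(3)]
    return [(f, o, p) for f, o, p in out if p]


@dataclass
class SpliceParams:
    flank_nt: int = 66
    min_len_aa: int = 8
    min_depth: int = 0
    drop_stop: bool = True
    strand_aware: bool = False


@dataclass
class SpliceBuildReport:
    n_observed: int = 0
    n_known: int = 0
    n_novel: int = 0
    removed_depth: int = 0
    skipped_edge: int = 0
    removed_length: int = 0
    removed_stop: int = 0
    removed_offset_outside: int = 0
    n_entries: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def build_splice_database(
    observed: list[Junction],
    known: set[tuple],
    genome: GenomeSequence,
    params: SpliceParams | None = None,
) -> tuple[FastaDatabase, SpliceBuildReport]:
    """Full pipeline: novelty subtraction, flank extraction, translation,
    depth/length/stop filtering.

    Depth filtering uses ``depth >= min_depth`` to keep a junction.  One
    entry is emitted per surviving (junction, frame, orientation).
    """
    params = params or SpliceParams()
    report = SpliceBuildReport(n_observed=len(observed), n_known=len(known))
    novel = novel_junctions(observed, known, params.strand_aware)
    report.n_novel = len(novel)

    db = FastaDatabase()
    for j in novel:
        if j.depth < params.min_depth:
            report.removed_depth += 1
            continue
        flanked = junction_flanking_sequence(j, genome, params.flank_nt)
        if flanked is None:
            report.skipped_edge += 1
            continue
        dna, offset_nt = flanked
        for frame, orientation, protein in translate_junction(dna, j.strand):
            if orientation == "-":
                boundary = len(dna) - offset_nt
            else:
                boundary = offset_nt
            offset_aa = _junction_codon(boundary, frame, len(protein))
            if offset_aa is None:
                report.removed_offset_outside += 1
                continue
            if len(protein) < params.min_len_aa:
                report.removed_length += 1
                continue
            if params.drop_stop and "*" in protein:
                report.removed_stop += 1
                continue
            header = (
                f"jnc|{j.chrom}:{j.intron_start}-{j.intron_end}"
                f"|s.{j.strand}|f.{frame}{orientation}|d.{j.depth}|o.{offset_aa}"
            )
            db.append(FastaRecord(header=header, sequence=protein, tag="splice"))
    report.n_entries = len(db)
    return db, report


_JNC_HEADER_RE = re.compile(
    r"^jnc\|(?P<chrom>[^:|]+):(?P<start>\d+)-(?P<end>\d+)"
    r"\|s\.(?P<strand>[+\-.])\|f\.(?P<frame>[0-2])(?P<orientation>[+\-])"
    r"\|d\.(?P<depth>\d+)\|o\.(?P<offset>\d+)"
)


def parse_splice_header(header: str) -> dict:
    """Parse a ``jnc|`` header into its fields."""
    m = _JNC_HEADER_RE.match(header.split()[0])
    if not m:
        raise ValueError(f"unparseable splice header: {header!r}")
    d = m.groupdict()
    for k in ("start", "end", "frame", "depth", "offset"):
        d[k] = int(d[k])
    return d
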