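"""Convert annotated missense SNVs into a FASTA of SAP polypeptide windows.

A SAP (single amino acid polymorphism) entry is a window of the mutated
protein centred on the substituted residue, with a structured header that
records the genomic SNP, the CDS change, the protein change and the window
coordinates:

``sap|<tid>|g.<chrom>:<pos><ref>><alt>|c.<cdspos><refnt>><altnt>|p.<refaa><pos><altaa>|w.<start>-<end>``

Multiple transcript blocks for an identical deduplicated window are joined
with ``;`` after the leading ``sap|``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pysam
from Bio.SeqUtils import seq1

from rnaseq2protdb.fasta import FastaDatabase, FastaRecord
from rnaseq2protdb.seq_model import (
    CoordinateError,
    GenomeSequence,
    TranscriptModel,
    genomic_to_protein_position,
    spliced_cds_sequence,
    translate_dna,
)

__all__ = [
    "VariantEffect",
    "SapRecord",
    "SapBuildReport",
    "parse_variant_effects",
    "apply_sap",
    "sap_window",
    "build_sap_database",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# SAP header block, e.g. t1|g.chr1:52A>G|c.14A>G|p.Y5C|w.2-8
_HEADER_BLOCK_RE = re.compile(
    r"(?P<tid>[^|;]+)\|"
    r"g\.(?P<chrom>[^:]+):(?P<gpos>\d+)(?P<ref>[ACGT])>(?P<alt>[ACGT])\|"
    r"c\.(?P<cpos>\d+)(?P<refnt>[ACGT])>(?P<altnt>[ACGT])\|"
    r"p\.(?P<refaa>[A-Z])(?P<ppos>\d+)(?P<altaa>[A-Z])\|"
    r"w\.(?P<wstart>\d+)-(?P<wend>\d+)"
)


@dataclass(frozen=True)
class VariantEffect:
    """One missense consequence of one SNV on one transcript."""

    chrom: str
    genomic_pos: int
    ref_allele: str
    alt_allele: str
    transcript_id: str
    effect_class: str  # "missense" | "other"
    ref_aa: str = ""
    alt_aa: str = ""
    protein_pos: int = 0
    cds_pos: int | None = None

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError("only single-nucleotide substitutions are supported")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.effect_class == "missense" and self.ref_aa == self.alt_aa:
            raise ValueError("missense effect requires ref_aa != alt_aa")


@dataclass(frozen=True)
class SapRecord:
    header: str
    sequence: str
    transcript_id: str
    sap_offset_in_window: int


@dataclass
class SapBuildReport:
    """Aggregated per-effect outcomes of a SAP database build."""

    n_effects: int = 0
    applied: int = 0
    skipped_missing_transcript: int = 0
    skipped_untranslatable: int = 0
    skipped_not_in_cds: int = 0
    mismatched: int = 0
    dropped_stop_window: int = 0
    merged_duplicates: int = 0
    n_entries: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


_AA3_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")
_AA1_RE = re.compile(r"^p?\.?([A-Z])(\d+)([A-Z])$")


def _parse_hgvs_p(text: str) -> tuple[str, str, int] | None:
    """Parse p.Tyr5Cys / p.Y5C into (ref_aa, alt_aa, protein_pos)."""
    m = _AA3_RE.match(text)
    if m:
        try:
            return seq1(m.group(1)), seq1(m.group(3)), int(m.group(2))
        except (KeyError, ValueError):
            return None
    m = _AA1_RE.match(text)
    if m:
        return m.group(1), m.group(3), int(m.group(2))
    return None


_CDS_POS_RE = re.compile(r"^(\d+)(?:/\d+)?$")


def _effects_from_ann(
    rec, ann_entries: tuple[str, ...]
) -> tuple[list[VariantEffect], int]:
    effects: list[VariantEffect] = []
    skipped = 0
    for entry in ann_entries:
        fields = entry.split("|")
        if len(fields) < 11:
            skipped += 1
            warnings.warn(
                f"malformed ANN entry at {rec.chrom}:{rec.pos}: {entry!r}"
            )
            continue
        allele, annotation, tid, hgvs_p = fields[0], fields[1], fields[6], fields[10]
        terms = set(annotation.split("&"))
        if "missense_variant" not in terms:
            continue
        if rec.alts is None or allele not in rec.alts:
            skipped += 1
            warnings.warn(
                f"ANN allele {allele!r} not among ALTs at {rec.chrom}:{rec.pos}"
            )
            continue
        if len(rec.ref) != 1 or len(allele) != 1:
            continue  # not an SNV; out of scope
        parsed = _parse_hgvs_p(hgvs_p)
        if parsed is None:
            skipped += 1
            warnings.warn(
                f"unparseable HGVS.p {hgvs_p!r} at {rec.chrom}:{rec.pos}"
            )
            continue
        ref_aa, alt_aa, protein_pos = parsed
        cds_pos = None
        if len(fields) > 12:
            m = _CDS_POS_RE.match(fields[12])
            if m:
                cds_pos = int(m.group(1))
        effects.append(
            VariantEffect(
                chrom=rec.chrom,
                genomic_pos=rec.pos,
                ref_allele=rec.ref.upper(),
                alt_allele=allele.upper(),
                transcript_id=tid,
                effect_class="missense",
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                protein_pos=protein_pos,
                cds_pos=cds_pos,
            )
        )
    return effects, skipped


_EFF_RE = re.compile(r"^(?P<name>[^()]+)\((?P<body>.*)\)$")


def _effects_from_eff(rec, eff_entries: tuple[str, ...]) -> tuple[list[VariantEffect], int]:
    """Legacy SnpEff EFF format:
    Effect(Impact|Functional_Class|Codon_Change|AA_Change|AA_Len|Gene|BioType|Coding|Transcript_ID|Rank...)
    """
    effects: list[VariantEffect] = []
    skipped = 0
    for entry in eff_entries:
        m = _EFF_RE.match(entry)
        if not m:
            skipped += 1
            warnings.warn(f"malformed EFF entry at {rec.chrom}:{rec.pos}: {entry!r}")
            continue
        if "missense" not in m.group("name").lower() and (
            "NON_SYNONYMOUS_CODING" not in m.group("name")
        ):
            continue
        body = m.group("body").split("|")
        if len(body) < 9:
            skipped += 1
            warnings.warn(f"malformed EFF body at {rec.chrom}:{rec.pos}: {entry!r}")
            continue
        aa_change = body[3].split("/")[0]
        parsed = _parse_hgvs_p(aa_change)
        if parsed is None:
            skipped += 1
            warnings.warn(f"unparseable EFF amino-acid change {aa_change!r}")
            continue
        ref_aa, alt_aa, protein_pos = parsed
        if rec.alts is None or len(rec.ref) != 1:
            continue
        for alt in rec.alts:
            if len(alt) != 1:
                continue
            effects.append(
                VariantEffect(
                    chrom=rec.chrom,
                    genomic_pos=rec.pos,
                    ref_allele=rec.ref.upper(),
                    alt_allele=alt.upper(),
                    transcript_id=body[8],
                    effect_class="missense",
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    protein_pos=protein_pos,
                )
            )
    return effects, skipped


def parse_variant_effects(path: str | Path) -> list[VariantEffect]:
    """Read missense effects from a VCF with SnpEff ANN (or legacy EFF) INFO.

    One :class:`VariantEffect` per (variant, transcript) annotation pair;
    only missense annotations are retained and multi-allelic sites are
    expanded per alt allele.  Malformed annotation entries are skipped with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    effects: list[VariantEffect] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if "ANN" in rec.info:
                found, _ = _effects_from_ann(rec, rec.info["ANN"])
            elif "EFF" in rec.info:
                found, _ = _effects_from_eff(rec, rec.info["EFF"])
            else:
                continue
            effects.extend(found)
    return effects


class ReferenceMismatchError(ValueError):
    """Annotated reference amino acid disagrees with the translated protein."""


def apply_sap(protein: str, protein_pos: int, ref_aa: str, alt_aa: str) -> str:
    """Substitute ``alt_aa`` at ``protein_pos`` (1-based), verifying ``ref_aa``."""
    if not 1 <= protein_pos <= len(protein):
        raise ValueError(
            f"protein_pos {protein_pos} outside protein of length {len(protein)}"
        )
    if protein[protein_pos - 1] != ref_aa:
        raise ReferenceMismatchError(
            f"reference mismatch at position {protein_pos}: translated "
            f"{protein[protein_pos - 1]!r}, annotated {ref_aa!r}"
        )
    return protein[: protein_pos - 1] + alt_aa + protein[protein_pos:]


def sap_window(
    protein_with_sap: str, protein_pos: int, flank: int
) -> tuple[str, int, int]:
    """Extract the ±``flank`` residue window around the SAP.

    Returns ``(window, window_start, sap_offset_in_window)``, 1-based;
    silently truncated at the protein termini.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    if not 1 <= protein_pos <= len(protein_with_sap):
        raise ValueError(
            f"protein_pos {protein_pos} outside protein of length "
            f"{len(protein_with_sap)}"
        )
    start = max(1, protein_pos - flank)
    end = min(len(protein_with_sap), protein_pos + flank)
    return protein_with_sap[start - 1 : end], start, protein_pos - start + 1


def build_sap_database(
    effects: list[VariantEffect],
    models: dict[str, TranscriptModel],
    genome: GenomeSequence,
    flank: int = 20,
    trust_annotation: bool = False,
) -> tuple[FastaDatabase, SapBuildReport]:
    """Build the SAP window FASTA from missense effects.

    For each effect the transcript CDS is spliced and translated, the
    annotated reference amino acid is verified against our own translation
    (unless ``trust_annotation``), the substitution is applied and the
    flanking window extracted.  Windows containing ``'*'`` (premature stop in
    the reference translation) are dropped.  Exact duplicate windows carrying
    the same substitution are collapsed into one entry whose header lists all
    source transcript blocks.
    """
    report = SapBuildReport(n_effects=len(effects))
    # dedupe key -> (window, sap_offset, [header blocks], first transcript)
    seen: dict[tuple[str, str, str, int], list] = {}
    order: list[tuple[str, str, str, int]] = []

    for eff in effects:
        if eff.effect_class != "missense":
            continue
        model = models.get(eff.transcript_id)
        if model is None:
            report.skipped_missing_transcript += 1
            warnings.warn(f"transcript {eff.transcript_id} not in gene models; skipped")
            continue
        if not model.is_translatable:
            report.skipped_untranslatable += 1
            continue
        try:
            cds_pos, protein_pos, _ = genomic_to_protein_position(
                model, eff.genomic_pos
            )
        except CoordinateError:
            report.skipped_not_in_cds += 1
            continue
        cds_seq = spliced_cds_sequence(model, genome)
        protein = translate_dna(cds_seq, 0)
        if protein.endswith("*"):
            protein = protein[:-1]
        if protein_pos > len(protein):
            report.mismatched += 1
            continue
        if model.strand == "-":
            refnt = eff.ref_allele.translate(_COMPLEMENT)
            altnt = eff.alt_allele.translate(_COMPLEMENT)
        else:
            refnt, altnt = eff.ref_allele, eff.alt_allele
        if not trust_annotation:
            if protein[protein_pos - 1] != eff.ref_aa:
                report.mismatched += 1
                continue
            if cds_seq[cds_pos - 1] != refnt:
                report.mismatched += 1
                continue
            if eff.protein_pos and eff.protein_pos != protein_pos:
                report.mismatched += 1
                continue
        try:
            mutated = apply_sap(protein, protein_pos, protein[protein_pos - 1],
                                eff.alt_aa)
        except ReferenceMismatchError:  # pragma: no cover - guarded above
            report.mismatched += 1
            continue
        window, wstart, sap_off = sap_window(mutated, protein_pos, flank)
        if "*" in window:
            report.dropped_stop_window += 1
            continue
        wend = wstart + len(window) - 1
        block = (
            f"{eff.transcript_id}"
            f"|g.{eff.chrom}:{eff.genomic_pos}{eff.ref_allele}>{eff.alt_allele}"
            f"|c.{cds_pos}{refnt}>{altnt}"
            f"|p.{eff.ref_aa}{protein_pos}{eff.alt_aa}"
            f"|w.{wstart}-{wend}"
        )
        key = (window, eff.ref_aa, eff.alt_aa, sap_off)
        if key in seen:
            if block not in seen[key][2]:
                seen[key][2].append(block)
            report.merged_duplicates += 1
        else:
            seen[key] = [window, sap_off, [block], eff.transcript_id]
            order.append(key)
        report.applied += 1

    db = FastaDatabase()
    for key in order:
        window, sap_off, blocks, _tid = seen[key]
        db.append(
            FastaRecord(header="sap|" + ";".join(blocks), sequence=window, tag="sap")
        )
    report.n_entries = len(db)
    return db, report


def parse_sap_header(header: str) -> list[dict]:
    """Parse a ``sap|`` header into per-transcript block dictionaries."""
    if not header.startswith("sap|"):
        raise ValueError(f"not a SAP header: {header!r}")
    blocks = []
    for block in header.split()[0][4:].split(";"):
        m = _HEADER_BLOCK_RE.match(block)
        if not m:
            raise ValueError(f"unparseable SAP header block: {block!r}")
        d = m.groupdict()
        for k in ("gpos", "cpos", "ppos", "wstart", "wend"):
            d[k] = int(d[k])
        blocks.append(d)
    return blocks
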