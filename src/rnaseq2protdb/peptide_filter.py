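"""Partition identified peptides into reference-matching vs novel.

A peptide is a reference hit iff its bare sequence occurs as a contiguous
substring of any reference entry; matching is plain substring (not
enzyme-aware), with I and L folded to a common symbol by default because the
two are isobaric and indistinguishable in the upstream MS workflow.

Novel peptides are then mapped back to the custom SAP/splice databases that
were searched, classed ``sap`` when they overlap the substituted residue of
a SAP window, ``splice`` when they match a junction entry, and ``other``
otherwise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from rnaseq2protdb.fasta import FastaDatabase
from rnaseq2protdb.sap_db import parse_sap_header
from rnaseq2protdb.splice_db import parse_splice_header

__all__ = [
    "NovelPeptideAnnotation",
    "PeptideIdentification",
    "annotate_novel_peptides",
    "filter_in_reference",
    "load_peptides",
    "normalize_peptide",
    "unique_variant_sites",
]

_AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")

# Modification normalization grammar, applied in order:
#   1. strip flanking-residue dots:  K.PEPTIDER.A -> PEPTIDER
#   2. drop bracketed tokens:        PEPT[+57.02]IDER, PEPT(ox)IDER
#   3. drop lowercase/non-letter:    PEPTIDERph, n-term marks
_FLANK_RE = re.compile(r"^(?:[A-Z*-]\.)?(?P<core>.*?)(?:\.[A-Z*-])?$")
_BRACKET_RE = re.compile(r"\[[^\]]*\]|\([^)]*\)|\{[^}]*\}")


def normalize_peptide(raw: str) -> str:
    """Strip modification tokens and flanking residues from a peptide string."""
    core = _FLANK_RE.match(raw.strip()).group("core")
    core = _BRACKET_RE.sub("", core)
    core = "".join(c for c in core if c.isalpha() and c.isupper())
    return core


@dataclass(frozen=True)
class PeptideIdentification:
    """One identified peptide (bare sequence, modifications stripped)."""

    peptide: str
    score: float = 0.0
    spectrum_id: str | None = None

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("peptide sequence must be non-empty")
        bad = set(self.peptide) - _AA20
        if bad:
            raise ValueError(
                f"peptide {self.peptide!r} contains non-standard residues {sorted(bad)}"
            )


def load_peptides(path: str | Path) -> list[PeptideIdentification]:
    """Read a peptide TSV with columns ``peptide``, ``score``
    and optional ``spectrum_id``; peptide strings are normalized at ingest."""
    df = pd.read_csv(path, sep="\t")
    if "peptide" not in df.columns:
        raise ValueError(f"{path}: missing 'peptide' column")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PeptideIdentification(
                peptide=normalize_peptide(str(row.peptide)),
                score=float(getattr(row, "score", 0.0)),
                spectrum_id=(
                    str(row.spectrum_id) if hasattr(row, "spectrum_id") else None
                ),
            )
        )
    return out


_IL_FOLD = str.maketrans("IL", "JJ")


def _fold(seq: str, equate_il: bool) -> str:
    return seq.translate(_IL_FOLD) if equate_il else seq


def filter_in_reference(
    peptides: list[PeptideIdentification],
    reference: FastaDatabase,
    equate_il: bool = True,
) -> tuple[list[PeptideIdentification], list[PeptideIdentification]]:
    """Split peptides into (reference_hits, novel).

    The partition is exhaustive and exclusive; input order is preserved
    within each part.  ``equate_il`` folds I/L to a common symbol on both
    sides before substring matching.
    """
    if len(reference) == 0:
        raise ValueError("reference database is empty")
    # single scan text with a separator outside the peptide alphabet, so a
    # match can never span two entries
    text = "\x00".join(_fold(s, equate_il) for s in reference.sequences)
    hits, novel = [], []
    for p in peptides:
        (hits if _fold(p.peptide, equate_il) in text else novel).append(p)
    return hits, novel


@dataclass
class NovelPeptideAnnotation:
    peptide: str
    matched_headers: list[str] = field(default_factory=list)
    inferred_class: str = "other"  # sap | splice | other
    variant_site_keys: list[tuple[str, int, str]] = field(default_factory=list)
    junction_keys: list[tuple[str, int, int]] = field(default_factory=list)


def _sap_match_sites(
    peptide: str, window: str, header: str, equate_il: bool
) -> list[tuple[str, int, str]]:
    """Variant site keys for occurrences of ``peptide`` covering the SAP."""
    sites: list[tuple[str, int, str]] = []
    blocks = parse_sap_header(header)
    folded_win = _fold(window, equate_il)
    folded_pep = _fold(peptide, equate_il)
    for block in blocks:
        sap_off = block["ppos"] - block["wstart"] + 1  # 1-based in window
        start = 0
        while True:
            idx = folded_win.find(folded_pep, start)
            if idx == -1:
                break
            if idx + 1 <= sap_off <= idx + len(peptide):
                sites.append((block["chrom"], block["gpos"], block["alt"]))
                break
            start = idx + 1
    return sites


def annotate_novel_peptides(
    novel: list[PeptideIdentification],
    custom_dbs: list[FastaDatabase],
    equate_il: bool = True,
) -> list[NovelPeptideAnnotation]:
    """Map novel peptides onto the custom databases used in the search.

    Classes: ``sap`` when the peptide matches a SAP window AND overlaps the
    substituted residue (a match in the wild-type stretch of a window stays
    ``other``); ``splice`` when it matches a junction entry; ``other``
    otherwise.  A peptide matching both kinds is classed ``sap``.
    """
    annotations = []
    for p in novel:
        ann = NovelPeptideAnnotation(peptide=p.peptide)
        folded_pep = _fold(p.peptide, equate_il)
        for db in custom_dbs:
            for rec in db:
                if folded_pep not in _fold(rec.sequence, equate_il):
                    continue
                if rec.header.startswith("sap|"):
                    sites = _sap_match_sites(
                        p.peptide, rec.sequence, rec.header, equate_il
                    )
                    if sites:
                        ann.inferred_class = "sap"
                        for s in sites:
                            if s not in ann.variant_site_keys:
                                ann.variant_site_keys.append(s)
                        ann.matched_headers.append(rec.header)
                    # match not covering the SAP: not evidence, not recorded
                elif rec.header.startswith("jnc|"):
                    d = parse_splice_header(rec.header)
                    if ann.inferred_class != "sap":
                        ann.inferred_class = "splice"
                    key = (d["chrom"], d["start"], d["end"])
                    if key not in ann.junction_keys:
                        ann.junction_keys.append(key)
                    ann.matched_headers.append(rec.header)
                else:
                    ann.matched_headers.append(rec.header)
        annotations.append(ann)
    return annotations


def unique_variant_sites(
    annotations: list[NovelPeptideAnnotation],
) -> tuple[int, int, pd.DataFrame]:
    """Collapse SAP peptide annotations to unique variant sites.

    Returns ``(n_sap_peptides, n_unique_sites, site_table)``; peptides
    mapping to multiple sites count toward each site and are flagged in the
    table's ``multi_site`` column.
    """
    sap = [a for a in annotations if a.inferred_class == "sap"]
    site_rows: dict[tuple[str, int, str], dict] = {}
    for a in sap:
        multi = len(a.variant_site_keys) > 1
        for key in a.variant_site_keys:
            row = site_rows.setdefault(
                key,
                {
                    "chrom": key[0],
                    "genomic_pos": key[1],
                    "alt_allele": key[2],
                    "n_peptides": 0,
                    "peptides": [],
                    "multi_site": False,
                },
            )
            row["n_peptides"] += 1
            row["peptides"].append(a.peptide)
            row["multi_site"] = row["multi_site"] or multi
    table = pd.DataFrame(
        [
            {**row, "peptides": ";".join(row["peptides"])}
            for row in site_rows.values()
        ]
    )
    n_sites = len(site_rows)
    if all(len(a.variant_site_keys) == 1 for a in sap):
        assert n_sites <= len(sap)
    return len(sap), n_sites, table
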