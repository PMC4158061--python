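"""Transcript-abundance (TPM) annotation and reduction of a protein database.

The reduced database keeps only entries whose linked transcript abundance is
strictly above the threshold (default 1 TPM, reading "above" literally).
Entries lacking a transcript mapping or an abundance value are removed by
default; ``keep_unmapped`` preserves them, mitigating the documented risk of
discarding proteins with high protein but low transcript abundance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

from rnaseq2protdb.fasta import FastaDatabase, FastaRecord
from rnaseq2protdb.seq_model import TranscriptModel

__all__ = [
    "ProteinTranscriptMap",
    "ReductionReport",
    "annotate_and_reduce",
    "load_abundance",
    "map_proteins_to_transcripts",
    "rna_protein_correlation",
]

_TRANSCRIPT_HEADER_RE = re.compile(r"\btranscript:(\S+)")


def load_abundance(path: str | Path) -> dict[str, float]:
    """Read an RSEM isoform-results style TSV into transcript_id → TPM.

    Requires ``transcript_id`` and ``TPM`` columns (others ignored);
    duplicate transcript ids and negative TPM values are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("transcript_id", "TPM"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["transcript_id"].duplicated().any():
        dups = df.loc[df["transcript_id"].duplicated(), "transcript_id"].tolist()
        raise ValueError(f"{path}: duplicate transcript ids {dups}")
    tpm = df["TPM"].astype(float)
    if (tpm < 0).any():
        raise ValueError(f"{path}: negative TPM values")
    return dict(zip(df["transcript_id"].astype(str), tpm))


@dataclass
class ProteinTranscriptMap:
    """Protein entry id → transcript id, with unmapped entries tracked."""

    mapping: dict[str, str] = field(default_factory=dict)
    unmapped: list[str] = field(default_factory=list)

    def get(self, protein_id: str) -> str | None:
        return self.mapping.get(protein_id)


def map_proteins_to_transcripts(
    proteome: FastaDatabase,
    models: dict[str, TranscriptModel] | None = None,
    explicit_map: str | Path | dict[str, str] | None = None,
) -> ProteinTranscriptMap:
    """Link each protein entry to its transcript.

    Precedence: explicit two-column map > GTF ``protein_id``/``transcript_id``
    pairing > Ensembl-style ``transcript:ENSTxxx`` header token.  Proteins
    resolvable by no source are listed in ``unmapped`` (a reported state,
    not an error).
    """
    explicit: dict[str, str] = {}
    if isinstance(explicit_map, (str, Path)):
        df = pd.read_csv(explicit_map, sep="\t", header=None, comment="#")
        explicit = dict(zip(df[0].astype(str), df[1].astype(str)))
    elif isinstance(explicit_map, dict):
        explicit = dict(explicit_map)

    gtf_map: dict[str, str] = {}
    if models:
        for t in models.values():
            if t.protein_id:
                gtf_map[t.protein_id] = t.transcript_id

    result = ProteinTranscriptMap()
    for rec in proteome:
        pid = rec.entry_id
        tid = explicit.get(pid) or gtf_map.get(pid)
        if tid is None:
            m = _TRANSCRIPT_HEADER_RE.search(rec.header)
            if m:
                tid = m.group(1)
        if tid is None:
            result.unmapped.append(pid)
        else:
            result.mapping[pid] = tid
    return result


@dataclass
class ReductionReport:
    threshold_tpm: float
    n_input: int = 0
    n_kept: int = 0
    n_removed_low_tpm: int = 0
    n_unmapped: int = 0
    n_unmapped_kept: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _format_tpm(tpm: float) -> str:
    return f"{tpm:g}"


def annotate_and_reduce(
    proteome: FastaDatabase,
    ptmap: ProteinTranscriptMap,
    abundance: dict[str, float],
    threshold_tpm: float = 1.0,
    keep_unmapped: bool = False,
) -> tuple[FastaDatabase, FastaDatabase, ReductionReport]:
    """Annotate headers with TPM and filter by ``tpm > threshold_tpm``.

    Returns ``(annotated, reduced, report)``.  Annotation suffixes every
    header with `` TPM=<value|NA>`` without touching sequences; the reduced
    database keeps entries strictly above the threshold, plus unmapped /
    unquantified entries when ``keep_unmapped`` is set.
    """
    if threshold_tpm < 0:
        raise ValueError("threshold_tpm must be >= 0")
    report = ReductionReport(threshold_tpm=threshold_tpm, n_input=len(proteome))
    annotated = FastaDatabase()
    reduced = FastaDatabase()
    for rec in proteome:
        tid = ptmap.get(rec.entry_id)
        tpm = abundance.get(tid) if tid is not None else None
        suffix = f" TPM={_format_tpm(tpm)}" if tpm is not None else " TPM=NA"
        ann = FastaRecord(rec.header + suffix, rec.sequence, rec.tag)
        annotated.append(ann)
        if tpm is None:
            report.n_unmapped += 1
            if keep_unmapped:
                reduced.append(ann)
                report.n_unmapped_kept += 1
        elif tpm > threshold_tpm:
            reduced.append(ann)
            report.n_kept += 1
        else:
            report.n_removed_low_tpm += 1
    return annotated, reduced, report


def rna_protein_correlation(
    abundance: dict[str, float],
    peptide_ids: list[tuple[str, str]],
    ptmap: ProteinTranscriptMap,
) -> tuple[float | None, int, pd.DataFrame]:
    """Spearman rank correlation between spectral counts and TPM.

    ``peptide_ids`` is a list of ``(peptide, protein_entry_id)`` pairs; the
    spectral count of a protein is its number of peptide identifications.
    Returns ``(rho, n, table)`` with a per-protein table of count vs TPM;
    ``rho`` is None when fewer than 3 proteins have both values.
    """
    if not peptide_ids:
        raise ValueError("peptide_ids must be non-empty")
    counts: dict[str, int] = {}
    for _pep, pid in peptide_ids:
        counts[pid] = counts.get(pid, 0) + 1
    rows = []
    for pid, count in counts.items():
        tid = ptmap.get(pid)
        tpm = abundance.get(tid) if tid is not None else None
        rows.append({"protein_id": pid, "spectral_count": count, "tpm": tpm})
    table = pd.DataFrame(rows)
    both = table.dropna(subset=["tpm"])
    n = len(both)
    if n < 3:
        return None, n, table
    rho = float(stats.spearmanr(both["spectral_count"], both["tpm"]).statistic)
    return rho, n, table
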