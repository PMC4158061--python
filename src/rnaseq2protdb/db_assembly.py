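"""Search-database assembly: concatenation and reversed-sequence decoys."""

from __future__ import annotations

from dataclasses import dataclass, field

from rnaseq2protdb.fasta import FastaDatabase, FastaRecord

__all__ = [
    "DecoyResult",
    "FastaDatabase",
    "FastaRecord",
    "generate_decoys",
    "merge_databases",
]

DECOY_PREFIX = "rev_"


def merge_databases(
    parts: list[FastaDatabase], on_duplicate_sequence: str = "keep_all"
) -> FastaDatabase:
    """Concatenate databases preserving part order.

    ``keep_all`` keeps every entry; header collisions across parts are
    resolved by suffixing the colliding entry's provenance tag (and a counter
    if needed).  ``collapse`` merges entries with identical sequences into
    one record whose header concatenates all source headers with ``;``.
    """
    if not parts:
        raise ValueError("merge_databases requires at least one part")
    if on_duplicate_sequence not in ("keep_all", "collapse"):
        raise ValueError(f"unknown mode {on_duplicate_sequence!r}")

    merged = FastaDatabase()
    if on_duplicate_sequence == "keep_all":
        for part in parts:
            for rec in part:
                header = rec.header
                if header in merged:
                    header = f"{rec.header}|{rec.tag}"
                    k = 2
                    while header in merged:
                        header = f"{rec.header}|{rec.tag}{k}"
                        k += 1
                merged.append(FastaRecord(header, rec.sequence, rec.tag))
        return merged

    # collapse: first occurrence wins the position and tag
    by_seq: dict[str, list[str]] = {}
    order: list[str] = []
    tags: dict[str, str] = {}
    for part in parts:
        for rec in part:
            if rec.sequence in by_seq:
                by_seq[rec.sequence].append(rec.header)
            else:
                by_seq[rec.sequence] = [rec.header]
                tags[rec.sequence] = rec.tag
                order.append(rec.sequence)
    for seq in order:
        merged.append(FastaRecord(";".join(by_seq[seq]), seq, tags[seq]))
    return merged


@dataclass
class DecoyResult:
    database: FastaDatabase
    palindromic_headers: list[str] = field(default_factory=list)


def generate_decoys(db: FastaDatabase, method: str = "reverse") -> DecoyResult:
    """One decoy per target: sequence reversed, header prefixed ``rev_``.

    Target order is preserved.  Palindromic sequences (decoy identical to
    target — allowed) are flagged in the result.
    """
    if method != "reverse":
        raise ValueError(f"unsupported decoy method {method!r}")
    if len(db) == 0:
        raise ValueError("cannot generate decoys for an empty database")
    decoys = FastaDatabase()
    palindromes: list[str] = []
    for rec in db:
        rev = rec.sequence[::-1]
        if rev == rec.sequence:
            palindromes.append(rec.header)
        decoys.append(FastaRecord(DECOY_PREFIX + rec.header, rev, "decoy"))
    return DecoyResult(database=decoys, palindromic_headers=palindromes)
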