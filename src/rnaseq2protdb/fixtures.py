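"""Deterministic synthetic fixtures with a machine-readable truth manifest.

Generates a toy genome, GTF gene models, a reference proteome, an annotated
VCF, junction BEDs, an abundance table and a peptide identification list —
everything the builders consume — together with a manifest of planted ground
truth (expected SAP windows, junction translations, reduced-database
membership, peptide class labels).

Oracle independence is a hard rule here: this module must not import any of
the builder modules, so translation, reverse complementation and coordinate
arithmetic are deliberately reimplemented from scratch (literal codon table,
direct string slicing).  All outputs are pure functions of (parameters,
seed).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "ToyReference",
    "generate_toy_reference",
    "plant_variants",
    "plant_junctions",
    "simulate_abundance_and_peptides",
    "generate_fixture_set",
    "PRESETS",
]

# Literal standard genetic code — intentionally duplicated here rather than
# shared with the translation module, so fixture truths stay independent.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

AA_3LETTER = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe",
    "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "L": "Leu",
    "M": "Met", "N": "Asn", "P": "Pro", "Q": "Gln", "R": "Arg",
    "S": "Ser", "T": "Thr", "V": "Val", "W": "Trp", "Y": "Tyr",
    "*": "Ter",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

STOP_CODONS = ("TAA", "TAG", "TGA")


def _revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def _translate(seq: str, frame: int = 0) -> str:
    out = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append("X" if "N" in codon else GENETIC_CODE[codon])
    return "".join(out)


@dataclass
class ToyReference:
    """In-memory handle on a generated fixture set."""

    out_dir: Path
    genome: dict[str, str]
    manifest: dict

    @property
    def genome_fasta(self) -> Path:
        return self.out_dir / "genome.fasta"

    @property
    def gtf(self) -> Path:
        return self.out_dir / "models.gtf"

    @property
    def proteome_fasta(self) -> Path:
        return self.out_dir / "proteome.fasta"

    @property
    def vcf(self) -> Path:
        return self.out_dir / "variants.vcf"

    @property
    def known_bed(self) -> Path:
        return self.out_dir / "known_junctions.bed"

    @property
    def observed_bed(self) -> Path:
        return self.out_dir / "observed_junctions.bed"

    @property
    def abundance_tsv(self) -> Path:
        return self.out_dir / "abundance.tsv"

    @property
    def peptides_tsv(self) -> Path:
        return self.out_dir / "peptides.tsv"

    @property
    def manifest_json(self) -> Path:
        return self.out_dir / "manifest.json"

    def save_manifest(self) -> None:
        self.manifest_json.write_text(
            json.dumps(self.manifest, indent=1, sort_keys=True) + "\n"
        )


def _random_coding_sequence(rng: random.Random, n_aa: int) -> tuple[str, str]:
    """CDS (with stop) and protein of length ``n_aa`` with no internal stop."""
    sense_codons = [c for c, aa in sorted(GENETIC_CODE.items()) if aa != "*"]
    codons = ["ATG"]
    protein = ["M"]
    for _ in range(n_aa - 1):
        c = rng.choice(sense_codons)
        codons.append(c)
        protein.append(GENETIC_CODE[c])
    codons.append(rng.choice(STOP_CODONS))
    return "".join(codons), "".join(protein)


def generate_toy_reference(
    out_dir: str | Path,
    n_chroms: int = 1,
    n_genes: int = 8,
    exons_per_gene: tuple[int, int] = (2, 4),
    chrom_len: int = 50_000,
    protein_len_range: tuple[int, int] = (40, 120),
    seed: int = 0,
) -> ToyReference:
    """Generate genome FASTA, GTF and reference proteome with planted genes.

    Genes are multi-exon, on both strands (alternating) with every CDS
    starting ATG, ending with a stop and free of internal in-frame stops.
    Raises if the requested genes cannot fit on the chromosomes.
    """
    if n_chroms < 1 or n_genes < 1:
        raise ValueError("n_chroms and n_genes must be positive")
    if exons_per_gene[0] < 1 or exons_per_gene[0] > exons_per_gene[1]:
        raise ValueError("invalid exons_per_gene range")
    rng = random.Random(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genome = {
        f"chr{i + 1}": "".join(rng.choice("ACGT") for _ in range(chrom_len))
        for i in range(n_chroms)
    }
    cursors = {chrom: 200 for chrom in genome}
    genes = []
    for gi in range(n_genes):
        chrom = f"chr{gi % n_chroms + 1}"
        strand = "+" if gi % 2 == 0 else "-"
        n_aa = rng.randint(*protein_len_range)
        cds_seq, protein = _random_coding_sequence(rng, n_aa)  # incl. stop
        n_exons = rng.randint(*exons_per_gene)
        # split CDS+stop into n_exons chunks of >= 12 nt
        total = len(cds_seq)
        while True:
            cuts = sorted(rng.sample(range(12, total - 11), n_exons - 1)) if n_exons > 1 else []
            bounds = [0] + cuts + [total]
            if all(b - a >= 12 for a, b in zip(bounds, bounds[1:])):
                break
        chunks = [cds_seq[a:b] for a, b in zip(bounds, bounds[1:])]
        introns = ["".join(rng.choice("ACGT") for _ in range(rng.randint(60, 300)))
                   for _ in range(n_exons - 1)]
        utr5 = "".join(rng.choice("ACGT") for _ in range(6))
        utr3 = "".join(rng.choice("ACGT") for _ in range(6))

        # sense-orientation layout: utr5 | chunk1 | intron1 | ... | chunkN | utr3
        blocks = [("utr5", utr5)]
        for i, chunk in enumerate(chunks):
            blocks.append(("cds", chunk))
            if i < len(introns):
                blocks.append(("intron", introns[i]))
        blocks.append(("utr3", utr3))
        sense = "".join(b for _, b in blocks)
        region_len = len(sense)

        start = cursors[chrom]
        end = start + region_len - 1
        if end > chrom_len - 200:
            raise ValueError(
                f"chromosome {chrom} too short for {n_genes} genes "
                f"(increase chrom_len)"
            )
        cursors[chrom] = end + rng.randint(200, 500)

        region_seq = sense if strand == "+" else _revcomp(sense)
        genome[chrom] = (
            genome[chrom][: start - 1] + region_seq + genome[chrom][end:]
        )

        # sense-coordinate block intervals → genomic intervals
        pos = 0
        sense_ivs = []
        for kind, b in blocks:
            sense_ivs.append((kind, pos + 1, pos + len(b)))
            pos += len(b)

        def to_genomic(s: int, e: int) -> tuple[int, int]:
            if strand == "+":
                return start + s - 1, start + e - 1
            return end - e + 1, end - s + 1

        cds_ivs = sorted(
            to_genomic(s, e) for kind, s, e in sense_ivs if kind == "cds"
        )
        # exons: merge UTRs into the first/last coding exon
        exon_sense = []
        for kind, s, e in sense_ivs:
            if kind == "intron":
                continue
            if exon_sense and exon_sense[-1][1] + 1 == s:
                exon_sense[-1] = (exon_sense[-1][0], e)
            else:
                exon_sense.append((s, e))
        exon_ivs = sorted(to_genomic(s, e) for s, e in exon_sense)

        gid, tid, pid = f"g{gi + 1:03d}", f"t{gi + 1:03d}", f"p{gi + 1:03d}"
        genes.append(
            {
                "gene_id": gid,
                "transcript_id": tid,
                "protein_id": pid,
                "chrom": chrom,
                "strand": strand,
                "exons": exon_ivs,
                "cds": cds_ivs,
                "cds_seq": cds_seq,
                "protein": protein,
            }
        )

    # -- write genome FASTA
    with open(out_dir / "genome.fasta", "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    # -- write GTF
    with open(out_dir / "models.gtf", "w") as fh:
        for g in genes:
            attr_base = f'gene_id "{g["gene_id"]}"; transcript_id "{g["transcript_id"]}";'
            rows = []
            for s, e in g["exons"]:
                rows.append((s, e, "exon", attr_base))
            for s, e in g["cds"]:
                rows.append(
                    (s, e, "CDS", attr_base + f' protein_id "{g["protein_id"]}";')
                )
            for s, e, feat, attrs in sorted(rows):
                fh.write(
                    f"{g['chrom']}\ttoy\t{feat}\t{s}\t{e}\t.\t{g['strand']}\t.\t{attrs}\n"
                )

    # -- write reference proteome (Ensembl-style headers)
    with open(out_dir / "proteome.fasta", "w") as fh:
        for g in genes:
            fh.write(
                f">{g['protein_id']} pep transcript:{g['transcript_id']} "
                f"gene:{g['gene_id']}\n{g['protein']}\n"
            )

    manifest = {
        "seed": seed,
        "params": {
            "n_chroms": n_chroms,
            "n_genes": n_genes,
            "exons_per_gene": list(exons_per_gene),
            "chrom_len": chrom_len,
        },
        "genes": genes,
    }
    ref = ToyReference(out_dir=out_dir, genome=genome, manifest=manifest)
    ref.save_manifest()
    return ref


def _cds_pos_to_genomic(gene: dict, cds_pos: int) -> int:
    """1-based transcript-oriented CDS position → genomic position."""
    ivs = gene["cds"]
    q = cds_pos
    if gene["strand"] == "+":
        for s, e in ivs:
            n = e - s + 1
            if q <= n:
                return s + q - 1
            q -= n
    else:
        for s, e in reversed(ivs):
            n = e - s + 1
            if q <= n:
                return e - q + 1
            q -= n
    raise ValueError(f"cds_pos {cds_pos} beyond CDS of {gene['transcript_id']}")


def plant_variants(
    ref: ToyReference,
    n_missense: int = 12,
    n_synonymous: int = 5,
    flank: int = 8,
    seed: int = 1,
) -> ToyReference:
    """Plant coding SNVs and write an annotated VCF.

    Missense sites are chosen so the ref→alt codon change alters the amino
    acid (never creating a stop); expected SAP windows are precomputed into
    the manifest by direct codon arithmetic — these are the independent
    oracle for the SAP builder.
    """
    rng = random.Random(seed)
    genes = ref.manifest["genes"]
    candidates = [
        (g, prot_pos)
        for g in genes
        for prot_pos in range(2, len(g["protein"]))  # skip start M and last aa
    ]
    if n_missense + n_synonymous > len(candidates):
        raise ValueError("requested variant count exceeds available codons")
    rng.shuffle(candidates)

    used_sites: set[tuple[str, int]] = set()
    used_window_keys: set[tuple] = set()
    missense, synonymous = [], []
    it = iter(candidates)
    while len(missense) < n_missense or len(synonymous) < n_synonymous:
        try:
            g, prot_pos = next(it)
        except StopIteration:
            raise ValueError("could not place all requested variants") from None
        want_missense = len(missense) < n_missense
        codon_start = 3 * (prot_pos - 1)
        codon = g["cds_seq"][codon_start : codon_start + 3]
        ref_aa = GENETIC_CODE[codon]
        choices = []
        for off in range(3):
            for alt_base in "ACGT":
                if alt_base == codon[off]:
                    continue
                alt_codon = codon[:off] + alt_base + codon[off + 1 :]
                alt_aa = GENETIC_CODE[alt_codon]
                if want_missense and alt_aa not in ("*", ref_aa):
                    choices.append((off, alt_base, alt_aa))
                elif not want_missense and alt_aa == ref_aa:
                    choices.append((off, alt_base, alt_aa))
        if not choices:
            continue
        off, alt_base, alt_aa = rng.choice(choices)
        cds_pos = codon_start + off + 1
        gpos = _cds_pos_to_genomic(g, cds_pos)
        if (g["chrom"], gpos) in used_sites:
            continue
        refnt = codon[off]  # transcript orientation
        if g["strand"] == "+":
            gref, galt = refnt, alt_base
        else:
            gref, galt = _COMP[refnt], _COMP[alt_base]

        if want_missense:
            mutated = (
                g["protein"][: prot_pos - 1] + alt_aa + g["protein"][prot_pos:]
            )
            ws = max(1, prot_pos - flank)
            we = min(len(mutated), prot_pos + flank)
            window = mutated[ws - 1 : we]
            sap_offset = prot_pos - ws + 1
            wkey = (window, ref_aa, alt_aa, sap_offset)
            if wkey in used_window_keys:
                continue
            used_window_keys.add(wkey)
            used_sites.add((g["chrom"], gpos))
            missense.append(
                {
                    "chrom": g["chrom"],
                    "genomic_pos": gpos,
                    "ref": gref,
                    "alt": galt,
                    "transcript_id": g["transcript_id"],
                    "gene_id": g["gene_id"],
                    "cds_pos": cds_pos,
                    "refnt": refnt,
                    "altnt": alt_base,
                    "protein_pos": prot_pos,
                    "ref_aa": ref_aa,
                    "alt_aa": alt_aa,
                    "window": window,
                    "window_start": ws,
                    "window_end": we,
                    "sap_offset": sap_offset,
                    "expected_header": (
                        f"sap|{g['transcript_id']}"
                        f"|g.{g['chrom']}:{gpos}{gref}>{galt}"
                        f"|c.{cds_pos}{refnt}>{alt_base}"
                        f"|p.{ref_aa}{prot_pos}{alt_aa}"
                        f"|w.{ws}-{we}"
                    ),
                }
            )
        else:
            used_sites.add((g["chrom"], gpos))
            synonymous.append(
                {
                    "chrom": g["chrom"],
                    "genomic_pos": gpos,
                    "ref": gref,
                    "alt": galt,
                    "transcript_id": g["transcript_id"],
                    "gene_id": g["gene_id"],
                    "cds_pos": cds_pos,
                    "protein_pos": prot_pos,
                    "aa": ref_aa,
                }
            )

    # -- write VCF
    records = []
    for v in missense:
        gene = next(
            g for g in genes if g["transcript_id"] == v["transcript_id"]
        )
        cds_len = len(gene["cds_seq"])
        aa_len = len(gene["protein"])
        ann = "|".join(
            [
                v["alt"],
                "missense_variant",
                "MODERATE",
                v["gene_id"],
                v["gene_id"],
                "transcript",
                v["transcript_id"],
                "protein_coding",
                "1/1",
                f"c.{v['cds_pos']}{v['refnt']}>{v['altnt']}",
                f"p.{AA_3LETTER[v['ref_aa']]}{v['protein_pos']}{AA_3LETTER[v['alt_aa']]}",
                f"{v['cds_pos']}/{cds_len}",
                f"{v['cds_pos']}/{cds_len}",
                f"{v['protein_pos']}/{aa_len}",
                "",
                "",
            ]
        )
        records.append((v["chrom"], v["genomic_pos"], v["ref"], v["alt"], ann))
    for v in synonymous:
        gene = next(
            g for g in genes if g["transcript_id"] == v["transcript_id"]
        )
        cds_len = len(gene["cds_seq"])
        aa_len = len(gene["protein"])
        ann = "|".join(
            [
                v["alt"],
                "synonymous_variant",
                "LOW",
                v["gene_id"],
                v["gene_id"],
                "transcript",
                v["transcript_id"],
                "protein_coding",
                "1/1",
                f"c.{v['cds_pos']}N>N",
                f"p.{AA_3LETTER[v['aa']]}{v['protein_pos']}{AA_3LETTER[v['aa']]}",
                f"{v['cds_pos']}/{cds_len}",
                f"{v['cds_pos']}/{cds_len}",
                f"{v['protein_pos']}/{aa_len}",
                "",
                "",
            ]
        )
        records.append((v["chrom"], v["genomic_pos"], v["ref"], v["alt"], ann))
    records.sort(key=lambda r: (r[0], r[1]))

    with open(ref.vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, seq in ref.genome.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write(
            '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional '
            "annotations: 'Allele | Annotation | Annotation_Impact | Gene_Name "
            "| Gene_ID | Feature_Type | Feature_ID | Transcript_BioType | "
            "Rank | HGVS.c | HGVS.p | cDNA.pos / cDNA.length | CDS.pos / "
            "CDS.length | AA.pos / AA.length | Distance | ERRORS / WARNINGS / "
            "INFO'\">\n"
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, r, a, ann in records:
            fh.write(f"{chrom}\t{pos}\t.\t{r}\t{a}\t.\t.\tANN={ann}\n")

    ref.manifest["variants"] = {
        "seed": seed,
        "flank": flank,
        "missense": missense,
        "synonymous": synonymous,
    }
    ref.save_manifest()
    return ref


def _junction_offset_aa(offset_nt: int, frame: int, protein_len: int) -> int | None:
    if offset_nt < frame:
        aa = 1
    else:
        aa = (offset_nt - frame) // 3 + 1
    return aa if aa <= protein_len else None


def plant_junctions(
    ref: ToyReference,
    n_known_used: int = 8,
    n_novel: int = 10,
    depth_range: tuple[int, int] = (1, 20),
    flank_nt: int = 66,
    seed: int = 3,
) -> ToyReference:
    """Plant novel junctions and write known/observed BED files.

    The observed BED (TopHat BED12 two-block dialect) carries every selected
    known junction plus ``n_novel`` junctions absent from the gene models.
    Each novel junction's flanking DNA and three-frame translations are
    precomputed into the manifest by direct string slicing — the independent
    oracle for the splice builder.  The lowest and highest requested depths
    are always represented so depth filtering is never vacuous.
    """
    rng = random.Random(seed)
    genes = ref.manifest["genes"]
    known = []
    seen = set()
    for g in genes:
        for (s1, e1), (s2, e2) in zip(g["exons"], g["exons"][1:]):
            key = (g["chrom"], e1 + 1, s2 - 1)
            if key not in seen:
                seen.add(key)
                known.append(
                    {
                        "chrom": g["chrom"],
                        "intron_start": e1 + 1,
                        "intron_end": s2 - 1,
                        "strand": g["strand"],
                    }
                )
    if n_known_used > len(known):
        raise ValueError(
            f"only {len(known)} known junctions available, {n_known_used} requested"
        )
    known_used = rng.sample(known, n_known_used)

    known_keys = {(k["chrom"], k["intron_start"], k["intron_end"]) for k in known}
    novel = []
    attempts = 0
    margin = flank_nt + 30
    while len(novel) < n_novel:
        attempts += 1
        if attempts > 10_000:
            raise ValueError("could not place novel junctions without collision")
        chrom = rng.choice(sorted(ref.genome))
        chrom_len = len(ref.genome[chrom])
        intron_len = rng.randint(60, 400)
        s = rng.randint(margin, chrom_len - margin - intron_len)
        e = s + intron_len - 1
        if (chrom, s, e) in known_keys:
            continue
        strand = rng.choice("+-")
        depth = rng.randint(*depth_range)
        seq = ref.genome[chrom]
        left = seq[s - 1 - flank_nt : s - 1]
        right = seq[e : e + flank_nt]
        dna_plus = left + right
        if strand == "-":
            dna = _revcomp(dna_plus)
            offset_nt = len(right)
        else:
            dna = dna_plus
            offset_nt = len(left)
        translations = []
        for frame in range(3):
            protein = _translate(dna, frame)
            off = _junction_offset_aa(offset_nt, frame, len(protein))
            translations.append(
                {
                    "frame": frame,
                    "orientation": "+",
                    "protein": protein,
                    "junction_offset_aa": off,
                }
            )
        known_keys.add((chrom, s, e))
        novel.append(
            {
                "chrom": chrom,
                "intron_start": s,
                "intron_end": e,
                "strand": strand,
                "depth": depth,
                "dna": dna,
                "junction_offset_nt": offset_nt,
                "translations": translations,
            }
        )
    # guarantee the depth range's extremes are present
    novel[0]["depth"] = depth_range[0]
    novel[-1]["depth"] = depth_range[1]

    def bed12_line(chrom, s, e, name, depth, strand, overhang=20):
        chrom_start = s - 1 - overhang
        chrom_end = e + overhang
        block_starts = f"0,{e - chrom_start}"
        return (
            f"{chrom}\t{chrom_start}\t{chrom_end}\t{name}\t{depth}\t{strand}"
            f"\t{chrom_start}\t{chrom_end}\t255,0,0\t2\t{overhang},{overhang}"
            f"\t{block_starts}\n"
        )

    observed = [
        ("known", k["chrom"], k["intron_start"], k["intron_end"], k["strand"],
         rng.randint(*depth_range))
        for k in known_used
    ] + [
        ("novel", j["chrom"], j["intron_start"], j["intron_end"], j["strand"],
         j["depth"])
        for j in novel
    ]
    rng.shuffle(observed)
    with open(ref.observed_bed, "w") as fh:
        for i, (_kind, chrom, s, e, strand, depth) in enumerate(observed, 1):
            fh.write(bed12_line(chrom, s, e, f"JUNC{i:05d}", depth, strand))

    # known BED: plain 6-column intron intervals (0-based half-open)
    with open(ref.known_bed, "w") as fh:
        for i, k in enumerate(sorted(
            known, key=lambda k: (k["chrom"], k["intron_start"])
        ), 1):
            fh.write(
                f"{k['chrom']}\t{k['intron_start'] - 1}\t{k['intron_end']}"
                f"\tKNOWN{i:05d}\t0\t{k['strand']}\n"
            )

    ref.manifest["junctions"] = {
        "seed": seed,
        "flank_nt": flank_nt,
        "depth_range": list(depth_range),
        "known": known,
        "known_used": known_used,
        "novel": novel,
    }
    ref.save_manifest()
    return ref


def _fold_il(seq: str) -> str:
    return seq.replace("I", "J").replace("L", "J")


def simulate_abundance_and_peptides(
    ref: ToyReference,
    frac_expressed: float = 0.6,
    n_ref_peptides: int = 30,
    n_sap_peptides: int = 8,
    n_junction_peptides: int = 6,
    tpm_range: tuple[float, float] = (0.1, 1000.0),
    reduce_threshold: float = 1.0,
    seed: int = 5,
) -> ToyReference:
    """Simulate an RSEM-style TPM table and a peptide identification list.

    A fraction of transcripts receives log-uniform TPM in ``tpm_range``, the
    rest zero; expected reduced-database membership at ``reduce_threshold``
    (strict >) is recorded.  Peptides are sampled from reference proteins,
    SAP windows (covering the substituted residue) and junction translations
    (covering the junction codon); variant/junction-derived peptides are
    guaranteed absent from the reference proteome even under I/L folding.
    """
    import math

    rng = random.Random(seed)
    genes = ref.manifest["genes"]
    n_expr = round(frac_expressed * len(genes))
    expressed = set(
        g["transcript_id"] for g in rng.sample(genes, n_expr)
    )
    tpm = {}
    lo, hi = math.log10(tpm_range[0]), math.log10(tpm_range[1])
    for g in genes:
        tid = g["transcript_id"]
        tpm[tid] = (
            round(10 ** rng.uniform(lo, hi), 2) if tid in expressed else 0.0
        )
    with open(ref.abundance_tsv, "w") as fh:
        fh.write(
            "transcript_id\tgene_id\tlength\teffective_length\texpected_count"
            "\tTPM\tFPKM\tIsoPct\n"
        )
        for g in genes:
            tid = g["transcript_id"]
            length = len(g["cds_seq"]) + 12
            fh.write(
                f"{tid}\t{g['gene_id']}\t{length}\t{length - 100}\t"
                f"{round(tpm[tid] * 10, 1)}\t{tpm[tid]}\t{round(tpm[tid] * 0.9, 2)}"
                f"\t100.0\n"
            )

    expected_reduced = sorted(
        g["protein_id"] for g in genes
        if tpm[g["transcript_id"]] > reduce_threshold
    )

    ref_text = "\x00".join(_fold_il(g["protein"]) for g in genes)

    def in_reference(pep: str) -> bool:
        return _fold_il(pep) in ref_text

    peptides = []

    for _ in range(n_ref_peptides):
        g = rng.choice(genes)
        plen = rng.randint(8, min(14, len(g["protein"])))
        start = rng.randint(0, len(g["protein"]) - plen)
        peptides.append(
            {
                "peptide": g["protein"][start : start + plen],
                "label": "reference",
                "source": g["protein_id"],
            }
        )

    variants = ref.manifest.get("variants", {}).get("missense", [])
    if n_sap_peptides > 0 and not variants:
        raise ValueError("plant_variants must run before sampling SAP peptides")
    sap_pool = list(variants)
    rng.shuffle(sap_pool)
    planted_sap = 0
    for v in sap_pool:
        if planted_sap >= n_sap_peptides:
            break
        window, off = v["window"], v["sap_offset"]
        found = None
        for _try in range(50):
            plen = rng.randint(8, min(14, len(window)))
            lo_start = max(0, off - plen)
            hi_start = min(len(window) - plen, off - 1)
            if hi_start < lo_start:
                continue
            start = rng.randint(lo_start, hi_start)
            pep = window[start : start + plen]
            if not in_reference(pep):
                found = pep
                break
        if found is None:
            continue
        planted_sap += 1
        peptides.append(
            {
                "peptide": found,
                "label": "sap",
                "site": [v["chrom"], v["genomic_pos"], v["alt"]],
            }
        )
    if planted_sap < n_sap_peptides:
        raise ValueError(
            f"could only place {planted_sap}/{n_sap_peptides} SAP peptides"
        )

    junctions = ref.manifest.get("junctions", {}).get("novel", [])
    if n_junction_peptides > 0 and not junctions:
        raise ValueError("plant_junctions must run before sampling junction peptides")
    jnc_pool = list(junctions)
    rng.shuffle(jnc_pool)
    planted_jnc = 0
    for j in jnc_pool:
        if planted_jnc >= n_junction_peptides:
            break
        found = None
        for t in j["translations"]:
            protein, off = t["protein"], t["junction_offset_aa"]
            if off is None:
                continue
            for _try in range(80):
                plen = rng.randint(8, min(14, len(protein)))
                lo_start = max(0, off - plen)
                hi_start = min(len(protein) - plen, off - 1)
                if hi_start < lo_start:
                    continue
                start = rng.randint(lo_start, hi_start)
                pep = protein[start : start + plen]
                if "*" in pep or "X" in pep:
                    continue
                if not in_reference(pep):
                    found = pep
                    break
            if found:
                break
        if found is None:
            continue
        planted_jnc += 1
        peptides.append(
            {
                "peptide": found,
                "label": "splice",
                "junction": [j["chrom"], j["intron_start"], j["intron_end"]],
            }
        )
    if planted_jnc < n_junction_peptides:
        raise ValueError(
            f"could only place {planted_jnc}/{n_junction_peptides} junction peptides"
        )

    rng.shuffle(peptides)
    with open(ref.peptides_tsv, "w") as fh:
        fh.write("peptide\tscore\tspectrum_id\n")
        for i, p in enumerate(peptides, 1):
            score = round(rng.uniform(10, 100), 2)
            fh.write(f"{p['peptide']}\t{score}\tscan{i:05d}\n")

    ref.manifest["abundance"] = {
        "seed": seed,
        "tpm": tpm,
        "reduce_threshold": reduce_threshold,
        "expected_reduced_protein_ids": expected_reduced,
    }
    ref.manifest["peptides"] = peptides
    ref.save_manifest()
    return ref


PRESETS = {
    "small": {
        "n_chroms": 1,
        "n_genes": 8,
        "chrom_len": 50_000,
        "n_missense": 12,
        "n_synonymous": 5,
        "n_known_used": 8,
        "n_novel": 10,
        "n_ref_peptides": 30,
        "n_sap_peptides": 8,
        "n_junction_peptides": 6,
    },
    "medium": {
        "n_chroms": 2,
        "n_genes": 20,
        "chrom_len": 120_000,
        "n_missense": 20,
        "n_synonymous": 8,
        "n_known_used": 15,
        "n_novel": 15,
        "n_ref_peptides": 150,
        "n_sap_peptides": 12,
        "n_junction_peptides": 10,
    },
}


def generate_fixture_set(
    out_dir: str | Path, preset: str = "small", seed: int = 0
) -> ToyReference:
    """Run all four generators with a preset; the single seed derives the
    per-step seeds deterministically."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    p = PRESETS[preset]
    ref = generate_toy_reference(
        out_dir,
        n_chroms=p["n_chroms"],
        n_genes=p["n_genes"],
        chrom_len=p["chrom_len"],
        seed=seed,
    )
    plant_variants(
        ref, n_missense=p["n_missense"], n_synonymous=p["n_synonymous"],
        seed=seed + 1,
    )
    plant_junctions(
        ref, n_known_used=p["n_known_used"], n_novel=p["n_novel"],
        seed=seed + 2,
    )
    simulate_abundance_and_peptides(
        ref,
        n_ref_peptides=p["n_ref_peptides"],
        n_sap_peptides=p["n_sap_peptides"],
        n_junction_peptides=p["n_junction_peptides"],
        seed=seed + 3,
    )
    return ref
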