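# rnaseq2protdb

Build sample-specific proteomic search databases from RNA-Seq derived
inputs, and filter the resulting peptide identifications against a
reference proteome.

Three database builders are provided, plus assembly and post-search
filtering:

- **SAP database** (`sap_db`) — converts missense SNVs from an annotated
  VCF (SnpEff-style `ANN`/`EFF` INFO fields) into a FASTA of single
  amino acid polymorphism (SAP) polypeptide windows. Each entry's header
  records the genomic SNP, CDS change, protein change and window
  coordinates; the annotated reference amino acid is verified against our
  own translation of the transcript CDS before the substitution is applied.
- **Splice-junction database** (`splice_db`) — compares observed junctions
  (TopHat `junctions.bed` BED12 dialect, or a 6-column intron BED) against
  the gene models, extracts genomic sequence flanking each novel intron,
  translates in three frames (six for unstranded junctions) and filters by
  read depth, translated length and stop-codon content.
- **Reduced database** (`reduced_db`) — links protein entries to
  transcripts (explicit map, GTF `protein_id`, or Ensembl-style
  `transcript:` header tokens), annotates headers with RSEM-style TPM
  values and keeps entries whose abundance is strictly above a threshold
  (default 1 TPM). Optional Spearman RNA–protein correlation summary.
- **Assembly** (`db_assembly`) — concatenates builder outputs with the
  reference proteome and a contaminant database, and generates
  reversed-sequence decoys (`rev_` prefix, one per target).
- **Peptide filtering** (`peptide_filter`) — partitions identified
  peptides into reference hits vs novel by substring matching (I/L folded
  together by default), annotates novel peptides against the SAP/splice
  databases (a SAP call requires the peptide to overlap the substituted
  residue) and collapses SAP peptides to unique variant sites.
- **Fixtures** (`fixtures`) — a deterministic synthetic-data generator
  producing a toy genome, GTF, proteome, annotated VCF, junction BEDs,
  abundance table and peptide list together with a ground-truth manifest.
  Its translation/coordinate arithmetic is deliberately independent of the
  builder modules so the manifest can serve as a test oracle.

## CLI

```bash
# generate a synthetic fixture set with ground truth
rnaseq2protdb fixtures --out-dir fx --seed 1 --preset small

# SAP database from an annotated VCF
rnaseq2protdb sap --vcf fx/variants.vcf --gtf fx/models.gtf \
    --genome fx/genome.fasta --flank 20 --out sap.fasta --report sap.json

# novel splice-junction database
rnaseq2protdb splice --observed fx/observed_junctions.bed --gtf fx/models.gtf \
    --genome fx/genome.fasta --min-depth 4 --out splice.fasta

# TPM-annotated and reduced databases
rnaseq2protdb reduce --proteome fx/proteome.fasta --tpm fx/abundance.tsv \
    --gtf fx/models.gtf --threshold 1 \
    --out-annotated annotated.fasta --out-reduced reduced.fasta

# concatenate + reversed decoys
rnaseq2protdb assemble --in reduced.fasta --in sap.fasta --in splice.fasta \
    --decoys reverse --out search.fasta

# partition peptides into reference hits vs novel, annotate the novel
rnaseq2protdb filter-novel --peptides fx/peptides.tsv \
    --reference fx/proteome.fasta --custom sap.fasta --custom splice.fasta \
    --out-prefix results
```

## Conventions

- All internal genomic coordinates are 1-based inclusive (GTF/VCF
  convention); BED input is converted at the file boundary.
- Junction identity is the intron interval `(chrom, start, end)`; strand
  is excluded from novelty comparison by default.
- `translate_dna` emits stops as `*` — stop handling is always the
  caller's policy (the splice stop filter depends on seeing them).
- "Above threshold" means strictly greater than, so the default 1 TPM cut
  removes entries at exactly 1 TPM.
- Depth filtering keeps junctions with `depth >= min_depth`.

## Tests

```bash
python -m pytest tests/
```

The suite includes per-module unit tests, hypothesis property tests and
`tests/test_acceptance.py`, which asserts the planted-fixture round-trip
properties (SAP recovery, splice translation byte-equality, reduction
membership, decoy laws, filter/brute-force equivalence, translation
oracle, end-to-end determinism).

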