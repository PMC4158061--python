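import pytest

from rnaseq2protdb import fixtures
from rnaseq2protdb.fasta import FastaDatabase
from rnaseq2protdb.seq_model import load_gene_models, load_genome

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """Small synthetic reference with planted variants/junctions/peptides."""
    out = tmp_path_factory.mktemp("toyref")
    return fixtures.generate_fixture_set(out, preset="small", seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def genome(fixture_set):
    return load_genome(fixture_set.genome_fasta)


@pytest.fixture(scope="session")
def models(fixture_set):
    return load_gene_models(fixture_set.gtf)


@pytest.fixture(scope="session")
def proteome(fixture_set):
    return FastaDatabase.from_fasta(fixture_set.proteome_fasta)


@pytest.fixture()
def write_fasta(tmp_path):
    def _write(name, entries):
        path = tmp_path / name
        with open(path, "w") as fh:
            for header, seq in entries:
                fh.write(f">{header}\n{seq}\n")
        return path

    return _write


@pytest.fixture()
def write_gtf(tmp_path):
    def _write(name, rows):
        """rows: (chrom, feature, start, end, strand, attrs)"""
        path = tmp_path / name
        with open(path, "w") as fh:
            for chrom, feature, start, end, strand, attrs in rows:
                fh.write(
                    f"{chrom}\ttest\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"
                )
        return path

    return _write
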