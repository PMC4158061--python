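import pytest

from rnaseq2protdb.sap_db import (
    ReferenceMismatchError,
    VariantEffect,
    apply_sap,
    build_sap_database,
    parse_sap_header,
    parse_variant_effects,
    sap_window,
)
from rnaseq2protdb.seq_model import GenomeSequence, TranscriptModel, load_gene_models


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=1000>\n"
    '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def _ann(allele, effect, tid, hgvs_p, cds="14/30"):
    return (
        f"{allele}|{effect}|MODERATE|g1|g1|transcript|{tid}|protein_coding|1/1"
        f"|c.14A>G|{hgvs_p}|{cds}|{cds}|5/10||"
    )


def _write_vcf(tmp_path, body):
    path = tmp_path / "v.vcf"
    path.write_text(VCF_HEADER + body)
    return path


class TestParseVariantEffects:
    def test_missense_three_letter_hgvs(self, tmp_path):
        path = _write_vcf(
            tmp_path,
            f"chr1\t14\t.\tA\tG\t.\t.\tANN={_ann('G', 'missense_variant', 'ENST01', 'p.Tyr5Cys')}\n",
        )
        effects = parse_variant_effects(path)
        assert len(effects) == 1
        e = effects[0]
        assert (e.ref_aa, e.alt_aa, e.protein_pos) == ("Y", "C", 5)
        assert (e.ref_allele, e.alt_allele) == ("A", "G")
        assert e.transcript_id == "ENST01"
        assert e.cds_pos == 14

    def test_synonymous_filtered(self, tmp_path):
        path = _write_vcf(
            tmp_path,
            f"chr1\t14\t.\tA\tG\t.\t.\tANN={_ann('G', 'synonymous_variant', 'ENST01', 'p.Tyr5Tyr')}\n",
        )
        assert parse_variant_effects(path) == []

    def test_two_transcripts_two_effects(self, tmp_path):
        ann = ",".join(
            [
                _ann("G", "missense_variant", "ENST01", "p.Tyr5Cys"),
                _ann("G", "missense_variant", "ENST02", "p.Tyr7Cys"),
            ]
        )
        path = _write_vcf(tmp_path, f"chr1\t14\t.\tA\tG\t.\t.\tANN={ann}\n")
        effects = parse_variant_effects(path)
        assert [e.transcript_id for e in effects] == ["ENST01", "ENST02"]

    def test_multiallelic_expanded(self, tmp_path):
        ann = ",".join(
            [
                _ann("G", "missense_variant", "ENST01", "p.Tyr5Cys"),
                _ann("T", "missense_variant", "ENST01", "p.Tyr5Phe"),
            ]
        )
        path = _write_vcf(tmp_path, f"chr1\t14\t.\tA\tG,T\t.\t.\tANN={ann}\n")
        effects = parse_variant_effects(path)
        assert sorted(e.alt_allele for e in effects) == ["G", "T"]

    def test_malformed_ann_skipped_with_warning(self, tmp_path):
        path = _write_vcf(tmp_path, "chr1\t14\t.\tA\tG\t.\t.\tANN=broken\n")
        with pytest.warns(UserWarning, match="malformed"):
            assert parse_variant_effects(path) == []

    def test_fixture_vcf_counts(self, fixture_set):
        effects = parse_variant_effects(fixture_set.vcf)
        assert len(effects) == len(fixture_set.manifest["variants"]["missense"])
        assert all(e.effect_class == "missense" for e in effects)


class TestVariantEffectInvariants:
    def test_rejects_identical_alleles(self):
        with pytest.raises(ValueError):
            VariantEffect("chr1", 1, "A", "A", "t1", "missense", "Y", "C", 1)

    def test_rejects_missense_without_aa_change(self):
        with pytest.raises(ValueError):
            VariantEffect("chr1", 1, "A", "G", "t1", "missense", "Y", "Y", 1)

    def test_rejects_multibase(self):
        with pytest.raises(ValueError):
            VariantEffect("chr1", 1, "AT", "G", "t1", "missense", "Y", "C", 1)


class TestApplySap:
    def test_substitution(self):
        assert apply_sap("MKTAYIAKQR", 5, "Y", "C") == "MKTACIAKQR"

    def test_length_one_boundary(self):
        assert apply_sap("M", 1, "M", "V") == "V"

    def test_reference_mismatch(self):
        with pytest.raises(ReferenceMismatchError):
            apply_sap("MKTA", 3, "Y", "C")

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            apply_sap("MKTA", 5, "A", "C")


class TestSapWindow:
    def test_interior(self):
        assert sap_window("MKTACIAKQR", 5, 3) == ("KTACIAK", 2, 4)

    def test_truncation_both_ends(self):
        assert sap_window("MKTACIAKQR", 5, 100) == ("MKTACIAKQR", 1, 5)

    def test_zero_flank(self):
        assert sap_window("MKTACIAKQR", 5, 0) == ("C", 5, 1)

    def test_negative_flank(self):
        with pytest.raises(ValueError):
            sap_window("MKTA", 1, -1)


class TestBuildSapDatabase:
    def test_fixture_round_trip(self, fixture_set, models, genome):
        """Every planted missense variant yields exactly the manifest window."""
        effects = parse_variant_effects(fixture_set.vcf)
        flank = fixture_set.manifest["variants"]["flank"]
        db, report = build_sap_database(effects, models, genome, flank=flank)
        planted = fixture_set.manifest["variants"]["missense"]
        assert report.applied == len(planted)
        assert report.mismatched == 0
        expected = {v["expected_header"]: v for v in planted}
        assert len(db) == len(expected)
        for rec in db:
            v = expected[rec.header]
            assert rec.sequence == v["window"]
            block = parse_sap_header(rec.header)[0]
            assert block["gpos"] == v["genomic_pos"]
            assert block["cpos"] == v["cds_pos"]
            assert rec.sequence[v["sap_offset"] - 1] == v["alt_aa"]

    def test_window_length_law(self, fixture_set, models, genome):
        effects = parse_variant_effects(fixture_set.vcf)
        flank = fixture_set.manifest["variants"]["flank"]
        db, _ = build_sap_database(effects, models, genome, flank=flank)
        by_tid = {
            v["expected_header"]: v
            for v in fixture_set.manifest["variants"]["missense"]
        }
        for rec in db:
            v = by_tid[rec.header]
            pos, L = v["protein_pos"], len(
                next(
                    g["protein"]
                    for g in fixture_set.manifest["genes"]
                    if g["transcript_id"] == v["transcript_id"]
                )
            )
            assert len(rec.sequence) == min(pos - 1, flank) + 1 + min(L - pos, flank)

    def test_empty_effects(self, models, genome):
        db, report = build_sap_database([], models, genome)
        assert len(db) == 0
        assert report.n_effects == 0

    def test_ref_aa_mismatch_skipped(self, fixture_set, models, genome):
        v = fixture_set.manifest["variants"]["missense"][0]
        wrong_ref = "W" if v["ref_aa"] != "W" else "F"
        eff = VariantEffect(
            chrom=v["chrom"],
            genomic_pos=v["genomic_pos"],
            ref_allele=v["ref"],
            alt_allele=v["alt"],
            transcript_id=v["transcript_id"],
            effect_class="missense",
            ref_aa=wrong_ref,
            alt_aa=v["alt_aa"],
            protein_pos=v["protein_pos"],
        )
        db, report = build_sap_database([eff], models, genome)
        assert len(db) == 0
        assert report.mismatched == 1

    def test_missing_transcript_skipped_with_warning(self, models, genome, fixture_set):
        v = fixture_set.manifest["variants"]["missense"][0]
        eff = VariantEffect(
            chrom=v["chrom"],
            genomic_pos=v["genomic_pos"],
            ref_allele=v["ref"],
            alt_allele=v["alt"],
            transcript_id="tXXX",
            effect_class="missense",
            ref_aa=v["ref_aa"],
            alt_aa=v["alt_aa"],
            protein_pos=v["protein_pos"],
        )
        with pytest.warns(UserWarning, match="not in gene models"):
            db, report = build_sap_database([eff], models, genome)
        assert report.skipped_missing_transcript == 1

    def test_idempotent_fasta_bytes(self, fixture_set, models, genome, tmp_path):
        effects = parse_variant_effects(fixture_set.vcf)
        db1, _ = build_sap_database(effects, models, genome, flank=8)
        db2, _ = build_sap_database(effects, models, genome, flank=8)
        assert db1.to_fasta() == db2.to_fasta()

    def test_duplicate_windows_merge_headers(self, write_gtf, tmp_path):
        # two identical genes -> identical windows -> one entry, two blocks
        genome = GenomeSequence({"chr1": "ATGAAATTTCCCTAG" + "ATGAAATTTCCCTAG"})
        models = {}
        for i, start in enumerate((1, 16), 1):
            models[f"t{i}"] = TranscriptModel(
                transcript_id=f"t{i}",
                gene_id=f"g{i}",
                chrom="chr1",
                strand="+",
                exons=[(start, start + 14)],
                cds=[(start, start + 14)],
            )
        effects = [
            VariantEffect("chr1", 4, "A", "G", "t1", "missense", "K", "E", 2),
            VariantEffect("chr1", 19, "A", "G", "t2", "missense", "K", "E", 2),
        ]
        db, report = build_sap_database(effects, models, genome, flank=5)
        assert len(db) == 1
        assert report.merged_duplicates == 1
        blocks = parse_sap_header(db[0].header)
        assert [b["tid"] for b in blocks] == ["t1", "t2"]

    def test_no_unplanted_substitutions(self, fixture_set, models, genome):
        """Each window differs from the reference protein stretch at exactly
        the SAP position."""
        effects = parse_variant_effects(fixture_set.vcf)
        flank = fixture_set.manifest["variants"]["flank"]
        db, _ = build_sap_database(effects, models, genome, flank=flank)
        proteins = {
            g["transcript_id"]: g["protein"]
            for g in fixture_set.manifest["genes"]
        }
        for rec in db:
            block = parse_sap_header(rec.header)[0]
            ref_stretch = proteins[block["tid"]][block["wstart"] - 1 : block["wend"]]
            diffs = [
                i for i, (a, b) in enumerate(zip(ref_stretch, rec.sequence)) if a != b
            ]
            assert diffs == [block["ppos"] - block["wstart"]]
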