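import pytest

from rnaseq2protdb.seq_model import GenomeSequence, TranscriptModel, reverse_complement
from rnaseq2protdb.splice_db import (
    Junction,
    SpliceParams,
    build_splice_database,
    junction_flanking_sequence,
    known_junctions_from_models,
    novel_junctions,
    parse_junction_bed,
    parse_splice_header,
    translate_junction,
)

# Independent translation oracle (literal table in the fixtures module)
from rnaseq2protdb.fixtures import GENETIC_CODE, _revcomp, _translate


class TestParseJunctionBed:
    def test_bed12_tophat_dialect(self, tmp_path):
        p = tmp_path / "j.bed"
        p.write_text("chr1\t100\t300\tJ1\t12\t+\t100\t300\t0\t2\t20,20\t0,180\n")
        (j,) = parse_junction_bed(p)
        assert (j.intron_start, j.intron_end) == (121, 280)
        assert j.depth == 12
        assert (j.left_overhang, j.right_overhang) == (20, 20)

    def test_six_column_intron_dialect(self, tmp_path):
        p = tmp_path / "j.bed"
        p.write_text("chr1\t120\t280\tJ1\t12\t+\n")
        (j,) = parse_junction_bed(p)
        assert (j.intron_start, j.intron_end) == (121, 280)
        assert j.depth == 12

    def test_three_block_rejected(self, tmp_path):
        p = tmp_path / "j.bed"
        p.write_text(
            "chr1\t100\t300\tJ1\t12\t+\t100\t300\t0\t3\t20,20,20\t0,90,180\n"
        )
        with pytest.warns(UserWarning, match="3 blocks"):
            assert parse_junction_bed(p) == []

    def test_track_lines_skipped(self, tmp_path):
        p = tmp_path / "j.bed"
        p.write_text('track name="junctions"\nchr1\t120\t280\tJ1\t3\t-\n')
        assert len(parse_junction_bed(p)) == 1

    def test_fixture_observed_bed(self, fixture_set):
        observed = parse_junction_bed(fixture_set.observed_bed)
        man = fixture_set.manifest["junctions"]
        assert len(observed) == len(man["known_used"]) + len(man["novel"])


class TestKnownJunctions:
    def _model(self, exons, strand="+", tid="t1"):
        return TranscriptModel(
            transcript_id=tid, gene_id="g1", chrom="chr1", strand=strand,
            exons=exons, cds=[],
        )

    def test_gap_between_exons(self):
        known = known_junctions_from_models([self._model([(1, 100), (201, 300)])])
        assert known == {("chr1", 101, 200, "+")}

    def test_single_exon_contributes_nothing(self):
        assert known_junctions_from_models([self._model([(1, 100)])]) == set()

    def test_shared_intron_deduplicated(self):
        m1 = self._model([(1, 100), (201, 300)], tid="t1")
        m2 = self._model([(51, 100), (201, 400)], tid="t2")
        assert len(known_junctions_from_models([m1, m2])) == 1

    def test_never_reports_model_introns_as_novel(self, models, fixture_set):
        known = known_junctions_from_models(models)
        observed = parse_junction_bed(fixture_set.observed_bed)
        novel = novel_junctions(observed, known)
        model_introns = {
            (t.chrom, e1 + 1, s2 - 1)
            for t in models.values()
            for (s1, e1), (s2, e2) in zip(t.exons, t.exons[1:])
        }
        assert all(j.key() not in model_introns for j in novel)


class TestNovelJunctions:
    def test_set_subtraction(self):
        a = Junction("chr1", 101, 200)
        b = Junction("chr1", 501, 600)
        assert novel_junctions([a, b], {("chr1", 101, 200)}) == [b]

    def test_strand_ignored_by_default(self):
        j = Junction("chr1", 101, 200, strand="-")
        assert novel_junctions([j], {("chr1", 101, 200, "+")}, strand_aware=False) == []
        assert novel_junctions([j], {("chr1", 101, 200, "+")}, strand_aware=True) == [j]

    def test_all_known_gives_empty(self):
        j = Junction("chr1", 101, 200)
        assert novel_junctions([j], {j.key(True)}) == []

    def test_recovers_planted_novel(self, fixture_set, models):
        observed = parse_junction_bed(fixture_set.observed_bed)
        known = known_junctions_from_models(models)
        novel = novel_junctions(observed, known)
        planted = {
            (j["chrom"], j["intron_start"], j["intron_end"])
            for j in fixture_set.manifest["junctions"]["novel"]
        }
        assert {j.key() for j in novel} == planted


class TestFlankingSequence:
    @pytest.fixture()
    def toy_genome(self):
        import random

        rng = random.Random(99)
        return GenomeSequence(
            {"chr1": "".join(rng.choice("ACGT") for _ in range(400))}
        )

    def test_plus_strand_extraction(self, toy_genome):
        j = Junction("chr1", 121, 280, strand="+", depth=5)
        dna, off = junction_flanking_sequence(j, toy_genome, 6)
        expected = toy_genome.fetch("chr1", 115, 120) + toy_genome.fetch(
            "chr1", 281, 286
        )
        assert dna == expected
        assert off == 6

    def test_minus_strand_is_revcomp(self, toy_genome):
        plus = junction_flanking_sequence(
            Junction("chr1", 121, 280, strand="+"), toy_genome, 6
        )[0]
        dna, off = junction_flanking_sequence(
            Junction("chr1", 121, 280, strand="-"), toy_genome, 6
        )
        assert dna == reverse_complement(plus)
        assert off == 6

    def test_left_flank_truncated(self, toy_genome):
        j = Junction("chr1", 2, 100, strand="+")
        dna, off = junction_flanking_sequence(j, toy_genome, 6)
        assert off == 1
        assert dna == toy_genome.fetch("chr1", 1, 1) + toy_genome.fetch(
            "chr1", 101, 106
        )

    def test_zero_flank_side_skipped(self, toy_genome):
        j = Junction("chr1", 1, 100, strand="+")
        with pytest.warns(UserWarning, match="edge"):
            assert junction_flanking_sequence(j, toy_genome, 6) is None

    def test_small_flank_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            junction_flanking_sequence(Junction("chr1", 10, 20), toy_genome, 2)


class TestTranslateJunction:
    def test_three_frames_lengths(self):
        out = translate_junction("ATGTTTAAACCC", "+")
        assert [len(p) for _, _, p in out] == [4, 3, 3]

    def test_stop_retained_at_this_stage(self):
        out = translate_junction("ATGTTTTGAAAA", "+")
        frame0 = next(p for f, o, p in out if f == 0)
        assert frame0 == "MF*K"

    def test_unstranded_six_frames(self):
        assert len(translate_junction("ATGTTTAAACCC", ".")) == 6

    def test_too_short(self):
        assert translate_junction("AT", "+") == []


class TestBuildSpliceDatabase:
    @pytest.fixture()
    def pipeline_inputs(self, fixture_set, models):
        from rnaseq2protdb.seq_model import load_genome

        observed = parse_junction_bed(fixture_set.observed_bed)
        known = known_junctions_from_models(models)
        genome = load_genome(fixture_set.genome_fasta)
        return observed, known, genome

    @staticmethod
    def expected_entries(fixture_set, params: SpliceParams):
        """Brute-force filter over the manifest truth table."""
        count = 0
        for j in fixture_set.manifest["junctions"]["novel"]:
            if j["depth"] < params.min_depth:
                continue
            for t in j["translations"]:
                if t["junction_offset_aa"] is None:
                    continue
                if len(t["protein"]) < params.min_len_aa:
                    continue
                if params.drop_stop and "*" in t["protein"]:
                    continue
                count += 1
        return count

    def test_translations_byte_match_manifest(self, fixture_set, pipeline_inputs):
        observed, known, genome = pipeline_inputs
        params = SpliceParams(min_depth=0, min_len_aa=1, drop_stop=False)
        db, report = build_splice_database(observed, known, genome, params)
        man = {
            (j["chrom"], j["intron_start"], j["intron_end"], t["frame"]): t
            for j in fixture_set.manifest["junctions"]["novel"]
            for t in j["translations"]
        }
        assert len(db) == self.expected_entries(fixture_set, params)
        for rec in db:
            d = parse_splice_header(rec.header)
            t = man[(d["chrom"], d["start"], d["end"], d["frame"])]
            assert rec.sequence == t["protein"]
            assert d["offset"] == t["junction_offset_aa"]

    def test_depth_filter_exact(self, fixture_set, pipeline_inputs):
        observed, known, genome = pipeline_inputs
        depths = sorted({j["depth"] for j in fixture_set.manifest["junctions"]["novel"]})
        cut = depths[len(depths) // 2]
        params = SpliceParams(min_depth=cut, min_len_aa=1, drop_stop=False)
        db, report = build_splice_database(observed, known, genome, params)
        assert len(db) == self.expected_entries(fixture_set, params)
        n_below = sum(
            1
            for j in fixture_set.manifest["junctions"]["novel"]
            if j["depth"] < cut
        )
        assert report.removed_depth == n_below

    def test_stop_filter_exact(self, fixture_set, pipeline_inputs):
        observed, known, genome = pipeline_inputs
        params = SpliceParams(min_depth=0, min_len_aa=1, drop_stop=True)
        db, _ = build_splice_database(observed, known, genome, params)
        assert len(db) == self.expected_entries(fixture_set, params)
        assert all("*" not in rec.sequence for rec in db)

    def test_length_filter_exact(self, fixture_set, pipeline_inputs):
        observed, known, genome = pipeline_inputs
        params = SpliceParams(min_depth=0, min_len_aa=44, drop_stop=False)
        db, _ = build_splice_database(observed, known, genome, params)
        assert len(db) == self.expected_entries(fixture_set, params)

    def test_filter_monotonicity(self, fixture_set, pipeline_inputs):
        observed, known, genome = pipeline_inputs
        prev = None
        for d in (0, 2, 5, 10, 21):
            db, _ = build_splice_database(
                observed, known, genome, SpliceParams(min_depth=d, drop_stop=False)
            )
            if prev is not None:
                assert len(db) <= prev
            prev = len(db)
        prev = None
        for L in (1, 8, 20, 43, 44, 45):
            db, _ = build_splice_database(
                observed, known, genome,
                SpliceParams(min_len_aa=L, drop_stop=False),
            )
            if prev is not None:
                assert len(db) <= prev
            prev = len(db)

    def test_min_depth_above_all_planted_gives_zero(self, fixture_set, pipeline_inputs):
        observed, known, genome = pipeline_inputs
        top = max(j["depth"] for j in fixture_set.manifest["junctions"]["novel"])
        db, _ = build_splice_database(
            observed, known, genome, SpliceParams(min_depth=top + 1)
        )
        assert len(db) == 0

    def test_minus_strand_frame0_matches_revcomp_oracle(
        self, fixture_set, pipeline_inputs
    ):
        observed, known, genome = pipeline_inputs
        params = SpliceParams(min_depth=0, min_len_aa=1, drop_stop=False)
        db, _ = build_splice_database(observed, known, genome, params)
        flank = fixture_set.manifest["junctions"]["flank_nt"]
        for rec in db:
            d = parse_splice_header(rec.header)
            if d["strand"] != "-" or d["frame"] != 0:
                continue
            seq = genome.sequence(d["chrom"])
            left = seq[d["start"] - 1 - flank : d["start"] - 1]
            right = seq[d["end"] : d["end"] + flank]
            assert rec.sequence == _translate(_revcomp(left + right), 0)
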