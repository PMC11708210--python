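import numpy as np
import pytest

from conftest import make_gene
from urscan.genomeannot import (
    annotate,
    anonymous_regions,
    parse_gff3,
    promoters,
    sequence_regions,
)
from urscan.regions import GenomicInterval, URSet
from urscan.seqindex import InputFormatError

GFF = """##gff-version 3
##sequence-region chr1 1 100000
chr1\tsrc\tgene\t5001\t7000\t.\t+\t.\tID=gene-A;Dbxref=GeneID:111
chr1\tsrc\tmRNA\t5001\t7000\t.\t+\t.\tID=rna-A;Parent=gene-A
chr1\tsrc\tCDS\t5001\t5600\t.\t+\t0\tID=cds-A1;Parent=rna-A;protein_id=P1
chr1\tsrc\tCDS\t6001\t7000\t.\t+\t0\tID=cds-A2;Parent=rna-A;protein_id=P1
chr1\tsrc\tgene\t5001\t7000\t.\t-\t.\tID=gene-B
chr1\tsrc\tmRNA\t5001\t7000\t.\t-\t.\tID=rna-B;Parent=gene-B
chr1\tsrc\tgene\t20001\t21000\t.\t+\t.\tID=gene-C;Dbxref=GeneID:333
chr1\tsrc\tmRNA\t20001\t21000\t.\t+\t.\tID=rna-orphan;Parent=gene-missing
"""


@pytest.fixture
def gff_path(tmp_path):
    p = tmp_path / "toy.gff3"
    p.write_text(GFF)
    return p


class TestParseGff3:
    def test_coordinates_converted_to_half_open(self, gff_path):
        with pytest.warns(UserWarning, match="orphan"):
            models = parse_gff3(gff_path)
        a = next(m for m in models if m.gene_id == "111")
        assert a.transcripts == [(5000, 7000)]
        assert a.strand == "+"

    def test_protein_ids_deduplicated(self, gff_path):
        with pytest.warns(UserWarning):
            models = parse_gff3(gff_path)
        a = next(m for m in models if m.gene_id == "111")
        assert a.protein_ids == ["P1"]

    def test_gene_id_falls_back_to_feature_id(self, gff_path):
        with pytest.warns(UserWarning):
            models = parse_gff3(gff_path)
        assert any(m.gene_id == "gene-B" for m in models)

    def test_gene_without_transcript_kept_but_promoterless(self, gff_path):
        with pytest.warns(UserWarning):
            models = parse_gff3(gff_path)
        c = next(m for m in models if m.gene_id == "333")
        assert c.transcripts == []
        assert all(g != "333" for g, _ in promoters(models))

    def test_orphan_transcript_skipped_with_warning(self, gff_path):
        with pytest.warns(UserWarning, match="rna-orphan"):
            parse_gff3(gff_path)

    def test_sequence_region_lengths(self, gff_path):
        assert sequence_regions(gff_path) == {"chr1": 100_000}

    def test_malformed_line_named(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("##gff-version 3\nchr1\tsrc\tgene\t1\n")
        with pytest.raises(InputFormatError, match="line 2"):
            parse_gff3(p)


class TestPromoters:
    def test_plus_strand_upstream(self):
        m = make_gene("g", "c", "+", [(5_000, 7_000)])
        assert promoters([m]).promoters == [("g", GenomicInterval("c", 3_000, 5_000))]

    def test_minus_strand_reflected(self):
        m = make_gene("g", "c", "-", [(5_000, 7_000)])
        got = promoters([m], chrom_lengths={"c": 100_000})
        assert got.promoters == [("g", GenomicInterval("c", 7_000, 9_000))]

    def test_truncation_at_chromosome_start(self):
        m = make_gene("g", "c", "+", [(500, 2_000)])
        assert promoters([m]).promoters == [("g", GenomicInterval("c", 0, 500))]

    def test_tss_at_origin_dropped(self):
        m = make_gene("g", "c", "+", [(0, 2_000)])
        assert len(promoters([m])) == 0

    def test_one_promoter_per_distinct_tss(self):
        m = make_gene("g", "c", "+", [(5_000, 7_000), (5_000, 8_000), (6_000, 8_000)])
        assert len(promoters([m])) == 2

    def test_strand_symmetry_under_reverse_complement(self):
        # flipping the genome maps promoters onto promoters bijectively
        L = 50_000
        rng = np.random.default_rng(0)
        models = [
            make_gene(
                f"g{i}",
                "c",
                rng.choice(["+", "-"]),
                [tuple(sorted(rng.integers(3_000, L - 3_000, 2).tolist()))],
            )
            for i in range(10)
        ]
        flipped = [
            make_gene(
                m.gene_id,
                "c",
                "-" if m.strand == "+" else "+",
                [(L - e, L - s) for s, e in m.transcripts],
            )
            for m in models
        ]
        fwd = {(g, iv.start, iv.end) for g, iv in promoters(models, {"c": L})}
        rev = {
            (g, L - iv.end, L - iv.start) for g, iv in promoters(flipped, {"c": L})
        }
        assert fwd == rev


class TestAnnotate:
    def test_single_bp_overlap_reported(self):
        m = make_gene("g", "c", "+", [(5_000, 7_000)])  # promoter [3000,5000)
        assert annotate([GenomicInterval("c", 4_999, 5_001)], [m]) == ["g"]

    def test_half_open_abutment_not_reported(self):
        m = make_gene("g", "c", "+", [(5_000, 7_000)])
        assert annotate([GenomicInterval("c", 5_000, 6_000)], [m], mode="promoter") == []

    def test_transcript_mode_uses_span(self):
        m = make_gene("g", "c", "+", [(5_000, 7_000)])
        assert annotate([GenomicInterval("c", 6_999, 7_500)], [m], mode="transcript") == ["g"]

    def test_unknown_chromosomes_listed(self):
        m = make_gene("g", "c", "+", [(5_000, 7_000)])
        with pytest.raises(ValueError, match="cX"):
            annotate([GenomicInterval("cX", 0, 10)], [m], known_chromosomes={"c"})

    @pytest.mark.parametrize("mode", ["promoter", "transcript"])
    def test_matches_quadratic_overlap_scan(self, mode):
        rng = np.random.default_rng(42)
        L = 200_000
        models = []
        for i in range(30):
            s = int(rng.integers(3_000, L - 10_000))
            e = s + int(rng.integers(500, 6_000))
            models.append(make_gene(f"g{i}", "c", rng.choice(["+", "-"]), [(s, e)]))
        intervals = []
        for _ in range(15):
            s = int(rng.integers(0, L - 5_000))
            intervals.append(GenomicInterval("c", s, s + int(rng.integers(100, 5_000))))
        got = annotate(intervals, models, mode=mode, chrom_lengths={"c": L})
        if mode == "promoter":
            feats = [(g, iv) for g, iv in promoters(models, {"c": L})]
        else:
            feats = [
                (m.gene_id, GenomicInterval("c", s, e))
                for m in models
                for s, e in m.transcripts
            ]
        expected = sorted(
            {
                g
                for g, f in feats
                for iv in intervals
                if f.start < iv.end and iv.start < f.end
            }
        )
        assert got == expected


class TestAnonymousRegions:
    def _urs(self, ivs):
        return URSet(intervals=list(ivs))

    def test_promoter_hit_excludes(self):
        m = make_gene("g", "c", "+", [(5_000, 7_000)])
        urs = self._urs([GenomicInterval("c", 3_500, 4_000)])
        assert len(anonymous_regions(urs, [m], {"c": 100_000})) == 0

    def test_geneless_chromosome_included(self):
        m = make_gene("g", "c", "+", [(5_000, 7_000)])
        urs = self._urs([GenomicInterval("empty", 0, 10_000)])
        got = anonymous_regions(urs, [m], {"c": 100_000, "empty": 50_000})
        assert got.intervals == urs.intervals

    def test_complement_of_both_annotation_modes(self):
        rng = np.random.default_rng(1)
        L = 100_000
        models = [
            make_gene(
                f"g{i}", "c", rng.choice(["+", "-"]),
                [tuple(sorted(rng.integers(3_000, L - 3_000, 2).tolist()))],
            )
            for i in range(12)
        ]
        ivs = []
        for _ in range(20):
            s = int(rng.integers(0, L - 2_000))
            ivs.append(GenomicInterval("c", s, s + int(rng.integers(100, 2_000))))
        urs = self._urs(ivs)
        anon = anonymous_regions(urs, models, {"c": L})
        feats = [iv for _, iv in promoters(models, {"c": L})] + [
            GenomicInterval("c", s, e) for m in models for s, e in m.transcripts
        ]
        expected = [
            iv
            for iv in ivs
            if not any(f.start < iv.end and iv.start < f.end for f in feats)
        ]
        assert anon.intervals == expected

    def test_sorted_by_length_on_request(self):
        urs = self._urs(
            [GenomicInterval("empty", 0, 1_000), GenomicInterval("empty", 2_000, 12_000)]
        )
        got = anonymous_regions(urs, [], by_length=True)
        assert [iv.length for iv in got] == [10_000, 1_000]
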