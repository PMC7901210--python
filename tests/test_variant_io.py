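"""Format readers/writers: MAF, VCF, segments, clinical, interval lookup."""

import textwrap

import numpy as np
import pytest

from ith_biomarker import variant_io
from ith_biomarker.model import ClinicalRecord, CopyNumberSegment, Effect
from ith_biomarker.variant_io import FormatError

MAF_HEADER = "\t".join(variant_io.MAF_REQUIRED_COLUMNS)


def _maf_line(gene="EGFR", chrom="7", pos=55249071, ref="C", alt="T",
              cls="Missense_Mutation", sample="P001", rc=60, ac=40):
    return f"{gene}\t{chrom}\t{pos}\t{ref}\t{alt}\t{cls}\t{sample}\t{rc}\t{ac}"


class TestMaf:
    def test_counts_become_vaf(self, tmp_path):
        p = tmp_path / "x.maf"
        p.write_text(MAF_HEADER + "\n" + _maf_line(rc=60, ac=40) + "\n")
        (call,) = variant_io.read_maf(p)
        assert call.vaf == pytest.approx(0.40)
        assert call.effect is Effect.MISSENSE
        assert call.gene == "EGFR" and call.sample_id == "P001"

    def test_header_only_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.maf"
        p.write_text(MAF_HEADER + "\n")
        assert variant_io.read_maf(p) == []

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "bad.maf"
        p.write_text("Hugo_Symbol\tChromosome\n" "EGFR\t7\n")
        with pytest.raises(FormatError, match="t_ref_count"):
            variant_io.read_maf(p)

    def test_non_integer_counts_report_line(self, tmp_path):
        p = tmp_path / "bad.maf"
        p.write_text(MAF_HEADER + "\n" + _maf_line(rc="sixty") + "\n")
        with pytest.raises(FormatError, match="line 2"):
            variant_io.read_maf(p)

    def test_round_trip_preserves_fields(self, tmp_path, make_variant):
        calls = [
            make_variant(pos=100, effect=Effect.MISSENSE),
            make_variant(chrom="X", pos=200, ref="G", alt="A",
                         effect=Effect.SYNONYMOUS, gene="AR"),
            make_variant(pos=300, ref_count=0, alt_count=15,
                         effect=Effect.FRAMESHIFT),
        ]
        p = tmp_path / "rt.maf"
        variant_io.write_maf(calls, p)
        assert variant_io.read_maf(p) == calls


VCF_TEMPLATE = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR
    {records}
    """
)


class TestVcf:
    def test_ad_maps_to_counts(self, tmp_path):
        p = tmp_path / "x.vcf"
        p.write_text(VCF_TEMPLATE.format(records="1\t100\t.\tA\tG\t.\t.\t.\tAD\t70,30"))
        (call,) = variant_io.read_vcf(p)
        assert (call.ref_count, call.alt_count) == (70, 30)
        assert call.sample_id == "TUMOR"

    def test_multiallelic_record_splits(self, tmp_path):
        p = tmp_path / "x.vcf"
        p.write_text(
            VCF_TEMPLATE.format(records="2\t500\t.\tC\tT,G\t.\t.\t.\tAD\t50,30,20")
        )
        calls = variant_io.read_vcf(p)
        assert [(c.alt, c.alt_count) for c in calls] == [("T", 30), ("G", 20)]
        assert all(c.ref_count == 50 for c in calls)

    def test_missing_ad_is_instructive_error(self, tmp_path):
        p = tmp_path / "x.vcf"
        body = VCF_TEMPLATE.format(records="1\t100\t.\tA\tG\t.\t.\t.\tDP\t55")
        p.write_text(
            body.replace(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
                '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
            )
        )
        with pytest.raises(FormatError, match="AD"):
            variant_io.read_vcf(p)

    def test_fifty_records_vafs_equal_ad_ratios(self, tmp_path, rng):
        refs = rng.integers(10, 200, size=50)
        alts = rng.integers(1, 100, size=50)
        recs = "\n".join(
            f"1\t{1000 + i}\t.\tA\tG\t.\t.\t.\tAD\t{r},{a}"
            for i, (r, a) in enumerate(zip(refs, alts))
        )
        p = tmp_path / "x.vcf"
        p.write_text(VCF_TEMPLATE.format(records=recs))
        calls = variant_io.read_vcf(p)
        assert len(calls) == 50
        np.testing.assert_allclose(
            [c.vaf for c in calls], alts / (refs + alts), rtol=1e-12
        )


SEG_HEADER = "chrom\tstart\tend\tmajor_cn\tminor_cn\tsample_id"


class TestSegments:
    def test_total_cn(self, tmp_path):
        p = tmp_path / "x.seg"
        p.write_text(SEG_HEADER + "\n1\t1\t1000\t2\t1\tP001\n")
        (seg,) = variant_io.read_segments(p)
        assert seg.total_cn == 3

    def test_overlap_rejected_with_coordinates(self, tmp_path):
        p = tmp_path / "x.seg"
        p.write_text(
            SEG_HEADER + "\n1\t1\t1000\t2\t1\tP001\n1\t900\t2000\t1\t1\tP001\n"
        )
        with pytest.raises(FormatError, match="900-2000"):
            variant_io.read_segments(p)

    def test_major_below_minor_rejected(self, tmp_path):
        p = tmp_path / "x.seg"
        p.write_text(SEG_HEADER + "\n1\t1\t1000\t1\t2\tP001\n")
        with pytest.raises(ValueError, match="major_cn"):
            variant_io.read_segments(p)

    def test_whole_genome_diploid_lookup(self, tmp_path, make_variant, rng):
        rows = "\n".join(
            f"{c}\t1\t100000000\t1\t1\tP001" for c in range(1, 23)
        )
        p = tmp_path / "wg.seg"
        p.write_text(SEG_HEADER + "\n" + rows + "\n")
        segments = variant_io.read_segments(p)
        index = variant_io.SegmentIndex(segments)
        for _ in range(50):
            v = make_variant(
                chrom=str(rng.integers(1, 23)), pos=int(rng.integers(1, 10**8))
            )
            assert index.lookup(v).total_cn == 2


class TestClinical:
    def test_row_parses(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text(
            "patient_id\tdcb\torr\tpfs_days\tpfs_event\tpurity\n"
            "P001\t1\t0\t160\t1\t0.8\n"
        )
        (rec,) = variant_io.read_clinical(p)
        assert rec.dcb and not rec.orr and rec.pfs_days == 160 and rec.pfs_event

    def test_duplicate_patient_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text(
            "patient_id\tdcb\torr\tpfs_days\tpfs_event\tpurity\n"
            "P001\t1\t0\t160\t1\t0.8\nP001\t0\t0\t60\t1\t0.5\n"
        )
        with pytest.raises(FormatError, match="duplicate"):
            variant_io.read_clinical(p)

    def test_nonpositive_pfs_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text(
            "patient_id\tdcb\torr\tpfs_days\tpfs_event\tpurity\n"
            "P001\t1\t0\t0\t1\t0.8\n"
        )
        with pytest.raises(ValueError, match="pfs_days"):
            variant_io.read_clinical(p)

    def test_sixty_nine_patient_round_trip(self, tmp_path, rng):
        records = [
            ClinicalRecord(
                patient_id=f"P{i:03d}",
                dcb=bool(rng.integers(2)),
                orr=bool(rng.integers(2)),
                pfs_days=float(rng.integers(20, 800)),
                pfs_event=bool(rng.integers(2)),
                purity=round(float(rng.uniform(0.2, 1.0)), 3),
            )
            for i in range(69)
        ]
        p = tmp_path / "c.tsv"
        variant_io.write_clinical(records, p)
        assert variant_io.read_clinical(p) == records


class TestLookup:
    segs = [
        CopyNumberSegment("1", 100, 200, 2, 1, "P001"),
        CopyNumberSegment("1", 300, 400, 3, 0, "P001"),
        CopyNumberSegment("2", 1, 10**6, 1, 1, "P001"),
    ]

    def test_segment_start_is_inclusive(self, make_variant):
        v = make_variant(chrom="1", pos=100)
        assert variant_io.lookup_cn(v, self.segs).major_cn == 2

    def test_position_past_end_falls_back_to_default(self, make_variant):
        v = make_variant(chrom="1", pos=201)
        seg = variant_io.lookup_cn(v, self.segs)
        assert (seg.major_cn, seg.minor_cn) == (1, 1)
        assert seg is variant_io.DEFAULT_SEGMENT

    def test_agrees_with_linear_scan_on_random_positions(self, make_variant, rng):
        index = variant_io.SegmentIndex(self.segs)
        for _ in range(1000):
            v = make_variant(
                chrom=str(rng.integers(1, 4)), pos=int(rng.integers(1, 500))
            )
            brute = next(
                (
                    s
                    for s in self.segs
                    if s.sample_id == v.sample_id and s.contains(v.chrom, v.pos)
                ),
                variant_io.DEFAULT_SEGMENT,
            )
            assert index.lookup(v) == brute
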