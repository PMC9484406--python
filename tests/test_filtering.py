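"""Variant selection filters and VCF reading."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from eoadtriage.filtering import (
    EffectClass, FilterConfig, RegionSet, VariantCall, Zygosity,
    REASON_AB, REASON_DEPTH, REASON_MAF, REASON_MISSING, REASON_REGION,
    allelic_balance, apply_filters, count_distinct_variants, read_vcf,
)


def call(pid="P1", chrom="chr1", pos=100, ref="A", alt="G", **kw):
    return VariantCall(patient_id=pid, chrom=chrom, pos=pos, ref=ref, alt=alt, **kw)


class TestVariantCall:
    def test_ref_equals_alt_rejected(self):
        with pytest.raises(ValueError):
            call(ref="A", alt="A")

    def test_position_one_based(self):
        with pytest.raises(ValueError):
            call(pos=0)

    def test_ad_sum_cannot_exceed_depth(self):
        with pytest.raises(ValueError):
            call(depth=10, ref_depth=8, alt_depth=8)
        call(depth=20, ref_depth=8, alt_depth=8)  # other alleles allowed


class TestAllelicBalance:
    @pytest.mark.parametrize("ref_d,alt_d,expected", [
        (12, 8, 0.4),
        (0, 30, 1.0),
        (None, 8, None),
        (0, 0, None),
    ])
    def test_values(self, ref_d, alt_d, expected):
        c = call(ref_depth=ref_d, alt_depth=alt_d)
        assert allelic_balance(c) == expected


class TestRegionSet:
    def test_lookup_with_flank(self):
        rs = RegionSet([("chr1", 100, 200, "GENE1")])  # 0-based half-open
        assert rs.lookup("chr1", 101) == "GENE1"   # first base (1-based 101)
        assert rs.lookup("chr1", 200) == "GENE1"   # last base
        assert rs.lookup("chr1", 100) is None
        assert rs.lookup("chr1", 201) is None
        assert rs.lookup("chr1", 94, flank=7) == "GENE1"
        assert rs.lookup("chr1", 207, flank=7) == "GENE1"
        assert rs.lookup("chr1", 93, flank=7) is None
        assert rs.lookup("chr2", 150) is None

    def test_same_gene_intervals_merge(self):
        rs = RegionSet([("chr1", 100, 200, "G"), ("chr1", 150, 300, "G")])
        assert rs.intervals == [("chr1", 100, 300, "G")]

    def test_cross_gene_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RegionSet([("chr1", 100, 200, "G1"), ("chr1", 150, 300, "G2")])

    def test_bed_roundtrip(self, tmp_path):
        rs = RegionSet([("chr1", 100, 200, "G1"), ("chr2", 0, 50, "G2")])
        rs.to_bed(tmp_path / "r.bed")
        assert RegionSet.from_bed(tmp_path / "r.bed").intervals == rs.intervals


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
chr1\t100\t.\tA\tG\t.\t.\t.\tGT:AD:DP\t0/1:12,8:20\t0/0:20,0:20
chr1\t200\t.\tA\tG,T\t.\t.\t.\tGT:AD:DP\t0/1:10,9,0:20\t0/2:11,0,8:20
chr1\t300\t.\tC\tT\t.\t.\t.\tGT:AD:DP\t1/1:0,30:30\t0/0:25,0:25
chr1\t400\t.\tG\tC\t.\t.\t.\tGT\t0/1\t0/0
"""


class TestReadVcf:
    @pytest.fixture()
    def vcf_path(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(VCF_TEXT)
        return p

    def test_het_call_copies_quality_fields(self, vcf_path):
        calls = read_vcf(vcf_path)
        c = next(c for c in calls if c.pos == 100)
        assert (c.patient_id, c.zygosity) == ("S1", Zygosity.HET)
        assert (c.ref_depth, c.alt_depth, c.depth) == (12, 8, 20)
        assert allelic_balance(c) == 0.4

    def test_multiallelic_decomposition(self, vcf_path):
        calls = [c for c in read_vcf(vcf_path) if c.pos == 200]
        assert len(calls) == 2
        by_alt = {c.alt: c for c in calls}
        assert by_alt["G"].patient_id == "S1" and by_alt["G"].alt_depth == 9
        assert by_alt["T"].patient_id == "S2" and by_alt["T"].alt_depth == 8

    def test_hom_alt_and_ref_only_skipped(self, vcf_path):
        calls = [c for c in read_vcf(vcf_path) if c.pos == 300]
        assert len(calls) == 1
        assert calls[0].zygosity is Zygosity.HOM_ALT

    def test_missing_ad_dp_stay_missing(self, vcf_path):
        c = next(c for c in read_vcf(vcf_path) if c.pos == 400)
        assert c.depth is None and c.alt_depth is None

    def test_sample_map_must_cover_samples(self, vcf_path):
        with pytest.raises(ValueError, match="S2"):
            read_vcf(vcf_path, sample_map={"S1": "P1"})
        calls = read_vcf(vcf_path, sample_map={"S1": "P1", "S2": "P2"})
        assert {c.patient_id for c in calls} == {"P1", "P2"}


def het_with_ab(ab_hundredths, depth=100, **kw):
    alt = ab_hundredths
    return call(alt_depth=alt, ref_depth=depth - alt, depth=depth,
                zygosity=Zygosity.HET, **kw)


class TestApplyFilters:
    cfg = FilterConfig()

    def test_depth_below_10_rejected(self):
        res = apply_filters([call(depth=9, ref_depth=5, alt_depth=4)], self.cfg)
        assert res.rejected[0][1] == REASON_DEPTH
        res = apply_filters([call(depth=10, ref_depth=5, alt_depth=5)], self.cfg)
        assert res.kept

    @pytest.mark.parametrize("ab,kept", [(29, False), (30, True), (70, True), (71, False)])
    def test_ab_bounds_inclusive(self, ab, kept):
        res = apply_filters([het_with_ab(ab)], self.cfg)
        assert bool(res.kept) is kept
        if not kept:
            assert res.rejected[0][1] == REASON_AB

    def test_hom_alt_exempt_from_ab(self):
        c = call(depth=30, ref_depth=0, alt_depth=30, zygosity=Zygosity.HOM_ALT)
        assert apply_filters([c], self.cfg).kept

    def test_absent_from_reference_passes_rarity(self):
        res = apply_filters([het_with_ab(50)], self.cfg, ref_freq=lambda c: None)
        assert res.kept

    def test_common_variant_rejected(self):
        res = apply_filters([het_with_ab(50)], self.cfg, ref_freq=lambda c: 0.05)
        assert res.rejected[0][1] == REASON_MAF
        res = apply_filters([het_with_ab(50)], self.cfg, ref_freq=lambda c: 0.0099)
        assert res.kept

    def test_region_checked_first(self):
        regions = RegionSet([("chr1", 1000, 2000, "G")])
        c = call(pos=100, depth=5, ref_depth=3, alt_depth=2)  # fails region AND depth
        res = apply_filters([c], self.cfg, regions=regions)
        assert res.rejected[0][1] == REASON_REGION

    def test_missing_quality_reason_and_keep_mode(self):
        c = call(depth=None)
        assert apply_filters([c], self.cfg).rejected[0][1] == REASON_MISSING
        keep_cfg = FilterConfig(drop_missing_quality=False)
        assert apply_filters([c], keep_cfg).kept

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(ab_min=0.8, ab_max=0.3)
        with pytest.raises(ValueError):
            FilterConfig(max_maf=0.0)


@st.composite
def random_calls(draw):
    n = draw(st.integers(0, 30))
    calls = []
    for i in range(n):
        depth = draw(st.integers(1, 60))
        alt = draw(st.integers(0, depth))
        calls.append(VariantCall(
            patient_id=f"P{draw(st.integers(1, 5))}",
            chrom="chr1",
            pos=draw(st.integers(1, 3000)),
            ref="A", alt="G",
            depth=depth, alt_depth=alt, ref_depth=depth - alt,
            zygosity=draw(st.sampled_from([Zygosity.HET, Zygosity.HOM_ALT])),
        ))
    return calls


class TestFilterProperties:
    regions = RegionSet([("chr1", 0, 2000, "G")])

    @staticmethod
    def ref_freq(c):
        return None if c.pos % 3 else 0.05

    @given(calls=random_calls())
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_partition_and_idempotence(self, calls):
        """kept + rejected partition the input; re-filtering kept is a no-op."""
        res = apply_filters(calls, FilterConfig(), self.regions, self.ref_freq)
        assert len(res.kept) + len(res.rejected) == len(calls)
        again = apply_filters(res.kept, FilterConfig(), self.regions, self.ref_freq)
        assert again.kept == res.kept and not again.rejected

    @given(calls=random_calls(), seed=st.integers(0, 2**16))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_order_independence(self, calls, seed):
        res = apply_filters(calls, FilterConfig(), self.regions, self.ref_freq)
        shuffled = list(calls)
        random.Random(seed).shuffle(shuffled)
        res2 = apply_filters(shuffled, FilterConfig(), self.regions, self.ref_freq)
        assert set(res.kept) == set(res2.kept)
        assert set(res.rejected) == set(res2.rejected)


class TestCountDistinct:
    def test_shared_variant_counts_once(self):
        calls = [call(pid="P1", gene="APP"), call(pid="P2", gene="APP")]
        assert count_distinct_variants(calls) == 1

    def test_empty(self):
        assert count_distinct_variants([]) == 0

    def test_gene_restriction(self):
        calls = [call(pos=1, gene="APP"), call(pos=2, gene="MAPT")]
        assert count_distinct_variants(calls, genes={"APP"}) == 1
        assert count_distinct_variants(calls) == 2
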