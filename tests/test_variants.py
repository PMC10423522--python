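"""Callset reading, normalisation, merging, annotation parsing, masks
and inclusion lists."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from intervaltree import IntervalTree

from oculovar.variants import (
    VariantIOError,
    VarClass,
    Zygosity,
    apply_region_mask,
    merge_callsets,
    normalize_allele,
    parse_annotation_block,
    read_annotations,
    read_bed,
    read_callset,
    read_inclusion_lists,
)

from helpers import mk_call, write_vcf

CSQ_DESC = ["Allele", "Consequence", "IMPACT", "SYMBOL", "Feature", "CANONICAL", "MAX_AF"]


class TestReadCallset:
    def test_multiallelic_split_into_het_calls(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "a.vcf",
            ["chr1\t100\t.\tG\tA,C\t50\tPASS\tCSQ=A|missense_variant|MODERATE|G1|T1|YES|\t" "GT\t1/2"],
        )
        calls = read_callset(vcf, "S1")
        assert len(calls) == 2
        assert {c.alt for c in calls} == {"A", "C"}
        assert all(c.zygosity is Zygosity.HET for c in calls)

    def test_homozygous_alt(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "a.vcf",
            ["chr1\t100\t.\tG\tA\t50\tPASS\tCSQ=A|missense_variant|MODERATE|G1|T1|YES|\tGT\t1/1"],
        )
        (call,) = read_callset(vcf, "S1")
        assert call.zygosity is Zygosity.HOM_ALT

    def test_single_allele_genotype_is_hemizygous(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "x.vcf",
            ["chrX\t500\t.\tG\tA\t50\tPASS\tCSQ=A|stop_gained|HIGH|GX|T1|YES|\tGT\t1"],
        )
        (call,) = read_callset(vcf, "S1")
        assert call.zygosity is Zygosity.HEMIZYGOUS

    def test_missing_genotype_dropped_and_filter_status_kept(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "a.vcf",
            [
                "chr1\t100\t.\tG\tA\t50\tPASS\tCSQ=A|missense_variant|MODERATE|G1|T1|YES|\tGT\t./.",
                "chr1\t200\t.\tG\tA\t50\tLowQual\tCSQ=A|missense_variant|MODERATE|G1|T1|YES|\tGT\t0/1",
            ],
        )
        calls = read_callset(vcf, "S1")
        assert [c.pos for c in calls] == [200]
        assert not calls[0].quality_ok

    def test_indels_are_left_trimmed(self, tmp_path):
        # GCC>GC is a 1-bp deletion; shared trailing base is trimmed first
        vcf = write_vcf(
            tmp_path / "a.vcf",
            ["chr1\t100\t.\tGCC\tGC\t50\tPASS\tCSQ=GC|frameshift_variant|HIGH|G1|T1|YES|\tGT\t0/1"],
        )
        (call,) = read_callset(vcf, "S1")
        assert (call.pos, call.ref, call.alt) == (100, "GC", "G")
        assert call.var_class is VarClass.INDEL

    def test_unknown_sample_error_names_available(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "a.vcf",
            ["chr1\t100\t.\tG\tA\t50\tPASS\tCSQ=A|missense_variant|MODERATE|G1|T1|YES|\tGT\t0/1"],
        )
        with pytest.raises(VariantIOError, match="S1"):
            read_callset(vcf, "NOPE")

    def test_symbolic_deletion_keeps_end(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "a.vcf",
            ["chr1\t1000\t.\tN\t<DEL>\t50\tPASS\tSVTYPE=DEL;END=5000;CSQ=DEL|feature_truncation|HIGH|G1|T1|YES|\tGT\t0/1"],
        )
        (call,) = read_callset(vcf, "S1")
        assert call.var_class is VarClass.CNV_DEL
        assert call.end == 5000
        assert call.span == (999, 5000)


class TestNormalize:
    @pytest.mark.parametrize(
        "pos,ref,alt,expected",
        [
            (100, "GCC", "GC", (100, "GC", "G")),
            (100, "A", "T", (100, "A", "T")),
            (100, "ATT", "A", (100, "ATT", "A")),
            (100, "CAG", "CTG", (101, "A", "T")),
            (100, "N", "<DEL>", (100, "N", "<DEL>")),
        ],
    )
    def test_examples(self, pos, ref, alt, expected):
        assert normalize_allele(pos, ref, alt) == expected

    @given(
        pos=st.integers(1, 10_000),
        ref=st.text(alphabet="ACGT", min_size=1, max_size=8),
        alt=st.text(alphabet="ACGT", min_size=1, max_size=8),
    )
    @settings(max_examples=200, deadline=None)
    def test_idempotent(self, pos, ref, alt):
        once = normalize_allele(pos, ref, alt)
        assert normalize_allele(*once) == once


class TestMerge:
    def test_concatenates_and_sorts(self):
        snvs = [mk_call(pos=p) for p in (300, 100, 200)]
        cnvs = [mk_call(pos=150, ref="N", alt="<DEL>", var_class=VarClass.CNV_DEL, end=900)]
        merged = merge_callsets(snvs, cnvs)
        assert [c.pos for c in merged] == [100, 150, 200, 300]

    def test_duplicate_key_keeps_small_variant(self):
        small = mk_call(pos=100, sample="small")
        dup = mk_call(pos=100, sample="cnvside")
        merged = merge_callsets([small], [dup])
        assert len(merged) == 1
        assert merged[0].sample == "small"

    def test_empty_cnv_list_is_identity(self):
        snvs = [mk_call(pos=p) for p in (100, 200)]
        assert merge_callsets(snvs, []) == sorted(snvs, key=lambda c: c.pos)

    def test_count_conservation_with_overlap(self):
        a = [mk_call(pos=p) for p in (100, 200, 300)]
        b = [mk_call(pos=p) for p in (200, 400)]
        merged = merge_callsets(a, b)
        assert len(merged) == len(a) + len(b) - 1
        assert len({c.key for c in merged}) == len(merged)


class TestAnnotationBlock:
    KEY = ("chr1", 100, "G", "T")

    def test_field_mapping(self):
        anns = parse_annotation_block(
            "T|missense_variant|MODERATE|ABCA4|ENST00000370225|YES|0.0002",
            CSQ_DESC,
            self.KEY,
        )
        (ann,) = anns
        assert ann.gene_symbol == "ABCA4"
        assert ann.canonical
        assert ann.max_pop_af == pytest.approx(0.0002)
        assert ann.impact == "moderate"

    def test_ampersand_splits_so_terms(self):
        (ann,) = parse_annotation_block(
            "T|stop_gained&splice_region_variant|HIGH|G1|T1|YES|", CSQ_DESC, self.KEY
        )
        assert ann.so_terms == ("stop_gained", "splice_region_variant")

    def test_empty_af_field_is_missing(self):
        (ann,) = parse_annotation_block(
            "T|missense_variant|MODERATE|G1|T1||", CSQ_DESC, self.KEY
        )
        assert ann.max_pop_af is None
        assert not ann.canonical

    def test_max_over_multiple_af_fields(self):
        desc = CSQ_DESC + ["gnomAD_AF", "AF_EUR"]
        (ann,) = parse_annotation_block(
            "T|missense_variant|MODERATE|G1|T1||0.001|0.004|0.002", desc, self.KEY
        )
        assert ann.max_pop_af == pytest.approx(0.004)

    def test_field_count_mismatch_raises(self):
        with pytest.raises(VariantIOError, match="fields"):
            parse_annotation_block("T|missense_variant", CSQ_DESC, self.KEY)

    def test_read_annotations_keys_join_normalised_callset(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "a.vcf",
            ["chr1\t100\t.\tGCC\tGC\t50\tPASS\tCSQ=GC|frameshift_variant|HIGH|G1|T1|YES|0.0001\tGT\t0/1"],
        )
        (call,) = read_callset(vcf, "S1")
        annotations = read_annotations(vcf)
        assert call.key in annotations
        assert annotations[call.key][0].gene_symbol == "G1"


class TestRegionMask:
    def mask(self):
        tree = IntervalTree()
        tree.addi(90, 110, "masked")
        return {"chr1": tree}

    def test_contained_snv_removed(self):
        kept, removed = apply_region_mask([mk_call(pos=100)], self.mask())
        assert kept == [] and removed == 1

    def test_half_open_boundary_retained(self):
        kept, removed = apply_region_mask([mk_call(pos=111)], self.mask())
        assert len(kept) == 1 and removed == 0

    def test_empty_mask_is_identity(self):
        calls = [mk_call(pos=100)]
        kept, removed = apply_region_mask(calls, {})
        assert kept == calls and removed == 0

    def test_cnv_overlap_uses_span(self):
        cnv = mk_call(pos=50, ref="N", alt="<DEL>", var_class=VarClass.CNV_DEL, end=95)
        kept, removed = apply_region_mask([cnv], self.mask())
        assert removed == 1

    def test_never_removes_outside_mask_random(self):
        """Brute-force interval scan agrees with the tree-based mask."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            intervals = [
                (int(a), int(a) + int(b))
                for a, b in zip(rng.integers(0, 5000, 5), rng.integers(1, 500, 5))
            ]
            tree = IntervalTree()
            for s, e in intervals:
                tree.addi(s, e)
            calls = [mk_call(pos=int(p)) for p in rng.integers(1, 6000, 50)]
            kept, removed = apply_region_mask(calls, {"chr1": tree})
            expect_removed = [
                c for c in calls if any(s < c.pos <= e for s, e in intervals)
            ]
            assert removed == len(expect_removed)
            assert {c.pos for c in kept} | {c.pos for c in expect_removed} == {
                c.pos for c in calls
            }


class TestInclusionLists:
    def test_pathogenic_set_and_duplicate_rows(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("chrom\tpos\tref\talt\nchr1\t100\tG\tA\nchr1\t100\tG\tA\nchr2\t5\tT\tC\n")
        lists = read_inclusion_lists(known_pathogenic=path)
        assert len(lists.known_pathogenic) == 2

    def test_splice_scores_and_normalised_keys(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("chrom\tpos\tref\talt\tdelta\nchr1\t100\tGCC\tGC\t0.8\n")
        lists = read_inclusion_lists(splice_flagged=path)
        assert lists.splice_flagged == {("chr1", 100, "GC", "G"): 0.8}

    def test_score_outside_unit_interval_rejected(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("chr1\t100\tG\tA\t1.4\n")
        with pytest.raises(VariantIOError, match=r"\[0,1\]"):
            read_inclusion_lists(splice_flagged=path)

    def test_comma_separated_also_accepted(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("chr1,100,G,A\n")
        lists = read_inclusion_lists(hypomorphic=path)
        assert lists.hypomorphic == {("chr1", 100, "G", "A")}


def test_read_bed_rejects_malformed_line(tmp_path):
    bed = tmp_path / "m.bed"
    bed.write_text("chr1\t100\n")
    with pytest.raises(VariantIOError, match="m.bed:1"):
        read_bed(bed)
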