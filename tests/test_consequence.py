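"""Consequence annotation: SNVs, indels, frameshift extensions, NMD rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dntb.consequence import (
    PtcLocation,
    ReferenceMismatchError,
    UnsupportedVariantError,
    VariantCall,
    annotate_indel,
    annotate_snv,
    annotate_variant,
    annotate_vcf,
    classify_nmd,
    normalize_variant,
)
from dntb.synthetic_data import GeneSpec, make_gene

from .conftest import build_single_exon, build_two_exon
from .oracles import fs_extension_oracle, snv_effect_oracle


class TestSnv:
    # micro CDS: ATG CAA CCC TGG TGA at genomic pos0 14..28 (1-based 15..29)
    @pytest.mark.parametrize(
        "pos,ref,alt,effect,hgvs",
        [
            (18, "C", "T", "stop_gain", "p.Q2X"),  # CAA -> TAA
            (23, "C", "A", "synonymous", "p.P3="),  # CCC -> CCA
            (24, "T", "C", "missense", "p.W4R"),  # TGG -> CGG
            (28, "G", "A", "synonymous", "p.*5="),  # TGA -> TAA, stop retained
            (27, "T", "C", "stop_loss", "p.*5R"),  # TGA -> CGA
            (15, "A", "G", "start_loss", "p.M1V"),  # ATG -> GTG
        ],
    )
    def test_micro_examples(self, micro_tm, pos, ref, alt, effect, hgvs):
        c = annotate_snv(micro_tm, VariantCall("chrM1", pos, ref, alt))
        assert c.effect == effect
        assert c.hgvs_p == hgvs

    def test_reference_mismatch_raises(self, micro_tm):
        with pytest.raises(ReferenceMismatchError):
            annotate_snv(micro_tm, VariantCall("chrM1", 18, "G", "T"))

    def test_noncoding_positions(self, two_exon_tm):
        intronic = annotate_snv(two_exon_tm, VariantCall("chrT", 120, "A", "C"))
        assert intronic.effect == "noncoding" and intronic.region == "intron"
        outside = annotate_variant(two_exon_tm, VariantCall("chrT", 500, "A", "C"))
        assert outside.effect == "noncoding"

    def test_minus_strand_alleles_are_plus_strand(self):
        tm = build_two_exon("-")
        # CAA codon at CDS offsets 3..5; make it TAA: coding T at cds offset 3
        g = tm.cds_to_genomic(3)
        ref = tm.base_at(g - 1)
        alt = "A"  # plus-strand A complements coding T
        c = annotate_snv(tm, VariantCall("chrT", g, ref, alt))
        assert c.effect == "stop_gain" and c.hgvs_p == "p.Q2X"

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 5_000))
    def test_effect_matches_full_retranslation_oracle(self, seed):
        tm = make_gene(GeneSpec(n_exons=1 + seed % 4, exon_lengths=(200, 350),
                                seed=seed))
        rng = np.random.default_rng(seed)
        for _ in range(20):
            g0 = int(rng.integers(tm.span_start, tm.span_end))
            ref = tm.base_at(g0)
            alt = "ACGT"[rng.integers(4)]
            if ref not in "ACGT" or alt == ref:
                continue
            v = VariantCall(tm.chrom, g0 + 1, ref, alt)
            assert annotate_variant(tm, v).effect == snv_effect_oracle(tm, v)


class TestIndel:
    def test_insertion_shifting_stop_into_frame_immediately(self):
        # ATG AAA GAT GAC TGA; insert T after ATG -> ATG TAA ...
        tm = build_single_exon("ATGAAAGATGACTGA")
        v = VariantCall("chrM1", 17, "G", "GT")  # anchor = last base of ATG
        c = annotate_indel(tm, v)
        assert c.effect == "frameshift"
        assert c.fs_extension_aa == 0
        assert c.new_stop_codon == "TAA"
        assert c.hgvs_p == "p.K2fsX0"

    def test_inframe_deletion_of_one_codon(self):
        tm = build_single_exon("ATGAAAGATGACTGA")
        v = VariantCall("chrM1", 17, "GAAA", "G")  # removes codon 2 (AAA)
        c = annotate_indel(tm, v)
        assert c.effect == "inframe_indel"
        assert c.ptc is None and c.nmd_class == "not_applicable"

    def test_frameshift_with_no_downstream_stop_is_flagged(self):
        tm = build_single_exon("ATGAAATGA", utr3="AAC" * 10)
        v = VariantCall("chrM1", 17, "G", "GC")  # ATG C AAA TGA AAC...
        c = annotate_indel(tm, v)
        assert c.effect == "frameshift"
        assert c.no_stop_found
        assert c.nmd_class == "not_applicable"

    def test_junction_spanning_deletion_is_refused(self, two_exon_tm):
        # exon1 ends at pos0 109; delete across the boundary
        ref = two_exon_tm.seq[107:113]
        v = VariantCall("chrT", 108, ref, ref[0])
        with pytest.raises(UnsupportedVariantError):
            annotate_indel(two_exon_tm, v)

    def test_left_normalization_collapses_representations(self, micro_tm):
        # CCC homopolymer at pos0 20..22: deleting any C is the same event
        a = normalize_variant(micro_tm, VariantCall("chrM1", 21, "CC", "C"))
        b = normalize_variant(micro_tm, VariantCall("chrM1", 22, "CC", "C"))
        assert a.key == b.key

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 5_000))
    def test_fs_extension_matches_naive_retranslation(self, seed):
        tm = make_gene(GeneSpec(n_exons=1 + seed % 3, exon_lengths=(250, 400),
                                seed=seed))
        rng = np.random.default_rng(seed ^ 0xABCD)
        c0, c1 = tm.cds_mrna_interval
        for _ in range(8):
            # anchored indel strictly inside the CDS of one exon
            off = int(rng.integers(3, tm.cds_length - 12))
            g = tm.cds_to_genomic(off)
            pos0 = g - 1
            if rng.random() < 0.5:
                ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=1 + rng.integers(2)))
                v = VariantCall(tm.chrom, g, tm.base_at(pos0), tm.base_at(pos0) + ins)
            else:
                dlen = 1 + int(rng.integers(2))
                ref = "".join(tm.base_at(pos0 + i) for i in range(dlen + 1))
                exon = next(i for i, (a, b) in enumerate(tm.exons) if a <= pos0 < b)
                if pos0 + dlen >= tm.exons[exon][1]:
                    continue  # would cross a junction; not the property under test
                v = VariantCall(tm.chrom, g, ref, ref[0])
            try:
                c = annotate_indel(tm, v)
            except UnsupportedVariantError:
                continue
            net = len(v.alt) - len(v.ref)
            if net % 3 == 0:
                assert c.effect in ("inframe_indel", "stop_loss")
                continue
            if c.effect != "frameshift":
                continue  # e.g. edit normalized into UTR/stop codon
            first, ext, found = fs_extension_oracle(tm, v)
            assert (c.protein_pos, c.fs_extension_aa, not c.no_stop_found) == (
                first, ext, found,
            )


class TestNmd:
    def test_last_exon_ptc_escapes(self, two_exon_tm):
        ptc = PtcLocation(mrna_offset=120, exon_index=2,
                          distance_to_last_junction=-21)
        assert classify_nmd(two_exon_tm, ptc) == "nmd_escape"

    def test_distance_69_triggers_and_39_escapes(self, two_exon_tm):
        # junction at 99: PTC at 30 -> 69 nt upstream; PTC at 60 -> 39 nt
        predicted = classify_nmd(
            two_exon_tm, PtcLocation(30, 1, 69), rule_threshold=50
        )
        escape = classify_nmd(
            two_exon_tm, PtcLocation(60, 1, 39), rule_threshold=50
        )
        assert (predicted, escape) == ("nmd_predicted", "nmd_escape")

    def test_single_exon_always_escapes(self, micro_tm):
        c = annotate_snv(micro_tm, VariantCall("chrM1", 18, "C", "T"))
        assert c.nmd_class == "nmd_escape"

    def test_stop_gain_annotation_sets_nmd_by_position(self, two_exon_tm):
        # CAA codons start every 3 nt from CDS offset 3; C>T makes TAA
        def cls_at(cds_off):
            g = two_exon_tm.cds_to_genomic(cds_off)
            c = annotate_snv(two_exon_tm, VariantCall("chrT", g, "C", "T"))
            assert c.effect == "stop_gain"
            return c.nmd_class

        assert cls_at(24) == "nmd_predicted"  # PTC mRNA offset 30
        assert cls_at(54) == "nmd_escape"  # PTC mRNA offset 60

    def test_nmd_monotone_in_ptc_position(self):
        for seed in (2, 9, 31):
            tm = make_gene(GeneSpec(n_exons=2 + seed % 6, seed=seed))
            classes = [
                classify_nmd(tm, PtcLocation(m, 1, 0.0))
                for m in range(0, tm.mrna_length, 3)
            ]
            # once a PTC escapes, every more-3' PTC escapes too
            first_escape = classes.index("nmd_escape")
            assert all(c == "nmd_escape" for c in classes[first_escape:])


def test_annotate_vcf_writes_tsv_and_info_fields(tmp_path, micro_tm):
    import pysam

    vcf = tmp_path / "in.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chrM1,length=1000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chrM1\t18\t.\tC\tT\t.\tPASS\t.\n"
    )
    out_tsv, out_vcf = tmp_path / "out.tsv", tmp_path / "out.vcf"
    results = annotate_vcf(micro_tm, vcf, out_tsv=out_tsv, out_vcf=out_vcf)
    assert len(results) == 1 and results[0][1].effect == "stop_gain"
    assert "p.Q2X" in out_tsv.read_text()
    with pysam.VariantFile(str(out_vcf)) as vf:
        rec = next(iter(vf))
        assert rec.info["EFFECT"] == "stop_gain"
        assert rec.info["NMD"] == "nmd_escape"
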