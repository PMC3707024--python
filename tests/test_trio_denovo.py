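"""In-silico subtraction, quality filters and known-variant flagging."""

import numpy as np
import pytest

from dntb.consequence import SampleSupport, VariantCall
from dntb.synthetic_data import GeneSpec, TrioSpec, make_family, make_gene
from dntb.trio_denovo import (
    FamilyCallSet,
    PedigreeError,
    call_denovo,
    flag_known,
    load_family,
    load_known_table,
    quality_filter,
    read_ped,
    subtract_parental,
)


def vc(pos, ref="A", alt="T", alt_reads=10, depth=20, qual=True):
    return VariantCall(
        "chr1", pos, ref, alt,
        {"P1": SampleSupport(depth, alt_reads, qual, depth - alt_reads)},
    )


def family(proband, father=(), mother=(), sibling=None):
    roles = {"proband": "P1", "father": "F1", "mother": "M1"}
    calls = {"P1": list(proband), "F1": list(father), "M1": list(mother)}
    if sibling is not None:
        roles["sibling"] = "S1"
        calls["S1"] = list(sibling)
    return FamilyCallSet(pedigree=roles, calls=calls)


class TestSubtraction:
    def test_proband_only_variant_is_retained(self):
        v = vc(100)
        assert subtract_parental(family([v])) == [v]

    def test_variant_shared_with_father_is_removed(self):
        v = vc(100)
        fcs = family([v], father=[VariantCall("chr1", 100, "A", "T")])
        assert subtract_parental(fcs) == []
        assert call_denovo(fcs)[0].status == "fail_inherited"

    def test_quartet_sibling_subtraction(self):
        only_in_sib = VariantCall("chr1", 50, "G", "C")
        shared_with_sib = vc(100)
        proband_only = vc(200)
        fcs = family(
            [shared_with_sib, proband_only],
            sibling=[VariantCall("chr1", 100, "A", "T"), only_in_sib],
        )
        kept = subtract_parental(fcs)
        assert kept == [proband_only]  # sibling counts as a family member

    def test_same_position_different_allele_is_not_inherited(self):
        v = vc(100, alt="T")
        fcs = family([v], mother=[VariantCall("chr1", 100, "A", "G")])
        assert subtract_parental(fcs) == [v]

    def test_missing_member_calls_raise(self):
        fcs = family([vc(1)])
        del fcs.calls["M1"]
        with pytest.raises(PedigreeError):
            subtract_parental(fcs)


class TestQualityFilter:
    @pytest.mark.parametrize(
        "alt_reads,depth,qual,status",
        [
            (5, 10, True, "pass"),  # fraction 0.50
            (4, 10, True, "fail_support"),  # below five reads
            (39, 100, True, "fail_allele_fraction"),  # 0.39 < 0.4
            (40, 100, True, "pass"),  # inclusive lower bound
            (60, 100, True, "pass"),  # inclusive upper bound
            (61, 100, True, "fail_allele_fraction"),
            (10, 20, False, "fail_quality"),
            (0, 0, True, "fail_support"),  # zero depth: no division error
        ],
    )
    def test_thresholds(self, alt_reads, depth, qual, status):
        calls = quality_filter([vc(1, alt_reads=alt_reads, depth=depth, qual=qual)], "P1")
        assert calls[0].status == status

    def test_failure_order_support_before_fraction(self):
        # 2 alt of 100 fails both criteria; support is reported first
        calls = quality_filter([vc(1, alt_reads=2, depth=100)], "P1")
        assert calls[0].status == "fail_support"


class TestKnownFlagging:
    def test_matching_call_is_flagged_not_removed(self, tmp_path):
        table = tmp_path / "known.tsv"
        table.write_text("chr1\t100\tA\tT\trs191950160\n")
        known = load_known_table(table)
        calls = call_denovo(family([vc(100)]), known=known)
        assert calls[0].known_flag and calls[0].known_id == "rs191950160"
        assert calls[0].status == "pass"

    def test_empty_table_flags_nothing(self):
        calls = flag_known(call_denovo(family([vc(100)])), {})
        assert not calls[0].known_flag

    def test_positional_match_with_other_allele_not_flagged(self, tmp_path):
        table = tmp_path / "known.tsv"
        table.write_text("chr1\t100\tA\tG\trsX\n")
        calls = flag_known(call_denovo(family([vc(100, alt='T')])),
                           load_known_table(table))
        assert not calls[0].known_flag

    def test_malformed_rows_skipped(self, tmp_path):
        table = tmp_path / "known.tsv"
        table.write_text("chr1\tnot_a_pos\tA\tG\n" "chr1\t5\tA\tG\trsY\n")
        known = load_known_table(table)
        assert len(known) == 1

    def test_vcf_known_table(self, tmp_path):
        table = tmp_path / "known.vcf"
        table.write_text(
            "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\trs1\tA\tT\t.\t.\t.\n"
        )
        assert load_known_table(table) == {("chr1", 100, "A", "T"): "rs1"}


class TestPedAndVcf:
    def test_read_ped_roles(self, tmp_path):
        ped = tmp_path / "f.ped"
        ped.write_text(
            "FAM\tF1\t0\t0\t1\t1\nFAM\tM1\t0\t0\t2\t1\n"
            "FAM\tP1\tF1\tM1\t1\t2\nFAM\tS1\tF1\tM1\t2\t1\n"
        )
        roles = read_ped(ped)
        assert roles == {"proband": "P1", "father": "F1", "mother": "M1",
                         "sibling": "S1"}

    def test_no_affected_child_raises(self, tmp_path):
        ped = tmp_path / "f.ped"
        ped.write_text("FAM\tF1\t0\t0\t1\t1\n")
        with pytest.raises(PedigreeError):
            read_ped(ped)

    def test_vcf_round_trip_preserves_denovo_statuses(self, tmp_path):
        tm = make_gene(GeneSpec(seed=21, n_exons=4))
        spec = TrioSpec(seed=22, n_inherited_het=20, n_denovo=2,
                        include_sibling=True)
        fcs_mem, truth = make_family(spec, tm, out_dir=tmp_path)
        fcs_file = load_family(tmp_path / "family.vcf", tmp_path / "family.ped")
        mem = {(c.variant.key, c.status) for c in call_denovo(fcs_mem)}
        file = {(c.variant.key, c.status) for c in call_denovo(fcs_file)}
        assert mem == file


class TestSimulatedFamilies:
    def test_planted_truth_recovered_exactly(self):
        """Across seeded trios: passes == planted de novos meeting thresholds."""
        for seed in range(20):
            tm = make_gene(GeneSpec(seed=1000 + seed, n_exons=3,
                                    exon_lengths=(200, 400)))
            fcs, truth = make_family(
                TrioSpec(seed=seed, n_inherited_het=30, n_denovo=3), tm
            )
            statuses = {c.variant.key: c.status for c in call_denovo(fcs)}
            for row in truth.to_dict("records"):
                got = statuses[(tm.chrom, row["pos"], row["ref"], row["alt"])]
                if row["class"] == "inherited":
                    assert got == "fail_inherited"
                else:
                    af = (row["proband_alt_reads"] / row["proband_depth"]
                          if row["proband_depth"] else 0.0)
                    expect_pass = (
                        row["proband_alt_reads"] >= 5 and 0.4 <= af <= 0.6
                    )
                    assert (got == "pass") == expect_pass

    def test_false_denovo_rate_under_parent_dropout(self):
        """Dropout rate e converts inherited sites into false candidates
        at the generator's analytic Binomial(n, e) rate."""
        e, n_inh, n_trios = 0.05, 60, 40
        false_candidates = dropouts = 0
        for seed in range(n_trios):
            tm = make_gene(GeneSpec(seed=77, n_exons=3, exon_lengths=(250, 400)))
            fcs, truth = make_family(
                TrioSpec(seed=3000 + seed, n_inherited_het=n_inh, n_denovo=0,
                         error_rate=e), tm
            )
            calls = call_denovo(fcs)
            inherited_keys = {
                (tm.chrom, r["pos"], r["ref"], r["alt"])
                for r in truth.to_dict("records") if r["class"] == "inherited"
            }
            false_candidates += sum(
                1 for c in calls
                if c.status != "fail_inherited" and c.variant.key in inherited_keys
            )
            dropouts += int(truth["parent_dropout"].sum())
        assert false_candidates == dropouts  # pipeline finds exactly the dropouts
        total = n_inh * n_trios
        sd = np.sqrt(total * e * (1 - e))
        assert abs(dropouts - total * e) < 4 * sd
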