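import numpy as np
import pytest

from editrace.classify import (
    categorize,
    classify,
    deletion_placements,
    insertion_placements,
    is_plus1_duplication,
    microhomology,
)
from editrace.core import ConfigError, DonorSpec, EditAllele, EditOp, apply_allele

from conftest import build_amplicon, mirror_amplicon


def brute_force_placements(ref: str, s: int, e: int) -> list[tuple[int, int]]:
    """Oracle: every equal-length deletion producing the identical string."""
    target = ref[:s] + ref[e:]
    d = e - s
    return [
        (a, a + d)
        for a in range(len(ref) - d + 1)
        if ref[:a] + ref[a + d :] == target
    ]


class TestMicrohomology:
    def test_worked_example(self):
        mh = microhomology("TTACGACGTT", 2, 5)
        assert mh.length == 3
        assert mh.sequence == "ACG"
        assert len(mh.placements) == 4

    def test_distinct_flanks_give_zero(self):
        mh = microhomology("AACGTAGCAT", 4, 5)
        assert mh.length == 0
        assert len(mh.placements) == 1

    def test_tandem_repeat_capped_at_16(self):
        unit = "ACGTTGCAACGATCGGATCT"  # 20 nt
        ref = unit * 4
        mh = microhomology(ref, 20, 40)
        assert mh.raw_length >= 20
        assert mh.length == 16

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(20, 80))
            ref = "".join(rng.choice(list("ACGT"), size=n))
            d = int(rng.integers(1, min(12, n - 2)))
            s = int(rng.integers(0, n - d))
            mh = microhomology(ref, s, s + d)
            oracle = brute_force_placements(ref, s, s + d)
            assert set(mh.placements) <= set(oracle)
            assert mh.raw_length == len(mh.placements) - 1
            assert len(mh.sequence) == mh.raw_length

    def test_placement_count_equals_length_plus_one(self):
        mh = microhomology("AAAACCCCAAAA", 4, 8)
        assert len(mh.placements) == mh.raw_length + 1


class TestInsertionPlacements:
    def test_homopolymer_slide(self):
        ref = "AATTTTCC"
        placements = insertion_placements(ref, 4, "T")
        positions = {p for p, _ in placements}
        assert positions == {2, 3, 4, 5, 6}

    def test_rotation(self):
        ref = "AAGCGC"
        placements = insertion_placements(ref, 2, "GC")
        assert (4, "CG") in placements or (4, "GC") in placements


class TestPlus1Duplication:
    def test_duplication_detected(self, amp_t):
        cut = amp_t.cut_site
        allele = EditAllele(ops=(EditOp(cut, cut, "insertion", "T"),))
        assert is_plus1_duplication(allele, amp_t) == "T"

    def test_left_aligned_equivalent_detected(self, amp_t):
        cut = amp_t.cut_site
        allele = EditAllele(ops=(EditOp(cut - 1, cut - 1, "insertion", "T"),))
        assert is_plus1_duplication(allele, amp_t) == "T"

    def test_other_base_not_duplication(self, amp_t):
        cut = amp_t.cut_site
        allele = EditAllele(ops=(EditOp(cut, cut, "insertion", "G"),))
        assert is_plus1_duplication(allele, amp_t) is None

    def test_two_nt_insertion_excluded(self, amp_t):
        cut = amp_t.cut_site
        allele = EditAllele(ops=(EditOp(cut, cut, "insertion", "TT"),))
        assert is_plus1_duplication(allele, amp_t) is None

    def test_strand_invariance(self, amp_t):
        mirrored = mirror_amplicon(amp_t)
        cut = mirrored.cut_site
        # duplication on the mirrored reference: insert the complement base
        allele = EditAllele(ops=(EditOp(cut, cut, "insertion", "A"),))
        assert is_plus1_duplication(allele, mirrored) == "T"


def _mh_deletion_amplicon():
    """Amplicon with a planted ACC/ACC microhomology around the cut."""
    # plant ACC at [64,67) and again at [68,71): deleting [65,69) leaves
    # one ACC copy -> a 4-nt deletion with 3-nt microhomology
    edits = {64: "A", 65: "C", 66: "C", 67: "G", 68: "A", 69: "C", 70: "C", 71: "T"}
    return build_amplicon(seed=3, edits=edits, amplicon_id="mh_amp")


class TestClassify:
    def test_mh_deletion_is_mmej(self):
        amp = _mh_deletion_amplicon()
        # any placement deleting 4 nt between the ACC copies
        allele = EditAllele(ops=(EditOp(65, 69, "deletion"),))
        call = classify(allele, amp)
        assert call.repair_class == "MMEJ"
        assert call.microhomology.length >= 3

    def test_placement_invariance(self):
        amp = _mh_deletion_amplicon()
        ref = amp.reference_sequence
        base = EditOp(65, 69, "deletion")
        for s, e in deletion_placements(ref, 65, 69):
            call = classify(EditAllele(ops=(EditOp(s, e, "deletion"),)), amp)
            assert call.repair_class == "MMEJ"

    def test_gg_single_deletion_is_mmej(self, amp_gg):
        cut = amp_gg.cut_site
        call = classify(EditAllele(ops=(EditOp(cut, cut + 1, "deletion"),)), amp_gg)
        assert call.repair_class == "MMEJ"
        assert "G|G" in call.subtype

    def test_tt_single_deletion_is_nhej(self, amp_tt):
        cut = amp_tt.cut_site
        call = classify(EditAllele(ops=(EditOp(cut, cut + 1, "deletion"),)), amp_tt)
        assert call.repair_class == "NHEJ"

    def test_hdr_requires_donor(self, amp_t):
        cut = amp_t.cut_site
        allele = EditAllele(ops=(EditOp(cut, cut, "insertion", "TACGATCA"),))
        donor = DonorSpec("TACGATCA", cut)
        assert classify(allele, amp_t, donor=donor).repair_class == "HDR"
        assert classify(allele, amp_t, donor=None).repair_class == "NHEJ"

    def test_hdr_string_equality_oracle(self, amp_t):
        from editrace.core import donor_edited_sequence

        cut = amp_t.cut_site
        donor = DonorSpec("TACGATCA", cut)
        allele = EditAllele(ops=(EditOp(cut, cut, "insertion", "TACGATCA"),))
        assert apply_allele(amp_t, allele) == donor_edited_sequence(amp_t, donor)

    def test_hdr_with_extra_indel_falls_through(self, amp_t):
        cut = amp_t.cut_site
        allele = EditAllele(
            ops=(
                EditOp(cut - 5, cut - 3, "deletion"),
                EditOp(cut, cut, "insertion", "TACGATCA"),
            )
        )
        donor = DonorSpec("TACGATCA", cut)
        assert classify(allele, amp_t, donor=donor).repair_class == "NHEJ"

    def test_insertions_are_nhej(self, amp_t):
        cut = amp_t.cut_site
        call = classify(EditAllele(ops=(EditOp(cut, cut, "insertion", "T"),)), amp_t)
        assert call.repair_class == "NHEJ"
        assert call.subtype == "+T duplication"

    def test_no_mh_deletion_is_nhej(self):
        amp = build_amplicon(seed=9, edits={67: "A", 68: "C", 69: "G", 70: "T",
                                            71: "A", 72: "C"})
        allele = EditAllele(ops=(EditOp(69, 71, "deletion"),))
        mh = microhomology(amp.reference_sequence, 69, 71)
        if mh.length < 2:  # construction guard
            assert classify(allele, amp).repair_class == "NHEJ"

    def test_complex_allele_is_nhej(self, amp_t):
        amp = _mh_deletion_amplicon()
        allele = EditAllele(
            ops=(EditOp(60, 62, "deletion"), EditOp(65, 69, "deletion"))
        )
        assert classify(allele, amp).repair_class == "NHEJ"

    def test_every_edited_allele_gets_one_class(self, amp_t, rng):
        cut = amp_t.cut_site
        donor = DonorSpec("TACGATCA", cut)
        for _ in range(200):
            length = int(rng.integers(1, 25))
            start = int(rng.integers(cut - length, cut + 1))
            allele = EditAllele(ops=(EditOp(start, start + length, "deletion"),))
            call = classify(allele, amp_t, donor=donor)
            assert call.repair_class in ("NHEJ", "MMEJ", "HDR")


class TestCategorize:
    def _call(self, allele, amp, donor=None):
        return classify(allele, amp, donor=donor)

    def test_plus_t_bins(self, amp_t):
        cut = amp_t.cut_site
        allele = EditAllele(ops=(EditOp(cut, cut, "insertion", "T"),))
        call = self._call(allele, amp_t)
        assert categorize(call, allele, amp_t, "seven_group") == "+A/T"
        assert categorize(call, allele, amp_t, "eleven_cat") == "+T"
        assert categorize(call, allele, amp_t, "competition_bins") == "+1"

    def test_minus7_bins(self, amp_t):
        cut = amp_t.cut_site
        allele = EditAllele(ops=(EditOp(cut - 4, cut + 3, "deletion"),))
        call = self._call(allele, amp_t)
        assert categorize(call, allele, amp_t, "seven_group") == "-6 to -9"
        assert categorize(call, allele, amp_t, "eleven_cat") == "-6 to -9"
        assert categorize(call, allele, amp_t, "t50_bins") == "-6 to -9"
        assert categorize(call, allele, amp_t, "competition_bins") == "-6 to -9"

    def test_minus40_excluded_or_other(self, amp_t):
        cut = amp_t.cut_site
        allele = EditAllele(ops=(EditOp(cut - 20, cut + 20, "deletion"),))
        call = self._call(allele, amp_t)
        assert categorize(call, allele, amp_t, "seven_group") is None
        assert categorize(call, allele, amp_t, "eleven_cat") == "other"

    def test_minus12_t50_bin(self, amp_t):
        cut = amp_t.cut_site
        allele = EditAllele(ops=(EditOp(cut - 6, cut + 6, "deletion"),))
        call = self._call(allele, amp_t)
        assert categorize(call, allele, amp_t, "t50_bins") == ">= -10"
        assert categorize(call, allele, amp_t, "eleven_cat") == "-10 to -23"

    def test_hdr_competition_bin(self, amp_t):
        cut = amp_t.cut_site
        donor = DonorSpec("TACGATCA", cut)
        allele = EditAllele(ops=(EditOp(cut, cut, "insertion", "TACGATCA"),))
        call = self._call(allele, amp_t, donor)
        assert categorize(call, allele, amp_t, "competition_bins") == "HDR"

    def test_unknown_scheme_errors(self, amp_t):
        cut = amp_t.cut_site
        allele = EditAllele(ops=(EditOp(cut, cut, "insertion", "T"),))
        call = self._call(allele, amp_t)
        with pytest.raises(ConfigError, match="scheme"):
            categorize(call, allele, amp_t, "nope")

    def test_net_size_drives_bins(self, amp_t):
        cut = amp_t.cut_site
        allele = EditAllele(
            ops=(EditOp(cut - 8, cut - 4, "deletion"), EditOp(cut, cut, "insertion", "A"))
        )
        call = self._call(allele, amp_t)
        assert allele.net_size == -3
        assert categorize(call, allele, amp_t, "seven_group") == "-3 to -5"
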