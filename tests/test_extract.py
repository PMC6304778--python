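"""End-to-end tag extraction from single Read 1 sequences."""

import random

import pytest

from surecell.extract import extract_tags
from surecell.model import ErrorCode

from conftest import (
    TOY_BLOCKS,
    TOY_L1,
    TOY_L2,
    TOY_UMI,
    build_read,
    delete,
    insert,
    other_base,
    sub,
)
from oracles import scan_linker

CLEAN_BARCODE = "".join(TOY_BLOCKS)


@pytest.fixture(scope="module")
def clean_result(toy_cfg, toy_whitelist):
    return extract_tags(build_read(), toy_cfg, toy_whitelist, "r")


class TestBasicOutcomes:
    def test_clean_read(self, clean_result):
        assert clean_result.is_valid
        assert clean_result.cell_barcode == CLEAN_BARCODE
        assert clean_result.umi == TOY_UMI

    def test_one_substitution_in_l2_absorbed(self, toy_cfg, toy_whitelist, clean_result):
        read = build_read(linker2=sub(TOY_L2, 6, "T"))
        assert extract_tags(read, toy_cfg, toy_whitelist, "r") == clean_result

    def test_one_deletion_in_l1_absorbed(self, toy_cfg, toy_whitelist):
        read = build_read(linker1=delete(TOY_L1, 7))
        res = extract_tags(read, toy_cfg, toy_whitelist, "r")
        assert res.is_valid and res.cell_barcode == CLEAN_BARCODE and res.umi == TOY_UMI

    def test_two_substitutions_in_l1_rejected(self, toy_cfg, toy_whitelist):
        bad = sub(sub(TOY_L1, 3, "C"), 9, "A")
        res = extract_tags(build_read(linker1=bad), toy_cfg, toy_whitelist, "r")
        assert res.error_code is ErrorCode.L1

    def test_random_short_read_is_LX(self, toy_cfg, toy_whitelist):
        rng = random.Random(1)
        read = "".join(rng.choice("ACGT") for _ in range(20))
        res = extract_tags(read, toy_cfg, toy_whitelist, "r")
        assert res.error_code is ErrorCode.LX

    def test_missing_single_linker_codes(self, toy_cfg, toy_whitelist):
        no_l1 = build_read(linker1="C" * 15)
        assert extract_tags(no_l1, toy_cfg, toy_whitelist, "r").error_code is ErrorCode.L1
        no_l2 = build_read(linker2="T" * 15)
        assert extract_tags(no_l2, toy_cfg, toy_whitelist, "r").error_code is ErrorCode.L2

    def test_phase_too_short_is_P(self, toy_cfg, toy_whitelist):
        res = extract_tags(build_read(phase=""), toy_cfg, toy_whitelist, "r")
        assert res.error_code is ErrorCode.P

    def test_truncated_read_is_S(self, toy_cfg, toy_whitelist):
        read = build_read(tail="")[:-10]  # cuts into the UMI/flanker region
        res = extract_tags(read, toy_cfg, toy_whitelist, "r")
        assert res.error_code is ErrorCode.S

    def test_two_flanker_mismatches_is_T(self, toy_cfg, toy_whitelist):
        res = extract_tags(
            build_read(pre="ATG", post="GTC"), toy_cfg, toy_whitelist, "r"
        )
        assert res.error_code is ErrorCode.T

    def test_unmatchable_barcode_is_B(self, toy_cfg, toy_whitelist):
        res = extract_tags(build_read(bc2="TTTTTT"), toy_cfg, toy_whitelist, "r")
        assert res.error_code is ErrorCode.B

    def test_lowercase_input_handled(self, toy_cfg, toy_whitelist):
        res = extract_tags(build_read().lower(), toy_cfg, toy_whitelist, "r")
        assert res.is_valid and res.cell_barcode == CLEAN_BARCODE


class TestPerfectRecoverySweep:
    @pytest.mark.parametrize("pb_len", range(1, 11))
    def test_any_phase_block_length(self, toy_cfg, toy_whitelist, pb_len):
        rng = random.Random(pb_len)
        for _ in range(20):
            phase = "".join(rng.choice("ACGT") for _ in range(pb_len))
            umi = "".join(rng.choice("ACGT") for _ in range(8))
            read = build_read(phase=phase, umi=umi)
            res = extract_tags(read, toy_cfg, toy_whitelist, "r")
            assert res.is_valid
            assert res.cell_barcode == CLEAN_BARCODE
            assert res.umi == umi


class TestOneEditRobustness:
    """A single edit anywhere inside either linker leaves the result
    identical to the clean read's."""

    @pytest.mark.parametrize("which", ["linker1", "linker2"])
    @pytest.mark.parametrize("pos", range(15))
    def test_substitution(self, toy_cfg, toy_whitelist, which, pos):
        linker = TOY_L1 if which == "linker1" else TOY_L2
        read = build_read(**{which: sub(linker, pos, other_base(linker[pos]))})
        res = extract_tags(read, toy_cfg, toy_whitelist, "r")
        assert res.is_valid and res.cell_barcode == CLEAN_BARCODE and res.umi == TOY_UMI

    @pytest.mark.parametrize("which", ["linker1", "linker2"])
    @pytest.mark.parametrize("pos", range(15))
    def test_deletion(self, toy_cfg, toy_whitelist, which, pos):
        linker = TOY_L1 if which == "linker1" else TOY_L2
        read = build_read(**{which: delete(linker, pos)})
        res = extract_tags(read, toy_cfg, toy_whitelist, "r")
        assert res.is_valid and res.cell_barcode == CLEAN_BARCODE and res.umi == TOY_UMI

    @pytest.mark.parametrize("which", ["linker1", "linker2"])
    @pytest.mark.parametrize("pos", range(15))
    def test_insertion(self, toy_cfg, toy_whitelist, which, pos):
        # the inserted base must differ from its new neighbors, otherwise
        # the read is sequence-identical to a boundary insertion
        linker = TOY_L1 if which == "linker1" else TOY_L2
        avoid = {linker[pos]}
        if pos > 0:
            avoid.add(linker[pos - 1])
        base = other_base(linker[pos], *avoid)
        read = build_read(**{which: insert(linker, pos, base)})
        res = extract_tags(read, toy_cfg, toy_whitelist, "r")
        assert res.is_valid and res.cell_barcode == CLEAN_BARCODE and res.umi == TOY_UMI


class TestTwoEditRejection:
    @pytest.mark.parametrize("which,code", [("linker1", ErrorCode.L1), ("linker2", ErrorCode.L2)])
    def test_all_position_pairs(self, toy_cfg, toy_whitelist, which, code):
        linker = TOY_L1 if which == "linker1" else TOY_L2
        for p1 in range(15):
            for p2 in range(p1 + 1, 15):
                mutated = None
                for b1 in "ACGT":
                    if b1 == linker[p1]:
                        continue
                    for b2 in "ACGT":
                        if b2 == linker[p2]:
                            continue
                        cand = sub(sub(linker, p1, b1), p2, b2)
                        read = build_read(**{which: cand})
                        # premise: the doubly-substituted read must not
                        # coincidentally contain a within-1-edit window
                        if not scan_linker(read, linker, 1):
                            mutated = read
                            break
                    if mutated:
                        break
                assert mutated is not None, (which, p1, p2)
                res = extract_tags(mutated, toy_cfg, toy_whitelist, "r")
                assert res.error_code is code, (which, p1, p2)

    def test_both_linkers_broken_is_LX(self, toy_cfg, toy_whitelist):
        read = build_read(
            linker1=sub(sub(TOY_L1, 2, "C"), 9, "A"),
            linker2=sub(sub(TOY_L2, 2, "T"), 9, "T"),
        )
        assert extract_tags(read, toy_cfg, toy_whitelist, "r").error_code is ErrorCode.LX


class TestBarcodeCorrectionAndUmi:
    def test_substituted_barcode_corrected_to_whitelist_entry(self, toy_cfg, toy_whitelist):
        read = build_read(bc2=sub(TOY_BLOCKS[1], 3, "C"))
        res = extract_tags(read, toy_cfg, toy_whitelist, "r")
        assert res.is_valid and res.cell_barcode == CLEAN_BARCODE

    def test_bc2_indels_absorbed_via_gap(self, toy_cfg, toy_whitelist):
        for mutated in (delete(TOY_BLOCKS[1], 2), insert(TOY_BLOCKS[1], 2, "A")):
            res = extract_tags(build_read(bc2=mutated), toy_cfg, toy_whitelist, "r")
            assert res.is_valid and res.cell_barcode == CLEAN_BARCODE

    def test_umi_reported_verbatim_never_corrected(self, toy_cfg, toy_whitelist):
        umi = "NNNNNNNN"
        read = build_read(umi=umi)
        res = extract_tags(read, toy_cfg, toy_whitelist, "r")
        assert res.is_valid and res.umi == umi
        assert res.umi in read

    def test_ambiguous_correction_is_B_not_guessed(self, toy_cfg):
        from surecell.model import BarcodeWhitelist

        wl = BarcodeWhitelist(["AAAAAA", "AAAAAT", "TGCATG", "GATCGA"])
        read = build_read(bc1="AAAAAG")
        res = extract_tags(read, toy_cfg, wl, "r")
        assert res.error_code is ErrorCode.B
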