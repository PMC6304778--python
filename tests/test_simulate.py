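"""Synthetic dataset generator and its independent outcome oracle."""

import math

import pytest

import surecell as sc
from surecell.model import ReadStructureConfig
from surecell.simulate import (
    ErrorSpec,
    ReadParts,
    expected_code_fractions,
    expected_status,
    generate_dataset,
    inject_errors,
    sample_cells,
)

import random


def extract_all(ds, cfg, wl):
    for pair, row in zip(sc.read_pairs(ds.r1_path, ds.r2_path), ds.truth().itertuples()):
        yield sc.extract_tags(pair.r1_seq, cfg, wl, pair.read_id), row


class TestGeneration:
    def test_counts_and_distinct_cells(self, tmp_path, surecell_cfg, packaged_whitelist):
        ds = generate_dataset(3, 10, tmp_path, seed=1)
        assert ds.n_reads == 30
        truth = ds.truth()
        assert len(truth) == 30
        assert truth.expected_status.eq("valid").all()
        assert truth.true_cell_barcode.nunique() == 3
        assert len(list(sc.read_pairs(ds.r1_path, ds.r2_path))) == 30

    def test_same_seed_byte_identical(self, tmp_path):
        a = generate_dataset(3, 5, tmp_path / "a", seed=7)
        b = generate_dataset(3, 5, tmp_path / "b", seed=7)
        assert a.r1_path.read_bytes() == b.r1_path.read_bytes()
        assert a.r2_path.read_bytes() == b.r2_path.read_bytes()
        assert a.truth_path.read_text() == b.truth_path.read_text()
        c = generate_dataset(3, 5, tmp_path / "c", seed=8)
        assert c.r1_path.read_bytes() != a.r1_path.read_bytes()

    def test_single_linker_substitution_all_expected_valid(self, tmp_path):
        model = {ErrorSpec("linker1", "substitution"): 1.0}
        ds = generate_dataset(3, 10, tmp_path, error_model=model, seed=1)
        assert ds.truth().expected_status.eq("valid").all()

    def test_double_linker_substitution_all_expected_L1(self, tmp_path):
        model = {ErrorSpec("linker1", "substitution", count=2): 1.0}
        ds = generate_dataset(3, 10, tmp_path, error_model=model, seed=1)
        assert ds.truth().expected_status.eq("L1").all()

    def test_infeasible_cell_count_rejected(self, tmp_path):
        wl = sc.BarcodeWhitelist(["ACGTAC", "TGCATG"])
        with pytest.raises(ValueError):
            generate_dataset(9, 1, tmp_path, whitelist=wl, seed=0)

    def test_phase_lengths_cover_range(self, tmp_path):
        ds = generate_dataset(5, 40, tmp_path, seed=2, phase_range=(1, 5))
        assert set(ds.truth().phase_block_len) == {1, 2, 3, 4, 5}


class TestExpectedStatusOracle:
    def cell(self, wl):
        return (wl.entries[0], wl.entries[1], wl.entries[2])

    def parts(self, cfg, wl, **kw):
        return ReadParts.clean(self.cell(wl), umi="A" * 8, phase="GTG", cfg=cfg, tail="ACGT")

    def test_clean_parts_valid(self, surecell_cfg, packaged_whitelist):
        status, bc, umi = expected_status(
            self.parts(surecell_cfg, packaged_whitelist), surecell_cfg, packaged_whitelist
        )
        assert status == "valid"
        assert bc == "".join(self.cell(packaged_whitelist))
        assert umi == "A" * 8

    def test_unique_bc_substitution_corrected(self, surecell_cfg, packaged_whitelist):
        import dataclasses

        p = self.parts(surecell_cfg, packaged_whitelist)
        mutated = ("T" if p.bc1[0] != "T" else "G") + p.bc1[1:]
        p = dataclasses.replace(p, bc1=mutated)
        status, bc, _ = expected_status(p, surecell_cfg, packaged_whitelist)
        assert status == "valid"
        assert bc[:6] == self.cell(packaged_whitelist)[0]  # corrected, not raw

    def test_deletion_in_each_linker_within_per_linker_budget(
        self, surecell_cfg, packaged_whitelist
    ):
        import dataclasses

        p = self.parts(surecell_cfg, packaged_whitelist)
        p = dataclasses.replace(
            p,
            linker1=surecell_cfg.linker1[:7] + surecell_cfg.linker1[8:],
            linker2=surecell_cfg.linker2[:3] + surecell_cfg.linker2[4:],
        )
        status, bc, _ = expected_status(p, surecell_cfg, packaged_whitelist)
        assert status == "valid"
        assert bc == "".join(self.cell(packaged_whitelist))


class TestEndToEndAgreement:
    """Extraction reproduces the generator's expected status for every
    read, across single-error classes and the empty model."""

    @pytest.mark.parametrize(
        "spec",
        [
            None,
            ErrorSpec("linker1", "substitution"),
            ErrorSpec("linker2", "substitution"),
            ErrorSpec("linker1", "deletion"),
            ErrorSpec("linker2", "deletion"),
            ErrorSpec("linker1", "insertion"),
            ErrorSpec("linker2", "insertion"),
            ErrorSpec("bc1", "substitution"),
            ErrorSpec("bc2", "substitution"),
            ErrorSpec("bc3", "substitution"),
            ErrorSpec("bc2", "deletion"),
            ErrorSpec("bc2", "insertion"),
            ErrorSpec("bc1", "deletion"),
            ErrorSpec("bc3", "insertion"),
            ErrorSpec("flanker_pre", "substitution"),
            ErrorSpec("umi", "substitution"),
            ErrorSpec("phase", "deletion"),
            ErrorSpec("linker1", "substitution", count=2),
            ErrorSpec("flanker_post", "substitution", count=2),
        ],
        ids=lambda s: "clean" if s is None else f"{s.target}-{s.kind}-x{s.count}",
    )
    def test_status_agreement_is_total(self, tmp_path, surecell_cfg, packaged_whitelist, spec):
        model = {spec: 1.0} if spec else {}
        ds = generate_dataset(20, 15, tmp_path, error_model=model, seed=5)
        for res, row in extract_all(ds, surecell_cfg, packaged_whitelist):
            obs = "valid" if res.is_valid else res.error_code.value
            assert obs == row.expected_status, row.injected_errors

    def test_barcode_and_umi_recovered_for_substitution_classes(
        self, tmp_path, surecell_cfg, packaged_whitelist
    ):
        model = {
            ErrorSpec("bc1", "substitution"): 0.3,
            ErrorSpec("bc2", "substitution"): 0.3,
            ErrorSpec("umi", "substitution"): 0.3,
            ErrorSpec("linker1", "substitution"): 0.3,
        }
        ds = generate_dataset(20, 20, tmp_path, error_model=model, seed=6)
        for res, row in extract_all(ds, surecell_cfg, packaged_whitelist):
            assert res.is_valid
            assert res.cell_barcode == row.expected_cell_barcode
            assert res.umi == row.expected_umi


class TestAnalyticExpectation:
    def model(self):
        return {
            ErrorSpec("linker1", "substitution"): 0.05,
            ErrorSpec("linker2", "substitution"): 0.05,
            ErrorSpec("linker1", "substitution", count=2): 0.02,
            ErrorSpec("bc2", "substitution", count=2): 0.02,
            ErrorSpec("flanker_pre", "substitution", count=2): 0.01,
        }

    def test_fractions_sum_to_one(self, surecell_cfg, packaged_whitelist):
        rng = random.Random(0)
        cells = sample_cells(30, packaged_whitelist, rng)
        exp = expected_code_fractions(self.model(), cells, surecell_cfg, packaged_whitelist)
        assert sum(exp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empirical_within_three_binomial_sd(self, tmp_path, surecell_cfg, packaged_whitelist):
        model = self.model()
        ds = generate_dataset(30, 400, tmp_path, error_model=model, seed=17)
        obs: dict[str, int] = {}
        for res, _ in extract_all(ds, surecell_cfg, packaged_whitelist):
            key = "PASS" if res.is_valid else res.error_code.value
            obs[key] = obs.get(key, 0) + 1
        exp = expected_code_fractions(model, ds.cells, surecell_cfg, packaged_whitelist)
        n = ds.n_reads
        for code, p in exp.items():
            if p == 0:
                assert obs.get(code, 0) == 0, code
                continue
            sd = math.sqrt(n * p * (1 - p))
            assert abs(obs.get(code, 0) - n * p) <= 3 * max(sd, 1.0), code

    def test_unsupported_spec_rejected(self, surecell_cfg, packaged_whitelist):
        rng = random.Random(0)
        cells = sample_cells(5, packaged_whitelist, rng)
        with pytest.raises(ValueError):
            expected_code_fractions(
                {ErrorSpec("bc3", "deletion"): 0.1}, cells, surecell_cfg, packaged_whitelist
            )


def test_inject_errors_records_positions(surecell_cfg, packaged_whitelist):
    rng = random.Random(4)
    cell = (packaged_whitelist.entries[0],) * 3
    parts = ReadParts.clean(cell, umi="A" * 8, phase="GT", cfg=surecell_cfg, tail="")
    mutated, realized = inject_errors(parts, [ErrorSpec("umi", "substitution")], rng)
    assert len(realized) == 1 and realized[0].startswith("umi:substitution:")
    assert mutated.umi != parts.umi
    assert sum(a != b for a, b in zip(mutated.umi, parts.umi)) == 1
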