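from __future__ import annotations

import pytest

from surecell import BarcodeWhitelist, ReadStructureConfig, default_whitelist

# toy 15-nt linkers and whitelist used to build readable fixture reads
TOY_L1 = "AAAAATTTTTGGGGG"
TOY_L2 = "CCCCCGGGGGAAAAA"
TOY_BLOCKS = ("ACGTAC", "TGCATG", "GATCGA")
TOY_UMI = "AACCGGTT"


@pytest.fixture(scope="session")
def toy_cfg() -> ReadStructureConfig:
    return ReadStructureConfig(linker1=TOY_L1, linker2=TOY_L2)


@pytest.fixture(scope="session")
def toy_whitelist() -> BarcodeWhitelist:
    return BarcodeWhitelist(TOY_BLOCKS)


@pytest.fixture(scope="session")
def packaged_whitelist() -> BarcodeWhitelist:
    return default_whitelist()


@pytest.fixture(scope="session")
def surecell_cfg() -> ReadStructureConfig:
    return ReadStructureConfig()


def build_read(
    phase: str = "GT",
    bc1: str = TOY_BLOCKS[0],
    linker1: str = TOY_L1,
    bc2: str = TOY_BLOCKS[1],
    linker2: str = TOY_L2,
    bc3: str = TOY_BLOCKS[2],
    pre: str = "ACG",
    umi: str = TOY_UMI,
    post: str = "GAC",
    tail: str = "ACGT",
) -> str:
    """Assemble a Read 1 sequence from its anatomical parts."""
    return phase + bc1 + linker1 + bc2 + linker2 + bc3 + pre + umi + post + tail


def sub(seq: str, pos: int, base: str) -> str:
    assert seq[pos] != base
    return seq[:pos] + base + seq[pos + 1 :]


def delete(seq: str, pos: int) -> str:
    return seq[:pos] + seq[pos + 1 :]


def insert(seq: str, pos: int, base: str) -> str:
    return seq[:pos] + base + seq[pos:]


def other_base(b: str, *avoid: str) -> str:
    for c in "ACGT":
        if c != b and c not in avoid:
            return c
    raise AssertionError("no base available")
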