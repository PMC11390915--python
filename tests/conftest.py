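import csv
from pathlib import Path

import pytest

from histofold.fixture_forge import (
    ALPHA3_PRESET,
    NUCLEOSOMAL_PRESET,
    AssemblySpec,
    assemble_oligomer,
    build_fold_monomer,
    write_golden_suite,
)


@pytest.fixture(scope="session")
def golden_dir(tmp_path_factory) -> Path:
    """The golden fixture suite, generated once per session (seed 42)."""
    out = tmp_path_factory.mktemp("golden")
    write_golden_suite(out, seed=42)
    return out


@pytest.fixture(scope="session")
def golden_truth(golden_dir) -> dict:
    with open(golden_dir / "truth.tsv") as fh:
        return {
            row["protein_id"]: row["expected_category"]
            for row in csv.DictReader(fh, delimiter="\t")
        }


@pytest.fixture(scope="session")
def nuc_monomer():
    return build_fold_monomer(NUCLEOSOMAL_PRESET, seed=1)


@pytest.fixture(scope="session")
def a3_monomer():
    return build_fold_monomer(ALPHA3_PRESET, seed=1)


@pytest.fixture(scope="session")
def nuc_dimer():
    return assemble_oligomer(AssemblySpec(NUCLEOSOMAL_PRESET, "handshake_dimer", seed=1))


@pytest.fixture(scope="session")
def a3_ftf_tetramer():
    return assemble_oligomer(AssemblySpec(ALPHA3_PRESET, "ftf_tetramer", seed=1))


@pytest.fixture(scope="session")
def nuc_cc_tetramer():
    from dataclasses import replace

    from histofold.fixture_forge import FlankSpec

    arch = replace(NUCLEOSOMAL_PRESET, c_flank=FlankSpec(25, "cc_extension"))
    return assemble_oligomer(AssemblySpec(arch, "cc_tetramer", seed=1))
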