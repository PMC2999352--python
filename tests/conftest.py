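"""Shared fixtures: a toy dimer template with special bonds, derived matrices
and single-sequence chain profiles."""

from __future__ import annotations

import pytest

from interolog3d import build_profile, build_template, parse_structure
from interolog3d.matrices import derive_matrix_set
from interolog3d.synthetic import ToyDimerSpec, make_toy_dimer


@pytest.fixture(scope="session")
def toy_spec() -> ToyDimerSpec:
    return ToyDimerSpec(
        seed=11,
        n_contacts=26,
        special_bond_plan={
            0: "disulfide",
            1: "salt_bridge",
            2: "hydrogen_bond",
            3: "hydrogen_bond_sb",
        },
    )


@pytest.fixture(scope="session")
def toy_dimer(toy_spec):
    pdb_text, ground_truth, seq_a, seq_b = make_toy_dimer(toy_spec)
    return {"pdb": pdb_text, "truth": ground_truth, "seq_a": seq_a,
            "seq_b": seq_b}


@pytest.fixture(scope="session")
def toy_structure(toy_dimer):
    return parse_structure(toy_dimer["pdb"], structure_id="toy")


@pytest.fixture(scope="session")
def toy_template(toy_structure):
    return build_template(toy_structure, "A", "B", template_id="toy")


@pytest.fixture(scope="session")
def toy_matrices(toy_template):
    matrices, table = derive_matrix_set([toy_template])
    return matrices


@pytest.fixture(scope="session")
def toy_background(toy_template):
    from interolog3d.matrices import count_pairs

    return count_pairs([toy_template]).interface_background()


@pytest.fixture(scope="session")
def toy_profiles(toy_template):
    return (
        build_profile([toy_template.chain_a_seq], chain_id="A"),
        build_profile([toy_template.chain_b_seq], chain_id="B"),
    )


@pytest.fixture(scope="session")
def blosum():
    from interolog3d import load_substitution_matrix

    return load_substitution_matrix("BLOSUM62")
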