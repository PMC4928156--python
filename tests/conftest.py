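"""Shared fixtures: all inputs are generated programmatically at test time."""

import numpy as np
import pytest

from stabilis import compute_sasa, relative_accessibility
from stabilis.structure import AtomRecord, ResidueSite, Structure
from stabilis.synthetic import (
    SyntheticConfig,
    load_reference_tables,
    make_toy_complex,
    make_toy_structure,
    make_training_set,
)


@pytest.fixture(scope="session")
def helix9():
    """9-residue ideal helix with a central glycine, RSA computed."""
    s, text = make_toy_structure(9, sequence="AAAAGAAAA")
    compute_sasa(s)
    relative_accessibility(s)
    return s, text


@pytest.fixture(scope="session")
def toy_complex():
    """Isolated helix + caged 'assembly' with RSA computed on both."""
    iso, cpx, text_iso, text_cpx = make_toy_complex()
    for s in (iso, cpx):
        compute_sasa(s)
        relative_accessibility(s)
    return iso, cpx, text_iso, text_cpx


@pytest.fixture(scope="session")
def reference_tables():
    return load_reference_tables()


@pytest.fixture(scope="session")
def training_records_small():
    """300 planted-signal records on 6 proteins (fast fits)."""
    return make_training_set(SyntheticConfig(seed=11, n_proteins=6, variants_per_protein=50))


def make_point_structure(positions, aas=None, chain_id="A", structure_id="pts"):
    """Structure of single-CA residues at given coordinates (test helper)."""
    positions = np.asarray(positions, dtype=float)
    if aas is None:
        aas = ["A"] * len(positions)
    residues = [
        ResidueSite(
            chain_id=chain_id,
            seq_pos=i + 1,
            aa=aa,
            atoms=[AtomRecord(name="CA", element="C", coords=pos)],
        )
        for i, (pos, aa) in enumerate(zip(positions, aas))
    ]
    return Structure(
        id=structure_id, assembly_kind="isolated_chain", chains={chain_id: residues}
    )


def make_random_structure(rng, n_res=10, atoms_per_res=3, box=12.0):
    """Random residue cloud for contact-rule oracle tests (test helper)."""
    from stabilis._aa_data import AA1

    residues = []
    for i in range(n_res):
        center = rng.uniform(0, box, size=3)
        atoms = [
            AtomRecord(
                name=f"X{k}",
                element="C",
                coords=center + rng.normal(0, 1.0, size=3),
            )
            for k in range(atoms_per_res)
        ]
        residues.append(
            ResidueSite(chain_id="A", seq_pos=i + 1, aa=AA1[rng.integers(20)], atoms=atoms)
        )
    return Structure(id="rand", assembly_kind="isolated_chain", chains={"A": residues})
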