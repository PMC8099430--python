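"""Shared fixtures and builders for the test suite.

Systems are constructed programmatically: bead chains through the topology
builder, pseudo-atomic structures through gemmi, coordinates overwritten
explicitly where a test needs exact geometry.
"""

from __future__ import annotations

import gemmi
import numpy as np
import pytest

from xlwalk.representation import Molecule, Segment, Topology, build_system


def structure_from_chains(
    chains: dict[str, np.ndarray], atom_name: str = "CA", res_name: str = "ALA"
) -> gemmi.Structure:
    """A one-model structure with one atom per residue per chain."""
    st = gemmi.Structure()
    st.name = "test"
    model = gemmi.Model(1)
    for name, coords in chains.items():
        chain = gemmi.Chain(name)
        for num, row in enumerate(np.atleast_2d(coords), start=1):
            res = gemmi.Residue()
            res.name = res_name
            res.seqid = gemmi.SeqId(num, " ")
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*row)
            atom.occ = 1.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def bead_system(
    molecules: list[tuple[str, int, int]], seed: int = 0, fixed: set[str] = frozenset()
):
    """System of pure bead chains: (name, length, copy_count) triples."""
    mols = tuple(
        Molecule(
            name,
            length,
            (Segment(1, length, "beads"),),
            copy_count=copies,
            fixed=name in fixed,
            anchor_xyz=(0.0, 0.0, 0.0),
        )
        for name, length, copies in molecules
    )
    return build_system(Topology(mols), seed=seed)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_copy_system():
    """Receptor R (1 bead) + ligand L (3 beads) in two copies."""
    return bead_system([("R", 1, 1), ("L", 3, 2)], seed=1)
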