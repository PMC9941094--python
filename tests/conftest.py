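import numpy as np
import pytest

from abvisc.structure_io import Atom, Structure, assign_parameters, canonicalize
from abvisc.surface import DESK_GRID, GridSpec
from abvisc.synthetic import PatchSpec, ToySpec, make_toy_structure


def make_atoms(entries, resname="GLY", chain="A"):
    """Hand-build a Structure from (name, element, resnum, xyz[, charge, radius])."""
    atoms = []
    for i, e in enumerate(entries):
        name, element, resnum, pos = e[:4]
        a = Atom(
            serial=i + 1,
            name=name,
            element=element,
            residue_name=resname if isinstance(resname, str) else resname[i],
            residue_number=resnum,
            insertion_code="",
            chain_id=chain,
            position=np.array(pos, dtype=float),
        )
        if len(e) > 4:
            a.partial_charge = e[4]
        if len(e) > 5:
            a.radius = e[5]
        a.mass = 12.0
        atoms.append(a)
    return Structure(atoms=atoms, chains={chain: "other"})


@pytest.fixture(scope="session")
def toy_structure():
    """Parameterized, centered toy with a negative and a cation patch."""
    s = make_toy_structure(
        ToySpec(
            patches=(
                PatchSpec((0.0, 0.0, 1.0), 6, "ASP"),
                PatchSpec((0.0, 0.0, -1.0), 2, "LYS"),
            ),
            seed=11,
        )
    )
    return canonicalize(assign_parameters(s))


@pytest.fixture(scope="session")
def desk_grid():
    return DESK_GRID


@pytest.fixture
def small_grid():
    """17^3 physical grid without padding, for surface oracles."""
    return GridSpec(extent=6.0, spacing=0.75, padded_dim=17)
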