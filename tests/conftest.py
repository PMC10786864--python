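import numpy as np
import pytest

from ppirep.structure import Atom, Chain, Residue, StructureModel, VdwTable


@pytest.fixture(scope="session")
def vdw() -> VdwTable:
    return VdwTable()


def single_atom_chain(chain_id: str, coord, element: str = "C",
                      number: int = 1, resname: str = "ALA") -> Chain:
    atom = Atom(name="CA", element=element, coord=np.asarray(coord, float))
    return Chain(chain_id, [Residue(resname, number, atoms=[atom])])


def ca_chain(chain_id: str, coords, start: int = 1) -> Chain:
    residues = [
        Residue("ALA", start + i,
                atoms=[Atom(name="CA", element="C", coord=np.asarray(c, float))])
        for i, c in enumerate(coords)
    ]
    return Chain(chain_id, residues)


@pytest.fixture
def two_chain_model(vdw) -> StructureModel:
    a = ca_chain("A", [[i * 6.0, 0, 0] for i in range(8)])
    b = ca_chain("B", [[i * 6.0, 3.5, 0] for i in range(8)])
    return StructureModel("FIX1", [a, b])
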