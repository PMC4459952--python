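import numpy as np
import pytest

from remcdock.energy import EnergyParams
from remcdock.toys import ToyComplexSpec, generate_start, make_toy_complex


@pytest.fixture(scope="session")
def toy():
    """Default toy complex: (native pose, atom params, rotamer library)."""
    return make_toy_complex()


@pytest.fixture(scope="session")
def native(toy):
    return toy[0]


@pytest.fixture(scope="session")
def library(toy):
    return toy[2]


@pytest.fixture(scope="session")
def energy_params():
    return EnergyParams()


@pytest.fixture(scope="session")
def start_pose(native):
    return generate_start(native, rng=np.random.default_rng(99))


@pytest.fixture(scope="session")
def one_residue_pose():
    """Minimal system with a single χ-bearing ligand residue."""
    pose, _, _ = make_toy_complex(ToyComplexSpec(receptor_atom_count=1, ligand_atom_count=5))
    return pose


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def toy_pdb_text(n_receptor=5, n_ligand=3, with_hydrogens=False):
    """Minimal two-chain PDB text: receptor chain R, ligand chain L."""
    lines = []
    serial = 1

    def atom_line(name, element, chain, res_id, res_name, x, y, z):
        nonlocal serial
        line = (
            f"ATOM  {serial:5d} {name:>4s} {res_name:<3s} {chain}{res_id:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
        )
        serial += 1
        return line

    for i in range(n_receptor):
        lines.append(atom_line("CA", "C", "R", i + 1, "PKT", 4.0 * i, 0.0, 0.0))
        if with_hydrogens:
            lines.append(atom_line("H", "H", "R", i + 1, "PKT", 4.0 * i, 0.5, 0.5))
    for i in range(n_ligand):
        lines.append(atom_line("CA", "C", "L", i + 1, "LAN", 4.0 * i, 0.0, 4.0))
        if with_hydrogens:
            lines.append(atom_line("H", "H", "L", i + 1, "LAN", 4.0 * i, 0.5, 4.5))
    lines.append("END")
    return "\n".join(lines) + "\n"
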