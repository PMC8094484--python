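"""Shared fixtures: tiny hand-written PDB texts, full-atom mini-structures,
synthetic complexes, and the worked-example residue lists for the DateHub
complexes 1A0A and 1E9G."""

from __future__ import annotations

import numpy as np
import pytest

from hotregions import SyntheticSpec, generate_complex


def _atom_line(serial, name, resname, chain, seq, x, y, z, element=None):
    element = element or name[0]
    return (
        f"ATOM  {serial:5d} {name:^4s}{resname:>4s} {chain:1s}{seq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


@pytest.fixture(scope="session")
def two_chain_pdb_text() -> str:
    """2 chains x 5 residues, Calpha only, 3.8 angstrom spacing."""
    lines = []
    serial = 1
    for chain, y in (("A", 0.0), ("B", 20.0)):
        for i in range(5):
            lines.append(
                _atom_line(serial, "CA", "GLY", chain, i + 1, 3.8 * i, y, 0.0, "C")
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def missing_ca_pdb_text() -> str:
    """Same as two_chain_pdb_text but residue B3 carries only an N atom."""
    lines = []
    serial = 1
    for chain, y in (("A", 0.0), ("B", 20.0)):
        for i in range(5):
            name = "N" if (chain == "B" and i == 2) else "CA"
            elem = "N" if name == "N" else "C"
            lines.append(
                _atom_line(serial, name, "GLY", chain, i + 1, 3.8 * i, y, 0.0, elem)
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


_GLY_TEMPLATE = [
    ("N", "N", np.array([0.000, 0.000, 0.000])),
    ("CA", "C", np.array([1.458, 0.000, 0.000])),
    ("C", "C", np.array([2.009, 1.420, 0.000])),
    ("O", "O", np.array([1.251, 2.390, 0.000])),
]


def _glycine_chain(chain: str, n: int, offset: np.ndarray, start_serial: int) -> tuple[list[str], int]:
    lines = []
    serial = start_serial
    for i in range(n):
        shift = offset + np.array([3.8 * i, 0.0, 0.0])
        for name, elem, pos in _GLY_TEMPLATE:
            p = pos + shift
            lines.append(_atom_line(serial, name, "GLY", chain, i + 1, *p, elem))
            serial += 1
    return lines, serial


@pytest.fixture(scope="session")
def single_glycine_pdb_text() -> str:
    lines, _ = _glycine_chain("A", 1, np.zeros(3), 1)
    return "\n".join(lines + ["END"]) + "\n"


@pytest.fixture(scope="session")
def glycine_dimer_pdb_text() -> str:
    """Two 3-residue glycine chains packed against each other."""
    a, serial = _glycine_chain("A", 3, np.zeros(3), 1)
    b, _ = _glycine_chain("B", 3, np.array([0.0, 4.5, 0.0]), serial)
    return "\n".join(a + b + ["END"]) + "\n"


@pytest.fixture(scope="session")
def buried_atom_pdb_text() -> str:
    """A central carbon fully enclosed by an icosahedral shell of carbons."""
    phi = (1 + np.sqrt(5)) / 2
    verts = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            verts += [np.array([0, a, b]), np.array([a, b, 0]), np.array([b, 0, a])]
    verts = [3.0 * v / np.linalg.norm(v) for v in verts]
    lines = [_atom_line(1, "C1", "UNL", "A", 1, 0.0, 0.0, 0.0, "C")]
    for i, v in enumerate(verts):
        lines.append(_atom_line(i + 2, f"C{i + 2}", "UNL", "A", 2, *v, "C"))
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def synthetic_complex():
    """Default synthetic complex: 2 planted regions of 5, 50 decoys."""
    return generate_complex(SyntheticSpec(seed=7))


# Worked-example prediction lists for the DateHub complexes 1A0A and 1E9G:
# hot spots predicted / missed / false before optimization, then the missed
# hot spots recovered or not and the false predictions removed afterwards.
WORKED_EXAMPLES = {
    "1A0A": dict(
        predicted="A16 A19 A49 A52 A53 B16 B29 B52 B53".split(),
        unpredicted="A20 A23 A46 A50 A56 B23 B43 B46 B49 B50".split(),
        false="A22 A43 A47 A57 B13 B19 B22 B28 B42 B47 B54 B57".split(),
        recovered="A23 A46 A50 A56 B49 B50".split(),
        unrecovered="A20 B23 B43 B46".split(),
        false_recovered="A43 A47 B22 B28 B47 B54 B57".split(),
        false_after="A22 A57 B13 B19 B42".split(),
    ),
    "1E9G": dict(
        predicted="A51 A52 A90 A279 A281 B51 B90".split(),
        unpredicted="A84 A87 A178 A181 B52 B84 B87 B178 B181 B279".split(),
        false="A82 A126 A127 A128 A184 A278 B82 B16 B128 B179 B180 B278 B281 B283".split(),
        recovered="A87 A178 A181 B84 B87 B178".split(),
        unrecovered="A84 B52 B181 B279".split(),
        false_recovered="A82 A126 A127 A184 A278 B16 B180 B281 B283".split(),
        false_after="A128 B82 B128 B179 B278".split(),
    ),
}


@pytest.fixture(scope="session")
def worked_examples():
    return WORKED_EXAMPLES
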