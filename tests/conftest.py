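import numpy as np
import pytest


def _atom_line(serial, name, resname, resnum, x, y, z, element):
    return (
        f"ATOM  {serial:5d} {name:<4s}{resname:>4s} A{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
    )


def write_pdb(path, residues):
    """Write a minimal PDB from [(resnum, resname, {atom: (x,y,z)}), ...]."""
    lines = []
    serial = 1
    for resnum, resname, atoms in residues:
        for name, (x, y, z) in atoms.items():
            element = name.strip()[0]
            lines.append(_atom_line(serial, name, resname, resnum, x, y, z, element))
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def two_residue_pdb(tmp_path):
    """Two alanines; residue 2 has N and H placed 1.02 A apart along +z."""
    return write_pdb(
        tmp_path / "pair.pdb",
        [
            (1, "ALA", {"N": (0, 0, 0), "CA": (1.46, 0, 0), "C": (2.0, 1.2, 0)}),
            (2, "ALA", {"N": (3.3, 1.4, 0), "H": (3.3, 1.4, 1.02),
                        "CA": (4.7, 1.8, 0), "C": (5.4, 3.0, 0)}),
        ],
    )


@pytest.fixture
def helix_pdb(tmp_path):
    """Ideal-helix-like 10-residue backbone (N, CA, C only; H reconstructed)."""
    residues = []
    rise, twist = 1.5, np.radians(100.0)
    for i in range(10):
        ang = i * twist
        ca = (2.3 * np.cos(ang), 2.3 * np.sin(ang), rise * i)
        n = (1.5 * np.cos(ang - 0.5), 1.5 * np.sin(ang - 0.5), rise * i - 0.6)
        c = (2.0 * np.cos(ang + 0.6), 2.0 * np.sin(ang + 0.6), rise * i + 0.7)
        residues.append((i + 1, "ALA", {"N": n, "CA": ca, "C": c}))
    return write_pdb(tmp_path / "helix.pdb", residues)
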