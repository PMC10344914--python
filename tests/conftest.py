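"""Shared fixtures: tiny constructed structures and random-cloud builders."""

from __future__ import annotations

import numpy as np
import pytest

from barriereng.structure_io import Atom, LigandPose, Residue, Structure


def fibonacci_shell(n: int, radius: float) -> np.ndarray:
    """Quasi-uniform points on a sphere of the given radius."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return radius * np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)],
        axis=1,
    )


def cloud_structure(points: np.ndarray, element: str = "C",
                    res_name: str = "ALA") -> Structure:
    """One single-atom residue per point."""
    residues = [
        Residue("A", i + 1, res_name, [Atom(element, element, p, i + 1)])
        for i, p in enumerate(points)
    ]
    return Structure(models=[residues])


def single_atom_ligand(position, element: str = "C", seq_id: int = 999) -> LigandPose:
    res = Residue("L", seq_id, "BHT",
                  [Atom(f"{element}1", element, np.asarray(position, float), 1)],
                  is_hetatm=True)
    return LigandPose(residue=res, pose_id=f"BHT:{seq_id}")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    from scipy.stats import special_ortho_group

    return special_ortho_group.rvs(3, random_state=rng)


@pytest.fixture
def toy_pdb(tmp_path):
    """Small hand-written single-model PDB with a protein chain and a ligand."""
    text = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       3.990   2.838   0.123  1.00  0.00           C
ATOM      6  N   SER A   3       5.332   2.736   0.400  1.00  0.00           N
ATOM      7  CA  SER A   3       6.190   3.888   0.623  1.00  0.00           C
ATOM      8  OG  SER A   3       7.490   3.388   0.923  1.00  0.00           O
HETATM    9  C7  BHT L   1       9.000   3.400   1.000  1.00  0.00           C
HETATM   10  C10 BHT L   1      11.500   3.400   1.000  1.00  0.00           C
HETATM   11  O1  BHT L   1       9.500   4.500   1.200  1.00  0.00           O
END
"""
    path = tmp_path / "toy.pdb"
    path.write_text(text)
    return path
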