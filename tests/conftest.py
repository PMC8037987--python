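"""Shared fixtures: tiny PDB text files and synthetic ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from ffentropy.synth import build_backbone, build_ideal_helix

_BACKBONE = ("N", "CA", "C", "O")
_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O"}


def _pdb_atom_line(serial, name, resname, chain, resseq, xyz, element):
    pad_name = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {pad_name}{'':1s}{resname:<3s} {chain}"
        f"{resseq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"  1.00  0.00          {element:>2s}"
    )


def make_pdb_text(
    n_residues=3,
    with_waters=False,
    skip_atoms=(),
    resname="ALA",
):
    """Minimal poly-Ala backbone PDB text built from ideal geometry.

    ``skip_atoms`` is a set of (residue_index, atom_name) pairs to omit,
    for degenerate-input tests.  ``with_waters`` interleaves HOH/ion
    HETATM records that a protein reader must drop.
    """
    phi = np.full(n_residues, -57.0)
    psi = np.full(n_residues, -47.0)
    xyz = build_backbone(phi, psi)
    lines = []
    serial = 1
    k = 0
    for r in range(n_residues):
        for name in _BACKBONE:
            coord = xyz[k]
            k += 1
            if (r, name) in skip_atoms:
                continue
            lines.append(
                _pdb_atom_line(serial, name, resname, "A", r + 1, coord,
                               _ELEMENT[name])
            )
            serial += 1
        if with_waters:
            lines.append(
                "HETATM" + _pdb_atom_line(
                    serial, "O", "HOH", "A", 900 + r,
                    coord + np.array([5.0, 5.0, 5.0]), "O"
                )[6:]
            )
            serial += 1
    if with_waters:
        lines.append(
            "HETATM" + _pdb_atom_line(
                serial, "NA", "NA", "A", 999, np.array([9.0, 9.0, 9.0]), "NA"
            )[6:]
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def tri_ala_pdb(tmp_path):
    path = tmp_path / "tri_ala.pdb"
    path.write_text(make_pdb_text(3))
    return path


@pytest.fixture
def tri_ala_with_waters_pdb(tmp_path):
    path = tmp_path / "tri_ala_wat.pdb"
    path.write_text(make_pdb_text(3, with_waters=True))
    return path


@pytest.fixture
def helix10():
    return build_ideal_helix(10, "alpha")


@pytest.fixture
def helix15():
    return build_ideal_helix(15, "alpha")
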