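"""Core in-memory containers: reference structure and coordinate ensemble.

All coordinates are stored in Angstrom. Residues are indexed 0-based and
contiguously within a model; the original author-assigned residue numbers
are retained as labels for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import ParameterError, SelectionError, TopologyMismatchError

# Masses (Da) for element inference when a file carries none.
_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45, "BR": 79.904,
}

_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


def infer_element(atom_name: str) -> str:
    """Guess the element from a PDB atom name.

    Handles the usual protein ambiguities ("CA" is a carbon, "HG1" a
    hydrogen, "SD" a sulfur); two-letter elements are only accepted when
    they cannot be a remoteness-coded protein atom.
    """
    name = atom_name.strip().upper()
    if not name:
        raise ParameterError("empty atom name")
    if name[0].isdigit():  # e.g. 1HB
        name = name.lstrip("0123456789")
    first = name[0]
    if first in "HCNOSP":
        return first if first != "S" or not name.startswith("SE") else "SE"
    if name[:2] in _ELEMENT_MASSES:
        return name[:2]
    if first in _ELEMENT_MASSES:
        return first
    raise ParameterError(f"cannot infer element for atom name {atom_name!r}")


@dataclass
class StructureModel:
    """A single protein chain: topology plus one set of coordinates.

    Attributes
    ----------
    atom_names : per-atom PDB-style names.
    residue_ids : per-atom residue index, 0-based and contiguous.
    residue_names : per-residue 3-letter codes.
    residue_labels : per-residue original (author) residue numbers.
    coordinates : (n_atoms, 3) array, Angstrom.
    masses : per-atom masses in Da.
    chain_id : chain identifier string.
    elements : per-atom element symbols.
    """

    atom_names: list[str]
    residue_ids: np.ndarray
    residue_names: list[str]
    coordinates: np.ndarray
    masses: np.ndarray
    chain_id: str = "A"
    residue_labels: Optional[list[int]] = None
    elements: Optional[list[str]] = None

    def __post_init__(self):
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n = len(self.atom_names)
        if self.coordinates.shape != (n, 3):
            raise ParameterError(
                f"coordinates shape {self.coordinates.shape} does not match "
                f"{n} atoms"
            )
        if self.residue_ids.shape != (n,) or self.masses.shape != (n,):
            raise ParameterError("per-atom field lengths disagree")
        if not np.all(np.isfinite(self.coordinates)):
            raise ParameterError("non-finite coordinates")
        ids = np.unique(self.residue_ids)
        if len(ids) != len(self.residue_names) or not np.array_equal(
            ids, np.arange(len(ids))
        ):
            raise ParameterError("residue ids must be 0-based and contiguous")
        if self.residue_labels is None:
            self.residue_labels = list(range(1, self.n_residues + 1))
        if self.elements is None:
            self.elements = [infer_element(a) for a in self.atom_names]

    # -- basic shape ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    # -- selections ----------------------------------------------------
    def select(self, selection: str = "ca") -> np.ndarray:
        """Return atom indices for a named selection.

        ``ca`` — alpha carbons; ``backbone`` — N/CA/C/O(/OXT) heavy
        backbone; ``heavy`` — all non-hydrogen atoms; ``all`` — everything.
        """
        sel = selection.lower()
        names = np.array([a.strip().upper() for a in self.atom_names])
        elements = np.array(self.elements)
        if sel == "ca":
            mask = names == "CA"
        elif sel == "backbone":
            mask = np.isin(names, sorted(_BACKBONE_NAMES)) & (elements != "H")
        elif sel == "heavy":
            mask = elements != "H"
        elif sel == "all":
            mask = np.ones(self.n_atoms, dtype=bool)
        else:
            raise SelectionError(f"unknown selection {selection!r}")
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise SelectionError(f"selection {selection!r} matched no atoms")
        return idx

    def atoms_of_residue(self, residue: int) -> np.ndarray:
        return np.flatnonzero(self.residue_ids == residue)

    def atom_index(self, residue: int, atom_name: str) -> Optional[int]:
        """Index of a named atom in a residue, or None if absent."""
        target = atom_name.strip().upper()
        for i in self.atoms_of_residue(residue):
            if self.atom_names[i].strip().upper() == target:
                return int(i)
        return None

    # -- interoperability ----------------------------------------------
    def to_mdtraj_topology(self):
        """Build an mdtraj.Topology mirroring this model."""
        import mdtraj
        from mdtraj.core import element as md_element

        top = mdtraj.Topology()
        chain = top.add_chain()
        res_objs = []
        for r in range(self.n_residues):
            res_objs.append(
                top.add_residue(
                    self.residue_names[r], chain, resSeq=self.residue_labels[r]
                )
            )
        for i, name in enumerate(self.atom_names):
            elem = md_element.get_by_symbol(
                self.elements[i].capitalize()
            )
            top.add_atom(name.strip(), elem, res_objs[self.residue_ids[i]])
        return top


@dataclass
class TrajectoryEnsemble:
    """Ordered coordinate frames sharing a StructureModel topology.

    ``coordinates`` has shape (n_frames, n_atoms, 3), Angstrom.
    ``frame_times`` (ns) is optional and must be strictly increasing.
    """

    coordinates: np.ndarray
    topology: StructureModel
    frame_times: Optional[np.ndarray] = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ParameterError(
                f"expected (n_frames, n_atoms, 3), got {self.coordinates.shape}"
            )
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise TopologyMismatchError(
                self.coordinates.shape[1], self.topology.n_atoms
            )
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.n_frames,):
                raise ParameterError("frame_times length mismatch")
            if np.any(np.diff(self.frame_times) <= 0):
                raise ParameterError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def window(self, start: int, end: int) -> "TrajectoryEnsemble":
        """Frames [start, end) as a new ensemble (times carried along)."""
        if not (0 <= start < end <= self.n_frames):
            raise ParameterError(
                f"window [{start}, {end}) outside trajectory of "
                f"{self.n_frames} frames"
            )
        times = None if self.frame_times is None else self.frame_times[start:end]
        return TrajectoryEnsemble(
            self.coordinates[start:end], self.topology, times
        )


def resolve_window(
    n_frames: int,
    start_frac: float = 0.0,
    end_frac: float = 1.0,
) -> tuple[int, int]:
    """Convert fractional window bounds into a frame range [start, end)."""
    if not (0.0 <= start_frac < end_frac <= 1.0):
        raise ParameterError(
            f"invalid window fractions ({start_frac}, {end_frac})"
        )
    start = int(np.floor(start_frac * n_frames))
    end = int(np.ceil(end_frac * n_frames))
    if end - start < 1:
        raise ParameterError("window contains no frames")
    return start, end
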