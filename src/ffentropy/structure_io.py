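"""Reading reference structures and trajectories; writing tables.

mdtraj does the heavy lifting for the standard formats (PDB in, DCD/XTC
in and out); this module converts between mdtraj's nm-based objects and
the Angstrom-based containers in :mod:`ffentropy.model`, applying the
protein-only / single-chain policy documented on :func:`read_structure`.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import ParseError, SelectionError, TopologyMismatchError
from .model import StructureModel, TrajectoryEnsemble

_NM_TO_ANGSTROM = 10.0


def _load_mdtraj(path, top=None):
    import mdtraj

    try:
        if top is None:
            return mdtraj.load(str(path))
        return mdtraj.load(str(path), top=top)
    except (OSError, IOError) as exc:
        if not os.path.exists(str(path)):
            raise ParseError(f"file not found: {path}") from exc
        raise ParseError(f"could not read {path}: {exc}") from exc


def read_structure(
    path,
    chain: Optional[Union[int, str]] = None,
    model_index: int = 0,
) -> StructureModel:
    """Read one protein chain from a PDB file.

    Only the requested model of a multi-model file is kept (the first by
    default), and only standard protein residues of a single chain:
    waters, ions and other heteroatoms are excluded.  Missing masses are
    filled from the inferred element.

    Parameters
    ----------
    path : PDB file path.
    chain : chain selector; an integer index into the protein chains or
        a chain-identifier letter.  Default: the first protein chain.
    model_index : which model of a multi-model (e.g. NMR) file to keep.

    Raises
    ------
    ParseError : unreadable or malformed file.
    SelectionError : no protein atoms, or the chain selector matches none.
    """
    try:
        traj = _load_mdtraj(path)
    except ParseError:
        raise
    except Exception as exc:  # malformed records inside the file
        raise ParseError(f"could not parse {path}: {exc}") from exc

    top = traj.topology
    protein_chains = [
        ch for ch in top.chains
        if any(res.is_protein for res in ch.residues)
    ]
    if not protein_chains:
        raise SelectionError(f"no protein atoms in {path}")

    if chain is None:
        picked = protein_chains[0]
    elif isinstance(chain, int):
        try:
            picked = protein_chains[chain]
        except IndexError:
            raise SelectionError(
                f"chain index {chain} out of range "
                f"({len(protein_chains)} protein chains)"
            )
    else:
        matches = [
            ch for ch in protein_chains
            if str(getattr(ch, "chain_id", "")) == str(chain)
        ]
        if not matches:
            raise SelectionError(f"no protein chain with id {chain!r}")
        picked = matches[0]

    atoms = [
        a for res in picked.residues if res.is_protein for a in res.atoms
    ]
    if not atoms:
        raise SelectionError(f"chain selection produced no atoms in {path}")

    residues = []
    residue_of_atom = {}
    for a in atoms:
        if a.residue not in residues:
            residues.append(a.residue)
        residue_of_atom[a.index] = residues.index(a.residue)

    if model_index < 0 or model_index >= traj.n_frames:
        raise ParseError(
            f"model {model_index} not present ({traj.n_frames} models)"
        )
    xyz = traj.xyz[model_index] * _NM_TO_ANGSTROM

    atom_indices = [a.index for a in atoms]
    return StructureModel(
        atom_names=[a.name for a in atoms],
        residue_ids=np.array([residue_of_atom[a.index] for a in atoms]),
        residue_names=[r.name for r in residues],
        residue_labels=[int(r.resSeq) for r in residues],
        coordinates=xyz[atom_indices],
        masses=np.array([a.element.mass for a in atoms], dtype=float),
        chain_id=str(getattr(picked, "chain_id", None) or picked.index),
        elements=[a.element.symbol.upper() for a in atoms],
    )


def _trajectory_file_atom_count(path) -> Optional[int]:
    """Atom count stored in a trajectory file, if cheaply determinable."""
    import mdtraj

    try:
        with mdtraj.open(str(path)) as f:
            out = f.read(1)
        xyz = out[0] if isinstance(out, tuple) else out
        return int(np.asarray(xyz).shape[1])
    except Exception:
        return None


def read_trajectory(path, topology: StructureModel) -> TrajectoryEnsemble:
    """Read all frames of a DCD/XTC (or multi-model PDB) trajectory.

    Frames come back in file order with coordinates in Angstrom.  The
    file's atom count must equal the topology's.
    """
    n_file = _trajectory_file_atom_count(path)
    if n_file is not None and n_file != topology.n_atoms:
        raise TopologyMismatchError(n_file, topology.n_atoms)

    md_top = topology.to_mdtraj_topology()
    try:
        traj = _load_mdtraj(path, top=md_top)
    except ParseError:
        raise
    except Exception as exc:
        msg = str(exc)
        if "atoms" in msg and n_file is not None:
            raise TopologyMismatchError(n_file, topology.n_atoms) from exc
        raise ParseError(
            f"could not read trajectory {path} "
            f"(last complete frame unknown): {exc}"
        ) from exc

    times = None
    if traj.time is not None:
        t = np.asarray(traj.time, dtype=float) / 1000.0  # ps -> ns
        if t.size == traj.n_frames and np.all(np.diff(t) > 0):
            times = t
    return TrajectoryEnsemble(
        coordinates=traj.xyz * _NM_TO_ANGSTROM,
        topology=topology,
        frame_times=times,
    )


def write_structure(model: StructureModel, path) -> None:
    """Write a StructureModel as a single-model PDB file."""
    import mdtraj

    traj = mdtraj.Trajectory(
        xyz=model.coordinates[np.newaxis] / _NM_TO_ANGSTROM,
        topology=model.to_mdtraj_topology(),
    )
    traj.save(str(path))


def write_ensemble(ensemble: TrajectoryEnsemble, path) -> None:
    """Write an ensemble to DCD/XTC/PDB, chosen by file extension."""
    import mdtraj

    time = None
    if ensemble.frame_times is not None:
        time = ensemble.frame_times * 1000.0  # ns -> ps
    traj = mdtraj.Trajectory(
        xyz=ensemble.coordinates / _NM_TO_ANGSTROM,
        topology=ensemble.topology.to_mdtraj_topology(),
        time=time,
    )
    traj.save(str(path))


def write_table(rows, path, format: str = "csv") -> None:
    """Write labelled records to CSV or JSON.

    ``rows`` may be a DataFrame or a sequence of dicts sharing one
    schema; an empty sequence yields a header-only file (CSV) or an
    empty list (JSON).
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows:
            schema = set(rows[0].keys())
            for r in rows:
                if set(r.keys()) != schema:
                    raise ParseError("records do not share a schema")
        df = pd.DataFrame(rows)

    fmt = format.lower()
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=2)
    else:
        raise ParseError(f"unknown table format {format!r}")


def read_table(path, format: Optional[str] = None) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    fmt = format or ("json" if str(path).endswith(".json") else "csv")
    if fmt == "csv":
        try:
            return pd.read_csv(path)
        except pd.errors.EmptyDataError:
            return pd.DataFrame()
    with open(path) as fh:
        return pd.DataFrame(json.load(fh))
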