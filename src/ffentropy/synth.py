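"""Synthetic ensembles with known ground truth.

Four generators cover what the analysis layer needs to be testable
without molecular dynamics:

* ideal poly-alanine helices of each type (alpha, pi, 3-10) built by
  internal-coordinate chain extension with canonical dihedrals;
* Gaussian-fluctuation ensembles — independent zero-mean displacements
  of prescribed per-coordinate amplitude about a rigid reference, whose
  RMSF has the closed form sigma*sqrt(3);
* rigid-body ensembles — the reference under random proper rotations
  and bounded translations (all internal observables constant);
* two-state helix/coil dihedral series with prescribed per-residue
  helicity probabilities p_i, designed so the expected classified
  pairwise helicity equals p_i (see ``two_state_dihedral_series``).

Every generator is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import ParameterError
from .helix import DihedralSeries
from .model import StructureModel, TrajectoryEnsemble

# Canonical backbone dihedrals (phi, psi) in degrees per helix type.
CANONICAL_DIHEDRALS = {
    "alpha": (-57.0, -47.0),
    "pi": (-57.0, -70.0),
    "three_ten": (-49.0, -26.0),
}

# Standard backbone geometry: bond lengths (Angstrom) and angles (deg).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA_TRANS = 180.0

_MASS = {"N": 14.007, "C": 12.011, "O": 15.999}

# Two-state generator: coil-state psi range (deg) and per-angle jitter.
# The coil state keeps the helical phi and flips psi into an extended
# region, so the pair sum psi(i)+phi(i+1) classifies helical exactly
# when residue i is helical; 2.5 deg per-angle jitter keeps the jittered
# pair sum inside its +-10 deg window with probability > 0.987.
COIL_PSI_RANGE = (120.0, 180.0)
TWO_STATE_JITTER_DEG = 2.5


def _place_atom(a, b, c, bond_length, bond_angle_deg, torsion_deg):
    """Next-atom position from three predecessors (internal coordinates).

    Places D so that |C-D| = bond_length, angle(B, C, D) = bond_angle
    and torsion(A, B, C, D) = torsion.
    """
    theta = np.radians(bond_angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.column_stack([bc, np.cross(n, bc), n])
    d_local = np.array([
        -bond_length * np.cos(theta),
        bond_length * np.cos(chi) * np.sin(theta),
        bond_length * np.sin(chi) * np.sin(theta),
    ])
    return c + m @ d_local


def build_backbone(
    phi: np.ndarray, psi: np.ndarray, with_oxygen: bool = True
) -> np.ndarray:
    """Poly-peptide backbone coordinates from per-residue (phi, psi).

    ``phi[0]`` is unused (the first residue has no preceding carbonyl);
    omega is fixed trans.  Returns (n_atoms, 3) with atoms ordered
    N, CA, C[, O] per residue.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n_res = len(phi)
    if len(psi) != n_res:
        raise ParameterError("phi and psi lengths differ")

    n_xyz = np.zeros((n_res, 3))
    ca_xyz = np.zeros((n_res, 3))
    c_xyz = np.zeros((n_res, 3))

    n_xyz[0] = (0.0, 0.0, 0.0)
    ca_xyz[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    c_xyz[0] = ca_xyz[0] + BOND_CA_C * np.array(
        [np.cos(ang), np.sin(ang), 0.0]
    )

    for i in range(1, n_res):
        n_xyz[i] = _place_atom(
            n_xyz[i - 1], ca_xyz[i - 1], c_xyz[i - 1],
            BOND_C_N, ANGLE_CA_C_N, psi[i - 1],
        )
        ca_xyz[i] = _place_atom(
            ca_xyz[i - 1], c_xyz[i - 1], n_xyz[i],
            BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS,
        )
        c_xyz[i] = _place_atom(
            c_xyz[i - 1], n_xyz[i], ca_xyz[i],
            BOND_CA_C, ANGLE_N_CA_C, phi[i],
        )

    per_res = [n_xyz, ca_xyz, c_xyz]
    if with_oxygen:
        o_xyz = np.zeros((n_res, 3))
        for i in range(n_res):
            o_xyz[i] = _place_atom(
                n_xyz[i], ca_xyz[i], c_xyz[i],
                BOND_C_O, ANGLE_CA_C_O, psi[i] + 180.0,
            )
        per_res.append(o_xyz)
    return np.stack(per_res, axis=1).reshape(-1, 3)


def build_ideal_helix(n_residues: int, helix_type: str) -> StructureModel:
    """Ideal poly-alanine helix of a canonical type.

    alpha: (phi, psi) = (-57, -47); pi: (-57, -70); three_ten:
    (-49, -26) degrees, trans omega, standard backbone geometry.
    """
    if helix_type not in CANONICAL_DIHEDRALS:
        raise ParameterError(
            f"unknown helix type {helix_type!r}; "
            f"expected one of {sorted(CANONICAL_DIHEDRALS)}"
        )
    if n_residues < 4:
        raise ParameterError(
            f"need at least 4 residues for a helix, got {n_residues}"
        )
    phi_c, psi_c = CANONICAL_DIHEDRALS[helix_type]
    xyz = build_backbone(
        np.full(n_residues, phi_c), np.full(n_residues, psi_c)
    )
    names = ["N", "CA", "C", "O"] * n_residues
    elements = ["N", "C", "C", "O"] * n_residues
    return StructureModel(
        atom_names=names,
        residue_ids=np.repeat(np.arange(n_residues), 4),
        residue_names=["ALA"] * n_residues,
        coordinates=xyz,
        masses=np.array([_MASS[e] for e in elements]),
        chain_id="A",
        elements=elements,
    )


def _sigma_per_atom(
    reference: StructureModel,
    per_atom_sigma: Union[float, np.ndarray],
) -> np.ndarray:
    sigma = np.asarray(per_atom_sigma, dtype=float)
    if sigma.ndim == 0:
        sigma = np.full(reference.n_atoms, float(sigma))
    elif sigma.shape == (reference.n_residues,):
        sigma = sigma[reference.residue_ids]
    elif sigma.shape != (reference.n_atoms,):
        raise ParameterError(
            "per_atom_sigma must be scalar, per-residue or per-atom"
        )
    if np.any(sigma < 0):
        raise ParameterError("sigma must be non-negative")
    return sigma


def gaussian_ensemble(
    reference: StructureModel,
    per_atom_sigma: Union[float, np.ndarray],
    n_frames: int,
    seed: int,
) -> TrajectoryEnsemble:
    """Frames = reference + i.i.d. Gaussian displacements.

    Each coordinate of each atom is displaced independently with
    standard deviation sigma (scalar, per-residue, or per-atom).  The
    frames are drawn in order from one seeded stream, so the first k
    frames do not change when n_frames grows.
    """
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    sigma = _sigma_per_atom(reference, per_atom_sigma)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_frames, reference.n_atoms, 3))
    coords = reference.coordinates[None] + noise * sigma[None, :, None]
    return TrajectoryEnsemble(coords, reference)


def rigid_body_ensemble(
    reference: StructureModel,
    n_frames: int,
    seed: int,
    max_translation: float = 10.0,
) -> TrajectoryEnsemble:
    """Reference under uniform random proper rotations and translations.

    Translations are uniform in [-max_translation, max_translation]^3
    Angstrom.  All internal observables (Rg, aligned RMSD/RMSF) are
    exactly those of the reference.
    """
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    rots = Rotation.random(n_frames, random_state=rng)
    trans = rng.uniform(-max_translation, max_translation, (n_frames, 3))
    centered = reference.coordinates - reference.coordinates.mean(0)
    coords = np.einsum("fij,aj->fai", rots.as_matrix(), centered)
    coords += trans[:, None, :]
    return TrajectoryEnsemble(coords, reference)


def two_state_dihedral_series(
    helicity_probs: Sequence[float],
    helix_type: str = "alpha",
    n_frames: int = 1000,
    seed: int = 0,
    jitter_deg: float = TWO_STATE_JITTER_DEG,
) -> DihedralSeries:
    """Per-residue two-state helix/coil dihedral series.

    In every frame each residue is independently helical with
    probability p_i.  A helical residue carries the canonical (phi,
    psi) of ``helix_type`` plus Gaussian jitter; a coil residue keeps
    the helical phi but flips psi into the extended region
    [120, 180] degrees — a psi-flip helix/coil model.  Because the
    pairwise classifier reads s = psi(i) + phi(i+1) and phi is always
    near canonical, residue i classifies helical essentially iff its
    own state is helical, making the prescribed p_i the exact expected
    helicity of the classified profile.

    The first and last residues are masked undefined, mimicking chain
    termini.
    """
    p = np.asarray(helicity_probs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("helicity probabilities must lie in [0, 1]")
    if helix_type not in CANONICAL_DIHEDRALS:
        raise ParameterError(f"unknown helix type {helix_type!r}")
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    n_res = len(p)
    phi_c, psi_c = CANONICAL_DIHEDRALS[helix_type]

    rng = np.random.default_rng(seed)
    helical = rng.random((n_frames, n_res)) < p[None, :]
    phi = phi_c + jitter_deg * rng.standard_normal((n_frames, n_res))
    psi_helix = psi_c + jitter_deg * rng.standard_normal((n_frames, n_res))
    psi_coil = rng.uniform(*COIL_PSI_RANGE, (n_frames, n_res))
    psi = np.where(helical, psi_helix, psi_coil)

    mask = np.ones((n_frames, n_res), dtype=bool)
    mask[:, 0] = False
    mask[:, -1] = False
    phi = np.where(mask, phi, np.nan)
    psi = np.where(mask, psi, np.nan)
    return DihedralSeries(phi=phi, psi=psi, defined_mask=mask)


@dataclass
class SyntheticEnsembleSpec:
    """Declarative recipe for a synthetic ensemble (reproducible by seed)."""

    kind: str  # gaussian | rigid | helix | two_state_dihedral
    n_residues: int = 15
    n_frames: int = 100
    per_atom_sigma: Union[float, Sequence[float]] = 0.4
    helix_type: str = "alpha"
    helicity_probs: Optional[Sequence[float]] = None
    seed: int = 0

    def realize(self):
        """Materialize the spec.

        Returns a StructureModel (helix), a TrajectoryEnsemble
        (gaussian/rigid, built over an ideal alpha-helix reference), or
        a DihedralSeries (two_state_dihedral).
        """
        if self.kind == "helix":
            return build_ideal_helix(self.n_residues, self.helix_type)
        if self.kind == "gaussian":
            ref = build_ideal_helix(self.n_residues, "alpha")
            return gaussian_ensemble(
                ref, self.per_atom_sigma, self.n_frames, self.seed
            )
        if self.kind == "rigid":
            ref = build_ideal_helix(self.n_residues, "alpha")
            return rigid_body_ensemble(ref, self.n_frames, self.seed)
        if self.kind == "two_state_dihedral":
            probs = self.helicity_probs
            if probs is None:
                probs = np.full(self.n_residues, 0.25)
            return two_state_dihedral_series(
                probs, self.helix_type, self.n_frames, self.seed
            )
        raise ParameterError(f"unknown synthetic kind {self.kind!r}")
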