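"""Backbone dihedrals and residue-resolved helix classification.

Two helicity definitions are implemented:

* the **sequential** alpha criterion — a residue is helical in a frame
  when it belongs to a run of at least three consecutive residues whose
  backbone dihedrals all sit in a broad alpha basin
  (phi in [-160, -30], psi in [-67, -7] degrees);
* the **pairwise** criterion — the sum s = psi(i) + phi(i+1) of a
  residue pair falls in a +-10 degree window around -125 (pi-helix),
  -105 (alpha-helix) or -75 (3-10 helix) degrees.  The label is carried
  by residue i, and the first and last defined pairs of the chain are
  excluded.

The pairwise windows tile [-135, -65] without overlap; the shared
boundary at -115 is assigned to the alpha window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .model import StructureModel, TrajectoryEnsemble

# Pairwise-sum windows, degrees: half-open at the alpha/pi boundary.
PI_WINDOW = (-135.0, -115.0)        # [-135, -115)
ALPHA_WINDOW = (-115.0, -95.0)      # [-115, -95]
THREE_TEN_WINDOW = (-85.0, -65.0)   # [-85, -65]

# Sequential alpha-basin windows, degrees (closed intervals).
SEQ_PHI_WINDOW = (-160.0, -30.0)
SEQ_PSI_WINDOW = (-67.0, -7.0)
SEQ_MIN_RUN = 3

# Integer label codes for the pairwise classifier.
NONE_LABEL = 0
ALPHA = 1
PI = 2
THREE_TEN = 3
LABEL_NAMES = {NONE_LABEL: "none", ALPHA: "alpha", PI: "pi",
               THREE_TEN: "three_ten"}
HELIX_CATEGORIES = ("alpha", "pi", "three_ten")


def wrap_angle(angle):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = ((a + 180.0) % 360.0) - 180.0
    wrapped = np.where(np.isclose(wrapped, -180.0), 180.0, wrapped)
    return wrapped if wrapped.shape else float(wrapped)


def dihedral_angle(p0, p1, p2, p3) -> np.ndarray:
    """Signed torsion angle(s) in degrees for points of shape (..., 3).

    Positive by the right-hand rule looking down the p1->p2 bond
    (the IUPAC convention used for phi/psi).
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - (b0 * b1n).sum(-1, keepdims=True) * b1n
    w = b2 - (b2 * b1n).sum(-1, keepdims=True) * b1n
    x = (v * w).sum(-1)
    y = (np.cross(b1n, v) * w).sum(-1)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


@dataclass
class DihedralSeries:
    """Per-residue, per-frame backbone dihedrals in degrees.

    ``phi`` and ``psi`` have shape (n_frames, n_residues); entries where
    ``defined_mask`` is False (chain termini, missing backbone atoms)
    carry NaN and must be ignored by consumers.
    """

    phi: np.ndarray
    psi: np.ndarray
    defined_mask: np.ndarray
    residue_labels: Optional[Sequence[int]] = None

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.defined_mask = np.asarray(self.defined_mask, dtype=bool)
        if not (self.phi.shape == self.psi.shape == self.defined_mask.shape):
            raise ParameterError("phi/psi/mask shapes disagree")
        if self.phi.ndim != 2:
            raise ParameterError("expected (n_frames, n_residues) arrays")
        if self.residue_labels is None:
            self.residue_labels = list(range(1, self.n_residues + 1))

    @property
    def n_frames(self) -> int:
        return self.phi.shape[0]

    @property
    def n_residues(self) -> int:
        return self.phi.shape[1]


@dataclass
class HelixProfile:
    """Per-residue helical percentages (0-100) under both definitions."""

    sequential_alpha: np.ndarray
    alpha: np.ndarray
    pi: np.ndarray
    three_ten: np.ndarray
    combined: np.ndarray
    n_frames: int
    temperature_label: str = ""
    residue_labels: Optional[Sequence[int]] = None

    def __post_init__(self):
        arrays = [self.sequential_alpha, self.alpha, self.pi,
                  self.three_ten, self.combined]
        n = len(self.alpha)
        for a in arrays:
            a = np.asarray(a, dtype=float)
            if len(a) != n:
                raise ParameterError("profile arrays disagree in length")
            if np.any(a < 0) or np.any(a > 100):
                raise ParameterError("fractions must lie in [0, 100]")
        if self.residue_labels is None:
            self.residue_labels = list(range(1, n + 1))

    @property
    def n_residues(self) -> int:
        return len(self.alpha)

    def category(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "residue": list(self.residue_labels),
            "sequential_alpha_pct": self.sequential_alpha,
            "alpha_pct": self.alpha,
            "pi_pct": self.pi,
            "three_ten_pct": self.three_ten,
            "combined_pct": self.combined,
        })


# ----------------------------------------------------------------------
# Dihedral extraction
# ----------------------------------------------------------------------

def backbone_dihedrals(traj: TrajectoryEnsemble) -> DihedralSeries:
    """phi/psi series for every residue of a trajectory.

    phi(i) is the C(i-1)-N(i)-CA(i)-C(i) torsion, psi(i) the
    N(i)-CA(i)-C(i)-N(i+1) torsion.  Terminal residues and residues
    missing any required backbone atom are masked undefined (a residue
    needs both phi and psi to count as defined).
    """
    top = traj.topology
    n_res = top.n_residues
    n_idx = [top.atom_index(r, "N") for r in range(n_res)]
    ca_idx = [top.atom_index(r, "CA") for r in range(n_res)]
    c_idx = [top.atom_index(r, "C") for r in range(n_res)]

    n_frames = traj.n_frames
    phi = np.full((n_frames, n_res), np.nan)
    psi = np.full((n_frames, n_res), np.nan)
    xyz = traj.coordinates

    for i in range(n_res):
        if i > 0 and None not in (c_idx[i - 1], n_idx[i], ca_idx[i], c_idx[i]):
            phi[:, i] = dihedral_angle(
                xyz[:, c_idx[i - 1]], xyz[:, n_idx[i]],
                xyz[:, ca_idx[i]], xyz[:, c_idx[i]],
            )
        if i < n_res - 1 and None not in (
            n_idx[i], ca_idx[i], c_idx[i], n_idx[i + 1]
        ):
            psi[:, i] = dihedral_angle(
                xyz[:, n_idx[i]], xyz[:, ca_idx[i]],
                xyz[:, c_idx[i]], xyz[:, n_idx[i + 1]],
            )

    mask = np.isfinite(phi) & np.isfinite(psi)
    return DihedralSeries(phi=phi, psi=psi, defined_mask=mask,
                          residue_labels=list(top.residue_labels))


# ----------------------------------------------------------------------
# Classification
# ----------------------------------------------------------------------

def classify_sequential_alpha(dihedrals: DihedralSeries) -> np.ndarray:
    """Boolean (n_frames, n_residues): in a run of >= 3 alpha-basin residues.

    A residue is in the basin when phi in [-160, -30] and psi in
    [-67, -7]; undefined residues break runs.
    """
    phi, psi, mask = dihedrals.phi, dihedrals.psi, dihedrals.defined_mask
    with np.errstate(invalid="ignore"):
        in_basin = (
            mask
            & (phi >= SEQ_PHI_WINDOW[0]) & (phi <= SEQ_PHI_WINDOW[1])
            & (psi >= SEQ_PSI_WINDOW[0]) & (psi <= SEQ_PSI_WINDOW[1])
        )
    n_res = dihedrals.n_residues
    if n_res < SEQ_MIN_RUN:
        return np.zeros_like(in_basin)
    # residue i is helical iff some window of SEQ_MIN_RUN consecutive
    # in-basin residues contains it
    run_start = in_basin[:, : n_res - SEQ_MIN_RUN + 1].copy()
    for k in range(1, SEQ_MIN_RUN):
        run_start &= in_basin[:, k: n_res - SEQ_MIN_RUN + 1 + k]
    helical = np.zeros_like(in_basin)
    for k in range(SEQ_MIN_RUN):
        helical[:, k: n_res - SEQ_MIN_RUN + 1 + k] |= run_start
    return helical


def classify_pairwise_helix(dihedrals: DihedralSeries) -> np.ndarray:
    """Integer labels (n_frames, n_residues) from the pair-sum windows.

    For each defined pair (i, i+1), s = psi(i) + phi(i+1) wrapped to
    (-180, 180]; residue i is labelled PI for s in [-135, -115), ALPHA
    for s in [-115, -95], THREE_TEN for s in [-85, -65], else NONE.  In
    every frame the first and last defined pairs are excluded.
    """
    if dihedrals.n_residues < 4:
        raise ParameterError(
            "pairwise classification needs at least 4 residues"
        )
    psi_i = dihedrals.psi[:, :-1]
    phi_next = dihedrals.phi[:, 1:]
    pair_ok = np.isfinite(psi_i) & np.isfinite(phi_next)

    labels = np.zeros(dihedrals.phi.shape, dtype=int)
    with np.errstate(invalid="ignore"):
        s = wrap_angle(psi_i + phi_next)
        pair_label = np.zeros(s.shape, dtype=int)
        pair_label[pair_ok & (s >= PI_WINDOW[0]) & (s < PI_WINDOW[1])] = PI
        pair_label[
            pair_ok & (s >= ALPHA_WINDOW[0]) & (s <= ALPHA_WINDOW[1])
        ] = ALPHA
        pair_label[
            pair_ok & (s >= THREE_TEN_WINDOW[0]) & (s <= THREE_TEN_WINDOW[1])
        ] = THREE_TEN

    # exclude the first and last defined pair, frame by frame
    any_pair = pair_ok.any(axis=1)
    first = np.argmax(pair_ok, axis=1)
    last = pair_ok.shape[1] - 1 - np.argmax(pair_ok[:, ::-1], axis=1)
    rows = np.flatnonzero(any_pair)
    pair_label[rows, first[rows]] = NONE_LABEL
    pair_label[rows, last[rows]] = NONE_LABEL

    labels[:, :-1] = pair_label
    return labels


def helical_fraction_profile(
    pairwise_labels: np.ndarray,
    sequential_flags: Optional[np.ndarray] = None,
    temperature_label: str = "",
    residue_labels: Optional[Sequence[int]] = None,
) -> HelixProfile:
    """Per-residue helical percentages over the frames of a label matrix.

    ``combined`` is the percentage of frames in which the residue
    carries any pairwise helix label (the windows are disjoint, so this
    equals the sum of the three per-type percentages).
    """
    labels = np.asarray(pairwise_labels)
    if labels.ndim != 2:
        raise ParameterError("expected (n_frames, n_residues) labels")
    n_frames = labels.shape[0]
    if n_frames < 1:
        raise ParameterError("need at least one frame")
    pct = lambda m: 100.0 * m.mean(axis=0)
    if sequential_flags is None:
        seq = np.zeros(labels.shape[1])
    else:
        sequential_flags = np.asarray(sequential_flags)
        if sequential_flags.shape != labels.shape:
            raise ParameterError("sequential flags shape mismatch")
        seq = pct(sequential_flags)
    return HelixProfile(
        sequential_alpha=seq,
        alpha=pct(labels == ALPHA),
        pi=pct(labels == PI),
        three_ten=pct(labels == THREE_TEN),
        combined=pct(labels != NONE_LABEL),
        n_frames=n_frames,
        temperature_label=temperature_label,
        residue_labels=residue_labels,
    )


def compare_temperatures(
    profile_a: HelixProfile, profile_b: HelixProfile
) -> pd.DataFrame:
    """Per-residue helicity differences (a - b) between two conditions.

    Returns one row per residue with the difference for every category;
    ``summary_mean_abs_change`` is attached in ``DataFrame.attrs``.
    """
    if profile_a.n_residues != profile_b.n_residues:
        raise ParameterError(
            f"residue counts differ: {profile_a.n_residues} vs "
            f"{profile_b.n_residues}"
        )
    cats = ("sequential_alpha",) + HELIX_CATEGORIES + ("combined",)
    data = {"residue": list(profile_a.residue_labels)}
    summary = {}
    for c in cats:
        diff = profile_a.category(c) - profile_b.category(c)
        data[f"d_{c}_pct"] = diff
        summary[c] = float(np.abs(diff).mean())
    df = pd.DataFrame(data)
    df.attrs["summary_mean_abs_change"] = summary
    df.attrs["labels"] = (
        profile_a.temperature_label, profile_b.temperature_label
    )
    return df
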