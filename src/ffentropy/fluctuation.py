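"""Structural-fluctuation metrics: RMSD, RMSF, Rg, block averaging.

The observables here quantify how far a simulated ensemble strays from
a reference structure (RMSD after optimal superposition), how much each
residue fluctuates about the ensemble mean (RMSF), and how compact each
frame is (radius of gyration).  Block averaging turns the correlated
per-frame series into a mean with a defensible standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateGeometryError,
    InsufficientDataError,
    ParameterError,
    SelectionError,
)
from .model import StructureModel, TrajectoryEnsemble, resolve_window


@dataclass
class TimeSeries:
    """A per-frame scalar observable (Angstrom for RMSD/Rg)."""

    values: np.ndarray
    frame_times: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ParameterError("TimeSeries values must be 1-D")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def to_table(self) -> pd.DataFrame:
        data = {"frame": np.arange(len(self.values)), self.label or "value":
                self.values}
        if self.frame_times is not None:
            data["time_ns"] = self.frame_times
        return pd.DataFrame(data)


@dataclass
class FluctuationProfile:
    """Per-residue RMSF (Angstrom) over a stated frame window."""

    rmsf: np.ndarray
    residue_labels: Sequence[int]
    window: tuple[int, int]

    def __post_init__(self):
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if np.any(self.rmsf < 0):
            raise ParameterError("RMSF values must be non-negative")
        if len(self.rmsf) != len(self.residue_labels):
            raise ParameterError("rmsf / residue_labels length mismatch")

    @property
    def n_residues(self) -> int:
        return len(self.rmsf)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue": list(self.residue_labels), "rmsf_A": self.rmsf}
        )


@dataclass
class BlockStats:
    """Mean and block-averaging standard error of a time series."""

    mean: float
    standard_error: float
    block_length: int
    n_blocks: int

    def __post_init__(self):
        if self.n_blocks < 2:
            raise ParameterError("block statistics need at least 2 blocks")
        if self.standard_error < 0:
            raise ParameterError("standard error must be non-negative")


@dataclass
class DensityEstimate:
    """Histogram probability density: sum(density) * bin_width == 1."""

    bin_centers: np.ndarray
    density: np.ndarray
    bin_width: float

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_center": self.bin_centers, "density": self.density}
        )


# ----------------------------------------------------------------------
# Optimal superposition
# ----------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the weighted RMSD to
    ``reference``.  The rotation is always proper (det +1): reflections
    are excluded, so a structure is never matched to its mirror image.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 points, or a configuration of rank < 2 (all points
        collinear), for which the optimal rotation is not unique.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or \
            mobile.shape[1] != 3:
        raise ParameterError(
            f"point sets must share shape (n, 3); got {mobile.shape} and "
            f"{reference.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need at least 3 points, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ParameterError("weights must be non-negative, not all zero")
    wsum = w.sum()

    mob_c = mobile - (w[:, None] * mobile).sum(0) / wsum
    ref_c = reference - (w[:, None] * reference).sum(0) / wsum

    h = (w[:, None] * mob_c).T @ ref_c
    u, s, vt = np.linalg.svd(h)
    # rank < 2 (coincident or collinear points) leaves a free rotation axis
    if s[0] <= 0 or s[1] <= 1e-9 * s[0]:
        raise DegenerateGeometryError(
            "point configuration is (near-)collinear; rotation not unique"
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        d = 1.0
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    ref_centroid = (w[:, None] * reference).sum(0) / wsum
    mob_centroid = (w[:, None] * mobile).sum(0) / wsum
    trans = ref_centroid - rot @ mob_centroid

    moved = mobile @ rot.T + trans
    rmsd = float(
        np.sqrt((w * ((moved - reference) ** 2).sum(1)).sum() / wsum)
    )
    return rot, trans, rmsd


def _superposed_rmsd_batch(
    frames: np.ndarray, reference: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> np.ndarray:
    """RMSD of each frame to the reference after superposition."""
    return np.array(
        [kabsch_superpose(f, reference, weights)[2] for f in frames]
    )


# ----------------------------------------------------------------------
# Series metrics
# ----------------------------------------------------------------------

def rmsd_series(
    traj: TrajectoryEnsemble,
    reference: Union[StructureModel, np.ndarray, None] = None,
    selection: str = "ca",
) -> TimeSeries:
    """Per-frame RMSD to a reference after optimal superposition.

    The superposition and the RMSD both use the named atom selection
    (default alpha carbons).  ``reference`` defaults to the trajectory's
    own topology coordinates (the starting structure).
    """
    if reference is None:
        reference = traj.topology
    idx = traj.topology.select(selection)
    if isinstance(reference, StructureModel):
        ref_xyz = reference.coordinates[reference.select(selection)]
    else:
        ref_xyz = np.asarray(reference, dtype=float)
        if ref_xyz.shape[0] == traj.n_atoms:
            ref_xyz = ref_xyz[idx]
    if ref_xyz.shape != (idx.size, 3):
        raise SelectionError(
            "selection sizes differ between trajectory and reference"
        )
    values = _superposed_rmsd_batch(traj.coordinates[:, idx], ref_xyz)
    return TimeSeries(values, traj.frame_times, label="rmsd_A")


def rmsf_per_residue(
    traj: TrajectoryEnsemble,
    selection: str = "ca",
    window: Optional[tuple[int, int]] = None,
    align: bool = True,
) -> FluctuationProfile:
    """Per-residue RMSF about the time-mean structure over a window.

    Each frame is (optionally) superposed onto the window-mean structure
    of the selection — one iteration: mean of the raw frames defines the
    alignment target, frames are superposed, and the mean of the aligned
    frames is the fluctuation reference.  RMSF(residue) is the square
    root of the time-averaged squared displacement of the residue's
    selected atoms from their mean positions.
    """
    start, end = window if window is not None else (0, traj.n_frames)
    if not (0 <= start < end <= traj.n_frames):
        raise ParameterError(
            f"window [{start}, {end}) outside trajectory of "
            f"{traj.n_frames} frames"
        )
    if end - start < 2:
        raise InsufficientDataError("RMSF needs at least 2 frames")

    idx = traj.topology.select(selection)
    frames = traj.coordinates[start:end, idx, :]

    if align:
        target = frames.mean(axis=0)
        aligned = np.empty_like(frames)
        for k, f in enumerate(frames):
            rot, trans, _ = kabsch_superpose(f, target)
            aligned[k] = f @ rot.T + trans
        frames = aligned

    mean_xyz = frames.mean(axis=0)
    sq_disp = ((frames - mean_xyz) ** 2).sum(axis=2)  # (frames, atoms)
    msd_per_atom = sq_disp.mean(axis=0)

    res_of_sel = traj.topology.residue_ids[idx]
    residues = np.unique(res_of_sel)
    rmsf = np.array([
        np.sqrt(msd_per_atom[res_of_sel == r].mean()) for r in residues
    ])
    labels = [traj.topology.residue_labels[r] for r in residues]
    return FluctuationProfile(rmsf=rmsf, residue_labels=labels,
                              window=(start, end))


def radius_of_gyration_series(
    traj: TrajectoryEnsemble,
    mass_weighted: bool = True,
    selection: str = "heavy",
) -> TimeSeries:
    """Per-frame radius of gyration of the selected atoms.

    Rg = sqrt( sum_i w_i |r_i - rbar|^2 / sum_i w_i ), with w_i the
    atomic masses when ``mass_weighted`` (the default) else 1 and rbar
    the weighted centroid.
    """
    if traj.n_frames < 1:
        raise InsufficientDataError("empty trajectory")
    idx = traj.topology.select(selection)
    xyz = traj.coordinates[:, idx, :]
    w = traj.topology.masses[idx] if mass_weighted else np.ones(idx.size)
    wsum = w.sum()
    center = (w[None, :, None] * xyz).sum(axis=1) / wsum
    sq = ((xyz - center[:, None, :]) ** 2).sum(axis=2)
    rg = np.sqrt((w[None, :] * sq).sum(axis=1) / wsum)
    return TimeSeries(rg, traj.frame_times, label="rg_A")


def block_average(
    series: Union[TimeSeries, np.ndarray],
    block_length: int,
    window: Optional[tuple[int, int]] = None,
) -> BlockStats:
    """Block-averaged mean and standard error of a time series.

    The window is split into contiguous blocks of ``block_length``
    frames; a trailing partial block is discarded.  The mean is the mean
    of block means and the standard error is their sample standard
    deviation divided by sqrt(n_blocks).
    """
    values = series.values if isinstance(series, TimeSeries) else \
        np.asarray(series, dtype=float)
    if block_length < 1:
        raise ParameterError("block_length must be >= 1")
    start, end = window if window is not None else (0, len(values))
    if not (0 <= start < end <= len(values)):
        raise ParameterError(f"window [{start}, {end}) outside series")
    used = values[start:end]
    n_blocks = len(used) // block_length
    if n_blocks < 2:
        raise InsufficientDataError(
            f"window of {len(used)} frames holds {n_blocks} complete "
            f"block(s) of {block_length}; need >= 2"
        )
    trimmed = used[: n_blocks * block_length]
    block_means = trimmed.reshape(n_blocks, block_length).mean(axis=1)
    se = float(block_means.std(ddof=1) / np.sqrt(n_blocks))
    return BlockStats(
        mean=float(block_means.mean()),
        standard_error=se,
        block_length=block_length,
        n_blocks=n_blocks,
    )


def distribution_estimate(
    series: Union[TimeSeries, np.ndarray],
    bin_width: float,
) -> DensityEstimate:
    """Histogram probability-density estimate with fixed bin width.

    Bin edges start at the sample minimum; the density is normalized so
    that sum(density) * bin_width == 1.
    """
    values = series.values if isinstance(series, TimeSeries) else \
        np.asarray(series, dtype=float)
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    if len(values) < 2:
        raise InsufficientDataError("need at least 2 values")
    lo, hi = float(values.min()), float(values.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    if edges[-1] <= hi:  # make the top edge inclusive of the max
        edges = np.append(edges, edges[-1] + bin_width)
        n_bins += 1
    counts, _ = np.histogram(values, bins=edges)
    density = counts / (counts.sum() * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityEstimate(bin_centers=centers, density=density,
                           bin_width=bin_width)
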