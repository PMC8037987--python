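"""Configurational-entropy indicators derived from fluctuation metrics.

Three families of indicators are produced:

* **Lindemann values** dL = <RMSF>/a — the melting criterion for solids
  carried over to proteins with ``a`` an average nonbonded distance
  (default 4.375 Angstrom).  Folded globular proteins in water sit near
  dL ~ 0.15-0.16 at room temperature; an interior core is solid-like
  (smaller dL) while the surface is fluid (larger dL).
* **Similarity thresholds** D0,sim / D0,dis — empirical chain-length-
  dependent RMSD levels below which an ensemble still represents the
  reference fold and at/above which it is as different as a mirror
  image.
* **Polymer-scaling Rg references** — a compact-globule scaling law
  Rg = prefactor * n^exponent to compare simulated compactness against,
  alongside the reference-structure Rg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np

from .exceptions import ParameterError, SelectionError
from .fluctuation import FluctuationProfile
from .published import (
    LINDEMANN_A,
    TSR4_D0_DIS,
    TSR4_D0_SIM,
    TSR4_N_RESIDUES,
)

# D0 thresholds follow compact-globule size scaling (exponent 1/3) with
# prefactors calibrated so the thresholds at the 55-residue TSR4 chain
# equal the published anchors 1.34 / 4.49 Angstrom.
D0_EXPONENT = 1.0 / 3.0
D0_SIM_PREFACTOR = TSR4_D0_SIM / TSR4_N_RESIDUES ** D0_EXPONENT
D0_DIS_PREFACTOR = TSR4_D0_DIS / TSR4_N_RESIDUES ** D0_EXPONENT

# Default compact-globule (poor-solvent) Rg scaling-law parameters.
RG_SCALING_PREFACTOR = 3.0   # Angstrom
RG_SCALING_EXPONENT = 1.0 / 3.0

SIMILAR = "similar"
INTERMEDIATE = "intermediate"
DISSIMILAR = "dissimilar"


@dataclass
class LindemannResult:
    """Lindemann values over all residues and a core/surface split."""

    delta_total: float
    delta_core: float
    delta_surf: float
    a: float
    core_residues: frozenset

    def __post_init__(self):
        for v in (self.delta_total, self.delta_core, self.delta_surf):
            if v < 0:
                raise ParameterError("Lindemann values must be >= 0")


@dataclass
class SimilarityThresholds:
    """Chain-length-dependent RMSD similarity/dissimilarity thresholds."""

    n: int
    d0_sim: float
    d0_dis: float
    below_fit_range: bool = False

    def __post_init__(self):
        if not (0 < self.d0_sim < self.d0_dis):
            raise ParameterError("require 0 < d0_sim < d0_dis")


@dataclass
class RgReference:
    """Reference-structure Rg next to a polymer-scaling-law estimate."""

    n: int
    rg_pdb: float
    rg_scaling: float
    prefactor: float
    exponent: float

    def __post_init__(self):
        if self.rg_scaling <= 0:
            raise ParameterError("rg_scaling must be positive")


def lindemann_value(
    profile: FluctuationProfile,
    a: float = LINDEMANN_A,
    residues: Optional[Iterable[int]] = None,
) -> float:
    """Lindemann value dL = <RMSF>/a over a residue subset.

    ``residues`` are 0-based indices into the profile; the default is
    all residues.  The mean RMSF over the subset is divided by ``a``.
    """
    if a <= 0:
        raise ParameterError(f"a must be positive, got {a}")
    if residues is None:
        idx = np.arange(profile.n_residues)
    else:
        idx = np.asarray(sorted(set(int(r) for r in residues)), dtype=int)
        if idx.size == 0:
            raise SelectionError("empty residue set")
        if idx.min() < 0 or idx.max() >= profile.n_residues:
            raise SelectionError(
                f"residue indices outside profile of {profile.n_residues}"
            )
    return float(profile.rmsf[idx].mean() / a)


def lindemann_partition(
    profile: FluctuationProfile,
    core_residues: Iterable[int],
    a: float = LINDEMANN_A,
) -> LindemannResult:
    """Total, core and surface Lindemann values for a core/surface split.

    ``core_residues`` (0-based profile indices) defines the structural
    core; the surface is its complement.  The core must be a proper
    subset so the surface is non-empty.
    """
    core = frozenset(int(r) for r in core_residues)
    if not core:
        raise SelectionError("core residue set is empty")
    all_res = frozenset(range(profile.n_residues))
    if not core <= all_res:
        raise SelectionError("core residues outside the profile")
    surf = all_res - core
    if not surf:
        raise SelectionError(
            "core equals the full residue set; surface would be empty"
        )
    return LindemannResult(
        delta_total=lindemann_value(profile, a),
        delta_core=lindemann_value(profile, a, core),
        delta_surf=lindemann_value(profile, a, surf),
        a=a,
        core_residues=core,
    )


def maiorov_crippen_thresholds(n: int) -> SimilarityThresholds:
    """Empirical similarity/dissimilarity RMSD thresholds at chain length n.

    Both thresholds grow as n^(1/3); the prefactors are calibrated to the
    published TSR4-domain anchors (1.34 and 4.49 Angstrom at 55 residues).
    The empirical fits were built from globular proteins of >= 20
    residues; smaller n produces a result flagged ``below_fit_range``.
    """
    if n < 1:
        raise ParameterError("chain length must be positive")
    below = n < 20
    if below:
        warnings.warn(
            f"chain length {n} is below the empirical fit range (>= 20); "
            "thresholds are an extrapolation",
            stacklevel=2,
        )
    return SimilarityThresholds(
        n=int(n),
        d0_sim=D0_SIM_PREFACTOR * n ** D0_EXPONENT,
        d0_dis=D0_DIS_PREFACTOR * n ** D0_EXPONENT,
        below_fit_range=below,
    )


def similarity_verdict(
    mean_rmsd: float, thresholds: SimilarityThresholds
) -> str:
    """Classify a mean RMSD against the similarity thresholds.

    ``similar`` for rmsd <= d0_sim (an ensemble still representing the
    reference fold), ``dissimilar`` for rmsd >= d0_dis (as different as
    a mirror image), ``intermediate`` in between.  Both boundaries are
    inclusive toward their verdict.
    """
    if mean_rmsd < 0:
        raise ParameterError("mean_rmsd must be >= 0")
    if mean_rmsd <= thresholds.d0_sim:
        return SIMILAR
    if mean_rmsd >= thresholds.d0_dis:
        return DISSIMILAR
    return INTERMEDIATE


def polymer_rg_reference(
    n: int,
    prefactor: float = RG_SCALING_PREFACTOR,
    exponent: float = RG_SCALING_EXPONENT,
    rg_pdb: float = float("nan"),
) -> RgReference:
    """Package the scaling-law Rg reference next to the structure's Rg.

    rg_scaling = prefactor * n ** exponent (Angstrom).  The default
    parameters describe compact globules in poor solvent.
    """
    if prefactor <= 0:
        raise ParameterError("prefactor must be positive")
    if not (0 < exponent < 1):
        raise ParameterError("exponent must lie in (0, 1)")
    if n < 1:
        raise ParameterError("chain length must be positive")
    return RgReference(
        n=int(n),
        rg_pdb=float(rg_pdb),
        rg_scaling=float(prefactor * n ** exponent),
        prefactor=prefactor,
        exponent=exponent,
    )


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (table-reproduction convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def aggregate_over_systems(values: Sequence[float]) -> tuple[float, float]:
    """Mean over per-system scalars plus its 2-d.p. table rounding."""
    vals = [float(v) for v in values]
    if not vals:
        raise ParameterError("no values to aggregate")
    mean = float(np.mean(vals))
    return mean, round_half_away(mean, 2)
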