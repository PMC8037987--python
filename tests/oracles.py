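"""Independent brute-force oracles used to validate the main code paths.

These deliberately avoid the library's own algorithms: the rigid
superposition oracle minimizes RMSD over rotations parameterized by a
progressively refined quaternion grid (no SVD), and the direct-sum
helpers recompute simple observables by naive summation.
"""

from __future__ import annotations

import numpy as np


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrices for unit quaternions of shape (m, 4) (w,x,y,z)."""
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    return np.stack([
        np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - z * w),
                  2 * (x * z + y * w)], -1),
        np.stack([2 * (x * y + z * w), 1 - 2 * (x * x + z * z),
                  2 * (y * z - x * w)], -1),
        np.stack([2 * (x * z - y * w), 2 * (y * z + x * w),
                  1 - 2 * (x * x + y * y)], -1),
    ], axis=1)


def _batch_rmsd(rots, mob_c, ref_c, w):
    moved = np.einsum("mij,aj->mai", rots, mob_c)
    d2 = ((moved - ref_c[None]) ** 2).sum(-1)
    return np.sqrt((d2 * w[None]).sum(-1) / w.sum())


def quaternion_grid_min_rmsd(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
    seed: int = 12345,
    coarse: int = 8000,
    refine: int = 1500,
    levels: int = 12,
) -> float:
    """Minimum weighted RMSD over proper rotations by grid refinement.

    Centers both point sets on their (weighted) centroids — the optimal
    translation — then searches unit quaternions: a coarse random cover
    of rotation space followed by progressively narrower perturbation
    grids around the incumbent best.  The final angular resolution is
    far below the requested 1e-6 Angstrom RMSD agreement.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    n = mobile.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    mob_c = mobile - (w[:, None] * mobile).sum(0) / w.sum()
    ref_c = reference - (w[:, None] * reference).sum(0) / w.sum()

    rng = np.random.default_rng(seed)
    q = rng.standard_normal((coarse, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    q = np.vstack([q, [[1.0, 0.0, 0.0, 0.0]]])
    rmsds = _batch_rmsd(_quat_to_matrix(q), mob_c, ref_c, w)
    best_q = q[np.argmin(rmsds)]
    best = rmsds.min()

    width = np.pi
    for _ in range(levels):
        width *= 0.25
        axes = rng.standard_normal((refine, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        angles = rng.uniform(0.0, width, refine)
        dq = np.concatenate(
            [np.cos(angles / 2)[:, None],
             np.sin(angles / 2)[:, None] * axes], axis=1
        )
        # quaternion product dq * best_q
        w0, x0, y0, z0 = dq.T
        w1, x1, y1, z1 = best_q
        cand = np.stack([
            w0 * w1 - x0 * x1 - y0 * y1 - z0 * z1,
            w0 * x1 + x0 * w1 + y0 * z1 - z0 * y1,
            w0 * y1 - x0 * z1 + y0 * w1 + z0 * x1,
            w0 * z1 + x0 * y1 - y0 * x1 + z0 * w1,
        ], axis=1)
        cand = np.vstack([cand, best_q[None]])
        rmsds = _batch_rmsd(_quat_to_matrix(cand), mob_c, ref_c, w)
        k = np.argmin(rmsds)
        best_q = cand[k]
        best = min(best, rmsds[k])
    return float(best)


def direct_rg(xyz: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Radius of gyration by naive summation."""
    xyz = np.asarray(xyz, float)
    m = np.ones(len(xyz)) if masses is None else np.asarray(masses, float)
    center = (m[:, None] * xyz).sum(0) / m.sum()
    return float(np.sqrt((m * ((xyz - center) ** 2).sum(1)).sum() / m.sum()))
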