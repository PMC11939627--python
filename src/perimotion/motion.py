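"""Point trajectories, inter-phase displacements and EAT-pericardium
nearest-point correspondence.

A trajectory transports reference-phase points through the phase-to-reference
mappings, one position per cardiac phase. Inter-phase displacement at phase
``k > 0`` is ``P(t_k) - P(t_{k-1})``; at ``k = 0`` it closes the cardiac
cycle with ``P(t_0) - P(t_8)``, so the displacements of one point telescope
to exactly zero over a full cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .errors import EmptyRegionError, PairingError
from .io import N_PHASES, world_to_voxel

logger = logging.getLogger(__name__)

_TIE_EPS = 1e-9  # mm; distances closer than this are treated as tied


@dataclass
class Trajectory:
    """Per-point positions over the nine phases.

    ``positions`` has shape ``(9, n_points, 3)`` in world mm; point identity
    (the second axis) is stable across phases.
    """

    positions: np.ndarray
    tissue: str
    delta_t: float = 1.0 / N_PHASES

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[0] != N_PHASES or self.positions.shape[2] != 3:
            raise ValueError(f"positions must have shape (9, n, 3), got {self.positions.shape}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("trajectory positions must be finite")

    @property
    def n_points(self) -> int:
        return self.positions.shape[1]


@dataclass
class Correspondence:
    """Nearest-pericardial-point assignment for every EAT point.

    ``peri_index[p]`` is the pericardial point id paired with EAT point
    ``p``; ``distance[p]`` the Euclidean pair distance in mm.
    """

    peri_index: np.ndarray
    distance: np.ndarray


def sample_field_at_points(
    field_mm: np.ndarray, affine: np.ndarray, points_mm: np.ndarray
) -> np.ndarray:
    """Trilinearly sample a (nx, ny, nz, 3) mm vector field at world points.

    Points outside the grid take the nearest-edge value (flagged in the log).
    """
    vox = world_to_voxel(points_mm, affine)
    upper = np.asarray(field_mm.shape[:3]) - 1
    outside = np.any((vox < 0) | (vox > upper), axis=1)
    if outside.any():
        logger.warning(
            "%d/%d points fall outside the field domain; nearest-edge values used",
            int(outside.sum()), len(vox),
        )
    coords = vox.T
    out = np.empty((len(vox), 3))
    for c in range(3):
        out[:, c] = map_coordinates(field_mm[..., c], coords, order=1, mode="nearest")
    return out


def build_trajectories(fields, points_ref: np.ndarray, tissue: str) -> Trajectory:
    """Transport reference-phase points through the per-phase mappings.

    ``fields`` is the list of nine :class:`~perimotion.registration.DisplacementField`
    objects (reference-to-phase direction); position at phase ``k`` is
    ``x + u_k(x)`` for each reference point ``x``.
    """
    points_ref = np.atleast_2d(np.asarray(points_ref, dtype=float))
    if len(points_ref) == 0:
        raise EmptyRegionError(f"no {tissue} points to track")
    if len(fields) != N_PHASES:
        raise ValueError(f"expected {N_PHASES} displacement fields, got {len(fields)}")
    positions = np.empty((N_PHASES, len(points_ref), 3))
    for k, fld in enumerate(fields):
        positions[k] = points_ref + sample_field_at_points(fld.vectors, fld.affine, points_ref)
    return Trajectory(positions=positions, tissue=tissue)


def displacement_at(traj: Trajectory, k: int) -> np.ndarray:
    """Inter-phase displacement vectors (mm) at phase index ``k``.

    ``k > 0`` returns ``P(t_k) - P(t_{k-1})``; ``k = 0`` returns the cyclic
    closure ``P(t_0) - P(t_8)``.
    """
    if not 0 <= k < N_PHASES:
        raise ValueError(f"phase index must be in 0..{N_PHASES - 1}, got {k}")
    if k == 0:
        return traj.positions[0] - traj.positions[N_PHASES - 1]
    return traj.positions[k] - traj.positions[k - 1]


def correspond(eat_points: np.ndarray, peri_points: np.ndarray) -> Correspondence:
    """Map every EAT point to its exact Euclidean nearest pericardial point.

    Distances are resolved through a KD-tree but the result is identical to
    exhaustive search; exact ties go to the smallest pericardial point id.
    """
    eat_points = np.atleast_2d(np.asarray(eat_points, dtype=float))
    peri_points = np.atleast_2d(np.asarray(peri_points, dtype=float))
    if len(eat_points) == 0:
        raise EmptyRegionError("empty EAT point set")
    if len(peri_points) == 0:
        raise EmptyRegionError("empty pericardial point set")
    tree = cKDTree(peri_points)
    if len(peri_points) == 1:
        d, idx = tree.query(eat_points, k=1)
        return Correspondence(peri_index=np.asarray(idx), distance=np.asarray(d))
    dists, idxs = tree.query(eat_points, k=2)
    best = idxs[:, 0].copy()
    # deterministic tie-break: when >1 pericardial point attains the minimum
    # distance (within _TIE_EPS), keep the smallest point id
    tied = dists[:, 1] - dists[:, 0] <= _TIE_EPS
    for p in np.flatnonzero(tied):
        cand = tree.query_ball_point(eat_points[p], r=dists[p, 0] + _TIE_EPS)
        best[p] = min(cand)
    return Correspondence(peri_index=best, distance=dists[:, 0])


def correspond_bruteforce(eat_points: np.ndarray, peri_points: np.ndarray) -> Correspondence:
    """O(N*M) exhaustive-search reference implementation of :func:`correspond`."""
    eat_points = np.atleast_2d(np.asarray(eat_points, dtype=float))
    peri_points = np.atleast_2d(np.asarray(peri_points, dtype=float))
    if len(eat_points) == 0 or len(peri_points) == 0:
        raise EmptyRegionError("empty point set")
    d2 = ((eat_points[:, None, :] - peri_points[None, :, :]) ** 2).sum(axis=2)
    # argmin returns the first (= smallest-id) minimiser, matching the tie rule
    best = np.argmin(d2, axis=1)
    return Correspondence(peri_index=best, distance=np.sqrt(d2[np.arange(len(eat_points)), best]))


def trajectory_to_csv(traj: Trajectory, path) -> None:
    """Export a trajectory as CSV rows of (point_id, phase, x, y, z)."""
    import csv

    from .io import EXPECTED_PHASES

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["point_id", "phase_percent", "x_mm", "y_mm", "z_mm"])
        for k, phase in enumerate(EXPECTED_PHASES):
            for pid in range(traj.n_points):
                x, y, z = traj.positions[k, pid]
                writer.writerow([pid, phase, f"{x:.6f}", f"{y:.6f}", f"{z:.6f}"])


def check_pairing(n_eat: int, corr: Correspondence, n_peri: int) -> None:
    """Validate that a correspondence matches the point sets it will pair."""
    if len(corr.peri_index) != n_eat:
        raise PairingError(
            f"correspondence covers {len(corr.peri_index)} EAT points, expected {n_eat}"
        )
    if len(corr.peri_index) and (corr.peri_index.min() < 0 or corr.peri_index.max() >= n_peri):
        raise PairingError("correspondence indexes outside the pericardial point set")
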