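"""Volume, mask, centerline and report I/O plus the grid conventions.

Conventions used throughout the package:

* volumes are numpy arrays indexed ``(i, j, k)`` with a 4x4 voxel-to-world
  affine in millimetres (NIfTI semantics; 0-based voxel indices);
* all geometry (points, displacement vectors, centerlines) lives in world
  millimetres obtained through the affine;
* masks are voxel-aligned with their parent volume (same grid, same affine);
* a cardiac study is exactly the nine 10-90% R-R phases with the 50% phase
  as registration reference, and phase ``k`` (k = 0..8) carries normalized
  time ``t_k = k / 9`` so the cyclic displacement closure pairs the 10% and
  90% phases.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .errors import (
    DegenerateCenterlineError,
    GridIncompatibilityError,
    IncompleteSeriesError,
)

EXPECTED_PHASES = tuple(range(10, 100, 10))
N_PHASES = len(EXPECTED_PHASES)

_AFFINE_ATOL = 1e-5  # mm; affines of one study must agree to this


@dataclass
class CTVolume:
    """A single 3D CT volume in Hounsfield units at one cardiac phase."""

    voxels: np.ndarray
    affine: np.ndarray
    phase_percent: int

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.voxels.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing (mm) along each grid axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class BinaryMask:
    """A boolean voxel mask on the grid of its parent volume."""

    voxels: np.ndarray
    affine: np.ndarray
    label: str = "pericardium"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def point_coordinates(self) -> np.ndarray:
        """World coordinates (mm) of the foreground voxel centers.

        Points come out in lexicographic voxel-index order, which is the
        point-id order used for deterministic tie-breaking downstream.
        """
        idx = np.argwhere(self.voxels)
        return voxel_to_world(idx, self.affine)


@dataclass
class PhaseSeries:
    """The nine-phase cardiac series with its 50% reference phase."""

    volumes: list[CTVolume]
    ref_index: int
    normalized_times: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        phases = [v.phase_percent for v in self.volumes]
        if tuple(phases) != EXPECTED_PHASES:
            raise IncompleteSeriesError(
                f"expected phases {EXPECTED_PHASES}, got {tuple(phases)}"
            )
        shapes = {v.voxels.shape for v in self.volumes}
        if len(shapes) != 1:
            raise GridIncompatibilityError(f"mixed grid shapes in series: {shapes}")
        ref_aff = self.volumes[0].affine
        for v in self.volumes[1:]:
            if not np.allclose(v.affine, ref_aff, atol=_AFFINE_ATOL):
                raise GridIncompatibilityError("volumes of one study must share an affine")
        self.normalized_times = np.arange(N_PHASES) / N_PHASES

    @property
    def reference(self) -> CTVolume:
        return self.volumes[self.ref_index]

    @property
    def affine(self) -> np.ndarray:
        return self.volumes[0].affine

    @property
    def shape(self) -> tuple[int, ...]:
        return self.volumes[0].voxels.shape

    @property
    def phase_labels(self) -> list[int]:
        return [v.phase_percent for v in self.volumes]


@dataclass
class Centerline:
    """An LAD-like centerline polyline in world millimetres.

    ``s_mid`` and ``s_dist`` are the arc lengths at which the middle and
    distal vessel segments begin; by default the polyline is split into
    arc-length thirds.
    """

    points: np.ndarray
    s_mid: float | None = None
    s_dist: float | None = None
    radius_r: float = 6.0
    arclengths: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise DegenerateCenterlineError(
                f"centerline needs >= 2 3D points, got array of shape {self.points.shape}"
            )
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0.0):
            warnings.warn("centerline contains duplicated consecutive points", stacklevel=2)
        self.arclengths = np.concatenate([[0.0], np.cumsum(seg)])
        L = float(self.arclengths[-1])
        if self.s_mid is None:
            self.s_mid = L / 3.0
        if self.s_dist is None:
            self.s_dist = 2.0 * L / 3.0
        if not 0.0 <= self.s_mid < self.s_dist <= L + 1e-9:
            raise ValueError(
                f"segment bounds must satisfy 0 <= s_mid < s_dist <= L, "
                f"got s_mid={self.s_mid}, s_dist={self.s_dist}, L={L}"
            )

    @property
    def total_length(self) -> float:
        return float(self.arclengths[-1])


# ---------------------------------------------------------------------------
# coordinate transforms


def voxel_to_world(indices: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map 0-based voxel indices (N, 3) to world mm through the affine."""
    indices = np.atleast_2d(indices)
    return indices @ affine[:3, :3].T + affine[:3, 3]


def world_to_voxel(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map world mm points (N, 3) to continuous voxel indices."""
    points = np.atleast_2d(points)
    inv = np.linalg.inv(affine)
    return points @ inv[:3, :3].T + inv[:3, 3]


# ---------------------------------------------------------------------------
# volume / mask I/O


def _phase_from_name(path: Path) -> int | None:
    """Extract a phase percentage from a filename such as ``phase_40.nii.gz``."""
    m = re.findall(r"(\d+)", path.name)
    for token in reversed(m):
        if int(token) in EXPECTED_PHASES:
            return int(token)
    return None


def read_volume(path: str | Path, phase_percent: int = 0) -> CTVolume:
    img = nib.load(str(path))
    return CTVolume(
        voxels=np.asarray(img.get_fdata(dtype=np.float32)),
        affine=img.affine,
        phase_percent=phase_percent,
    )


def write_volume(volume: CTVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float32), volume.affine), str(path))


def read_mask(path: str | Path, label: str = "pericardium") -> BinaryMask:
    img = nib.load(str(path))
    return BinaryMask(voxels=np.asarray(img.get_fdata()) > 0.5, affine=img.affine, label=label)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.affine), str(path))


def read_phase_series(
    paths: Sequence[str | Path],
    ref_phase: int = 50,
    phases: Sequence[int] | None = None,
) -> PhaseSeries:
    """Read the nine phase volumes into an ordered :class:`PhaseSeries`.

    Phase labels are taken from ``phases`` when given, otherwise parsed from
    the file names (the last number matching a 10-90 multiple of ten).
    """
    paths = [Path(p) for p in paths]
    if phases is None:
        parsed = [_phase_from_name(p) for p in paths]
        if any(p is None for p in parsed):
            bad = [str(p) for p, ph in zip(paths, parsed) if ph is None]
            raise IncompleteSeriesError(f"cannot parse a phase label from file name(s): {bad}")
        phases = [int(p) for p in parsed]  # type: ignore[arg-type]
    if sorted(phases) != list(EXPECTED_PHASES):
        raise IncompleteSeriesError(
            f"expected one file per phase {EXPECTED_PHASES}, got phases {sorted(phases)}"
        )
    order = np.argsort(phases)
    volumes = [read_volume(paths[i], phase_percent=int(phases[i])) for i in order]
    ref_index = [v.phase_percent for v in volumes].index(ref_phase)
    return PhaseSeries(volumes=volumes, ref_index=ref_index)


# ---------------------------------------------------------------------------
# centerline I/O


def read_centerline(
    path: str | Path,
    s_mid: float | None = None,
    s_dist: float | None = None,
    radius_r: float = 6.0,
) -> Centerline:
    """Read a centerline from JSON (``{"points_mm": [[x,y,z], ...]}``) or
    3-column CSV of world-mm coordinates."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        pts = np.asarray(data["points_mm"], dtype=float)
    else:
        rows = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if len(row) < 3 or not _is_number(row[0]):
                    continue  # skip blanks and a possible header row
                rows.append([float(c) for c in row[:3]])
        pts = np.asarray(rows, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise DegenerateCenterlineError(f"{path} does not contain >= 2 points")
    return Centerline(points=pts, s_mid=s_mid, s_dist=s_dist, radius_r=radius_r)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_centerline(centerline: Centerline, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"points_mm": centerline.points.tolist()}, indent=2)
    )


# ---------------------------------------------------------------------------
# report I/O


def write_report(report, path: str | Path) -> None:
    """Write an adhesion report as JSON plus a per-phase CSV sidecar.

    ``report`` is any dataclass exposing the report fields (PR, DWI, t*,
    per-phase totals, classification, config echo); numeric fields are
    emitted at fixed precision so equal runs produce byte-identical files.
    """
    path = Path(path)
    data = dataclasses.asdict(report)
    data = _round_floats(data, 10)
    path.write_text(json.dumps(data, indent=2, sort_keys=True))

    csv_path = path.with_suffix(".csv")
    m_t = data.get("m_t") or []
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["phase_percent", "m_t"])
        for phase, value in zip(EXPECTED_PHASES, m_t):
            writer.writerow([phase, f"{value:.10g}"])
        writer.writerow([])
        for key in ("pr", "dwi", "t_star", "classification"):
            writer.writerow([key, data.get(key)])


def _round_floats(obj, ndigits: int):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
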