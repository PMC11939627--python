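"""EAT-pericardium motion disparity, normalization, LAD ROI and phase totals.

The local motion disparity of an EAT point p at phase t is the difference
between its inter-phase displacement and that of its nearest pericardial
point q: ``Ddiff(p, q, t) = D_EAT(p, t) - D_peri(q, t)``. Magnitudes are
normalized to [0, 1] by the study-level maximum over all phases and pairs,
summed over a cylindrical ROI around the LAD centerline per phase, and the
phase of maximum total disparity t* selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyDisparityError, PairingError
from .io import Centerline
from .motion import Correspondence, check_pairing


@dataclass
class DisparityField:
    """Raw and normalized disparity for a set of point pairs.

    ``diffs`` holds the 3-vector differences (mm), ``magnitudes`` their
    Euclidean norms; after study-level normalization ``normalized`` holds
    magnitudes / d_max. Arrays may cover a single phase (shape ``(n, ...)``)
    or the whole study (shape ``(9, n, ...)``).
    """

    diffs: np.ndarray | None = None
    magnitudes: np.ndarray | None = None
    d_max: float | None = None
    normalized: np.ndarray | None = None


@dataclass
class ROISelection:
    """EAT point ids inside the cylindrical pericoronary assessment volume."""

    member_ids: np.ndarray
    window: tuple[float, float]
    radius_r: float

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


@dataclass
class PhaseDisparitySummary:
    """Total normalized disparity per phase and the optimal phase t*."""

    m_t: np.ndarray
    t_star: int = field(init=False)

    def __post_init__(self) -> None:
        self.m_t = np.asarray(self.m_t, dtype=float)
        if np.any(self.m_t < 0):
            raise ValueError("phase totals must be nonnegative")
        # argmax takes the smallest index on ties
        self.t_star = int(np.argmax(self.m_t))


def disparity(
    d_eat: np.ndarray, d_peri: np.ndarray, corr: Correspondence
) -> DisparityField:
    """Per-pair displacement difference and magnitude for one phase."""
    d_eat = np.atleast_2d(np.asarray(d_eat, dtype=float))
    d_peri = np.atleast_2d(np.asarray(d_peri, dtype=float))
    check_pairing(len(d_eat), corr, len(d_peri))
    diffs = d_eat - d_peri[corr.peri_index]
    return DisparityField(diffs=diffs, magnitudes=np.linalg.norm(diffs, axis=-1))


def normalize_study(all_magnitudes: np.ndarray) -> DisparityField:
    """Normalize disparity magnitudes by the study-level maximum.

    ``all_magnitudes`` gathers every (pair, phase) magnitude of one study;
    the global maximum d_max maps the values to [0, 1]. In the degenerate
    zero-motion limit (d_max = 0) all normalized values are 0.
    """
    mags = np.asarray(all_magnitudes, dtype=float)
    if mags.size == 0:
        raise EmptyDisparityError("no pair-phase samples to normalize")
    d_max = float(mags.max())
    normalized = mags / d_max if d_max > 0 else np.zeros_like(mags)
    return DisparityField(magnitudes=mags, d_max=d_max, normalized=normalized)


def _clip_polyline_to_window(
    centerline: Centerline, window: tuple[float, float]
) -> np.ndarray:
    """Vertices of the centerline restricted to an arc-length window,
    with interpolated break points at the window bounds."""
    s = centerline.arclengths
    pts = centerline.points
    lo, hi = window
    lo = max(lo, float(s[0]))
    hi = min(hi, float(s[-1]))
    samples = [lo] + [float(v) for v in s if lo < v < hi] + [hi]
    out = np.empty((len(samples), 3))
    for i, si in enumerate(samples):
        j = int(np.searchsorted(s, si, side="right") - 1)
        j = min(j, len(pts) - 2)
        seg = s[j + 1] - s[j]
        f = 0.0 if seg == 0 else (si - s[j]) / seg
        out[i] = pts[j] + f * (pts[j + 1] - pts[j])
    return out


def _point_to_polyline_distance(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Min Euclidean distance from each point to a piecewise-linear curve."""
    a = vertices[:-1]
    b = vertices[1:]
    ab = b - a
    ab2 = (ab**2).sum(axis=1)
    dmin = np.full(len(points), np.inf)
    for i in range(len(a)):
        if ab2[i] == 0.0:
            d = np.linalg.norm(points - a[i], axis=1)
        else:
            t = np.clip(((points - a[i]) @ ab[i]) / ab2[i], 0.0, 1.0)
            proj = a[i] + t[:, None] * ab[i]
            d = np.linalg.norm(points - proj, axis=1)
        np.minimum(dmin, d, out=dmin)
    return dmin


def select_roi(
    eat_points: np.ndarray,
    centerline: Centerline,
    radius_r: float | None = None,
    window: tuple[float, float] | None = None,
) -> ROISelection:
    """Select EAT points inside the cylinder around the LAD centerline.

    A point belongs to the ROI when its distance to the centerline restricted
    to the arc-length ``window`` is at most ``radius_r``. The default window
    runs from the middle-segment start to the end of the centerline and the
    default radius is the centerline's (6 mm).
    """
    eat_points = np.atleast_2d(np.asarray(eat_points, dtype=float))
    r = centerline.radius_r if radius_r is None else float(radius_r)
    if window is None:
        window = (float(centerline.s_mid), centerline.total_length)
    vertices = _clip_polyline_to_window(centerline, window)
    dist = _point_to_polyline_distance(eat_points, vertices)
    member_ids = np.flatnonzero(dist <= r)
    if len(member_ids) == 0:
        import warnings

        warnings.warn("empty pericoronary ROI selection", stacklevel=2)
    return ROISelection(member_ids=member_ids, window=(float(window[0]), float(window[1])), radius_r=r)


def phase_totals(
    normalized: np.ndarray, roi: ROISelection | list[ROISelection]
) -> PhaseDisparitySummary:
    """Total normalized disparity per phase, restricted to the ROI.

    ``normalized`` has shape ``(9, n_points)``; ``roi`` is either one
    selection applied to every phase or one selection per phase (membership
    re-evaluated at the deformed point positions).
    """
    normalized = np.asarray(normalized, dtype=float)
    if normalized.ndim != 2:
        raise ValueError(f"normalized must be (n_phases, n_points), got {normalized.shape}")
    n_phases = normalized.shape[0]
    rois = roi if isinstance(roi, list) else [roi] * n_phases
    if len(rois) != n_phases:
        raise PairingError(f"got {len(rois)} ROI selections for {n_phases} phases")
    m_t = np.array(
        [normalized[k, rois[k].member_ids].sum() for k in range(n_phases)]
    )
    return PhaseDisparitySummary(m_t=m_t)
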