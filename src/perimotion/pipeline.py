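"""End-to-end adhesion analysis: registration through classification.

`run_study` executes the full workflow on one cardiac study:

1. register each phase to the 50% reference and keep the nine
   reference-to-phase displacement fields;
2. segment EAT inside the pericardial sac on the reference volume;
3. transport EAT voxel centers and the pericardial boundary shell through
   the fields to build trajectories;
4. per phase: nearest-point correspondence, inter-phase displacements and
   their disparity;
5. normalize magnitudes by the study maximum, restrict to the cylindrical
   LAD ROI, total per phase, pick the optimal phase t*;
6. histogram the ROI values at t*, compute PR and DWI, build the
   phase-by-phase KS matrix and classify.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import metrics as met
from .disparity import (
    PhaseDisparitySummary,
    ROISelection,
    disparity as pair_disparity,
    normalize_study,
    phase_totals,
    select_roi,
)
from .config import AnalysisConfig
from .io import N_PHASES, BinaryMask, Centerline, PhaseSeries
from .motion import Trajectory, build_trajectories, correspond, displacement_at
from .registration import (
    Backend,
    DisplacementField,
    mask_boundary_shell,
    register_to_reference,
)
from .segmentation import EATSegmentation, segment_eat


@dataclass
class StudyResult:
    """Full pipeline output: report plus the intermediates useful for
    plots, surface exports and validation."""

    report: met.AdhesionReport
    fields: list[DisplacementField]
    eat_segmentation: EATSegmentation
    eat_trajectory: Trajectory
    peri_trajectory: Trajectory
    magnitudes: np.ndarray
    normalized: np.ndarray
    rois: list[ROISelection]
    summary: PhaseDisparitySummary
    histogram: met.DisparityHistogram
    ks: met.KSMatrix


def compute_disparity_matrix(
    eat_traj: Trajectory, peri_traj: Trajectory
) -> np.ndarray:
    """Per-(phase, EAT point) disparity magnitudes (mm), with nearest-point
    correspondence re-established at every phase."""
    n = eat_traj.n_points
    mags = np.empty((N_PHASES, n))
    for k in range(N_PHASES):
        corr = correspond(eat_traj.positions[k], peri_traj.positions[k])
        d_eat = displacement_at(eat_traj, k)
        d_peri = displacement_at(peri_traj, k)
        mags[k] = pair_disparity(d_eat, d_peri, corr).magnitudes
    return mags


def run_study(
    series: PhaseSeries,
    peri_mask: BinaryMask,
    centerline: Centerline,
    config: AnalysisConfig | None = None,
    backend: Backend | None = None,
    fields: list[DisplacementField] | None = None,
) -> StudyResult:
    """Run the complete adhesion analysis on one study.

    ``fields`` may be supplied to skip the registration stage (e.g. when
    re-analyzing with a different ROI or when ground-truth fields exist).
    """
    config = config or AnalysisConfig()
    if fields is None:
        fields = register_to_reference(series, backend, foreground=peri_mask.voxels)

    seg = segment_eat(series.reference, peri_mask, config)
    eat_points = seg.mask.point_coordinates()
    peri_points = mask_boundary_shell(peri_mask).point_coordinates()

    eat_traj = build_trajectories(fields, eat_points, tissue="EAT")
    peri_traj = build_trajectories(fields, peri_points, tissue="pericardium")

    magnitudes = compute_disparity_matrix(eat_traj, peri_traj)
    norm = normalize_study(magnitudes)

    rois = [
        select_roi(
            eat_traj.positions[k],
            centerline,
            radius_r=config.roi_radius_mm,
            window=_window(centerline, config),
        )
        for k in range(N_PHASES)
    ]
    summary = phase_totals(norm.normalized, rois)
    t_star = summary.t_star

    roi_samples = [norm.normalized[k, rois[k].member_ids] for k in range(N_PHASES)]
    hist = met.build_histogram(
        roi_samples[t_star], n_bins=config.n_bins, alpha_percent=config.alpha_percent
    )
    pr = met.peak_ratio(hist)
    dwi = met.distribution_width_index(hist)
    ks = met.ks_matrix(roi_samples)
    classification = met.classify(pr, dwi, config)

    report = met.AdhesionReport(
        pr=pr,
        dwi=dwi,
        t_star=t_star,
        t_star_phase_percent=series.phase_labels[t_star],
        classification=classification,
        m_t=summary.m_t.tolist(),
        d_max_mm=float(norm.d_max),
        h_alpha_raw=hist.h_alpha,
        n_roi_points=rois[t_star].n_members,
        config=config.to_dict(),
    )
    return StudyResult(
        report=report,
        fields=fields,
        eat_segmentation=seg,
        eat_trajectory=eat_traj,
        peri_trajectory=peri_traj,
        magnitudes=magnitudes,
        normalized=norm.normalized,
        rois=rois,
        summary=summary,
        histogram=hist,
        ks=ks,
    )


def _window(centerline: Centerline, config: AnalysisConfig) -> tuple[float, float]:
    if config.roi_window == "mid-to-dist":
        return (float(centerline.s_mid), float(centerline.s_dist))
    return (float(centerline.s_mid), centerline.total_length)


def eat_volume_per_phase(
    series: PhaseSeries,
    peri_mask: BinaryMask,
    fields: list[DisplacementField],
    config: AnalysisConfig | None = None,
) -> list[int]:
    """Per-phase EAT voxel counts from re-segmentation in the deformed sac.

    The sac mask is propagated through each phase mapping and EAT
    re-segmented on that phase's volume. Used for volume reporting only:
    point identity for motion always comes from trajectory transport of the
    reference segmentation.
    """
    from .registration import propagate_region

    config = config or AnalysisConfig()
    counts = []
    for k, fld in enumerate(fields):
        mask_k = propagate_region(peri_mask, fld)
        counts.append(segment_eat(series.volumes[k], mask_k, config).n_voxels)
    return counts


def write_study_tables(result: StudyResult, out_dir) -> None:
    """CSV sidecars: per-phase disparities, ROI membership and KS matrix."""
    import csv
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "disparity.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["point_id", "phase_percent", "magnitude_mm", "normalized"])
        for k, phase in enumerate(result.ks.phase_labels):
            for pid in range(result.magnitudes.shape[1]):
                writer.writerow([
                    pid, phase,
                    f"{result.magnitudes[k, pid]:.6f}",
                    f"{result.normalized[k, pid]:.6f}",
                ])
    with open(out_dir / "roi_members.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["phase_percent", "point_id"])
        for k, phase in enumerate(result.ks.phase_labels):
            for pid in result.rois[k].member_ids:
                writer.writerow([phase, int(pid)])
    np.savetxt(
        out_dir / "ks_matrix.csv", result.ks.d, delimiter=",", fmt="%.6f",
        header=",".join(f"{p}%" for p in result.ks.phase_labels),
    )


def metrics_for_samples(
    samples: np.ndarray, config: AnalysisConfig | None = None
) -> met.AdhesionReport:
    """Distribution-only analysis of pre-normalized disparity samples
    (imaging stages skipped; used by the `metrics` CLI)."""
    config = config or AnalysisConfig()
    hist = met.build_histogram(
        samples, n_bins=config.n_bins, alpha_percent=config.alpha_percent
    )
    pr = met.peak_ratio(hist)
    dwi = met.distribution_width_index(hist)
    return met.AdhesionReport(
        pr=pr,
        dwi=dwi,
        t_star=-1,
        t_star_phase_percent=-1,
        classification=met.classify(pr, dwi, config),
        m_t=[],
        d_max_mm=float("nan"),
        h_alpha_raw=hist.h_alpha,
        n_roi_points=hist.n_samples,
        config=config.to_dict(),
    )
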