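"""Synthetic 4D cardiac phantoms and distribution-level disparity generators.

Two fidelity levels:

* :func:`generate_phantom_series` builds a full nine-phase HU image study of
  a contracting ellipsoidal "heart" wrapped in an EAT layer and a static
  pericardial shell, with a tunable EAT-pericardium motion coupling
  ``kappa`` (0 = free sliding, 1 = fat locked to the pericardium), plus all
  ground truths (masks, analytic trajectories, an LAD-like centerline).
* :func:`generate_disparity_samples` draws normalized disparity values that
  mimic the two clinical regimes directly: a sharply decaying exponential
  for adhesion and a broad mid-peaked Gaussian for free sliding.

Phantom motion model. Cardiac tissue contracts in-plane towards the long
axis with a phase waveform peaking in early systole and a base-to-apex
amplitude taper (the base moves most, the apex is anchored), so the largest
inter-phase motion falls in the 10-30% phases and motion amplitude varies
along the LAD-like centerline. The pericardial shell and everything outside
it are static. The EAT layer moves with ``(1 - kappa)`` times the cardiac
motion: with ``kappa = 0`` the fat travels with the epicardial surface and
slides against the pericardium; with ``kappa = 1`` it is fused to the
pericardium and only the myocardium slides underneath it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .errors import PhantomSpecError
from .io import (
    EXPECTED_PHASES,
    N_PHASES,
    BinaryMask,
    Centerline,
    CTVolume,
    PhaseSeries,
    write_centerline,
    write_mask,
    write_volume,
)
from .motion import Trajectory

#: fractional contraction per phase (10%..90%), relative to the peak
#: amplitude: rapid early-systolic contraction, smooth diastolic recovery
DEFAULT_WAVEFORM = (0.05, 0.65, 1.00, 0.95, 0.85, 0.70, 0.50, 0.25, 0.10)


@dataclass
class PhantomSpec:
    """Geometry, tissue and motion parameters of the image phantom.

    All lengths in mm, attenuations in HU. Defaults give a 96^3 grid at
    1.5 mm spacing holding a (34, 34, 46) mm semi-axis "myocardium", a 10 mm
    EAT layer in the adipose HU range and a 3 mm pericardial shell.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: float = 1.5
    myo_semi_axes: tuple[float, float, float] = (34.0, 34.0, 46.0)
    eat_thickness_mm: float = 10.0
    peri_thickness_mm: float = 3.0
    centerline_offset_mm: float = 3.0
    eat_hu_mean: float = -100.0
    eat_hu_sd: float = 20.0
    myo_hu: float = 40.0
    myo_texture_sd: float = 15.0
    fluid_hu: float = 10.0
    peri_hu: float = 30.0
    background_hu: float = 0.0
    background_texture_sd: float = 20.0
    contraction_max: float = 0.12
    contraction_waveform: tuple[float, ...] = DEFAULT_WAVEFORM
    apex_base_taper: tuple[float, float] = (0.25, 1.0)
    adhesion_coupling: float = 0.0
    noise_sd: float = 5.0
    texture_smoothing_vox: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        # tolerate JSON-loaded specs (lists instead of tuples)
        self.shape = tuple(int(n) for n in self.shape)
        self.myo_semi_axes = tuple(float(a) for a in self.myo_semi_axes)
        self.contraction_waveform = tuple(float(w) for w in self.contraction_waveform)
        self.apex_base_taper = tuple(float(t) for t in self.apex_base_taper)
        if not 0.0 <= self.adhesion_coupling <= 1.0:
            raise PhantomSpecError(
                f"adhesion_coupling must be in [0, 1], got {self.adhesion_coupling}"
            )
        if len(self.contraction_waveform) != N_PHASES:
            raise PhantomSpecError("contraction waveform needs one value per phase")
        if not 0.0 <= self.contraction_max < 1.0:
            raise PhantomSpecError("contraction_max must be in [0, 1)")
        outer = np.asarray(self.myo_semi_axes) + self.eat_thickness_mm + self.peri_thickness_mm
        half_fov = np.asarray(self.shape) * self.spacing_mm / 2.0
        if np.any(outer >= half_fov - 2 * self.spacing_mm):
            raise PhantomSpecError(
                f"phantom layers (outer semi-axes {tuple(outer)}) overlap the grid "
                f"boundary (half FOV {tuple(half_fov)})"
            )
        if not (-190.0 <= self.eat_hu_mean <= -30.0):
            raise PhantomSpecError("EAT HU distribution must center in the adipose range")


@dataclass
class PhantomTruth:
    """Analytic ground truth attached to a generated phantom study."""

    eat_trajectory: Trajectory
    peri_trajectory: Trajectory
    eat_points_ref: np.ndarray
    peri_points_ref: np.ndarray
    kappa: float
    contraction_amplitudes: np.ndarray


class _MotionModel:
    """In-plane radial contraction about the long (z) axis with a
    z-dependent amplitude taper; analytic forward and inverse maps."""

    def __init__(self, spec: PhantomSpec, center: np.ndarray):
        self.spec = spec
        self.center = center
        outer_z = spec.myo_semi_axes[2] + spec.eat_thickness_mm
        self.z_apex = center[2] - outer_z
        self.z_base = center[2] + outer_z
        self.amp = spec.contraction_max * np.asarray(spec.contraction_waveform)

    def taper(self, z: np.ndarray) -> np.ndarray:
        lo, hi = self.spec.apex_base_taper
        f = np.clip((z - self.z_apex) / (self.z_base - self.z_apex), 0.0, 1.0)
        return lo + (hi - lo) * f

    def scale(self, k: int, z: np.ndarray, coupling: float = 0.0) -> np.ndarray:
        """In-plane scale factor at phase index k; ``coupling`` attenuates
        the motion (fat moves with (1 - kappa) times the cardiac motion)."""
        return 1.0 - (1.0 - coupling) * self.amp[k] * self.taper(z)

    def forward(self, pts: np.ndarray, k: int, coupling: float = 0.0) -> np.ndarray:
        """Material (uncontracted) coordinates -> phase-k coordinates."""
        s = self.scale(k, pts[:, 2], coupling)[:, None]
        out = pts.copy()
        out[:, :2] = self.center[:2] + s * (pts[:, :2] - self.center[:2])
        return out

    def inverse(self, pts: np.ndarray, k: int, coupling: float = 0.0) -> np.ndarray:
        """Phase-k coordinates -> material coordinates (z is unchanged by
        the map, so the scale factor is known exactly)."""
        s = self.scale(k, pts[:, 2], coupling)[:, None]
        out = pts.copy()
        out[:, :2] = self.center[:2] + (pts[:, :2] - self.center[:2]) / s
        return out


def _ellipsoid_r2(pts: np.ndarray, center: np.ndarray, semi_axes: np.ndarray) -> np.ndarray:
    return (((pts - center) / semi_axes) ** 2).sum(axis=1)


def _texture(rng: np.random.Generator, shape, mean, sd, smooth, clip=None) -> np.ndarray:
    tex = gaussian_filter(rng.standard_normal(shape), smooth)
    tex /= tex.std()
    tex = mean + sd * tex
    if clip is not None:
        tex = np.clip(tex, *clip)
    return tex.astype(np.float32)


def generate_phantom_series(
    spec: PhantomSpec | None = None,
) -> tuple[PhaseSeries, BinaryMask, BinaryMask, PhantomTruth, Centerline]:
    """Generate the nine-phase phantom study and its ground truths.

    Returns ``(series, pericardial sac mask, reference EAT mask, truth,
    centerline)``. The pericardial mask is the filled sac interior (the
    region an expert would delineate); the EAT mask is the exact fat region
    at the 50% reference phase, noise-free.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.rng_seed)
    shape = spec.shape
    sp = spec.spacing_mm
    affine = np.diag([sp, sp, sp, 1.0])
    center = np.asarray(shape) * sp / 2.0

    myo = np.asarray(spec.myo_semi_axes, dtype=float)
    fat_outer = myo + spec.eat_thickness_mm
    peri_outer = fat_outer + spec.peri_thickness_mm
    motion = _MotionModel(spec, center)
    kappa = spec.adhesion_coupling

    # world coordinates of every voxel center
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    world = idx * sp  # diagonal affine, zero origin

    # material-coordinate textures (sampled at warped positions per phase so
    # a material point keeps its attenuation across the cycle)
    fat_tex = _texture(
        rng, shape, spec.eat_hu_mean, spec.eat_hu_sd, spec.texture_smoothing_vox,
        clip=(-180.0, -40.0),
    )
    myo_tex = _texture(
        rng, shape, spec.myo_hu, spec.myo_texture_sd, spec.texture_smoothing_vox,
        clip=(5.0, None),
    )
    bg_tex = _texture(
        rng, shape, spec.background_hu, spec.background_texture_sd,
        spec.texture_smoothing_vox, clip=(-20.0, None),
    )

    # static region membership (world coordinates)
    r2_fat_outer = _ellipsoid_r2(world, center, fat_outer)
    r2_peri_outer = _ellipsoid_r2(world, center, peri_outer)
    inside_sac = r2_fat_outer <= 1.0
    in_peri_shell = (~inside_sac) & (r2_peri_outer <= 1.0)

    def sample_tex(tex: np.ndarray, pts: np.ndarray) -> np.ndarray:
        return map_coordinates(tex, (pts / sp).T, order=1, mode="nearest")

    volumes: list[CTVolume] = []
    for k, phase in enumerate(EXPECTED_PHASES):
        hu = np.empty(world.shape[0], dtype=np.float32)
        # static exterior: background and pericardial shell
        hu[~inside_sac] = sample_tex(bg_tex, world[~inside_sac])
        hu[in_peri_shell] = spec.peri_hu
        # interior: back-map through the fat and cardiac warps
        sac_pts = world[inside_sac]
        fat_pre = motion.inverse(sac_pts, k, coupling=kappa)
        in_fat = (_ellipsoid_r2(fat_pre, center, fat_outer) <= 1.0) & (
            _ellipsoid_r2(fat_pre, center, myo) > 1.0
        )
        myo_pre = motion.inverse(sac_pts, k, coupling=0.0)
        in_myo = _ellipsoid_r2(myo_pre, center, myo) <= 1.0
        interior = np.full(sac_pts.shape[0], spec.fluid_hu, dtype=np.float32)
        interior[in_myo] = sample_tex(myo_tex, myo_pre[in_myo])
        interior[in_fat] = sample_tex(fat_tex, fat_pre[in_fat])  # fat wins at overlap
        hu[inside_sac] = interior
        if spec.noise_sd > 0:
            hu = hu + rng.normal(0.0, spec.noise_sd, size=hu.shape).astype(np.float32)
        volumes.append(
            CTVolume(voxels=hu.reshape(shape), affine=affine, phase_percent=phase)
        )

    ref_index = EXPECTED_PHASES.index(50)
    series = PhaseSeries(volumes=volumes, ref_index=ref_index)

    # pericardial sac mask: filled interior up to the shell's inner surface
    peri_mask = BinaryMask(
        voxels=inside_sac.reshape(shape), affine=affine, label="pericardium"
    )

    # exact EAT region at the reference phase (noise-free ground truth)
    fat_pre_ref = motion.inverse(world, ref_index, coupling=kappa)
    eat_ref = (
        (_ellipsoid_r2(fat_pre_ref, center, fat_outer) <= 1.0)
        & (_ellipsoid_r2(fat_pre_ref, center, myo) > 1.0)
        & inside_sac
    )
    myo_pre_ref = motion.inverse(world, ref_index, coupling=0.0)
    eat_ref &= ~(_ellipsoid_r2(myo_pre_ref, center, myo) <= 1.0)
    eat_mask = BinaryMask(voxels=eat_ref.reshape(shape), affine=affine, label="EAT")

    # ground-truth trajectories of the reference EAT voxel centers and of the
    # (static) pericardial inner-surface shell points
    eat_pts_ref = world[eat_ref]
    material = motion.inverse(eat_pts_ref, ref_index, coupling=kappa)
    eat_positions = np.stack(
        [motion.forward(material, k, coupling=kappa) for k in range(N_PHASES)]
    )
    shell = inside_sac.reshape(shape) & ~_erode(inside_sac.reshape(shape))
    peri_pts = world.reshape(shape + (3,))[shell]
    peri_positions = np.repeat(peri_pts[None, :, :], N_PHASES, axis=0)
    truth = PhantomTruth(
        eat_trajectory=Trajectory(positions=eat_positions, tissue="EAT"),
        peri_trajectory=Trajectory(positions=peri_positions, tissue="pericardium"),
        eat_points_ref=eat_pts_ref,
        peri_points_ref=peri_pts,
        kappa=kappa,
        contraction_amplitudes=motion.amp,
    )

    centerline = _anterior_centerline(spec, center, motion, ref_index)
    return series, peri_mask, eat_mask, truth, centerline


def _erode(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    return ndimage.binary_erosion(mask, ndimage.generate_binary_structure(3, 1))


def _anterior_centerline(
    spec: PhantomSpec, center: np.ndarray, motion: _MotionModel, ref_index: int
) -> Centerline:
    """LAD-like curve along the anterior outer EAT surface at the reference
    phase, descending from near the base towards the apex. The polyline sits
    ``centerline_offset_mm`` outside the fat surface, where the vessel lumen
    center lies (the artery rides on the fat pad)."""
    fat_outer = np.asarray(spec.myo_semi_axes) + spec.eat_thickness_mm
    z_vals = np.linspace(0.80 * fat_outer[2], -0.95 * fat_outer[2], 25)
    pts = []
    for dz in z_vals:
        z = center[2] + dz
        y_surf = fat_outer[1] * np.sqrt(max(1.0 - (dz / fat_outer[2]) ** 2, 0.0))
        # place the point on the reference-phase (contracted) fat surface
        s = motion.scale(ref_index, np.array([z]), coupling=spec.adhesion_coupling)[0]
        pts.append([center[0], center[1] + s * y_surf + spec.centerline_offset_mm, z])
    return Centerline(points=np.asarray(pts), radius_r=6.0)


# ---------------------------------------------------------------------------
# distribution-level generators


@dataclass
class DistributionSpec:
    """Parameters of the distribution-level disparity generators.

    ``pattern`` selects the regime: ``"adhesion"`` draws from an exponential
    with the given ``decay_rate`` (sharp decay, mode at zero) and
    ``"non-adhesion"`` from a Gaussian with ``peak_location``/``peak_width``
    (broad mid-range peak); samples are clipped to [0, 1].
    """

    pattern: str = "adhesion"
    n_samples: int = 5000
    decay_rate: float = 40.0
    peak_location: float = 0.55
    peak_width: float = 0.15
    rng_seed: int | tuple = 0

    def __post_init__(self) -> None:
        if self.pattern not in ("adhesion", "non-adhesion"):
            raise PhantomSpecError(f"unknown pattern {self.pattern!r}")
        if self.n_samples < 1:
            raise PhantomSpecError("n_samples must be positive")


def generate_disparity_samples(spec: DistributionSpec) -> np.ndarray:
    """Draw normalized disparity samples for one synthetic case."""
    if spec.n_samples < 100:
        import warnings

        warnings.warn(
            f"only {spec.n_samples} samples; histogram metrics will be unstable",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.rng_seed)
    if spec.pattern == "adhesion":
        samples = rng.exponential(1.0 / spec.decay_rate, size=spec.n_samples)
    else:
        samples = rng.normal(spec.peak_location, spec.peak_width, size=spec.n_samples)
    return np.clip(samples, 0.0, 1.0)


@dataclass
class CohortCase:
    case_id: str
    label: str
    samples: np.ndarray
    seed: int | tuple


def generate_cohort(
    n_adhesion: int = 7,
    n_nonadhesion: int = 13,
    seeds: list | None = None,
    n_samples: int = 5000,
    seed_entropy: int | None = None,
) -> list[CohortCase]:
    """Generate an independent labelled cohort of per-case sample sets.

    Default per-case seeds are 1..n_adhesion for the adhesion group and
    11..10+n_nonadhesion for the non-adhesion group; when ``seed_entropy``
    is given each case is seeded with ``(seed_entropy, case_seed)`` so a
    study-level seed governs every draw.
    """
    if n_adhesion < 1 or n_nonadhesion < 1:
        raise PhantomSpecError("cohort group counts must be >= 1")
    if seeds is None:
        seeds = list(range(1, n_adhesion + 1)) + list(range(11, 11 + n_nonadhesion))
    if len(seeds) != n_adhesion + n_nonadhesion:
        raise PhantomSpecError("need one seed per case")
    cases: list[CohortCase] = []
    for i, seed in enumerate(seeds):
        label = "adhesion" if i < n_adhesion else "non-adhesion"
        eff_seed = seed if seed_entropy is None else (seed_entropy, seed)
        spec = DistributionSpec(pattern=label, n_samples=n_samples, rng_seed=eff_seed)
        cases.append(
            CohortCase(
                case_id=f"case{i + 1:02d}",
                label=label,
                samples=generate_disparity_samples(spec),
                seed=eff_seed,
            )
        )
    return cases


# ---------------------------------------------------------------------------
# on-disk export (CLI `simulate`)


def write_phantom_study(
    outdir: str | Path, spec: PhantomSpec | None = None
) -> dict[str, str]:
    """Write a phantom study (NIfTI series, masks, centerline, truth JSON)."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec or PhantomSpec()
    series, peri_mask, eat_mask, truth, centerline = generate_phantom_series(spec)
    paths: dict[str, str] = {}
    for vol in series.volumes:
        p = outdir / f"phase_{vol.phase_percent:02d}.nii.gz"
        write_volume(vol, p)
        paths[f"phase_{vol.phase_percent}"] = str(p)
    write_mask(peri_mask, outdir / "pericardium_mask.nii.gz")
    paths["pericardium_mask"] = str(outdir / "pericardium_mask.nii.gz")
    write_mask(eat_mask, outdir / "eat_mask_truth.nii.gz")
    paths["eat_mask_truth"] = str(outdir / "eat_mask_truth.nii.gz")
    write_centerline(centerline, outdir / "lad_centerline.json")
    paths["centerline"] = str(outdir / "lad_centerline.json")
    truth_meta = {
        "kappa": truth.kappa,
        "contraction_amplitudes": truth.contraction_amplitudes.tolist(),
        "n_eat_points": int(len(truth.eat_points_ref)),
        "n_peri_points": int(len(truth.peri_points_ref)),
    }
    (outdir / "truth.json").write_text(json.dumps(truth_meta, indent=2))
    paths["truth"] = str(outdir / "truth.json")
    return paths
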