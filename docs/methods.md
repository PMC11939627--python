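# Methods

This note documents the models, conventions and numerical choices behind
`perimotion`, and what the synthetic validation does and does not establish.

## Study conventions

A study is exactly nine CT volumes at 10–90% of the R-R interval. Phase *k*
(k = 0..8) carries normalized time t_k = k/9, so the cyclic displacement
closure pairs the 10% phase with the 90% phase; Δt = 1/9 is uniform because
the phases are equally spaced in the cardiac cycle. The 50% phase is the
registration reference. All geometry lives in world millimetres through the
NIfTI affine; voxel indices are 0-based; masks are voxel-aligned with their
parent volumes. Scanners that reconstruct additional phases outside 10–90%
are supported by simply not passing those files.

## Registration

Phase-to-reference alignment must produce a smooth, invertible mapping
φ_t with the stored displacement field on the reference grid in the
reference → phase direction (that is the direction needed to transport
reference-phase tissue points forward). The backend is pluggable behind
exactly that contract; the default is multi-resolution diffeomorphic demons
(SimpleITK's `DiffeomorphicDemonsRegistrationFilter`) with:

* pyramid shrink factors (4, 2) and image smoothing (3, 1) voxels,
* (60, 30) iterations per level,
* Gaussian field regularization of 1.0 voxel per iteration — the standard
  demons setting; heavier smoothing measurably drags the sliding
  fat–pericardium interface toward zero motion.

Every field is screened with the Jacobian determinant of (identity + u):
more than 1% nonpositive voxels over the foreground rejects the
registration. Region propagation rasterizes φ_t(Ω_ref) on the reference
grid by inverting the field (fixed-point iteration, tolerance 0.05 voxel)
and resampling the mask with nearest-neighbour interpolation.

Demons registration, like any intensity-based method with homogeneous
regularization, underestimates discontinuous sliding across the pericardial
interface; on phantoms the recovered motion of freely sliding fat is
attenuated by roughly a factor of two near the interface. The adhesion
metrics are robust to this because they are computed on *normalized*
disparities — the attenuation applies to numerator and denominator alike.

## Pericardial point sets

The expert input mask is the filled pericardial sac (the region a reader
delineates slice by slice). Two derived sets are used:

* **EAT points** — voxel centers of the HU-threshold segmentation inside
  the sac (inclusive window [−190, −30] HU, 26-connectivity, no minimum
  component size; all three are configurable);
* **pericardium points** — voxel centers of the one-voxel boundary shell of
  the sac, i.e. the membrane whose motion is compared against the fat.

Taking the full sac interior as "the pericardium" would make every EAT
point its own nearest pericardial neighbour and force the disparity to
zero, so the shell reading is the only self-consistent one.

Nearest-point correspondence is computed with a KD-tree but is exactly
equivalent to exhaustive search; ties in distance go to the smallest point
id (lexicographic voxel order) for determinism.

## Disparity, ROI and metrics

Per phase, the disparity of EAT point *p* is its inter-phase displacement
minus that of its nearest pericardial point, re-paired at every phase.
Magnitudes are normalized by the single study-wide maximum over all phases
and pairs; the degenerate all-zero case maps to all zeros rather than 0/0.

The ROI is the set of EAT points within radius r = 6 mm of the LAD
centerline restricted to an arc-length window. The window defaults to
[s_mid, L] (start of the middle segment to the end of the polyline), with
[s_mid, s_dist] available by configuration; segment boundaries default to
arc-length thirds since no coordinate convention for the clinical segment
split exists. Membership is evaluated against the exact point-to-segment
distance of the clipped polyline (verified in tests against dense 0.1 mm
arc sampling). ROI membership is re-evaluated at each phase's deformed
point positions.

The histogram at the optimal phase t\* uses 100 equal-width bins on [0, 1]
(last bin right-inclusive). The peak-ratio reference bin is the bin at the
α-percent *position* of the bin axis (index ⌊α/100 · n_bins⌋, default 25,
i.e. the bin covering normalized disparity 0.25) — not the α-th percentile
of the sample values, which would make PR ≈ 1 for any decaying unimodal
shape and could not separate the two regimes. An empty α bin is guarded as
a count of 1 (the raw zero is reported alongside), since sharply decayed
adhesion histograms routinely have no mass at 0.25. Classification uses
PR > 100 ∧ DWI < 0.3 for adhesion and PR < 50 ∧ DWI > 0.4 for non-adhesion;
the overlap-free middle zone is reported as indeterminate rather than
forced.

The KS matrix stores only the statistic sup|F_i − F_j| (no p-values); the
group comparison uses the exact two-sided Mann–Whitney U test (exact null
distribution for the tie-free case; normal approximation with tie
correction otherwise; all-tied input returns p = 1 with a warning). A rank
test is the defensible choice at n = 7 vs 13 with heavy-tailed PR values.

## Synthetic phantom

The image phantom emulates the features the measurement depends on, at a
desk-scale grid (default 96³ voxels, 1.5 mm isotropic):

* a "myocardium" ellipsoid (semi-axes 34, 34, 46 mm) that contracts
  in-plane toward the long axis with peak fractional contraction 12%,
  waveform (0.05, 0.65, 1.00, 0.95, 0.85, 0.70, 0.50, 0.25, 0.10) across
  the nine phases — steepest between 10% and 30%, so the optimal phase
  lands in early systole — and a base→apex amplitude taper 1.0 → 0.25
  (the base moves most; the apex is anchored but not static);
* a 10 mm EAT layer with a material-anchored smooth HU texture
  (−100 ± 20 HU, clipped to [−180, −40] so acquisition noise cannot push
  fat out of the segmentation window), moving with (1 − κ) times the
  cardiac motion: κ = 0 slides freely against the pericardium, κ = 1 is
  fused to it;
* a static 3 mm pericardial shell and static textured background; the gap
  opened by contraction fills with pericardial-fluid HU;
* additive per-phase Gaussian noise of 5 HU. Clinical gated CT is noisier
  per native voxel, but its voxels are ~6.5× smaller in-plane; averaged
  onto this simulation grid the effective noise would be well below 5 HU,
  so the choice is conservative;
* an LAD-like centerline on the anterior fat surface, descending base →
  apex, offset 3 mm outward (the lumen center of a ~4 mm vessel riding on
  the fat pad). The offset also keeps the 6 mm ROI cylinder inside the
  outer fat, away from the registration motion-bleed at the fat–myocardium
  interface — mirroring the clinical geometry in which the pericoronary
  ROI hugs the pericardium.

Phase volumes are rendered analytically (region membership through the
exact inverse of the motion map; textures sampled at material
coordinates), so ground-truth trajectories, masks and the centerline are
exact. With κ = 1 the true disparity is identically zero; with κ = 0 it
equals the planted cardiac displacement at the fat.

What the phantom does **not** model: real anatomy (chambers, valves,
vessels), through-plane twist and longitudinal shortening, contrast
gradients, gating artifacts, spatially varying or partial adhesions, and
low-EAT patients. Passing the end-to-end tests therefore demonstrates that
the measurement chain recovers the coupling parameter it was given under
idealized but honest conditions (sliding discontinuity, texture-limited
registration, CT-like HU and noise) — not clinical accuracy, which requires
patient data.

The distribution-level generators bypass imaging entirely: adhesion-pattern
cases draw from Exponential(rate 40) clipped to [0, 1] (sharp decay, mode at
zero) and non-adhesion cases from Normal(0.55, 0.15) clipped to [0, 1]
(broad mid-range peak), 5 000 samples per case. These parameters place
desk-scale cohorts inside the clinically reported PR/DWI ranges and
correspond to the published distribution shapes for the two groups.

## Numerical choices

* Cyclic conservation: the nine inter-phase displacements of any point
  telescope to zero; this is asserted *exactly* on grid-representable
  (dyadic-rational) coordinates, where IEEE arithmetic introduces no
  rounding, and to 10⁻⁹ mm on arbitrary float trajectories.
* t\* and the classification tie-breaks: argmax takes the smallest phase
  index; all-zero totals give t\* = 0.
* d_max = 0 ⇒ all normalized disparities 0 (uniform zero-motion limit).
* Points leaving the field domain during transport take nearest-edge field
  values and are flagged in the log.
* Problem sizes: the default test suite registers two 96³ phantom studies
  (~20 s each on one CPU) and keeps oracle-equivalence instances at ≤ 10³
  points, chosen so the whole suite runs in well under two minutes.

## Known limitations

* Demons is a single-modality, intensity-matching backend; studies with
  strong contrast differences between phases need a different backend via
  the registration contract.
* Only axis-aligned (orthogonal-direction) affines are exercised; oblique
  acquisitions should be resampled first.
* The indeterminate zone between the published threshold pairs is reported
  as such; the package deliberately does not re-estimate thresholds from
  its own synthetic data.
* Per-phase EAT re-segmentation is used only for volume reporting; point
  identity across phases always comes from trajectory transport of the
  reference segmentation.
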