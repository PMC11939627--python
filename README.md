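# perimotion

Quantitative, noninvasive detection of **pericardial adhesions** from 4D
cardiac CT.

Pericardial adhesions — fibrous fusion of the visceral and parietal
pericardial layers — abolish the normal sliding of the heart inside its sac.
They complicate redo cardiac surgery and epicardial ablation, yet static CT
findings (thickening, calcification) neither confirm nor exclude them. The
dynamic signature is unambiguous: in a healthy chest the epicardial adipose
tissue (EAT), which rides on the beating heart, slides freely against the
essentially stationary pericardium; under adhesion that relative motion
vanishes.

`perimotion` measures this sliding from a routine multiphase (4D) CT study —
nine volumes at 10–90% of the R-R interval — plus an expert pericardial mask
on the 50% reference phase and an LAD centerline, and classifies adhesion
status. It is aimed at imaging researchers and surgical-planning teams
working with ECG-gated cardiac CT.

## Method

1. **Registration.** Every phase is aligned to the 50% reference with a
   diffeomorphic registration, giving mappings φ_t (reference → phase *t*);
   the default backend is multi-resolution diffeomorphic demons (SimpleITK),
   and any symmetric-normalization (SyN) implementation can be plugged in.
2. **Segmentation.** EAT is segmented inside the pericardial sac as
   contiguous voxels with −190 ≤ HU ≤ −30.
3. **Motion.** EAT voxel centers and pericardial (sac-boundary) points are
   transported through φ_t; the inter-phase displacement at phase *k* is
   D(k) = P(t_k) − P(t_{k−1}), with the cyclic closure D(0) = P(t_0) − P(t_8).
4. **Disparity.** Each EAT point *p* is paired with its nearest pericardial
   point *q* and the motion disparity D_diff(p,q,t) = D_EAT(p,t) − D_peri(q,t)
   is computed; magnitudes are normalized by the study-wide maximum D_max.
5. **ROI and optimal phase.** Analysis is restricted to a 6 mm cylinder
   around the mid/distal LAD centerline; the per-phase total
   M_t = Σ_ROI ‖D̂_diff‖ peaks at the optimal phase t\* (empirically early
   systole).
6. **Classification.** The histogram (100 bins on [0, 1]) of normalized
   disparities at t\* yields two shape statistics:

   * **peak ratio** PR = H_max / H_α — maximum bin count over the count at
     the 25%-position bin; large when the distribution decays sharply from a
     peak near zero (restricted motion),
   * **distribution width index** DWI = N_nonzero / N_total — fraction of
     occupied bins; small for concentrated distributions.

   PR > 100 with DWI < 0.3 ⇒ **adhesion**; PR < 50 with DWI > 0.4 ⇒
   **non-adhesion**; anything else is indeterminate. A phase-by-phase
   two-sample Kolmogorov–Smirnov matrix D_ij = sup_x |F_i(x) − F_j(x)|
   validates the temporal structure, and an exact Mann–Whitney U test
   compares metric values between patient groups.

Because no clinical 4D CT data ship with the package, a first-class
synthetic module generates (a) full image phantoms — a contracting
ellipsoidal heart, an EAT layer in the adipose HU range, a static
pericardial shell, and a tunable EAT–pericardium motion coupling
κ ∈ [0, 1] (0 = free sliding, 1 = adhered) with analytic ground truth — and
(b) distribution-level disparity samples mimicking the two clinical regimes.

## Worked example

Simulate a small labelled cohort of disparity distributions and score it:

```sh
perimotion simulate --cohort 2 3 --seed 7 --out-dir demo/cohort
perimotion metrics demo/cohort/case*.csv --out-dir demo/metrics
```

prints

```
case_id,pr,dwi,classification,truth_label
case01_adhesion,1602,0.23,adhesion,adhesion
case02_adhesion,1635,0.2,adhesion,adhesion
case03_non-adhesion,7.68421,0.93,non-adhesion,non-adhesion
case04_non-adhesion,8,0.96,non-adhesion,non-adhesion
case05_non-adhesion,9.6,0.91,non-adhesion,non-adhesion
# group_p_value_pr,0.2
```

Each row is one synthetic case: adhesion-pattern cases show sharply decaying
disparity histograms (PR ≈ 1600, DWI ≈ 0.2), free-sliding cases broad
mid-peaked ones (PR < 10, DWI ≈ 0.9), and every case is classified in
agreement with its generating label. (The group p-value is limited by the
tiny 2-vs-3 demo; at the study's 7-vs-13 size it reaches 2.6 × 10⁻⁵.)

The full imaging pipeline runs the same way on a 4D phantom study:

```sh
perimotion simulate --kappa 0.0 --seed 1 --out-dir demo/free
perimotion run --peri-mask demo/free/pericardium_mask.nii.gz \
    --centerline demo/free/lad_centerline.json --out-dir demo/run \
    $(for f in demo/free/phase_*.nii.gz; do echo --phases $f; done)
```

which registers the nine phases, tracks both tissues and reports
`PR=7.1, DWI=0.50, t*=20%, classification=non-adhesion` for the free-sliding
phantom (κ = 0); with `--kappa 1.0` the same pipeline reports
`PR=321, DWI=0.19, classification=adhesion`. The run directory also contains
the disparity histogram, the KS-matrix heatmap and a PLY point cloud of the
EAT surface colored by normalized disparity.

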