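# Methods

This note documents the models behind `spinenav`: what the synthetic data
emulate, how each stage computes its quantities, the defaults that matter,
and what the package's passing tests do and do not establish about real
intraoperative data.

## Coordinate conventions

All coordinates are millimetres in right-handed LPS (+x left, +y posterior,
+z superior); volumes are 0-based with the voxel (0,0,0) centered at the
volume origin. Rigid transforms are 4×4 homogeneous matrices validated to
orthonormality 1e-9; they are serialized as plain-text row-major matrices.
Two spaces matter: the *reference* space defined by the tracked dynamic
reference object (DRO) on the specimen frame, and the *CT* space of the
preoperative volume. Frame poses map in-plane image millimetres
(lateral u, depth v, 0) to the reference space with the probe calibration
already folded in — calibration estimation is out of scope and treated as a
given input.

## Spine phantom

The specimen stand-in is parametric-primitive, not mesh-from-atlas: each
vertebra is a union of simple solids (mid-sagittal spinous fin, paired
lamina slabs, four articular-process spheres protruding posteriorly past
the laminae, deep transverse-process bars, a vertebral-body cylinder with
pedicle bars), voxelized at the 0.5 mm base grid. This is deliberate: the
geometry is seed-stable, bit-reproducible, and rich enough to exercise
every downstream metric (occlusion, region binning, lever arms), while no
claim is made that its shapes are anatomically faithful.

Successive spinous apices are separated by the measured inter-spinous gaps
of the study specimen — 69.36, 35.33, 38.21, 39.38, 39.46 mm caudal to
cranial, summing to a 221.74 mm L1–L6 span — so error-propagation analyses
operate at matched lever arms. Seven surface landmarks per level (spinous
apex, left/right laminae, left/right superior articular processes,
left/right transverse tips) are placed inside their primitives and
validated to lie within one voxel of the level's labels.

Depth staging is intentional: with the probe face 5 mm above the spinous
apices, a 5 cm imaging depth reaches SP, L and AP only; TP and VB enter the
field only at 7 cm (VB only through the inter-vertebral gaps). This
mirrors the visibility pattern of an open posterior approach, where deep
lateral and anterior structures only appear at the larger imaging depth.

The CT rendering assigns 40 HU to soft tissue, 1200 HU to bone and 3200 HU
to the four fiducial spheres (radius 5 mm, mounted near the caudal frame
end, non-coplanar), applies a 0.4 mm Gaussian point-spread blur and adds
seeded 8 HU noise. Coarser CT reconstructions (1, 2 mm) are linear
resamples of the base volume on the same physical extent; labelmaps are
resampled nearest-neighbor.

## Ultrasound sweep simulation

A sweep is a caudo-cranial sequence of axial frames (default 24) spanning
40 mm over one level. Image formation is a first-hit ray model per column:
speckle is folded-normal noise clipped to a 0.25 ceiling; the first
bone-labelled voxel along the column's depth axis produces a Gaussian echo
with σ = 4.8 mm/f (0.8 mm at 6 MHz, 0.4 mm at 12 MHz) and amplitude
attenuated by exp(−0.0006·f·depth); pixels deeper than the interface are
shadowed to 5% residual speckle. The 14 mm field width is fixed; the 5/7 cm
depth settings change the imaged range and row pitch. There is no
refraction, no transverse-wave component, no beam-incidence model and no
soft-tissue layering — the coverage model downstream makes exactly the same
straight-ray assumption, so the simulator and the metric are consistent by
construction.

Operator variability enters as a per-sweep left-right tilt (σ = 2° about
the spine axis), lateral offset (σ = 1 mm), per-frame wobble (σ = 0.15°)
and a ±30% speed modulation of frame advance (monotone by construction).
The sweep seed is split into independent pose and speckle streams
(`SeedSequence.generate_state`), so pose variability and texture can be
controlled separately; both can be overridden.

The study-scale acquisition grid — 5 repetitions × 2 frequencies × 2 depths
× 6 levels = 120 sweeps — is driven by a master seed; each acquisition's
seed is `SeedSequence(master, spawn_key=(level, depth_idx, freq_idx, rep))`,
so any single acquisition can be regenerated in isolation. The frame count
per sweep (24) and image raster (128×64) were chosen once as the coarsest
sampling that keeps bone-point clouds dense enough for sub-millimetre
registration; the full experiment (120 sweeps, registrations at three CT
resolutions, coverage, models) completes in about two minutes on one CPU.

## Ground-truth alignment

As in an intraoperative-CT workflow, the reference-to-CT transform comes
from the fiducial spheres: voxels above a threshold midway between bone and
sphere intensities are grouped into 26-connected components, small
components (below the volume of a half-radius sphere) are discarded, and
intensity-weighted centroids give sub-voxel centers. Centers are ordered
lexicographically on (x, y, z) — a documented stand-in for the unstated
pairing convention of a tracked DRO — and fitted to the tracked positions
with the closed-form SVD solution of the rigid Procrustes problem
(reflection corrected by a sign flip of the smallest singular vector). FRE
is the RMS residual. Simulated camera tracking adds isotropic 0.1 mm noise
to the sphere positions by default, giving ground-truth FREs around 0.1 mm;
with noise disabled the round trip recovers the generator's transform to
1e-3 mm.

The validity caveat of a fiducial-based ground truth is reproduced
quantitatively: a pure angular error ε at the DRO displaces anatomy at
lever arm d by 2·d·sin(ε/2), and the propagation regression recovers this
slope to better than 1%.

## Registration stand-in

The production registration engine of a navigation system is typically
unpublished; `spinenav` substitutes a transparent pipeline whose role is to
be *evaluable*, not state-of-the-art:

1. **Bone points**: per image column, the deepest contiguous
   supra-threshold echo run's peak, kept only if the mean intensity below
   it is under 0.5× the peak (acoustic-shadow confirmation), refined to
   sub-pixel depth by a three-point parabolic fit.
2. **CT surface**: first-hit posterior surface of the target level
   (optionally ± the adjacent levels) by marching each (x, z) voxel column
   posterior→anterior.
3. **Initialization from the acquisition convention**: the sweep's travel
   direction is aligned to the CT +z axis, the mean beam direction to −y,
   and the sweep midpoint is placed on the probe standoff plane posterior
   to the level centroid. With the planner's protocol this lands within
   ~1 mm/1° of the truth before any image information is used.
4. **Trimmed ICP**: exact nearest neighbors on a k-d tree built once over
   the surface, worst 20% of pairs discarded per iteration, rigid update by
   the closed-form landmark fit applied to tangent-plane-projected targets.
   The projection (the classical approximation of point-to-plane ICP) is a
   deliberate choice: pure point-to-point updates stall a fraction of a
   voxel from the optimum on flat voxelized surfaces because nearest
   neighbors lock tangentially, which would violate the 0.1 mm recovery
   the evaluation needs. The accepted-iteration RMS of point-to-surface
   distances is non-increasing by construction (a worsening step reverts
   and stops); non-convergence is reported via a flag, never an exception.

Including adjacent levels in the match surface lets the clinically observed
failure mode occur naturally: an initialization displaced by one vertebral
gap converges onto the neighboring level with a low surface RMS and a
10–70 mm TRE at the scanned level. At default conditions the simulator's
initialization is accurate enough that spontaneous mismatches are rare;
the mismatch machinery is therefore exercised by constructed displacement
scenarios and simulated response designs rather than by the default grid.

## Evaluation metrics

TRE is the RMS Euclidean distance at the 7 landmarks between the evaluated
and ground-truth alignments, computed at every level for every acquisition.
Classification: success strictly below 2 mm (the clinical threshold
phrased as "below 2 mm"); level mismatch at ≥ 10 mm (the mismatch response
is negative when TRE is "lower than 10 mm", so the boundary belongs to the
positive class); failure in between — the three classes partition [0, ∞).
Rates are percentages on the 0–100 scale, rounded only at presentation;
medians and IQRs use the linear-interpolation quantile definition
(conventions differ between toolchains, so this is pinned). All 120
acquisitions are pooled within each stratum (per CT resolution, per
depth×frequency cell, per level). Wall-clock effectiveness is logged per
stage but never asserted — it is hardware-dependent.

The propagation matrix holds the median TRE per (acquisition level,
measured level) cell; the distance regression is ordinary least squares of
cell values on the cumulative inter-spinous distance. Intensity profiles
sample a volume trilinearly along a fixed CT-space segment; for sweeps the
same segment is mapped into each frame through the ground-truth alignment
and the nearest image plane supplies bilinear values, so one anatomical
line is comparable across acquisitions.

## Coverage model and statistics

Coverage marches one ray per image column (origin at the row-0 pixel
center, direction = image depth axis, default step = min(spacing)/4, always
≤ half a voxel) and stops at the first labelled voxel. Counts are **unique
voxel counts per bin** — re-scanning the same surface patch is not more
coverage — with own-level hits binned by region and hits on the directly
adjacent levels pooled into whole-vertebra Inf/Sup bins (hits on more
distant levels stop the ray uncounted). A per-ray brute-force oracle at
step = spacing/10 reproduces the vectorized implementation exactly on
randomized scenes.

The accuracy model is a linear mixed model of own-level TRE on the five
label counts and their C(5,2) = 10 pairwise interactions (interactions are
truncated at pairwise by default — a full interaction expansion is
combinatorially meaningless at n = 120 — with the design builder exposing
the columns for external audit), with a random intercept per level and
variance components for frequency-within-level and depth-within-level;
level-mismatch acquisitions are removed first, as a different failure mode.
Fixed-effect columns are standardized internally for conditioning and
reported back on the per-voxel scale. The mismatch model is a binomial
mixed model of the ≥10 mm indicator on the own-level coverage sum with the
same grouping, fitted by the variational-Bayes routine for binomial mixed
GLMs; the covariate is centered, making the slope exactly invariant to
covariate shifts, and complete separation is flagged rather than raised.
Fitting is delegated to statsmodels (`MixedLM`,
`BinomialBayesMixedGLM`); the package's contribution is the design,
response and grouping construction and the reported coefficient tables.

On simulated designs at study size (n = 120), a planted −0.001 mm/voxel
laminae effect is recovered with the correct sign and within 2 standard
errors at near-nominal rates, and under null responses both models reject
at 5% in well under 10% of datasets. P-values estimated on a physical
specimen depend on that specimen's data and are not reproduction targets.

## What passing tests do not show

The phantom's clean surfaces, noise-free tracking of poses, and
convention-exact initialization make the registration problem easier than
surgery: simulated success rates (≈ 95–100%) sit well above cadaver rates,
and spontaneous level mismatches are rare. The simulator omits soft-tissue
layers, refraction, beam-incidence effects, intervertebral and respiratory
motion (the rigid-spine assumption is inherited deliberately). Passing
tests therefore validate the *metrology* — transforms, detection,
registration recovery, metric arithmetic, coverage counting, statistical
calibration — not the clinical performance of any particular registration
algorithm.
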