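# Methods

`rhizoct` quantifies how roots and biopores reshape the soil around them in
3D X-ray µCT images: it segments the pore system and the tubular
root/biopore network, summarizes pore morphology, measures radial
gray-value and porosity gradients away from the root surface, and fits an
exponential compaction model to those gradients.  Because benchmark µCT
scans with known rhizosphere structure do not exist, the package ships a
phantom generator whose ground truth exercises every stage of the chain.

## The measurement chain

**Preprocessing.** Raw volumes are conditioned in the order: optional gray
inversion → 3D non-local means denoising → reduction to 8-bit (percentile
window 0.1–99.9) → unsharp mask (radius 2 voxels, weight 0.2, Fiji-style
weighted subtraction with renormalization).  The non-local means step is
performed in 16-bit with a +1000 offset, which keeps the filter's behavior
linear in dark regions; patch size 3³, search window 7³, and a filtering
strength tied to the noise level estimated from the volume are used because
the contract is noise-variance reduction with edge retention, not bit-exact
equivalence with any particular implementation.

**Pore segmentation.** Pores — air-, water- or root-filled alike — are the
dark phase.  Hysteresis thresholding labels voxels below the low threshold
as seeds and adds voxels below the high threshold that are 26-connected to
a seed; the connectivity rule is what lets root tissue (intermediate gray)
join the pore phase through the dark pores at its surface.  The default
threshold estimator takes the solid level from the dominant histogram mode
and the pore level from the dark tail (1st percentile), brackets their
midpoint with ±0.25 × half the inter-level distance, and refuses volumes
whose histogram shows no valley.  The midpoint rule replaces an Otsu-based
valley because partial-volume blur at 19 µm smears the fine-pore mode into
a shoulder; Otsu then lands between the root and solid modes and inflates
porosity by about +3 % absolute on three-phase phantoms, while the midpoint
keeps the bias below ±1 %.  Otsu remains available through the pluggable
`method` argument.

**Pore morphology.** Visible porosity is a voxel count ratio; structures
thinner than 2 voxels (38 µm at 19 µm resolution) are below the visibility
convention and absent by resolution, not by filtering.  Local thickness
follows the maximum-inscribed-ball definition: a voxel's thickness is the
diameter of the largest ball fully inside the mask that covers it.  It is
computed exactly by evaluating, for every ball radius present in the
distance transform, the morphological opening with the Euclidean ball of
that radius (two distance transforms per radius level, restricted to the
bounding box of candidate centers); all covering tests run on squared
integer distances so no float rounding can flip a strict comparison.  The
pore-size distribution bins the thickness map into diameter classes as ROI
volume fractions.  The Euler characteristic χ = components − handles +
cavities is computed with 26-connected foreground after a ball-of-radius-1
opening and removal of components of ≤ 4 voxels, because single-voxel
misclassifications dominate χ otherwise; χ is reported per mm³ of ROI.

**Tubular segmentation.** At scale σ the volume is Gaussian-smoothed and
the Hessian eigenvalues λ1 ≥ λ2 ≥ λ3 evaluated per voxel (closed-form
symmetric 3×3 eigenvalues; smoothing plus finite-difference Hessian, which
matches Gaussian-derivative filters closely for σ ≥ 1 voxel at a fraction
of the cost).  The tubeness response is σ²·sqrt(λ2·λ3) where both are
negative and 0 otherwise — large inside bright cylinders, small for sheets
and blobs.  The per-voxel maximum over a geometric σ ladder covering radii
d_min/2…d_max/2 detects tubes across diameters; 4 scales suffice for the
narrow diameter range of pot-grown roots, 8 for field biopores.  Because a
scale-normalized filter gives equal-contrast matrix pores nearly the same
amplitude as tubes at their own scale, segmentation thresholds the response
strictly (auto: 0.7 of the 99.9th percentile of positive response), drops
small components, then re-grows each surviving component into the pore
phase by conditional dilation, with the number of growth steps set by the
component's own winning scale.  The default minimum component size in the
pipeline is 5000 voxels (~0.034 mm³ at 19 µm); granular matrices shed
speckle components up to a few thousand voxels.  Tubes are split into
coarse/fine diameter classes by thresholding their local thickness at 13
voxels (247 µm — the operational "250 µm" boundary).  Lengths come from a
3D thinning skeleton: steps between 26-adjacent skeleton voxels contribute
1, √2 or √3 voxel lengths, each open endpoint is extended by its local
inscribed radius (thinning retracts tube caps by about one radius), and
length density is reported in mm per cm³.

**Radial gradients.** The Euclidean distance transform gives every soil
voxel its distance to the nearest root/biopore voxel.  Mean gray value and
mean pore indicator are accumulated in distance shells (default width 1
voxel); sampling can stride the grid deterministically (the protocol's
"every fifth voxel"), and profiles are normalized either by the mean gray
of all sampled soil voxels (sample-mean, the default, used for
cross-sample comparison) or by the mean beyond 1.5 mm (bulk mode).  For
per-class profiles the other diameter class is excluded together with a
5-step dilated margin (95 µm at 19 µm) so its own gradient cannot leak in.
An edge-bias guard (default on) drops voxels nearer to the volume boundary
than to any tube — in real samples such voxels may be closer to an
unobserved tube outside the field of view.  For synthetic single-tube
phantoms the guard only discards usable distant voxels, so the validation
runs disable it.  The three working channels (gray, pores, encoded
distances) can be packed into an 8-bit composite; the distance encoding is
linear with the µm-per-level factor recorded.

**Compaction model.** Porosity vs distance x from the root surface is
modeled as

    eps(x) = eps_bulk − delta_eps · exp(−x / (m · d_root))

an exponential deficit whose decay length is a constant multiple m of the
root diameter.  The wall-effect extension adds a near-surface excess
`A_w · exp(−x/(k·d_p))` from the loose packing of particles against the
root surface, with the decay tied to the packing particle diameter d_p.
The shape constant k = 0.03 places the excess inside ~0.1·d_p of the wall,
so a 2 mm sieved packing produces the observed sub-100 µm zone; other wall
shapes can be plugged in, and fitted d_p is comparable across studies only
in order of magnitude.  Fits are weighted nonlinear least squares (weights
= voxels per bin, scale-invariant) with multistart initialization; the
decay length is capped at the profile span, beyond which an exponential is
indistinguishable from a line, and a fit with vanishing amplitude is
flagged as unidentifiable rather than reported as converged.

**Two readouts, one model.** The pipeline fits the model to both profile
readouts and combines them: the deficit amplitude is taken from the
segmented-porosity profile (amplitude there is well calibrated: two-phase
phantoms recover absolute porosity to ±0.5 %), while the decay length is
taken from the gray-value profile, fitted from 100 µm outward.  Gray values
are linear in the sub-resolution solid fraction, so their decay length is
unbiased; the segmented-porosity profile inflates low porosities more than
high ones (partial-volume dilation is relatively stronger where pores are
scarce), which shortens its apparent decay length by ~15 % on phantoms.
This mirrors why gray values are the primary readout of the underlying
field protocol.  The porosity fit window starts at 2 voxels (partial-volume
cutoff), the gray window at 100 µm (past the wall-effect dip).

## The phantom generator

The generator emulates a repacked sieved-soil core imaged at 19 µm: a
granular matrix, one or more curved tubes (roots or empty biopores,
diameters 100–1500 µm), a prescribed radial halo, and CT-like rendering.

* **Matrix**: white noise smoothed at the grain scale and thresholded at
  the exact rank that realizes the target porosity (realized − target is at
  most one voxel in the volume).  The smoothing is periodic, which keeps
  the field statistics stationary up to the volume faces; reflective
  padding would inflate boundary variance and with it local porosity.  The
  correlation length (kernel σ = L/2) defaults to 48 µm ≈ 2.5 voxels:
  coarser texture makes shell porosities fluctuate beyond the generator's
  own ±0.01 fidelity bound through correlated fluctuations, finer texture
  is destroyed by the imaging point-spread function.
* **Tubes**: swept spheres along spline-interpolated centerlines; diameters
  may vary linearly along the tube; a tube whose centerline plus radius
  leaves the volume is rejected.
* **Halo**: the prescribed porosity eps(x) = eps_bulk + A_w·e^(−x/L_w) −
  A_c·e^(−x/L_c) is imposed stochastically — pore voxels deleted
  (compaction) or solid voxels converted (wall excess) with the probability
  that makes the expected shell porosity equal the prescription.  Only the
  expected radial profile matters downstream, so no particle rearrangement
  is simulated.  An amplitude equal to the bulk porosity means complete
  compaction at the wall; overshoots within 0.01 (sampling slack between
  nominal and realized bulk porosity) are clamped, larger ones rejected.
* **Rendering**: phase gray levels (pore 10000 < root 20000 < solid 30000,
  the attenuation ordering; root tissue is water-like, and the root/pore
  contrast is a free parameter), Gaussian PSF of σ = 9.5 µm (half a voxel,
  a sharp reconstruction), additive Gaussian noise of σ = 500 gray levels,
  clipped to 16-bit.  Empty biopores render at the pore level.

Everything is seeded through independent child streams (matrix, halo,
noise) and bit-reproducible.

**What the phantoms do not emulate**: beam hardening, ring artifacts,
cone-beam geometry, anisotropic grain shapes, aggregate structure,
mechanical particle rearrangement, root hairs, or sub-resolution porosity
gradients other than through the gray-level proxy.  Passing tests therefore
demonstrate that the measurement chain is correct and well-calibrated on
granular media with known radial structure — not that segmentation
parameters transfer to any particular scanner or soil.

## Validation design and problem sizes

The validation suite measures, at sizes chosen to keep the full run within
a desktop-scale budget:

* exact agreement of the Euclidean distance transform with brute-force
  nearest-surface minimization (200 random masks ≤ 32³);
* exact agreement of χ with a closed-cube-complex count (vertices − edges +
  faces − cubes; 200 random masks ≤ 20³) plus closed forms (disjoint balls,
  solid torus);
* exact agreement of local thickness with an all-inscribed-balls oracle
  (random masks ≤ 32³) and D ± 1 voxel on rasterized cylinders;
* monotone scale selection across tube diameters 100–1500 µm and tube-mask
  Dice ≥ 0.85 against ground truth on a 256³ matrix-plus-tube phantom;
* recovery of halo parameters (amplitude ±0.02, decay length ±20 %) by the
  full pipeline in ≥ 9 of 10 seeded 192³ phantoms under the standard study
  condition (bulk porosity 0.10, A_c = 0.10, L_c = 300 µm, 500 µm root, CT
  noise on);
* normalization fidelity (flat at 1.000 ± 0.02 without a halo; returning to
  1.0 ± 0.02 beyond 3·L_c with one) and stride-5 equivalence (< 1 % per
  bin) on the 256³ phantom;
* exclusion soundness: the fine-class profile is unchanged (± 0.01
  normalized units) by a coarse tube 1.5 mm away when the 5-step exclusion
  is active.

Recovery phantoms use exhaustive profiling (stride 1) and no edge guard:
at 192³ the stride-5 shortcut leaves too few voxels per shell, and the
guard has no role without out-of-volume tubes.  Denoising is skipped on
phantoms — shell averaging over ≥ 10⁴ voxels suppresses the synthetic noise
without it, and the non-local means contract is tested separately.

## Known limitations

* Fine tubes (< 250 µm) inside a granular matrix are not reliably segmented
  with the default scale-constant response threshold; scale-dependent
  thresholds are exposed as a configuration hook.  Diameter-class logic is
  validated on rasterized ground-truth tubes.
* The segmented-porosity profile carries a concave measurement bias at low
  porosity; its decay lengths are systematically ~15 % short.  Use the gray
  readout (the pipeline default) for decay lengths.
* 3D thinning can erode perfectly even-symmetric tubes to nothing; the
  length module falls back to the distance-ridge centerline with a warning.
  Real segmented tubes are never perfectly symmetric.
* The fitted particle diameter of the wall-effect model depends on the
  assumed wall-profile shape (default damped exponential, k = 0.03) and is
  comparable only in order of magnitude.
* χ is reported for the pore network as segmented; no attempt is made to
  separate percolating from isolated subnetworks.
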