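# Methods

## Delineation model

All six methods operate on a calibrated SUV volume sampled on a regular,
anisotropic voxel lattice. Voxel indices are 0-based in `(x, y, z)` order;
the physical centre of voxel *i* is `origin + i * spacing` (mm). Physical
distances are voxel-centre-to-voxel-centre Euclidean distances honouring
the anisotropic spacing; this matters because the background shell of the
adaptive threshold is defined by physical offsets (12 mm and 4 mm) on a
grid whose axial spacing (3.27 mm) differs from the in-plane spacing
(2.73 mm).

### Draw-and-refine

The operator input is a union of spheres enclosing the lesion; a voxel
belongs to the rasterised sketch iff its centre lies inside a sphere
(inclusive). The refine step keeps sketch voxels at or above a threshold:

* absolute: SUV 2.5 (the conventional fixed cut);
* relative: `fraction × SUVmax(sketch)` with fraction 0.40 or 0.50;
* background-adaptive: `t_N = beta * I70 + Ibgd`.

`I70` is the mean uptake of sketch voxels *strictly* above 70 % of the
sketch maximum (an isocontour is defined by exceedance); every other
threshold comparison is inclusive (`>=`), because the methods are
described as removing voxels *below* the threshold. `Ibgd` is the mean
uptake of the voxels at physical distance `[12, 16) mm` from the 70 %
core — offsetting fixes the inner shell surface at 12 mm, the 4 mm
thickness extends outward — after discarding shell voxels with SUV > 2.5
(to avoid counting adjacent hot structures as background). The shell is
not restricted to the sketch: background lies outside the sketched lesion
by construction. If the exclusion empties the shell, `Ibgd = 0` with a
warning; this is conservative (lower threshold) and keeps batch runs
alive. `beta` is a scanner/reconstruction-dependent constant; 0.30 by
default, 0.15 is the common alternative.

No connected-component post-filter is applied to refine outputs: the
methods are pure filters. Refinement therefore never adds voxels, giving
the subset invariants the tests assert (`result ⊆ sketch`,
`rel50 ⊆ rel40`).

### Click-and-draw

Flood fill is implemented as connected-component extraction on the
boolean field `uptake >= threshold` (scipy `ndimage.label`), taking the
component containing the seed. Connectivity defaults to 6-neighbour face
adjacency — conservative against diagonal leakage through single-voxel
corners — and 26 is available. The two-pass algorithm: first pass at
`t × I(seed)` (t = 0.7 or 0.4); a guard rejects first-pass regions above
500 cm³ (the volume of the guard is printed with an area unit in the
method's source description; it is read here as a volume); the adaptive
threshold is recomputed on the first-pass region (its own 70 % core and
shell); the second pass starts at the region's maximum-uptake voxel, with
ties broken by smallest flat index in raster order for determinism.

The second flood fill deliberately runs over the whole volume, not just
the first-pass region: that is the published behaviour and reproduces the
known failure mode in which the final ROI escapes into adjacent structures.
`restrict_to_first_pass=True` confines it. If the recomputed threshold
exceeds the region maximum the final mask is empty (returned with a
warning, scored DSC 0 / RVD −100 %).

## Evaluation and statistics

DSC and RVD are computed on voxel counts; both masks share a grid, so this
equals the volume-based definition exactly. An empty estimate is a valid
outcome (DSC 0, RVD −100 %), not an error — failed delineations must enter
the cohort statistics. Cohorts are summarised as median ± sample SD
(n−1 denominator; SD of a single value is reported as 0). Pairwise
comparisons use the two-sided Mann–Whitney U test on per-case values
(unpaired, matching the benchmarked design), exact for small tie-free
samples and normal-approximated with tie correction otherwise
(scipy `method="auto"`); direction is taken from sample medians and only
reported when the pair is significant at the Bonferroni-corrected level
`family_alpha / n_pairs`, applied per metric family.

## Synthetic phantoms

The generator emulates the statistical structure of clinical FDG-PET
tumour images, not their anatomy: ellipsoidal uptake foci painted at a
peak SUV on a uniform background, Gaussian-blurred, with additive Gaussian
noise clipped at zero. Defaults and their reasoning:

* grid spacing 2.73 × 2.73 × 3.27 mm — clinical PET reconstruction grid;
* background 1.5 SUV — typical soft-tissue uptake;
* PSF FWHM 6 mm (8 mm in the blurred-cohort checks) — post-reconstruction
  resolution of clinical scanners; per-axis sigma = FWHM / (2√(2 ln 2)) /
  spacing;
* noise SD 0.2 SUV (cohort range 0.1–0.3) — ≈ 7–20 % coefficient of
  variation on background, typical of clinical body FDG-PET;
* lesion radii 5–33 mm — spans lesion volumes ≈ 0.5–150 cm³, the size
  range of head-and-neck primaries; peak SUV 4–20.

Ground truth is the **pre-blur** ellipsoid support: unambiguous, and the
closest analogue of anatomical truth. The seed point is the lesion-centre
voxel; the sketch is a circumscribing sphere at 1.5 × the lesion bounding
radius (the operator margin). Cohorts draw radius, peak and noise
uniformly from their ranges with one seeded generator and deterministic
per-case sub-seeds; identical seeds give bit-identical volumes.

What the phantom reproduces well: partial-volume blur, spillover of hot
signal into the background (the fixed SUV 2.5 threshold overestimates
every blurred lesion whose 2.5-SUV isocontour lies outside the true
boundary), threshold nesting, and the two-pass flood-fill behaviour.

What it does not reproduce: **intra-lesion heterogeneity**. Real tumours
contain hot spots that inflate SUVmax well above the typical lesion
uptake, which drags relative thresholds (40 %/50 % SUVmax) deep into the
lesion and produces the strong volume underestimation seen clinically. On
homogeneous blurred spheres the 0.5 × SUVmax isocontour sits almost
exactly on the true boundary: the outward shift from the background
pedestal nearly cancels the inward shifts from curvature and from the
noise-inflated maximum. The 50 % threshold's median RVD on simulated
cohorts is therefore only weakly negative (≈ −0.6 %, and positive for an
occasional cohort draw) rather than tens of percent; passing or failing a
sign check at cohort size 30 carries real sampling noise. Multi-ellipsoid
lesions with distinct peaks are supported in `PhantomConfig` for modelling
heterogeneity explicitly, but cohort simulation keeps the single-lesion
contract. Attenuation, scatter, organs and reconstruction artefacts are
out of scope.

## Problem sizes and numerics

The shipped checks run on grids of ~40–60³ voxels and cohorts of 30 cases,
which resolve all the physical effects above while keeping the full suite
in minutes on one CPU. Oracle-equivalence tests (flood fill vs
breadth-first search, distance field vs exhaustive pairwise distances,
Mann–Whitney vs permutation enumeration) use small grids and samples where
brute force is exact. Floating-point policy: thresholds compare with `>=`
exactly as stored; the Nestle identity `t_N = beta*I70 + Ibgd` holds to
the double-precision arithmetic of its stored operands; mask I/O stores
{0,1} uint8 with spacing in the NIfTI header.
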