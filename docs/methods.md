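# Methods

## Data model and geometry conventions

All masks live on a `VolumeGrid`: a 3D lattice with shape, positive
anisotropic spacing (mm per voxel per axis) and a world origin. The
internal axis order is `(x, y, z)`; NIfTI volumes are reoriented to the
closest canonical (RAS) frame on read, so downstream geometry never
depends on how a file was stored. Voxel coordinates are 0-based indices;
world coordinates are voxel-center positions in mm. Two masks are
comparable only when their grids agree within 1e-6 mm on spacing and
origin — grid mismatch is an error, never silently resampled, because the
protocol presumes co-registered mask pairs. Multi-label volumes require an
explicit label selection; there is no guessing which label is which
structure.

## Centerlines, radii, and the tolerance δ

Tubular masks are thinned to one-voxel-wide centerlines with
`skimage.morphology.skeletonize` (Lee's 3D medial-axis thinning,
26-connectivity). Thinning operates on the voxel lattice; anisotropy
enters through the radii: the maximum inscribed radius at a center voxel
is taken from a spacing-aware Euclidean distance transform of the mask.

The raw EDT value is the distance to the nearest *background voxel
center*, which overshoots the physical wall by roughly half a voxel, so
the radius is `EDT − min(spacing)/2`, clamped below at `min(spacing)/2`.
Consequences of this convention:

- a single-voxel mask has radius `min(spacing)/2` and diameter
  `min(spacing)`;
- for solid cylinders of radius 1–4 mm at the supported spacings
  ((1,1,1) and (0.75,0.75,1.0) mm) the estimated δ lands within half the
  minimum spacing of the true radius, and recovered diameters within one
  voxel diagonal of the truth (both are exercised by the test suite);
- scaling all spacing components by k scales radii, δ and diameters by k.

Any sub-voxel surface convention carries ±half-voxel ambiguity; the
tolerances above are what this one guarantees, not estimates of a better
bound.

δ is the arithmetic mean of the inscribed radii over the *correct* mask's
centerline voxels ("average maximum radius"). Averaging voxelwise (rather
than per-branch maxima or a global maximum) is stable, reduces to the tube
radius for constant tubes, and weights branches by their centerline
length. δ is computed per structure class per case; a fixed δ can be
supplied instead (`delta_mode="fixed"`). Thinning can annihilate
components smaller than its template; any mask component left without a
center voxel is re-seeded with its deepest (max-EDT) voxel so every
component contributes at least one. Optional spur pruning removes terminal
skeleton branches shorter than a length threshold; it is off by default —
the raw skeleton is the least surprising output — and exposed as a flag.

## Centerline counts and boundary conventions

Distances are Euclidean in world mm (δ is a length, not a voxel count).
The strict inequalities of the protocol (`< δ` for TPc, `> δ` for
FPc/FNc) leave distance exactly δ unassigned; here TPc uses `< δ` and the
complement (`≥ δ`) goes to FNc/FPc, so the partition is exhaustive and
`TPc + FNc = |Gc|` holds exactly.

The FPc exclusion region ("extracted peripheral vessels outside the
clinically annotated region do not count") is geometrically unspecified in
the protocol; here the ROI is the correct-mask volume dilated by
`roi_margin_mm` (default: δ), computed via the EDT of the mask complement.
Extracted centerline points outside the ROI are excluded entirely and
tallied separately (`n_pc_excluded`), so the exclusion is always visible.
When no correct mask is available the ROI falls back to the union of
maximum inscribed spheres along Gc, dilated by the margin.

Cross-structure true negatives: an extracted center voxel of one vessel
class counts as TNc when its distance to the other class's correct
structure is at least the *other* class's δ. The printed specificity form
`TNc/(TNc+FNc)` is the default; the conventional `TNc/(TNc+FPc)` sits
behind `form="conventional"`, and every report records which form was
used. Empty-versus-empty comparisons define Dice (and DSCc with all-zero
counts) as 1.0 — nothing to find, nothing found — flagged in the report.

Complexities: Gc↔Pc distances use a KD-tree (exactly the nearest-neighbour
distances a brute-force pairwise scan computes); the acceptance suite
checks count-level equality against an O(n²) reference on hundreds of
random instances.

## Phantom generator

The generator emulates the *geometry* the metrics see, not CT intensities
(the engine that turns CT into masks is out of scope, as are anatomically
named vessels):

- parenchyma: an ellipsoid, default semi-axes (18, 9, 7) mm;
- main duct: a gently curved tube along the parenchyma axis, default
  radius 2 mm (4 mm diameter — the median of the emulated cohort), with
  optional linear taper;
- artery and vein: stochastic binary-branching tube trees (depth ≤ 3,
  default root radius 2.2 mm, radius decay 0.75), laid out above and below
  the parenchyma. Branches carry peripancreatic vessel labels purely for
  interface testing of visual-score tables.

The default grid is 64×64×48 voxels at (0.75, 0.75, 1.0) mm — a 48 mm
cube at the protocol's CT resolution.

"Extracted" masks are the clean geometry passed through failure-mode
operators in a fixed order: tumor/atrophy/cyst carving (parenchyma) →
erosion/dilation → tube interruptions → branch drop → boundary noise. The
all-zero perturbation is the identity. Interruptions cut arc-length
windows out of a tube, so k interior gaps yield exactly k+1 connected
components; the generator refuses specs whose cuts cannot fit. Boundary
noise flips voxels within the given distance of the surface with
probability 0.3; amplitudes below one voxel cannot move any boundary on
the lattice, so the cohort baseline is 0.8 mm (~one voxel). Structures
must not overlap beyond a configured fraction of the smaller structure
(default 5%); violations are generation errors, not silent fixes.

Cohort-level draws follow the emulated study population: tumor size
uniform on 5–80 mm; head/body/tail location at 56/31/13; UICC stage at
the cohort frequencies (0/IA/IB/IIA/IIB/III/IV = 7/18/7/27/16/11/14);
duct diameter log-normal with median 4 mm truncated to 1–15 mm (σ_log =
0.512, putting 15 mm near the 99.5th percentile). Cancer cases receive
perturbation severity growing linearly with tumor size times a single
coefficient (default 1); controls get the mild baseline. At severity
coefficient 0 the two groups' perturbation distributions coincide. The
severity→failure-mode map draws tumor replacement, atrophy and cysts with
relative prevalences 40/35/20, mirroring the reported causes of poor
parenchyma extraction. Manual-vs-true duct diameter pairs come from a
bivariate log-normal whose Gaussian-copula correlation is solved in closed
form (ρ = ln(1 + r(e^{σ²}−1))/σ²) so the mm-scale Pearson r equals the
stated generator parameter (default 0.61).

What phantoms do *not* emulate: real parenchymal texture and contrast
variability, anatomically correct vessel topology, registration error
between contrast phases, and observer variability in the correct masks.
Passing tests therefore demonstrate that the metrics, tolerances and
statistics behave correctly on known geometry — not that any particular
engine reaches a given accuracy on patients.

## Statistics layer

Group comparisons use the unpaired two-sided t test, Welch form by
default (the safer default when variances differ); the pooled-variance
Student form is a flag, and the choice is recorded. Identical constant
values in both groups return p = 1.0 by convention. Fisher's exact test
and Pearson correlation wrap scipy; the acceptance suite pins Fisher
against an exhaustive hypergeometric enumeration on all 2×2 tables with
margins ≤ 30. Raw p-values are reported by default — matching the
protocol, which applies no multiplicity correction across its per-vessel
comparisons — with Holm adjustment available as an explicit opt-in.
Diameter agreement reports Pearson r and the mean signed error
(measured − manual, mm).

## Problem sizes and numerical choices

Tests and the acceptance script run phantom cohorts of 4–20 cases on the
default 64×64×48 grid and recovery families on ~40 mm cylinders; the
oracle-equivalence checks use grids ≤ 32³ with ≤ 1000 centerline points
per instance, sizes at which the brute-force references are exact and
fast. The severity ladder uses 5 rungs × 20 fixed-seed phantoms, with
interruption counts capped at 3 (the capacity of a ~28 mm tube with 3 mm
gaps and clean-separation spacing). All generators run through a single
`numpy` PCG64 stream per case, so fixed seeds give bit-identical masks.

## Known limitations

- Whether the protocol's center voxels come from lattice thinning or a
  vendor-internal vessel-tracking representation is unknowable; the
  thinning choice is documented and centerlines are exportable (TSV) for
  audit.
- The cross-class reading of the true-negative definition (and taking δ
  from the other class's correct mask) is the most coherent reading of an
  ambiguously worded definition; both choices are surfaced, not asserted.
- The spur-pruning walk is O(endpoints × branch length) in Python —
  adequate for per-case skeletons, not tuned for whole-body vasculature.
- No DICOM series assembly, no resampling/registration, no NRRD.
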