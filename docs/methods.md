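# Methods

## Scope and model overview

`elfdose` implements the computational chain of a stroke ELF-MF stimulation
analysis: seeded region-growing segmentation of the ischemic hyperintensity on
DWI (acute, pre-treatment) and T2-FLAIR (1-month, post-treatment) volumes;
voxel volumetry and the FLAIR−DWI mismatch / FLAIR/DWI rate endpoints;
clinical-score trajectories on NIHSS, Barthel Index and modified Rankin Scale;
and magnetostatic dosimetry of the single-turn rectangular stimulation coil
overlaid on the lesion. Patient imaging is replaced throughout by synthetic
phantoms with analytic ground truth; the published six-patient cohort table is
carried as a fixture whose derived endpoints are recomputed, not transcribed.

Out of scope by design: induced electric field, SAR or any
conductivity-dependent quantity (at 75 Hz tissue does not perturb B, so the
tissue conductivity σ = 1.7 S/m for edema is carried as metadata only);
anatomical head models; DWI physics; registration between the two time points
(none is performed in the workflow being modeled); inferential statistics.

## Segmentation

Each seed voxel `s` defines an inclusion band from its own intensity
`I_s`: voxel `v` qualifies iff `|I_v − I_s| ≤ t·I_s`, with `t = 0.20` by
default. The band is symmetric because a one-sided rule (`I ≥ 0.8 I_s`) never
terminates on the bright side of a hyperintensity; the one-sided variant is
available (`band="upper"`) for sensitivity analysis. The mask is the set of
voxels connected to the seed through qualifying voxels; the union is taken
over seeds, each with its own band. Connectivity is 8 in-plane by default
(4 selectable), and three growth topologies are offered:

* `2d` — the region stays in the seed's axial slice (one seed per section,
  the strict section-by-section reading);
* `2d_propagate` (pipeline default) — sections are grown in-plane, and the
  grown footprint seeds the adjacent sections, iterating until no new section
  joins. This models an operator who segments every section of a lesion from
  one click, and it reduces to `2d` for a single-slice lesion;
* `3d` — full-volume growth (26-connectivity for the 8-connectivity setting).

The implementation labels the connected components of the band predicate with
`scipy.ndimage.label` and selects the component(s) reachable from the seed;
this is equivalent to flood fill but makes the result manifestly a function of
the reachable set, hence invariant to seed order and traversal strategy (the
test suite checks it against an independent BFS/DFS graph oracle, in both
orders). Intensities are used as stored; no normalization or bias-field
correction is applied because none is part of the modeled workflow.

Manual editing is modeled as `(mask ∪ add) \ remove`, with remove winning on
conflict. Volume is `N · p_x · p_y · h` (voxel count times pixel spacing times
slice thickness), reported in cm³; an empty mask yields 0.0 with a warning.

Seed-intensity sensitivity: because the band is relative to the seed voxel's
*noisy* value, a single seed drawn far below the lesion mean narrows the
effective band and can under-segment substantially (a 2.7 σ-low seed at 5%
noise loses ~20% of the volume). The operator model therefore seeds a small
in-plane neighborhood (center voxel plus 4-neighbors) when noise is present;
with per-seed bands and union semantics this is robust, since all seeds must
be unlucky simultaneously. Noiseless growth from the single center seed
recovers the ellipsoid truth mask exactly.

## Volumetric and clinical endpoints

`mismatch = V_FLAIR − V_DWI` and `rate = V_FLAIR / V_DWI` are computed at full
precision and rounded half-away-from-zero to 2 decimals only in reports (the
printed-table convention; bankers' rounding would differ on exact ties).
Evolution is `reduced` / `grew` for strictly negative / positive mismatch;
an exact zero is classed `unchanged` rather than forced into either bin.
Score changes are follow-up minus baseline; missing visits propagate as
absent (pandas NA in reports), never as zero, and group summaries count
available cases.

Two printed rate cells (patients 1 and 3) are inconsistent at the last digit
with the ratios of the printed volumes (the published analysis evidently
divided unrounded volumes); the fixture flags them (`rate_consistent`) and
exact checks cover the consistent cells only. Patient 1's clinical-score row
is ambiguous in the extracted source table; its best-effort parse is stored
with `scores_verified=False` and excluded from asserted values.

## Coil field

The coil is an ideal zero-cross-section filament polyline carrying
`I = 240 A`, default geometry a flat 0.14 × 0.106 m rectangle centered at the
origin in the x–y plane with axis +z (into the head). Each straight segment
contributes the exact closed form

    B = μ₀ I / (4 π ρ) · (cos θ₁ − cos θ₂) · ĉ

where ρ is the perpendicular distance to the segment's line, θ₁, θ₂ the
angles subtended at its endpoints, and ĉ the unit direction of `a × r₀`.
Because the kernel is exact per segment, a flat rectangle needs only its 4
corner segments; discretization (default 720 segments) matters only for the
warped coil. Collinear exterior points receive exactly zero; points within a
1 mm guard of the conductor raise a singularity error rather than being
regularized — no legitimate field point in this use case is that close.

Closed-form oracles: center field `μ₀I√(a²+b²)/(πab)` (2.2719 mT for the
default coil — the device's "about 2 mT" operating point) and on-axis field
`μ₀Iab/π · [1/(a²+z²) + 1/(b²+z²)] / √(a²+b²+z²)`, which decays as the
dipole 1/z³. The test suite checks the segment kernel against adaptive
quadrature of the raw Biot–Savart integrand (10⁻⁶ relative), the closed
forms (0.5%), the infinite-wire limit, current linearity, sign reversal
under orientation flip, monotone axial decay, and a central-difference
∇·B ≈ 0 check.

Head-curvature warp: the 14 cm dimension is wrapped arc-length-preservingly
onto a cylinder of radius R (default 90 mm, configurable — the mean coronal
head curvature is not recoverable exactly, so the radius is exposed), cylinder
axis along the coil height direction:
`(x, y, 0) → (R sin(x/R), y, R(1 − cos(x/R)))`. The flat coil is recovered as
R → ∞; segment lengths are preserved to within chordal discretization error
(< 0.1% at ≥ 400 segments). No claim is made that warping increases or
decreases the center field — only length preservation and the flat limit are
asserted.

The drive waveform is a rectangular pulse train: 75 Hz, 1.3 ms pulses
(duty fraction 0.0975), 1.8 mT measured peak with ±2 Hz / ±0.2 mT device
tolerances carried as metadata. The simulated coil's 2.27 mT center field and
the measured 1.8 ± 0.2 mT device peak are both reported; no reconciliation is
attempted.

## Lesion dosimetry

Distances are Euclidean from the coil center point to lesion voxel centers
(the convention of the published table), reported in cm; a nearest-vertex
"surface" mode exists for sensitivity analysis. Field extrema are min/max |B|
in mT over lesion voxels, with the fraction of voxels at or above the
threshold (default 1.0 mT, the preclinical A2A-upregulation level). The
biological-threshold check is peak-based and inclusive: pass iff
`b_max ≥ threshold`.

Per-patient published Bmin/Bmax cells are **not** reproduced cell-by-cell:
they depend on patient-specific anatomy and warped-coil placement that cannot
be reconstructed. The package validates the field model by physical
properties instead (kernel vs quadrature, closed forms, limits, divergence,
warp convergence) and checks the published column aggregates (lesion field
range 1.0–2.2 mT, distance range 1.6–6.7 cm) from the fixture. Note the
discrepancy this leaves open: an on-axis flat-coil model gives ≈ 0.79 mT at
6.7 cm, below the published 1.0 mT minimum, so the published geometry
(warped coil, off-axis anatomy) evidently differs from the idealized flat
model; the package documents rather than tunes away this gap.

## Synthetic phantoms

A phantom is a uniform background (default intensity 100) containing one
axis-aligned ellipsoidal lesion (default intensity 200, i.e. 100% contrast)
plus additive Gaussian noise (default SD 5, 2.5% of lesion intensity), on a
grid defaulting to 164 × 238 × 178 mm (1 × 1 mm in-plane, 2 mm slices) — the
head subdomain used by the dosimetry simulations. Gaussian rather than Rician
noise is used: the segmentation rule is intensity-relative and at the tested
contrasts the distinction is immaterial. Truth membership is
voxel-center-inside-ellipsoid with an inclusive boundary, matching an exact
brute-force oracle; no partial-volume weighting. Pre/post pairs share grid
geometry (one session geometry) while lesion size may differ; all randomness
flows from `numpy.random.default_rng(rng_seed)`, so identical specs are
bit-identical.

Discretization of the truth volume: at 1 mm isotropic spacing the mask volume
sits within ~1–2% of `4/3·π·abc` for generic lesion-center alignments. When
the center (or a half-voxel offset of it) places boundary voxel centers
exactly on the ellipsoid surface, the inclusive rule counts them all and the
error can exceed 2% and oscillate between refinement levels; tests and
examples use generic off-lattice centers. What phantoms do not emulate:
lesion texture heterogeneity, mass effect, partial-volume edges, Rician noise
floors, bias fields, or inter-sequence misregistration — so passing recovery
tests demonstrate correctness of the growth rule and volumetry, not clinical
segmentation accuracy on real MRI.

## Pipeline

Configuration is YAML with a versioned `schema` key; unknown keys are
rejected by name, defaults are filled (`rel_threshold` 0.20, coil
0.14 × 0.106 m at 240 A, threshold 1.0 mT), and exactly one of real inputs
or a phantom spec must be present (real inputs also require seeds). The coil
is placed with its axis along image +z, centered in-plane on the pre-treatment
lesion centroid, its plane `standoff_mm` (default 2 mm, modeling strap and
casing) outside the grid's z = 0 face — i.e. as close to the head surface as
the standoff allows with the lesion on the coil axis; an explicit
`coil.center_mm` overrides this. Outputs are NIfTI (volumes, masks, |B| in
mT) and CSV (UTF-8, decimal points) plus a JSON manifest echoing the full
config, seed and package version; stage failures abort with the stage name
and remove partial outputs. CSV outputs are byte-identical across reruns of
the same config and seed.

Problem sizes in the shipped tests and examples (48³-scale phantoms, 32³
random grids, 20 noisy replicates, 7³ divergence stencils) were chosen as the
smallest sizes at which each property is non-trivially exercised; all scale
up linearly through the same interfaces.
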