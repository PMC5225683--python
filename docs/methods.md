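# Methods

## The segmentation model

`liverwalker` segments the liver on contrast-enhanced axial CT as a
sequence of 2D seeded random-walker problems. The walker model: build an
undirected graph G = (V, E) whose nodes are the pixels of one slice, with
4- or 8-neighbour edges. Each edge e_ij carries a weight

    w_ij = exp(-β (g_i − g_j)²)                       intensity similarity
    w_s  = exp(-((x_i−x_j)² + (y_i−y_j)²) / λ_s)      spatial locality
    W_ij = w_ij · w_s + ω,

with g the display-windowed intensities in [0, 1]. W_ij is the relative
ease with which a walker crosses the edge: high β makes intensity steps
nearly uncrossable, so labels follow strong edges; at β = 0 the weights
are uniform and labels are decided purely by seed geometry. The additive
floor ω keeps every edge crossable so the linear algebra never degenerates
(it penalises the gradient norm of the solution; ω = 0 disables it).

For a set of seeded pixels v_m (labels L = liver, other, lesion…) and
unseeded pixels v_u, the probability P^L_i that a walker from pixel i
first reaches an L-seed is the harmonic function with boundary values 1 on
L-seeds, 0 on other seeds — the combinatorial Dirichlet problem. Writing
the graph Laplacian (degrees d_v on the diagonal, −W_ij off it) in block
form over (v_m, v_u), the unseeded probabilities solve the sparse,
symmetric positive-definite system

    L_U x_U = −Bᵀ m_L ,

one system per label except the last: probabilities sum to one at every
node, so the final label is the complement (L − 1 solves for L labels).
Pixels take the argmax label; ties break to the lowest label id; seeded
pixels keep their seed label.

Solver: sparse LU factorisation (SuperLU) up to 10⁶ unknowns, conjugate
gradients with an incomplete-LU preconditioner beyond, relative-residual
contract ‖L_U x − b‖/‖b‖ ≤ 1e-6 (CG tolerance 1e-8). Components that
contain no seed (possible only on degenerate graphs) receive uniform
probabilities and are logged. Probabilities are clipped to [0, 1] and
renormalised per node to absorb round-off.

Segmentation is strictly per 2D slice, with 3D coherence supplied by
slice-to-slice seed propagation; this keeps each linear system small and
matches the slice-sequential design of the surrounding pipeline.

## Pipeline stages and their parameters

**Preprocessing.** Canny edges (σ = 1.0; high threshold from Otsu on the
Sobel gradient, low = 0.4·high) are closed with a disk of radius 3 and
filled; the largest 8-connected filled region is the body, everything else
becomes air (−1000 HU). If the edge chain fails to enclose the body (the
edge-bounded region is < 50 % of a density-thresholded body at −500 HU),
the thresholded body is used instead — an edge gap otherwise collapses the
mask onto an internal structure. Two processed images are kept per slice:

* a *statistics image* (background removal + 3×3 median) used for every
  intensity decision — lung threshold, liver band, seed candidates, lesion
  outliers, rib threshold;
* an *edge image* (removal + top-hat/bottom-hat under a disk of radius 5 +
  median) fed to the walker's weighting.

The split matters: the hat enhancement sharpens edges but roughly doubles
the noise deviation (liver ±15 HU → ≈ ±20 HU), which would smear the
calibrated liver band into the soft-tissue range and corrupt seeding. The
median filter replaces each pixel by the median of its in-bounds 3×3
neighbourhood; it never invents values, so edges do not move.

**Dome detection.** Right lung = largest connected component below
−400 HU inside the body whose centroid lies in the patient-right (image
left) half; a flip flag covers non-standard orientation. The liver dome is
the first slice i+2 with area[i+1] ≤ 0.9·area[i] and
area[i+2] ≤ 0.9·area[i+1] (threshold configurable, default 10 %). The rule
tolerates missing one small dome slice; robustness is preferred over
catching every dome voxel.

**Ribcage masking.** Bone components (> 200 HU inside the body, area
20–2000 px) reduce to centroids ordered by polar angle around the body
centroid. A closed *cubic* B-spline (the configured "order 3" is
implemented as degree 3 with a periodic uniform knot vector; the curve is
C², which is what "smooth closed curve" requires) is evaluated by De
Boor's recursion at 360 parameters and rasterised by polygon fill;
everything outside becomes air. Slices with < 4 centroids, or whose
interior area falls below 70 % of the previous slice's, are refit with the
union of the neighbouring slices' centroids; if that also fails the slice
passes through unmasked with a warning.

**Extent calibration.** The two slices after the dome are segmented with
template seeds (the right-lung mask of slice dome−1, eroded 3 px,
restricted to 60–200 HU — a plausible contrast-enhanced-liver range used
only before calibration). Their liver pixels give the liver band
mean ± k·deviation (k = 2). The template then masks all remaining slices;
per-slice counts of in-band template pixels give the middle slice (argmax,
earliest on ties) and the last slice (first count < 100 after the middle —
the caudal liver tip is ~100 px on 512×512 CT — else the final slice).

**Seeding.** Budget: ≤ 1200 seeds per slice, ≤ 600 liver-side (liver +
lesion labels) and ≤ 600 other. Candidates are thinned onto the coarsest
regular sub-grid that fits the budget — fully deterministic, no RNG, and
seeds can never overlap. Initial slices: liver candidates = eroded
template ∩ intensity band (3×3 opening removes isolated noise pixels that
sneak into the band); other candidates = body outside a 5-px dilation of
the liver candidates. Later slices: liver candidates = 3-px-eroded
previous liver envelope, again intersected with the band — without the
band restriction, a liver cross-section that retreats faster than the
erosion margin leaves liver seeds stranded in soft tissue and the
segmentation grows without bound. Lesions: connected in-liver outliers
(|HU − mean| > 2·dev, ≥ 30 px) found inside the 3-px-eroded previous
liver region get the lesion label (replacing any liver seeds there); the
erosion keeps the search interior so a partial-volume or overshoot rim at
the region boundary is never mistaken for a lesion. The final liver mask
is the envelope: union of liver and lesion labels.

**Walker defaults.** β = 500 on windowed [0, 1] intensities, ω = 1e-6,
λ_s = 2.0, 8-connectivity, spatial term on. β was calibrated on the
phantom's contrast (liver/soft-tissue step ≈ 0.17 in windowed units over
noise ≈ 0.05): at β ≈ 90 the per-edge boundary-to-interior weight ratio is
only ~10 and the liver label creeps 1–3 px past the edge wherever liver
seeds sit closer to the boundary than other seeds — an error that
propagation compounds into runaway growth; β = 500 makes the boundary
effectively uncrossable while interior noise edges stay passable. The
abdominal display window defaults to level 40 / width 400 HU; a config
flag switches the walker to min-max-normalised raw HU instead.

## The phantom generator

The synthetic CT phantom renders, at any grid size (fractional geometry;
512×512 default, 256×256 for the reduced presets), exactly the structure
the pipeline's rules key on: air background (−1000 HU), an elliptical
soft-tissue body (40 HU) with a detached imaging-table arc, two −700 HU
lungs whose area tapers 1.5 %/slice and then drops 22 % and 100 % across
the dome transition (so the dome rule fires at the configured slice and
never earlier), a 100 ± 15 HU liver under the right lung growing linearly
in area to the configured middle slice and shrinking to a < 100 px tail at
the configured last slice, twelve 700 HU ribs on a ring at 87 % of the
body radius, and optional spherical lesions at liver − 60 HU. Noise is
independent Gaussian per tissue (air 5, lung 10, soft 10, liver 15, bone
20 HU), drawn from a recorded seed; the same spec is bit-reproducible.
Presets: healthy, single-lesion, multi-lesion (three lesions, one
straddling the liver boundary), rib-poor-slice (one mid-liver slice keeps
3 of 12 ribs, exercising the spline fallback), low-contrast
(liver−soft = 15 HU).

What the phantom does *not* emulate: partial-volume ramps at organ
boundaries, beam-hardening/streak artifacts, anatomical shape variability,
vessels, adjacent organs of near-liver attenuation (spleen, stomach wall),
and respiratory deformation. Passing the phantom therefore demonstrates
the pipeline's logic — stage order, rules, budgets, solver — and its
behaviour under Gaussian noise, not clinical-grade accuracy; the
low-contrast preset probes the failure direction clinical data would
stress but has no accuracy bar attached.

## Numerical and design choices

* Intensities are normalised to [0, 1] before weighting so β is
  image-independent.
* The intensity and spatial weight factors combine multiplicatively (the
  standard bilateral form); ω is an additive floor.
* Direct vs iterative solve switches at 10⁶ unknowns; every solve is
  checked against the residual contract and failures mark the slice
  failed rather than aborting the series (propagation then falls back to
  the last good slice).
* Degenerate inputs: uniform-air slices yield an empty body mask and pass
  through; a slice with all candidates seeded labels the effective body
  liver outright; collinear rib centroids raise a degenerate-curve signal
  and trigger the neighbour fallback.
* Mask I/O is NIfTI (uint8/uint16) through nibabel with the reference
  geometry; DICOM series are sorted superior→inferior by z-position with
  rescale slope/intercept applied; non-axial acquisitions are rejected.
* The reduced 40×256×256 presets are used for the end-to-end test suite
  and the acceptance script; the geometry is fractional, so the same specs
  render at 512×512 via the `shape` argument (the `phantom` CLI defaults
  to full size).

## Known limitations

* The walker runs per slice; a lesion or liver lobe that appears abruptly
  with no overlap to the previous slice's segmentation will not be seeded
  and is missed until it overlaps.
* Lesions touching the liver boundary are recovered only where they look
  different from the adjacent exterior tissue; their outer rim is
  genuinely ambiguous under an intensity-only model.
* Intensity calibration assumes the two slices after the dome contain
  representative liver tissue; a dome slice dominated by vessels or a
  large dome-adjacent lesion would bias the band.
* β is calibrated for contrast-enhanced abdominal windows; unenhanced CT
  (liver/soft contrast ≪ 60 HU) will need a different window or β.
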