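# Methods

## Curve model

Boundaries are closed polylines of continuous points in pixel coordinates
(x = column, y = row, origin at the center of the top-left pixel).
Contours are canonicalized to counterclockwise orientation (positive
shoelace area in the (x, y) plane) on construction, keeping the first
point first, so downstream mesh indexing is deterministic regardless of
how the input was drawn.

Smooth curves are piecewise Hermite cubics: segment k runs between control
points P_k and P_{k+1} with endpoint tangents u_k, u_{k+1}, blended by the
four cubic basis polynomials (2s³−3s²+1, −2s³+3s², s³−2s²+s, s³−s²).
Tangents are Catmull–Rom central differences, u_k = c·(P_{k+1} − P_{k−1})
with periodic indexing and tension c = 0.5 by default. Central-difference
tangents are what make editing *local*: moving one control point changes
only the four curve segments whose endpoints or tangents involve it.

**Sampling convention.** Segments are sampled at s = 0, Δs, …, 1−Δs —
the end point is excluded so chained segments share no duplicate joints —
giving round(1/Δs) points per segment (10 at the default Δs = 0.1). An
inclusive convention would give 11 points and duplicate every joint in the
concatenated curve; endpoint exclusion keeps the count at 10 and the curve
free of zero-length edges.

Uniform arc-length resampling interpolates linearly on the existing
polyline edges; total arc length is preserved to within one interpolation
step.

## Snake evolution

The external potential is E_ext = −|∇(G_σ ∗ I)|² on the [0, 1]-normalized
image: Gaussian smoothing (std σ, replicated borders) followed by
central-difference gradients, so edges are minima. The force is the
negative central-difference gradient of E_ext, bilinearly interpolated at
the (continuous) snake points; points outside the grid are clamped to the
border rather than propagating NaNs.

The internal energy is discretized with plain first/second differences
under periodic indexing, normalized by the point count — the uniform
parameter spacing is absorbed into α and β. A consequence worth knowing:
the effective stiffness scales with the squared inter-point spacing, so
the *number of points* on the snake is a real parameter. Coarse snakes
(large spacing) contract strongly and can cross weak edges; fine snakes
barely move under elasticity alone.

The descent equation ∂p/∂t = αp″ − βp⁗ + κf is discretized
semi-implicitly: internal terms implicit through the cyclic pentadiagonal
operator A = −αD₂ + βD₄ (D₂, D₄ the periodic difference circulants),
external force explicit,

    (I + τA) p_{t+1} = p_t + τ·κ·f(p_t).

Because A is circulant, (I + τA) is diagonalized by the DFT once per run
and each step costs two FFTs; this is numerically identical (to ~1e−13 in
the tests) to assembling and solving the dense system, and is
unconditionally stable for the stiff internal terms. Evolution stops when
the maximum per-point displacement falls below `tol` (default 0.1 px) or
after `max_iter` steps (default 50, on the premise of a near
initialization; set 200–300 for cold starts). A guard aborts with a
diagnostic if any coordinate leaves the image by more than 10% of its
extent.

**Default parameters.** α = 0.1, β = 1.0, σ = 2 px, τ = 1, tol = 0.1 px,
max_iter = 50, force multiplier κ = 30. The external energy is quadratic
in the image gradient, so on a [0, 1] image its magnitude is O(10⁻²);
κ = 30 rescales the edge force to balance the internal terms. These
defaults were calibrated once on the blurred-disk phantom (the package's
reference operating condition: radius 60 in a 256² image, edge blur 2 px,
48-point snake) such that a contour initialized 6 px outside the boundary
is captured and converges within the 50-iteration cap; all are exposed on
`SnakeParams`. There is no reparameterization during evolution; apply
`resample_uniform` beforehand (the pipeline and tracker do this) to avoid
point bunching.

## Multiscale editing

Level L places base_count·2^(L−1) control points at uniform arc length on
the contour, starting at its first point; refinement inserts the
arc-length midpoint of every consecutive pair, so counts double and
spacing exactly halves per level, and refining twice reproduces direct
generation two levels up. On a closed curve, midpoint insertion
necessarily maps n → 2n points. The default base_count is 13,
configurable; a mesh can never be finer than the contour it was generated
from.

Edit scripts are the declarative stand-in for mouse drags: each edit names
a (level, index) and either an absolute target (what a drag produces) or a
displacement (convenient in tests); at most one edit per control point.
Applying a script moves the points, recomputes tangents, and re-fits the
full closed Hermite curve; unedited segments more than two mesh spacings
away are bit-identical to the no-edit refit (local support). The refit
contour replaces the boundary and is the source for any further mesh
generation, matching the iterative revise-then-refine workflow.

Boundary error metrics: symmetric Hausdorff distance between contour
point sets, mean nearest-point distance, and mean radial error against a
reference circle (for disk phantoms). Point-set Hausdorff includes the
sampling gap of coarse contours; compare densely sampled contours when
sub-pixel boundary error is the quantity of interest.

## Slice propagation

`track` evolves the snake on each slice in order, carrying the returned
contour of slice i forward as the initialization of slice i+1 — valid
when the inter-slice boundary change is within the snake's capture range
(a few pixels at σ = 2). Per-slice edit scripts, keyed by slice id, are
applied after evolution and before the carry. By default each per-slice
result is resampled to uniform spacing at the initial point count;
iterated snakes otherwise accumulate point bunching. Reverse traversal is
a flag.

## Phantoms

Phantoms are bright objects (default fg 0.8) on a darker background (bg
0.2) with a Gaussian-blurred edge (default 2 px) and optional additive
zero-mean Gaussian noise, clipped to [0, 1]; the 0.3 headroom below 1.0
keeps clipping from biasing the noise statistics at the default noise
levels. All randomness flows through one explicit integer seed
(`numpy.random.default_rng`); a phantom is bitwise reproducible from its
meta record. Ground truth is a dense (720-point) polyline: an exact circle
for disks, the star polygon sampled evenly per edge with vertices
retained.

Rasterization is anti-aliased over one pixel of signed distance to the
true boundary (intensity ramps linearly across the edge) rather than
hard-thresholded. Binary rasterization leaves half-pixel jaggies that
survive blurring as intensity errors of order 10⁻¹ near the edge and
would dominate rotation-symmetry and gradient-localization checks; the
signed-distance ramp makes the noiseless image rotation-equivariant to
better than 1% of the intensity range.

What the phantoms do *not* emulate: multiplicative/speckle noise
statistics of ultrasound, intensity inhomogeneity, textured interiors,
neighbouring distractor structures, and anisotropic slice spacing.
Passing phantom tests therefore demonstrates the machinery (energy
descent, capture range, editing, tracking) under controlled contrast and
noise — not clinical-grade robustness.

## Study conditions used by tests and the acceptance script

- Disk recovery: noiseless blurred disk (radius 60, 256²), 48-point
  circular initializations at radius 66 (near) and 110 (far), default
  parameters. Near must converge with mean radial error < 1.5 px; far
  stays > 5 px under the same 50-iteration budget — the snake's
  documented initialization sensitivity.
- Star: 5 tips, r_outer 80, r_inner 45, blur 2. The snake starts from the
  5%-dilated truth at 144 points (the finer sampling keeps stiffness low
  enough to follow the concave edges; tips are still rounded by ~5 px —
  the high-curvature failure mode). The corrective level-3 edit script
  (52 control points) snaps each polygon vertex's nearest control point
  onto the vertex and every other control point farther than 0.5 px from
  the truth onto its nearest truth point — the scripted equivalent of a
  user dragging the visibly wrong points — bringing the Hausdorff error
  below 1.5 px.
- Tracking: 5-slice cylinder (radius 60, per-slice noise 0.02, fresh seed
  per slice) and 5-slice cone (radius 60 → 52), both tracked from a
  single radius-66 initialization.

These sizes keep the full suite and the acceptance script to a few
seconds of CPU.

## Known limitations

- The snake uses a fixed external field; no gradient vector flow, balloon
  force, or level-set variant, so deep concavities beyond the Gaussian
  capture range are unreachable without editing.
- Effective internal stiffness depends on point count (spacing absorbed
  into α, β); results are comparable only at a fixed sampling.
- Edit indices refer to the mesh of the contour they were authored
  against; regenerating a mesh after large edits renumbers control points.
- Volumes are processed strictly 2D; no 3D surface regularization across
  slices.
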