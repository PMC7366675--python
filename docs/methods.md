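# Methods

## Problem and model

Temporal-interference (TI) stimulation drives two electrode pairs with
sinusoidal currents at nearby kilohertz frequencies f1 and f2.  At a point
where the two fields E1 and E2 are both substantial, the superposed field

    E(t) = alpha E1 sin(2 pi f1 t) + beta E2 sin(2 pi f2 t)

is amplitude-modulated at the beat frequency f_TI = |f2 - f1| (10 Hz at the
default 2 kHz / 2.01 kHz carriers).  Neurons are assumed insensitive to the
kilohertz carriers but responsive to the low-frequency envelope, so the
quantity of interest at every node is the maximal envelope modulation depth
over all spatial projection directions,

    A = 2 max_theta min( ||E1|| |cos theta|, ||E2|| |cos(theta - phi)| ),

with phi the angle between E1 and E2 and theta restricted to their common
plane, where the maximum is attained.  Montage optimization maximizes the
peak ratio PR = A_target / A_cortex — the peak envelope amplitude inside a
deep target region divided by the peak over the cortical compartment —
subject to A_target > 0.2 V/m, a published threshold for entraining
endogenous oscillations.  An alternative objective maximizes A_target
subject to PR > 1.

## Head model

Real MRI-derived anatomy is out of scope; the geometric substrate is a
five-shell concentric sphere (scalp / skull / CSF / gray / white at outer
radii 92 / 86 / 80 / 78 / 70 mm) with isotropic conductivities 0.465, 0.010,
1.654, 0.276 and 0.126 S/m — typical literature values, all configurable.
The deep target is a 6 mm ball centred 55 mm below the vertex (radius 37 mm),
inside white matter on the sphere but playing the role of the hippocampus
head; being surrounded by gray/white tissue its conductivity is that of the
compartment it sits in, and the "cortex" of the peak ratio is the whole
gray-matter shell minus the target ball.  Peaks are evaluated at all nodes
of these compartments (volumes, not surfaces).

The mesh generator extrudes a single spherical surface triangulation (convex
hull of a Fibonacci point set at the requested ~edge-length spacing) through
a radial ladder containing every interface radius, so every element conforms
to the tissue interfaces exactly and element labelling by centroid radius is
exact; the ball inside the innermost interface is filled by a Delaunay mesh
over the shared interface points plus a seeded, jittered cubic lattice
(whose hull facets coincide with the surface triangulation).  At the default
10 mm edge length the five-layer head has ~12k nodes / ~68k tetrahedra and
every shell volume is within 0.5% of its analytic value; the generator
refuses edge lengths more than 5x the thinnest shell (elements spanning the
shell would be badly distorted).  All randomness flows from the single mesh
seed.

Electrodes are 10 mm diameter, 2.5 mm thick cylinders at 1 S/m, extruded
radially from the scalp as one-element-thick prism stacks whose bottom
triangles are original scalp-surface facets.  Because the surface sampling
is ~edge-length spaced, the footprint is the set of scalp triangles whose
centroid lies within max(diameter/2, 1.2 x edge length) arc distance of the
electrode axis — at coarse resolutions the effective contact is somewhat
larger than the nominal diameter, which matters only locally (fields are
rescaled to the injected current, and deep fields are insensitive to contact
size).  Candidate centres follow a deterministic golden-angle spiral over
the upper hemisphere — a fixed angular scheme approximating 10–10 coverage
for any candidate count — and the reference sits low-lateral at 115 deg
polar angle, the spherical analogue of the left mastoid.

## Forward solver

The quasi-static Laplace equation -div(sigma grad V) = 0 is discretized
with first-order tetrahedral elements.  One solve per candidate electrode
imposes +1 V on the top surface of that electrode and -1 V on the reference
top, by exact row/column elimination.  The reduced symmetric
positive-definite system is factorized directly (sparse LU); at this
package's problem sizes (<= ~1e5 nodes) a direct solve is faster than a
preconditioned iterative one, bit-deterministic, and leaves residuals near
machine precision (the solver still records the residual and enforces the
1e-10 default tolerance).  Element fields E = -grad V are constant per
element and volume-weight-averaged to nodes.

The injected current is evaluated as the variationally consistent (Galerkin)
flux: the assembled residual K V summed over the electrode's constrained top
nodes.  This equals the discrete flux through the scalp contact exactly and
is conservative across electrodes to machine precision, whereas naive
per-facet quadrature of the piecewise-constant field underestimates the
edge-concentrated contact current severely (by ~3x at the default
resolution).  Fields are then rescaled by (1 mA / computed current), so each
stored lead field is the field per 1 mA injected; by linearity one
real-valued solve serves all frequencies (conductivity dispersion at kHz is
ignored) and any montage field is a superposition of two stored lead fields.

### Validation against the analytic sphere series

For a homogeneous sphere with point source/sink electrodes on the surface
the interior potential is the classical Legendre series
V = I/(4 pi sigma R) sum_n ((2n+1)/n)(r/R)^n [P_n(cos g_src) - P_n(cos g_snk)].
Two numerical points: (i) the series convergence check requires two
successive small increments, because symmetric layouts zero out alternate
terms; (ii) FEM and series are compared after removing each solution's mean
over the query set — the Dirichlet drive pins the FEM potential level
through the two (mesh-dependent) contact resistances, while the series fixes
its level through a vanishing monopole moment, so the two gauges differ by a
constant.  Comparisons use interior nodes (r < 0.55 R, > 40 deg from the
electrode axes) where the finite-disc contact model and the point-source
idealization agree; at edge lengths 14 / 10 / 7 mm the normalized L-inf
error falls monotonically to ~1.2%.

## Envelope evaluation

The closed form used everywhere orders the two field norms u >= v and folds
phi into [0, pi/2] (the max–min expression is invariant to sign flips of
either field): if v <= u cos phi the weaker field lies inside the stronger
field's cone and A = 2v; otherwise the two projection amplitudes cross and
A = 2 ||E1 x E2|| / min(||E1 - E2||, ||E1 + E2||).  The vector form is
evaluated stably: cross products and difference norms come straight from the
vectors, the branch test compares products rather than a rounded cosine with
a 1e-12 relative slack (the branches agree to that order at the boundary),
and the crossed branch is clamped by its supremum 2v, which removes the
catastrophic cancellation otherwise suffered in the near-collinear limit.
Fields below 1e-14 V/m give A = 0.

Two independent oracles check the closed form.  A uniform theta-grid
maximization is a strict lower bound converging as the grid refines; because
the maximizer sits at a kink of the min(), the grid resolves it only to
~pi/n_theta, so 1e-6 relative agreement needs ~4e6 grid points.  A
time-domain route samples E(t) (0.5 s at 100 kHz), projects onto 181
in-plane directions, extracts each projection's Hilbert-envelope and takes
the peak-to-trough depth, discarding 10% of samples at each end against
transform edge artifacts; it agrees with the closed form to <1%.  The
single-frequency (tACS) amplitude is ||alpha E1 + beta E2||, which the same
time-domain machinery reproduces with its peak-envelope measure at f1 = f2.

## Exhaustive search

The search space is every 4-subset of candidates (lexicographic), each in
its 3 pair matchings in a fixed order, each over the current grid alpha in
{0.50, 0.55, ..., 1.50} mA with beta = 2 - alpha (built in integer
hundredths so the sum is exact); 61 candidates give C(61,4) = 521,855
subsets.  Lead fields are first restricted to the target + cortex nodes —
the only nodes either peak can live on.  Per montage the per-node norms,
|cos phi| and sin phi of the two pair fields are computed once and the
closed form is evaluated for the whole current grid as one array operation;
the winner is the feasible objective maximizer, ties broken by enumeration
order (first wins).  An infeasible search returns the unconstrained best,
flagged, so batch comparisons never abort.  The full-head pattern of the
single winner is recomputed afterwards for export.  The fast path is tested
to agree with naive nested loops over single-montage evaluations, and the
frequency-to-pair assignment is immaterial because the current grid is
symmetric (asserted by test).

## Comparison conditions

* Unoptimized TI: montage chosen by exhaustive search maximizing A_target
  on a conductivity-homogenized copy of the head (one tissue conductivity,
  0.276 S/m by default; electrodes keep 1 S/m), with fixed 1 mA + 1 mA, then
  re-evaluated on the heterogeneous head — both pairs searched jointly over
  the same montage space.
* Single-frequency tACS: the optimized montage and currents, both pairs in
  phase at one low frequency; amplitude = ||alpha E1 + beta E2||.
* Constrained multi-electrode tACS: per-electrode currents I (reference
  included via current conservation) maximizing the directional field at the
  target's centre-most node subject to sum(I) = 0, sum|I|/2 <= 2 mA and
  |I_i| <= 1 mA.  For each of 162 unit directions (subdivided icosahedron)
  the problem is a linear program (HiGHS); the best direction is reported.
  The direction fan is a documented discretization of the
  maximize-field-magnitude objective.

## Problem sizes and defaults

The shipped demo uses 16 candidates at 10 mm edge length — C(16,4) x 3 x 21
= 114,660 envelope evaluations over ~4,000 ROI nodes, which completes in
well under a minute together with its 2 x 17 FEM solves; the full
61-candidate configuration (C(61,4) x 3 x 21 ≈ 32.9M evaluations, finer
mesh) is supported through the same configuration file and scales linearly
in evaluations.  Validation studies default to: refinement ladder
14/10/7 mm; superposition check at 12 mm; envelope agreement on 1,000 random
pairs (4e6-point grid) and 100 pairs (Hilbert).

## What the synthetic model does and does not show

The sphere reproduces the mechanism end to end — layered conductive
shielding, deep beat-field formation, the dominance of optimized TI over
unoptimized TI and tACS in peak ratio, and feasibility against the 0.2 V/m
floor — with realistic field magnitudes (~0.2–0.4 V/m at 2 mA total).  It
does not reproduce subject-specific numbers: real heads break spherical
symmetry (ventricles concentrate envelope amplitude, gyri reshape cortical
peaks), the hippocampus is not a ball, and published per-subject peak values
depend on individual anatomy.  Passing tests therefore certify the solver,
the envelope arithmetic and the optimizer, not anatomical predictions.

## Known limitations

No contact-impedance (complete electrode) model; no anisotropic or
frequency-dependent conductivity; no phase-offset or amplitude-modulated
waveforms; exactly two pairs of current-carrying electrodes; electrode
footprints quantized to scalp facets at coarse resolutions.
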