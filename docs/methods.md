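# Methods

This note records the models, conventions and numerical choices behind
`pentastate`, and what the synthetic phantoms do and do not establish.

## The two-state rigid-body model

A pentameric channel is modelled as five copies of one rigid protomer
arranged about a C₅ pore axis. Each copy is in one of two conformations
obtained by rotating the docked protomer about a *tilt line*: the line
through the pivot residue's Cα (default residue 250, the narrowest point
of the subunit) with direction from the foot of its perpendicular on the
pore axis to the pivot — i.e. radially outward, which keeps tilted
neighbours from colliding. The taut state uses θ_t = −10° and the relaxed
state θ_r = +20° by default; both are user parameters, since at the
resolutions this model targets they are estimated rather than refined.

**Tilt sign convention.** Nothing in a rotation angle alone says which
sense flares the channel. We fix the sense geometrically: a positive angle
moves the motif marker (Gly278 Cα of the YGMNF motif by default) *away*
from the pore axis. The implementation evaluates the derivative of the
marker's axial radius under a right-handed rotation about the radial line
— sign((m − foot(m)) · (u × (m − pivot))) — and flips the rotation sense
when it is negative. The convention is therefore well defined whenever the
marker's radius responds to the tilt at first order; a `sense` argument
overrides it. The inverse-composition identity (tilt by +θ then −θ) holds
exactly when the marker radius is monotonic over the swept arc, which is
true for the phantom and for any geometry with a non-degenerate tangential
marker offset.

Chain *k* of a state model is the tilted protomer rotated by 72·k° about
the axis (tilt first, in the docked frame; tilting after replication about
the per-chain radial line is mathematically identical and is used as a
cross-check in the tests). State words are equivalent under cyclic
rotation — the C₅ frame has no preferred first chain — but *not* under
reflection: a pentamer and its mirror image are different objects, so
ttrtr and trtrr are distinct classes. Enumeration canonicalizes by the
lexicographically smallest rotation with 't' ordered before 'r'; counts
obey Burnside's formula (1/n)·Σ_{d|n} φ(d)·2^{n/d}.

## Pore-axis fitting

The Cₙ axis is the direction and in-plane offset minimizing the RMSD
between the full coordinate set and its copy rotated by 360/n°, with the
chain correspondence resolved by matching rotated chain centroids.
Initialization is the normal of the best plane through the centroid ring
(the smallest-eigenvalue eigenvector of their covariance); refinement is
Levenberg–Marquardt over four parameters (two direction, two offset).
Degenerate rings — collinear or coincident centroids — are rejected. The
axis direction is oriented from the chain C-terminal end toward the
N-terminal end, matching the convention that the cytoplasmic funnel of a
CorA-like channel is "up"; for CorA chains the C-terminus is
membrane-embedded.

## Density synthesis and comparison

Maps are cubic-voxel grids. Each atom contributes an isotropic Gaussian of
integral equal to its weight with σ = 0.225 × resolution — the width
convention of the molmap-style tools used for docking and rendering at
these resolutions. Different tools use slightly different width rules, so
σ is overridable; all linearity properties are independent of the choice.
Synthesis requires resolution ≥ 2 × voxel size (sampling) and errors on
points outside the box rather than silently truncating.

Map agreement is plain Pearson correlation over voxels (optionally under a
mask), which makes the abundance fit invariant to affine intensity
transformations and removes any global scale as a nuisance parameter.
Hand inversion is a single-axis flip through the box-centre plane (an
involution that preserves the pore-axis frame, unlike a point inversion).
Contour levels for a target mass use a packing density of 0.81 Da/Å³
(≈ 1.35 g/cm³, standard for protein) and pick the voxel-value threshold
whose superlevel volume best matches mass/density.

## Resolution estimation

FSC is the shell-wise normalized real part of the cross-spectrum of two
maps, in shells linear in S = 1/d from 0 to Nyquist (the DC shell is
dropped). The logistic model FSC(S) = 1/(1 + exp(aS − b)) is fitted by
least squares to the shells with 0.02 ≤ FSC ≤ 0.98 — the tails are
noise-dominated and the fit range is otherwise unconstrained —
initialized by logit-linear regression; the FSC = 0.5 point is S½ = b/a
by construction, i.e. a resolution of a/b Å. A model-free linear
interpolation of the first downward 0.5 crossing is provided alongside.

The half-map generator filters seeded white noise so the signal amplitude
spectrum is A(S) = A₀·exp(−S²/2σ_s²) and adds independent white noise of
RMS σ_n to each half; the expected FSC is then SNR/(1+SNR) with a closed
form 0.5 crossing at σ_s·√(2·ln(A₀/σ_n)). The suite checks the fitted
crossing against this analytic value to 10% over ten seeds (64³ grids).

## Crystallographic diagnostics

The native Patterson is a zero-phase Fourier synthesis with coefficients
|F|² = max(I, 0) on a fractional grid (both Friedel mates filled, so the
map is real and centrosymmetric with its maximum at the origin). Peaks are
local maxima under periodic boundary conditions, reported as fractions of
the origin height with sub-voxel quadratic refinement; a translational NCS
pair at fractional shift **t** produces an off-origin peak at **t**.

The rotation function is evaluated in real space as the Pearson
self-correlation of a map with its copy rotated by κ about the polar axis
(ω, φ) through the box centre, restricted to a sphere (trilinear
interpolation; voxels whose rotated source leaves the grid are excluded
from both operands). This reproduces the *diagnostic* — a κ = 72° peak
flags a C₅ axis — rather than any particular reciprocal-space program's
numeric values, and needs no phases. General (e.g. b-unique monoclinic)
cells are handled through the standard fractional/orthogonal matrices for
d-spacing computations.

## The abundance fit

The mixture model has exactly five degrees of freedom: one taut fraction
per protomer position, relaxed fractions being complements, and no scale
parameter (correlation absorbs it). Because the composite map is linear in
the fractions, all correlations reduce to precomputed Gram matrices of the
ten basis maps, so the 11⁵-point exhaustive search at grid step 0.1 costs
well under a second. The default optimizer is coordinate ascent from
f = 0.5 with seeded random restarts, ties broken toward the larger relaxed
fraction; the exhaustive search serves as a brute-force oracle in the
tests, which require bit-identical answers on noise-free targets. Fitted
partitions are reported as-is plus their canonical cyclic rotation,
because a phantom target may not fix the ring frame that a real map does.

## Pore statistics

Relative admittance of a state is its mean motif-marker radius (over the
five chains) divided by the untilted reference's; since the mean is linear
in the per-chain radii, it is strictly increasing in the number of relaxed
protomers whenever θ_r moves the marker outward and θ_t inward. The
reference is the docked conformation symmetrized about the fitted axis.
The pore profile is a sphere probe *centred on the axis*: at each axial
station the radius is the distance to the nearest atom surface (vdW radii
from a built-in Bondi-style element table, overridable). Without the
off-axis probe optimization of a full channel-profiling tool this is a
lower bound on the true maximal probe radius — adequate for testing an
"exceeds d" claim, and stated as such. Cα-only models are rejected.

## The phantom

The phantom protomer is a 120-pseudo-atom chain in three segments echoing
a CorA subunit: a cytoplasmic blob (residues 191–240), a conical stalk
descending to the pivot marker at residue 250 (radius 12 Å, z = 10 Å), and
a straight trans-membrane arm (residues 251–310) passing exactly through
the motif marker at residue 278, placed 8 Å from the intended +z pore axis
with a 6 Å tangential offset. That offset makes the marker radius
monotonic in the tilt angle over −10°…+20°, so taut tilts pull it inward
and relaxed tilts flare it outward, as required by the sign convention.
Default box (168 Å) and voxel (3.5 Å) echo the working scale of a
single-particle study of a detergent-solubilized pentamer; map-synthesis
resolution defaults to 25 Å. All generators draw from one explicit seed
and are byte-reproducible.

What the phantom does *not* emulate: projection imaging and CTF effects,
detergent-micelle density, conformational flexibility beyond the two-state
rigid tilt, and the particle-to-particle heterogeneity of real data.
Passing tests therefore establish the correctness of the geometry, the
synthesis/fit algebra and the estimators — not that a real channel's
population fractions are identifiable at any given noise level beyond the
SNR ≈ 3 recovery checks included.

## Numerical choices and degenerate inputs

* Angles are degrees at every public interface, radians internally;
  lengths Å; spatial frequency S = 1/d in Å⁻¹, with q = 2πS accepted via
  flags and converted on input.
* Guinier fits iterate the upper limit to q·R_g ≤ 1.3 (standard
  practice). For noise-free analytic profiles the truncation bias of the
  Guinier expansion scales as (q_max·R_g)², about +1.8% for a uniform
  sphere at 1.3; the sphere *validation* therefore uses a tighter window
  (q·R_g ≤ 0.75, bias ≈ 0.6%) while the default stays at 1.3.
* Alternate locations: first kept; insertion codes rejected (whole-residue,
  low-resolution work).
* Profile merging interpolates the high-S profile onto the low-S grid in
  the overlap (≥ 3 points required), applies the least-squares scalar
  scale, and keeps the low-S values in the overlap.
* Error paths are explicit throughout: empty selections, mismatched grids,
  anisotropic voxels, zero-variance maps, pivots on the axis, profiles
  without a 0.5 crossing, non-Guinier slopes and all-zero weights raise
  with messages naming the offending quantity.

## Known limitations

* Protomers are rigid; no torsional or per-domain flexibility.
* The rotation function is real-space and map-based; it does not
  reproduce reciprocal-space self-rotation values from crystallographic
  packages, only the symmetry conclusion.
* The pore probe stays on the axis (lower-bound radii).
* No CTF simulation, projection matching, particle classification,
  indirect-transform P(r), or bead-model reconstruction — those stages of
  a real single-particle/SAXS workflow are out of scope here.
* Tests that score the deposited MjCorA crystal structure (PDB 4EV6) need
  a local copy of that entry; everything else is generated on the fly.

## Problem sizes

The suite and the acceptance script run on 48³–64³ grids, 120-atom
protomers, ~7000-reflection dummy crystals and 10-seed replicates —
sizes chosen so every check is exact or tightly toleranced while the whole
pipeline re-runs in seconds.
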