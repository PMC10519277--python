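# Methods

`capflow` simulates deformable red blood cells (RBCs) flowing through
microvessel geometries at cellular resolution and computes the wall shear
stress (WSS) environment the flow imposes on the vessel wall.  This note
records the model, the discretization, the parameter choices, and the
limitations of the desk-scale configurations the package ships with.

## Flow model

Blood is a two-fluid suspension: plasma outside the cells and a hemoglobin
solution inside, both Newtonian.  The flow obeys the unsteady Stokes
equations with constant density and a variable viscosity field,

    rho du/dt = -grad P + div[ mu(x,t) (grad u + grad u^T) ] + F,

where `F` carries the membrane forces.  An indicator function I(x,t)
tracks cell interiors, and the viscosity blends as
`mu = mu_p + (mu_c - mu_p) I`.  Defaults: plasma viscosity mu_p = 1.2 cP,
interior/exterior viscosity ratio lambda = 5 (mu_c = 6.0 cP), density
1000 kg/m^3.  Internal units are um-s-pg; WSS is reported in dyne/cm^2
(1 Pa = 10 dyne/cm^2).

Vessel walls are rigid.  A sharp-interface ghost-node method decomposes
the uniform Cartesian grid into fluid (lumen) and solid nodes; solid nodes
with a fluid 6-neighbor become ghost nodes.  Each ghost node GN has a
boundary intercept BI (nearest wall point) and an image point IP mirrored
into the fluid; enforcing u_GN = 2 u_BI - u_IP (u_GN = -u_IP for resting
walls) makes the trilinearly interpolated velocity at the BI equal the
wall velocity.  Thin-gap fallback: when the IP lands outside the fluid the
mirror distance shrinks (floor of half a cell) and the ghost relation is
scaled by the actual distance ratio; such entries are flagged.

## Membrane model

Each RBC is a closed triangulated surface (icosahedral quadrisection;
level 4 = 5120 elements / 2562 vertices is production resolution).  The
resting shape is the Evans-Fung biconcave discocyte with a 7.8 um major
diameter (surface area ~134.1 um^2, volume ~94.1 um^3); the quartic
profile uses the standard normalized coefficients c0 = 0.207161,
c1 = 2.002558, c2 = -1.122762 on rho = 2r/D.

In-plane elasticity follows the Skalak strain-energy function

    W_s = (G_s/4) [ (I1^2 + 2 I1 - 2 I2) + C I2^2 ],

with invariants I1 = l1^2 + l2^2 - 2, I2 = (l1 l2)^2 - 1 built per element
from the induced metric relative to the stress-free reference (the rest
shape).  C = 100 renders the membrane nearly area-incompressible.
Defaults G_s = 2.5 uN/m and k_b = 2e-19 J are standard RBC literature
values, exposed in the material configuration.

Discretization: constant-strain triangles for the Skalak term and an
edge-hinge discretization of the Helfrich bending energy (quadratic in the
deviation of each dihedral angle from its rest value, weighted by
3 l^2 / (A1 + A2) on the undeformed mesh).  With this weighting the
discrete bending energy of a finely triangulated sphere with flat rest
angles reproduces the continuum Helfrich value 8 pi k_b to within about
1.5%; the remaining bias is a property of the discretization, not of the
physics.  Both energies are differentiated analytically, so the nodal
forces are the exact negative gradient of the discrete energy: rigid
translations and rotations are exact zero modes, net force and torque
vanish to round-off, and the finite-difference force/energy check holds at
1e-4 relative.  We chose this discretization over subdivision-surface
(box-spline) force evaluation deliberately: one-point-quadrature
subdivision forces are not the exact gradient of any discrete energy,
which would leave the membrane without a Lyapunov function at desk
resolutions.  Mean curvature diagnostics use the cotangent operator
(converges to 1/R on spheres under refinement).

## Discretization and coupling

The grid is a uniform MAC staggering: velocity components on cell faces,
pressure at cell centers.  The ghost machinery is generic over a point
lattice and is instantiated for each face lattice and the cell lattice.
Time stepping is an incremental pressure-correction projection.  All
operators are assembled sparse with the ghost response folded in (ghost
values are an affine function of the fluid unknowns), and factorized with
SuperLU behind a band-minimizing symmetric permutation; a step is then a
handful of triangular back-substitutions.  The projection operator is the
exact composition divergence x ghost-response x gradient, so the discrete
divergence at fluid cells vanishes to solver precision after every step.
In the axially periodic (feeder-tube) configuration the pressure system is
pinned at one cell after removing the mean of the right-hand side.

Viscosity contrast is handled implicitly: the per-component operator
carries all second derivatives of that component with the local viscosity
(own-axis coefficient doubled), and is refactorized whenever the indicator
field refreshes (every 100 steps by default; the cell advances well under
one cell per refresh interval).  Only the cross-component "transpose"
terms are explicit.  We first tried the cheaper constant-coefficient
split (implicit mu0, explicit remainder); it is linearly unstable at
viscosity ratio 5 because the effective explicit coefficient reaches
twice the contrast for some modes, and no constant mu0 or damping fixes
it.  The decomposition implemented here was verified to reproduce the
full variable-viscosity stress divergence to machine precision and is
observed to be contractive.

Membrane-fluid transfer uses Peskin's standard 4-point immersed-boundary
kernel for both spreading and interpolation (discrete adjoints); it
satisfies the partition-of-unity and first-moment identities exactly, so
total force is conserved and linear velocity fields interpolate exactly.
The indicator is built from a signed nearest-vertex distance passed
through a tanh profile of width 0.7 h (transition under three cells);
its volume integral matches the summed cell volumes to a few percent.

Three near-wall measures matter at desk resolution, where the lubrication
film between a tightly fitting cell and the wall is narrower than a grid
cell:

1. *Normalized spreading* -- part of a near-wall vertex's kernel support
   falls on ghost/solid faces that the momentum solve ignores; each
   vertex's force is rescaled by the kernel weight that actually lands on
   fluid faces.  Without this the cell rim loses its elastic resistance
   and strains run away.
2. *Wall standoff* -- a short-range repulsion (stiffness G_s, range one
   grid cell) stands in for the unresolved lubrication film.
3. *Advection smoothing* -- membrane vertices advect with a 25% blend
   toward their 1-ring mean velocity.  Membrane edges (0.27 um at level
   4) are finer than the grid, so the delta kernel can neither see nor
   damp sub-edge-scale modes; the blend suppresses exactly those modes
   and perturbs grid-resolved motion only at O(edge^2).

The time step is fixed per run (operators are factorized once) and chosen
from the explicit membrane-coupling bound
dt ~ 0.5 mu_p h / (G_s (1 + C/4)), about 3.7e-6 s at h = 0.4 um; bending
gives a much weaker h^3 bound.  Drives are ramped over several
milliseconds to avoid start-up shocks.  Periodic feeder tubes are driven
by the constant body force equal to the plasma Poiseuille pressure
gradient for the requested pseudo-shear rate (gamma_eff = U_mean / D); an
imposed-flux feedback controller is available but disabled by default
because its corrections perturb the membrane more than the drive error it
removes.  Networks are driven by a parabolic inlet velocity profile with
prescribed flux at the lower z face; outlets are zero-gradient velocity at
reference pressure zero.

## Synthetic vasculature

The generator replaces image-based reconstruction with parametric motifs
of angiogenic networks: straight and tortuous capillaries (alternating
centerline curvature), torus-arc bends, Y-bifurcations, microvascular
loop triads (three vessels closing a loop between two junctions),
pillar-like obstructions, and local bulges.  Diameters are restricted to
the 3-40 um microvascular range.  Single vessels are swept parametrically
(circular cross-sections on parallel-transport frames, near-equilateral
triangulation at a target edge length, default 0.5 um); junctions are
re-meshed from the zero level set of the union signed-distance field at
the target edge length, which blends branches of arbitrary angle without
interior walls.  Per-vertex vessel labels come from the nearest
centerline; vertices within a collar of a junction point form a junction
pseudo-vessel excluded from per-vessel statistics, because per-vessel
plots need an explicit vessel/junction decomposition rule.

RBC seeding is rejection sampling of positions and orientations along the
centerlines with strict inside-lumen and pairwise-separation tests,
reproducible for a fixed seed; vessels of 3 um diameter or less are
skipped (physical occlusion).  What the generator does *not* emulate:
traced centerlines of real mesenteric networks, out-of-plane vessels,
non-circular lumens, endothelial surface texture.  Passing tests on these
fixtures therefore validates the machinery and the qualitative trends
(curvature skew, RBC enhancement, junction gradients), not the absolute
statistics of any real network.

## WSS pipeline

Per wall vertex a local cylindrical frame is built: e_r the inward
normal, e_a the tangential projection of the mean undisturbed near-wall
flow (sampled two grid cells inside from the matching plasma-only field,
so paired RBC/plasma analyses share identical frames), e_theta = e_a x
e_r.  Stagnation points fall back to the nearest centerline tangent and
are flagged.  Viscous traction components use one-sided second-order
differencing inward from the wall with the no-slip value pinned at zero:
t_a = mu_p du_a/dr, t_theta = mu_p du_theta/dr, t_r = 2 mu_p du_r/dr,
evaluated with the plasma viscosity (the wall sits in plasma);
WSS = |t|.  The stencil is exact for profiles quadratic in wall distance
and second-order convergent beyond.  TAWSS is the arithmetic snapshot
mean.  Surface gradients step +/- delta_s (local mean edge length) along
e_a / e_theta, pull the stepped points back to the surface by closest
point, interpolate barycentrically, and difference centrally; boundary
pullbacks degrade to one-sided and are flagged.

## Network statistics

Per-vessel aggregates are area-weighted over wall vertices (gradients as
absolute values); vessel diameter is twice the area-weighted mean
vertex-to-centerline distance and length the centerline arc length.  The
nine-bin histograms span each vessel's own [min, max] TAWSS so the outer
bins are that vessel's low/high extremes; fractions are surface-area
weighted and sum to one per vessel before averaging.  Run ratios
(RBC/plasma "alpha" components, gamma scalings) mask denominators below
1e-3 dyne/cm^2.  Hot/cold spots are seeded where the TAWSSG magnitude
reaches 10 dyne/cm^2/um, grown along monotone TAWSS paths to the local
extremum, classified by the sign of the deviation from the vessel median
(an explicit operationalization of what is a visual identification in
practice), and kept above 1 um^2.  Time-signal metrics: RMS of the
mean-removed signal, and the oscillation timescale as the inverse of the
dominant FFT frequency (no window), flagged undefined below a noise
floor of three times the median spectral amplitude.  Power-law fits are
least squares on log-log axes.

## Desk-scale study cases and their sizes

* Area conservation: one level-4 RBC in an 8 um periodic tube, h = 0.4 um
  (26 x 26 x 40 cells), dt = 3.7e-6 s, ~5400 steps for 0.02 s, drive
  ramped over 8 ms at a plasma-equivalent pseudo-shear of 200 1/s.
* Gamma scaling: plasma-only Y-bifurcation (parent D = 12 um, daughters
  D = 8 um), wall mesh at 0.6 um edges, h = 0.6 um (~50k cells per
  velocity component), steady runs at gamma = 1 and 2.
* RBC vs plasma: one level-3 RBC in an 8 um tube at h = 0.5 um for 700
  steps, compared against a flux-matched plasma flow.

## Known limitations

* The confined-tube surface-area drift at h = 0.4 um is about 1% at its
  worst (during the acceleration transient; the post-transient band is
  roughly +/-0.3%).  The production-scale expectation for C = 100 is
  under 0.1%, which requires resolving the cell-wall lubrication film;
  at desk resolution the standoff layer and the kernel support are as
  wide as the film itself, and the squeeze tension of the 7.8 um cell in
  the 8 um tube elastically dilates the membrane by O(tension / (C G_s)).
  Grid refinement, not parameter adjustment, is the path to the
  production figure.
* Volume drift of the same run is of the same order (projection is
  divergence-exact on the grid, but the kernel-interpolated membrane
  velocity field is not exactly solenoidal).
* Inlet/outlet driving is implemented along the z axis only; fixtures are
  built accordingly.  Only one inlet per network is currently driven with
  a parabolic profile.
* The hinge bending discretization carries the ~1.5% sphere-energy bias
  noted above and no spontaneous-curvature or area-difference terms.
* Membrane viscosity, thermal fluctuations, adaptive grids, moving walls,
  and the endothelial surface layer are out of scope.
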