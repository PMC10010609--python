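# Methods

## Model and assumptions

The root is represented as a tree of cylindrical representative
elementary volumes (REVs) of length ~1 mm (of the order of the primary
root diameter) carrying two concentric media: peripheral tissues
crossed radially by water and solutes, and a xylem core carrying axial
bulk flow. Steady state is assumed at every recorded protocol point —
the experimental flows this class of model interprets are stable over
minutes — so no transients are modeled.

Water crosses the radial barrier down the combined hydrostatic and
osmotic potential difference, `j = k(Pe − P − π_peg_ext + π_peg −
σRT(Ce − C))S`. The lumped nutrient solute acts through an effective
reflection coefficient σ (default 0.85, a literature value for
nutrients on maize root systems); PEG 8000 is non-permeant and acts at
reflection 1. Solutes enter the xylem at a constant active rate `Js*`
and leak back with permeability `Ps`; without the leak no steady state
exists whenever a region has uptake but no advective export (the
solver raises this case explicitly). Axial sap flow follows
Hagen–Poiseuille with a conductance profile `K(x)` piecewise linear in
distance to the root tip, quoted at reference viscosity 1 mPa s and
divided by the local sap viscosity. Both axial halves of an internal
edge contribute their own half-resistance `(l/2)·µ/K`, each evaluated
with that REV's own sap viscosity — a symmetric convention that avoids
discontinuities when flows reverse.

Boundary conditions: Dirichlet P = 0 (relative) at the basal face; the
basal outflow `Jv` is the measured quantity. Apices are sealed. Razor
cuts open distal xylem faces held at bath pressure with advective
exchange of the bath composition; in a PEG bath this is the only route
by which PEG (and its viscosity) enters the root. Under reversed basal
flow the re-entering fluid carries the basal REV's own composition
(zero-gradient), switchable to a fixed composition.

## Physical laws of the PEG solution

Viscosity: `µ(w) = −17.4 + 18.4·exp(w/0.279)` mPa s with `w` in
kg l⁻¹, anchored at µ(0) = 1 exactly and giving ≈14 mPa s at
150 g l⁻¹. Water potential: the standard PEG 8000 calibration
`Ψ[bar] = (1.29·T[°C] − 140)·c² − 4·c` with `c` the mass of PEG per
mass of water, numerically identified with `w` in kg l⁻¹; this
reproduces the calibration anchors Ψ(0) = 0 and Ψ(0.150 kg l⁻¹,
25 °C) = −0.302 MPa, and together with the control solution's measured
−0.034 MPa gives the water-deficit medium's −0.336 MPa. The lumped
bath solute concentration, nowhere tabulated directly, is derived from
that −0.034 MPa as Ce = 0.034/RT = 13.72 mol m⁻³.

Units: m, s, MPa, mol m⁻³, kg l⁻¹ (PEG), K internally; flows are
reported in µl s⁻¹. T defaults to 298 K.

## Numerical scheme

Tree topology makes both linear sub-problems exactly solvable in O(n)
by leaf-to-root elimination (children always carry larger indices than
their parent): a symmetric positive-definite system for pressure and a
nonsymmetric M-matrix system for each concentration field. The
concentration system combines donor-cell (upwind) advective fluxes —
which guarantee non-negative concentrations — with a weak axial
dispersion of conductance 10⁻³ × the dominant flow per edge. The
dispersion emulates xylem molecular diffusion/dispersion (comparable
magnitude for these flows and geometries), is negligible against
through-flow (Péclet ~10³ on the main path), and anchors the
concentrations of near-stagnant regions, making the steady advection
balance continuous in the flow field. Both kernels are numba-compiled.

The osmosis–advection–viscosity coupling is a genuinely stiff fixed
point: near-stagnant laterals in a PEG bath exhibit positive feedback
between PEG accumulation, exponential viscosity growth and flow
stagnation, and plain damped alternation of the two solves limit-cycles
there. The solver therefore uses pseudo-transient continuation: the
advection solve carries an implicit storage term `V/dt·(C − C_prev)`
whose fixed point is the exact steady state for *any* step, so the
converged solution is step-independent. The pseudo step starts at one
median residence time and is adapted on the steady balance residual
(grow 1.4× while non-increasing, halve when it worsens >1.5×, reject
and revert the step beyond 100×); an Aitken extrapolation every 8
iterations removes the occasional near-unit-contraction mode of
osmotically coupled low-flow regions, and a best-state restart catches
excursions to spurious attractors after near-convergence. Transient
concentrations are capped far above any converged value (100× the
zero-flow ceiling for solutes; max(2·w_bath, 0.25 kg l⁻¹) for PEG) so
the exponential viscosity law cannot overflow mid-iteration.
Convergence requires both the steady balance residual and the
per-iteration (P, Jv) drift to fall below `tol` (default 1e-8, cap
1500 iterations). Conservation-critical analyses pass `tol = 1e-12`,
at which per-REV water and solute balances close to ~10⁻¹³–10⁻¹²
relative to the dominant flux.

Degenerate inputs: zero-throughflow regions with `Js* > 0, Ps = 0`
raise an explicit no-steady-state error; fully flowless fields take
the bath composition; negative concentrations are impossible by the
M-matrix structure and asserted after each solve.

## Discretization and geometry choices

Axes are split into `ceil(length/l_target)` equal REVs (no short
remainder element); basal flow changes by <1% between 1 mm and 0.5 mm
REVs on reference architectures. Blade positions and the K-profile
abscissae are anatomical distances from the *intact* primary tip,
preserved through cuts (a cut face at x keeps the conductance the
anatomy gives it). Cut laterals follow the experimental
stretched-tipward convention: a lateral attached at primary coordinate
p with length L spans [p − L, p], so a blade at x removes it entirely
when p ≤ x and leaves its basal p − x otherwise. Junctions carry no
extra resistance. The cutting geometry is switchable to the main
alternative (excising lateral REVs by their own distance to their own
tip) for architectures where the aligned-lateral assumption fails.

## Synthetic roots and protocols

The generator emulates an 11-day-old hydroponic maize seminal root:
one primary (~0.3 m, diameter 1.05 mm control / 1.03 mm water-deficit)
bearing first-order laterals only (0.36 / 0.39 mm), placed by a
Poisson process of default intensity 70 m⁻¹ outside a 2 cm apical
unbranched zone (≈20 laterals), with lateral lengths normal
(4 ± 1.5 cm, truncated at 5 mm) — values chosen once as realistic for
this material where no direct report exists. Pressure protocols use
the standard step sequence (0 → 0.5 MPa with interleaved returns);
cut-and-flow uses a first cut of 8.3 cm, subsequent cuts of 4.3 cm and
a basal remainder of ~5.2 cm at an operating pressure of 0.2 MPa
(control bath) or 0.3 MPa (PEG bath). Parameter-recovery studies use
0.35 m primaries so that this schedule yields six cuts, 2 mm REVs, and
eight pressure steps; generating parameter values are drawn within a
factor ~1.6 of the literature-informed defaults (k = 10⁻⁷ m MPa⁻¹ s⁻¹,
Js* = 10⁻⁷ mol m⁻² s⁻¹, Ps = 10⁻⁹ m s⁻¹, K from 10⁻¹² to 10⁻¹⁰
m⁴ MPa⁻¹ s⁻¹ rising around 0.1 m).

What the generator does not emulate: measurement drift and transients
during cutting, root growth between protocols, diameter taper along
axes, second-order laterals, and heterogeneity of k, Js*, Ps along the
root (all uniform). Passing recovery tests therefore demonstrate that
the staged inversion identifies the parameters *of this model* from
protocol-shaped data at realistic noise, not that real roots satisfy
the model.

## Inversion

`F = Σ(Jv_data − Jv_model)²` pooled over both protocols, µl² s⁻². One
K knot per cut, abscissae at the blade positions (≤9 knots; with the
three uniform parameters at most 12 unknowns). First guesses: the
literature step profile (10⁻¹² below ~0.1 m, 10⁻¹⁰ above) and the
default k, Js*, Ps. Stages: (1) {K, k} on cut-and-flow with solute
transport off and the osmotic term frozen at the pressure-axis
intercept of the linear part of Jv(P); (2) {k, Js*, Ps} on Jv(P) by
SLSQP with K fixed; (3) joint refinement on both series. All positive
parameters are optimized in log10 space (positivity by construction,
well-scaled finite differences across decades). Stages 1 and 3 use
bounded trust-region least squares with numerical Jacobians: the
problem is small-residual least squares, and Gauss–Newton steps reach
the noise floor in ~10² evaluations where simplex-class searches left
tens-of-percent errors on weakly identified tip knots at several times
the cost. The full objective is re-evaluated after each stage and the
best parameter set kept, so F decreases weakly across stages; a failed
stage falls back to its predecessor. Forward solves warm-start each
protocol point from its last converged fields (with a cold retry if
the optimizer has moved too far), and solver failures return a large
penalty rather than raising.

The pure-hydraulic comparison fit freezes the osmotic term at a
constant offset P0 (fitted), removes solute transport, and uses only
the linear part of Jv(P) (default Pe ≥ 0.1 MPa) plus cut-and-flow —
the classical interpretation whose bias on k and K the coupled model
exposes. The two-compartment (osmometer) closed form solves the same
closure for a well-mixed interior at basal pressure via a quadratic in
C − Ce (larger root: continuous in Pe, C ≥ 0); its fit to tree-model
curves quantifies what ignoring architecture heterogeneity does to the
parameters, with the tip-to-base concentration gradient (evaluated at
0.1 MPa overpressure, the heat-map condition) as the homogeneity
metric.

## Known limitations

- The dead-end PEG field is regularized by dispersion; PEG mass in
  truly stagnant regions equilibrates diffusively rather than
  accumulating without bound, a modeling choice the pure advection
  closure leaves open.
- The osmometer closed form and the tree model treat reversed basal
  flow differently (formal outflow-carrying-C versus zero-gradient
  re-entry), so their equivalence and comparison hold on
  positive-flow pressure ranges.
- Measured protocol curves with strong transients (e.g. incomplete
  equilibration after a cut) violate the steady-state assumption and
  will bias fits; nothing in the package detects this.
- Parameters are uniform over the architecture; per-axis heterogeneity
  is out of scope.
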