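# rootflow

Water and solute transport on branched root system architectures, for
plant hydraulics researchers who estimate root transport parameters
from pressure-chamber experiments. The package simulates a de-topped
root sealed into a pressure chamber — both the `Jv(P)` protocol
(xylem sap flow versus applied pressure) and the cut-and-flow protocol
(flow at fixed pressure while the root is progressively excised from
the tip) — and inverts such curves to estimate the root's radial
hydraulic conductivity, its axial conductance profile, and its solute
transport parameters. It targets young hydroponic maize seminal roots
under control conditions or PEG 8000–induced water deficit, where
osmotic driving forces dominate and purely hydraulic models fail.

## Model

The root is discretized into ~1 mm cylindrical representative
elementary volumes (REVs) on the branching tree. Per REV of lateral
surface *S* = π·d·l:

- radial water influx across the peripheral tissues
  `j = k (Pe − P − π_peg_ext + π_peg − σRT(Ce − C)) S`, with `k` the
  radial hydraulic conductivity (m s⁻¹ MPa⁻¹), `Pe`/`P` the bath and
  xylem relative pressures, `Ce`/`C` the bath and xylem lumped solute
  concentrations, σ the reflection coefficient (default 0.85), and
  π_peg the osmotic pressure of non-permeant PEG 8000 (reflection 1);
- axial Hagen–Poiseuille sap flow `J = K(µ) ΔP / l`, with the axial
  conductance profile `K` a piecewise-linear function of distance to
  the root tip (quoted at reference sap viscosity 1 mPa s) and µ the
  local sap viscosity, which rises steeply when PEG enters cut xylem
  vessels (µ(150 g l⁻¹) ≈ 14 mPa s);
- radial solute flux `j_s = (Js* − Ps (C − Ce)) S`: a constant active
  uptake rate `Js*` plus a passive leak of permeability `Ps` — the
  combination that explains spontaneous exudation at atmospheric
  pressure and steady *negative* sap flow under water deficit;
- axial solute and PEG advection `J·C` and `J·C_peg`, with PEG entering
  only through open cut faces.

The basal face is held at atmospheric (relative 0) pressure, apices
are sealed, and cut faces are open xylem surfaces at bath pressure
exchanging bath composition advectively. Both linear sub-problems
(pressure; upwind advection) are solved exactly in O(n) by tree
elimination; their nonlinear coupling is resolved by pseudo-transient
continuation. Inversion minimizes `F = Σ (Jv − J)²` over both
protocols with the field's staged workflow: axial profile and `k` on
cut-and-flow first, solute parameters on `Jv(P)` next, then a joint
refinement.

## Worked example

```python
import rootflow as rf

# a synthetic 0.3 m maize-like seminal root with ~20 laterals
rs = rf.generate_synthetic_rsa(primary_length=0.30, lateral_density=70.0, seed=1)
g = rf.discretize(rs, l_target=1e-3)

ctr = rf.TransportParams()            # k=1e-7 m/MPa/s, Js*=1e-7, Ps=1e-9
wd = rf.TransportParams(k=1e-8)       # water deficit: k reduced 10-fold
ctr_bath = rf.BathSolution()          # hydroponic control, Psi = -0.034 MPa
wd_bath = rf.BathSolution(w_peg=0.150)  # +150 g/l PEG 8000, Psi = -0.336 MPa

for name, params, bath in [("CTR", ctr, ctr_bath), ("WD", wd, wd_bath)]:
    series = rf.simulate_jvp(g, params, bath)
    print(name, "J0 = %.4f ul/s, linearity gap = %.3f"
          % (series.J0, rf.linearity_gap(series)))
```

prints

```
CTR J0 = 0.0050 ul/s, linearity gap = 0.060
WD J0 = -0.0016 ul/s, linearity gap = 0.086
```

The control root exudes spontaneously at atmospheric pressure (J0 > 0,
driven by active solute uptake), while the water-deficit root shows a
steady negative sap flow (the bath's PEG osmotic pull wins) and a more
curved `Jv(P)` relationship — the two signatures that require the
coupled water–solute closure. Parameter estimation from a pair of
simulated (or measured) curves:

```python
cuts = rf.default_cut_schedule(0.30)   # blade at 8.3 cm, then every 4.3 cm
jvp = rf.simulate_jvp(g, ctr, ctr_bath)
cfl = rf.simulate_cut_and_flow(g, ctr, ctr_bath, cuts)
result = rf.fit(g, jvp, cfl)
print("k = %.3g m/MPa/s, R2 = %.4f" % (result.params.k, result.r2))
```

A command-line interface mirrors the library
(`rootflow generate / simulate / jvp / cutflow / fit / fiscus`); every
run writes a manifest with the config hash and seed so identical
inputs reproduce identical outputs.

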