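# Methods

`wormtouch` models how a focal touch on the body of *C. elegans* becomes a
mechanoreceptor current. It couples two layers: a static, geometrically
nonlinear thin-shell model of the pressurized body indented by a rigid
bead, and a stochastic gating model of the mechano-electrical transduction
(MeT) channels distributed along the touch receptor neuron (TRN). This
note records the model, its numerical treatment, the default parameters
and the design decisions taken where the problem left room for choice.

## Body mechanics

### Model

The body is a circular cylindrical shell: mid-surface radius `R = 25 µm`,
wall thickness `t = 1 µm`, length `L = 1 mm`, Poisson ratio `ν = 0.3`,
Young's modulus `E`, inflated by an internal excess pressure `p ≥ 0`
(external atmospheric pressure is neglected; `p` is held constant during
indentation). Displacements are comparable to or larger than `t`, so the
strain is the nonlinear Green–Lagrange measure

    2 ε_ij = ∂_i u_j + ∂_j u_i + (∂_i u_k)(∂_j u_k),

while the material law stays linear (St. Venant–Kirchhoff / plane-stress
Hooke), valid because the strain components themselves stay moderate
(≲ 0.3 in every case exercised here).

The 3D equations are reduced to the thin-shell (mid-surface) limit.  The
discrete energy of a configuration is

    E[u] = E_stretch + E_bend − p (V − V₀) + E_contact .

* **Stretching** — constant-strain triangles on a structured `(s, φ)`
  mid-surface mesh; per-triangle Green–Lagrange strain from the 3D
  deformation gradient relative to the faceted reference, plane-stress
  density `½ σ:ε` with `σ = E/(1−ν²)[(1−ν)ε + ν tr(ε) I]`, integrated
  with thickness `t`.
* **Bending** (on by default) — a Donnell-type quadratic form in the
  normal displacement `w`: curvature changes `κ_ss = w_,ss`,
  `κ_cc = w_,cc + w/R²`, `κ_sc = w_,sc` by finite differences on the
  grid, rigidity `D = Et³/12(1−ν²)`.  In the pressure-dominated regime
  (`τ = pR²/Et² ≫ 1`) this term is a small regularizer (< 5 % of the
  energy); at `p = 0` it carries the response.
* **Pressure** — the enclosed volume `V` of the tube closed by virtual
  fans over the deformed end rings, by the divergence theorem.
* **Contact** — an area-weighted quadratic penalty on penetration of the
  bead *and of the vertical cylinder swept above it* (the supporting
  shaft).  The shaft is essential once `w₀ > 2R_b`: a small bead is then
  fully buried and a sphere-only obstacle lets the discrete surface
  escape around it.

**Free ends.** Experimentally the ends carry no load, but the virtual-cap
volume potential would pull them axially (a closed-tube load). The solver
therefore pins the axial position of the two end rings at the
zero-axial-stress homogeneous equilibrium; the caps push against those
pins and the shell interior stays free of axial prestress. The pins also
remove an otherwise genuine artifact: a pressurized tube loaded by its own
virtual caps Euler-buckles into a bowed configuration that gains enclosed
volume — correct physics for a capped tube, wrong physics for this
preparation.

### Solution procedure

1. **No-stress calibration.** The unloaded (reference) radius and length
   are found by fixed-point iteration so that free inflation to pressure
   `p` reproduces the target `R` and `L` within 0.1 %.  At the standard
   `p/E = 0.01` the hoop stretch is ≈ 1.18 — far outside linear response,
   which is why the calibration is numerical rather than perturbative.
   Inflation (and all unindented axisymmetric load cases) is solved in a
   reduced axisymmetric subspace `(dr(s), dy(s))`, which is fast and
   excludes the bowing modes noted above.
2. **Glue.** The lower half of the body (`φ ∈ [π/2, 3π/2]`) is fixed at
   its pressurized resting position (`fixed_lower_half`, the main-text
   condition; `vertically_rigid_lower_half` constrains only the vertical
   motion).
3. **Indentation.** The bead descends by `w₀` measured from the resting
   surface; the energy is minimized over the free nodal displacements
   with L-BFGS-B (displacements scaled to µm, energies to `E t R²`).
   Contact stiffness starts at 10¹² Pa/m and is escalated ×10 until the
   maximum penetration is below `t/100`; the escalated stiffness is
   carried along continuation ladders.  Deep indentations are reached by
   warm-started continuation with increments ≤ min(2 µm, 0.6 R_b) — the
   bead-dependent cap keeps the surface attached under buried beads.
4. **Force.** `F = ∂E/∂w₀` of the contact term at equilibrium (virtual
   work), which analytically equals the vertical penalty resultant; a
   central-difference `dE/dw₀` across re-solved equilibria agrees within
   1 % and is kept as a cross-check.

Meshes are graded axially (sinh clustering at the bead) and optionally
circumferentially (smooth `φ − b sin φ` map toward the contact side).
Standard runs use 56–72 axial × 28–48 circumferential nodes; doubling the
resolution changes `F` by < 2 % at the standard configuration.  The
force-indentation family behind the factorized law keeps `R/t = 25` fixed
across radii — thickness rescales out of the pressure-dominated response,
and a fixed `t` would otherwise push the larger shells to a ~0.5 hoop
prestrain where the factorized description degrades.

### Derived mechanical quantities

* `deformation_profile` — vertical displacement along a generatrix
  relative to rest and the half-maximum distance `y_h` (linear
  interpolation between bracketing stations).
* `strain_at` — bilinear interpolation of cell strains, reported in the
  (circumferential, axial, normal) frame with the plane-stress normal
  component `ε₃₃ = −ν(ε₁₁+ε₂₂)/(1−ν)`.
* `bulk_modulus` — `κ = Δp V₀/|ΔV|` under a uniform external pressure
  increment on the lateral wall.  The default load case is the free
  (unglued) shell, matching the pressure-chamber experiment the printed
  κ band comes from; at `p = 0` the computed κ agrees with the linear
  closed forms `Et/((2−ν)R)` (lateral) and `Et/((5/2−2ν)R)` (capped)
  within 3 %.  Gluing the whole lower half roughly triples κ because
  half the circumference can no longer contract.

### Analytic benchmarks

Two independent references validate the solver in limits (`oracles`):

* a radial point load on an unpressurized cylinder, evaluated by mode
  summation of the shallow-shell operator with Morley's low-harmonic
  correction `D(∇²+1/R²)²` (plain Donnell theory misstates the `n = 2`
  ovalization stiffness by (4/3)²).  Because 60 % of the free-cylinder
  compliance sits in the beam mode that any support suppresses, the
  solver comparison uses a *pinch* (two opposite beads, free shell,
  odd harmonics cancel identically in both descriptions): agreement is
  within 10 % at `w₀ = t/2`.
* point indentation of a pressurized sphere, by 1D minimization of the
  axisymmetric shallow Föppl–von Kármán energy about the pre-tensioned
  state (`T₀ = pR/2`).  Its stiffness is the classic log-suppressed
  membrane response and approaches the mirror-inverted-cap asymptote
  `πpRw₀` only slowly with depth; the tests therefore check the
  scaling behavior (linearity in `p`, monotone approach) rather than a
  5 % agreement with `πpR` that the point-load equation does not admit.

## Channel gating

Each channel connects to an elastic filament whose far end moves with the
tissue. With filament length rescaled to 1 and stiffness absorbed into
the gating constants, the extension obeys

    dx/dt + x/τ = dΓ/dt,    Γ(t) = (I + ∇u(t))·Γ(0),

integrated exactly per step for piecewise-linear `Γ`, followed by
projection on the half-space `x·ŵ₃ ≥ 0` imposed by the neural membrane
(`tangential_always` removes the normal component entirely). Constant
deformation drives `x → 0`: adaptation. The tangential force components
`ℱ₁ = −x·ŵ₁`, `ℱ₂ = −x·ŵ₂` tilt a three-state ladder C⇌S⇌O:

    βΔG_oc = g₀ − g₁ ℱ          (symmetric, ℱ = |tangential force|)
    βΔG_oc = g₀ − g₂ ℱ·v̂        (directional, per-channel preferred v̂)
    ΔG_os = a ΔG_oc,  ΔG_sc = (1−a) ΔG_oc .

Rates respect detailed balance with a symmetric Arrhenius split
`R_ij = r₀ e^{−βΔG_ij/2}` (direct C↔O transitions excluded), so the
stationary state is the Boltzmann distribution exactly. Occupancies are
propagated by the exact exponential of the piecewise-constant 3×3
generator (symmetrized eigendecomposition; a propagator table over the
scalar `βΔG_oc` accelerates population runs). A thinning-based Gillespie
simulator provides the stochastic cross-check.

### Default gating parameters

The quantitative gating constants are not printed in the available text;
the defaults were chosen once, on physical grounds, and are recovered
within 20 % by `fit_gating` from synthetic step responses:

| parameter | default | rationale |
|---|---|---|
| `g₀` | 7 kBT | rest open probability `e^{−7}`; small standing current |
| `g₁` | 200 | near-saturating drive under the bead for an 8 µm step at `p = 40 kPa`; peak currents in the recorded tens-of-pA range; roughly linear current–displacement relation |
| `g₂` | 280 | directional coupling, ≈ √2 compensation for projection loss |
| `a` | 0.5 | sub-state free energy midway between C and O |
| `τ` | 50 ms | rapidly adapting decay of the recorded currents |
| `r₀` | 500 s⁻¹ | ms-scale channel kinetics; finite response at high stimulus frequency |
| `i_o` | −1.6 pA | measured single-channel current |
| `i_s` | −0.8 pA | assumed `i_o/2` (sub-conductance not printed) |

## TRN population

Channels occupy puncta along the TRN with i.i.d. log-normal spacings
(default mean 3 µm, `σ_ln = 0.55` — configuration assumptions standing in
for the fluorescence-puncta statistics), one channel per punctum, over a
500 µm extent centred on the stimulus; the TRN line sits at `θ_TRN = 0`
(under the bead path) by default. Initial filament directions are uniform
on the outward hemisphere. Mechanics is quasi-static (the tissue is
purely elastic): the shell is solved at a ladder of depths, the TRN-line
kinematics (tangent stretch map, normal, plane-stress normal strain,
relative to the pressurized rest state — adaptation nulls the static
prestress) are tabulated and interpolated linearly in `s` and `w₀`; the
ladder is shared across the whole ensemble.

Total current: mean `⟨I⟩ = i_o ΣPo + i_s ΣPs`; variance as the sum of
single-channel current variances (independent channels). Ensembles
redraw placements and orientations per realization; summaries report peak
on/off currents in 150 ms windows after onset/offset, the RMS on–off
asymmetry across realizations, and the coefficient of variation of the
peak.

The strain is evaluated on the mid-surface. A fiber-offset evaluation
(strain at a radial station inside the wall) is a natural refinement —
the TRN sits near the cuticle — but the reference description does not
state the TRN's radial position, so the mid-surface thin-shell baseline
is kept.

## Protocols and fitting

Stimuli are steps, ramps, sinusoids and pre-indented steps on a uniform
grid with a 2 ms default rise (instantaneous steps are ill-posed for
`dΓ/dt`); dwell times of pre-indented steps must exceed `10τ` so
adaptation completes. Force clamp inverts the simulated monotone
force-indentation relation; commanded forces beyond the curve maximum are
flagged as saturated.

Fits: `p/E` by log-grid search plus golden-section refinement against
deformation profiles; `p` by 1D least squares on force curves (stiff
mode: `p/E` fixed with `E` co-varying; soft mode: `E`, `t` fixed, only
`p` varies); the factorized law by linear initialization plus
Levenberg–Marquardt on `(α₁, α₂, α₃)` with pooled-force `R²`; gating by
multi-start bounded least squares against ensemble-mean traces, with
at-bounds diagnostics (a flat trace is flagged unidentifiable).

## Synthetic data

The fixture generators run the real solver/pipeline at known parameters
and add i.i.d. Gaussian noise (relative SD configurable, default 1 %),
embedding the generating parameters and seed in the file header.  They
emulate the *structure* of the experimental datasets (profile tables,
per-animal force curves, current sweeps) but none of the instrument
artifacts (drift, filtering, series resistance), so closed-loop recovery
tests demonstrate estimator correctness, not robustness to real-world
noise.

## Problem sizes and determinism

Test-suite and acceptance runs use 48–72 × 24–48 meshes, 5–8-point depth
ladders, ensembles of 8–50 realizations and 0.5–2 s traces at 1–2 ms
resolution; these sizes keep every reported quantity within a few percent
of finer-resolution runs (mesh doubling changes forces by < 2 % at the
standard configuration). All stochastic entry points take explicit seeds
and are bit-reproducible.

## Known limitations

* Purely elastic tissue: no viscoelasticity, so frequency dependence
  enters only through channel kinetics.
* Isotropic wall; the annular cuticle's anisotropy is not represented.
* One channel per punctum, independent channels (no cooperativity),
  a single sub-conductance state, no membrane-potential dynamics.
* Plugged ends are a configuration stub only.
* The mid-surface contact ignores the `t/2` offset of the outer surface
  (sub-percent over the standard indentation range).
* At fixed indentation depth, the wider channel recruitment at low
  internal pressure compensates the weaker local strains almost
  exactly, so the displacement-clamped peak current is nearly
  pressure-independent (slightly decreasing) rather than increasing
  with `p`; the force-clamped peak decreases with `p` strongly, and the
  soft/stiff similarity under displacement clamp is reproduced.
* The simulated force–indentation curves are more convex than the
  factorized law: the solver's small-indentation stiffness matches an
  independent pre-tensioned shallow-shell computation and the law's own
  point-bead limit, but lies below the law's finite-bead linear
  extrapolation, which cannot hold as `w₀ → 0` (the contact degenerates
  to a point).  Fitted `α₁` and especially `α₃` therefore deviate from
  the printed coefficients even though the curves agree near `w₀ = 8 µm`
  and `α₂` and the pooled `R²` are reproduced.
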