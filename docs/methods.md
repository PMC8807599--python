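# Methods

This note documents the models, numerical choices and known limitations of
the `vlbm` package: a volumetric lattice Boltzmann (VLBM) pipeline that
turns a watertight triangulated vessel surface into pulsatile 3-D flow
fields and wall shear/normal stresses, validated against the closed-form
pulsatile-pipe (Womersley) solution.

## The volumetric lattice Boltzmann model

The solver evolves D3Q19 particle populations per cubic lattice *cell*
rather than per node.  Each cell carries a static solid fraction
`P ∈ [0, 1]` (0: fluid, 1: solid, otherwise a boundary cell cut by the
wall), and the cell populations relate to the usual node-based distributions
by `n_i = (1 − P) f_i`.  One update consists of

* **BGK collision** `n′_i = n_i − (n_i − n_i^eq)/τ + F_i` with the standard
  incompressible quadratic equilibrium and forcing
  `F_i = 3 ω_i N (e_i·a)/c²` whose moments inject momentum `+N a` per step
  (`Σ F_i = 0`);
* **volumetric streaming** with the no-slip wall embedded: the receiving
  cell `x` with upwind cell `A = x − e_i` takes, when `P(A) < P(x)`, the
  fraction `(1−P(x))/(1−P(A))` of `n′_i(A)`; otherwise it takes all of
  `n′_i(A)` plus the bounced-back part `(P(A)−P(x))/(1−P(x)) · n′_{i*}(x)`.
  This "generalized" operator conserves mass *exactly* for every pair of
  fluid fractions (proved numerically over a (P_A, P_B) grid in the test
  suite) and reduces to pass-through when both fractions are equal and to
  full bounce-back against a solid upwind cell.  The earlier "original"
  operator `n_i(x) = (1−P(x)) n′_i(x−e_i) + P(x−e_i) n′_{i*}(x)` is kept
  solely for the accuracy comparison.

With all `P = 0` the engine is the standard node-based D3Q19 BGK stepper
(verified against an independent reference implementation to 1e-12; exact
bitwise identity is not asserted because the reference orders its floating
point operations differently).

Macroscopic fields: `ρ = Σn_i/(1−P)`, `u = Σe_i n_i / Σn_i`,
`p − p₀ = c_s²(ρ − ρ₀)` with `ρ₀ = 1`, `c_s² = 1/3` in lattice units.

Stability: BGK with bounce-back walls requires `τ > 1/2`; the solver raises
below 1/2 and warns below 0.505, where stability is the user's
responsibility.  Runs monitor the low-Mach assumption and warn when
`max|u| > 0.1 c`.

## Geometry processing

The wall is given as a watertight STL surface (read through `trimesh`).  A
signed distance field φ is sampled at the vertices of the lattice
(negative in the fluid, positive in the solid; the wall is the zero level
set).  Numerics:

* inside/outside from exact ray-casting parity (one jittered +z ray per
  vertex column);
* in a narrow band (every vertex within ~2 cells of a sign change) the
  distance is evaluated *exactly* against candidate triangles gathered by a
  KD-tree ball search over chord-sized surface samples — the search radius
  `d(nearest sample) + r_piece` provably contains a sample of every
  possibly-nearest triangle, so the band values carry no search error;
* outside the band each vertex takes the distance to the nearest exact
  surface foot point among the 3³ band neighborhood of its
  distance-transform-nearest opposite-phase vertex.  This overestimates the
  true distance by at most `O(dx²/d)` — far below lattice resolution
  everywhere the solver reads φ; the eikonal property `|∇φ| = 1 ± 0.05` is
  asserted on analytic fixtures.

Cell classification follows the corner signs (all φ ≤ 0: fluid; all > 0:
solid; mixed: boundary; an exact zero counts as fluid so a wall lying on a
lattice plane behaves like half-way bounce-back).  Boundary cells are split
into `q³` sub-cells (default `q = 8`, the accuracy/cost compromise —
refining to `q = 16` changes the benchmark volume error by < 0.01
percentage points); trilinear interpolation of φ at the sub-cell centers
yields the solid fraction `P`, the fluid volumetric center `x_b`, and — via
central differences of φ at the cell corners interpolated to `x_b` — the
unit wall normal, stored oriented *into the fluid* (the distance gradient
points fluid → solid; WSS is insensitive to the orientation, the sign of
the wall-normal stress flips with it; output metadata records the
convention).  Cells whose sub-cell sampling quantizes to fully fluid/solid
are reclassified so that `class = fluid ⇔ P = 0` and `class = solid ⇔ P = 1`
hold exactly.

The benchmark cylinder generator triangulates its caps with concentric
rings (chord-sized triangles) rather than center fans: all spatial search
structures above assume reasonably shaped triangles, and giant fan
triangles degrade them badly.  Its faceted volume is
`(k/2) R² L sin(2π/k)` for `k` side facets.

## Wall stresses

The strain-rate tensor comes from the pre-collision non-equilibrium
populations, `S_ab = −Σ e_a e_b (n_i − n_i^eq) / (2 N τ c_s²)`; the total
stress is `T_ab = −[N c_s²/(1−P)] δ_ab + (2τ−1) c_s² S_ab`, and the wall
traction `T_ab N_b` is split into its normal (WNS) and tangential (WSS)
parts at each boundary cell.

The population-based S is exact (to a fraction of a percent) in resolved
fluid cells, but in partial-fraction boundary cells the populations
refilled by the embedded bounce-back carry a non-equilibrium part damped by
roughly `1 − 1/(2τ)` — measured directly on steady Poiseuille flow, a naive
local evaluation underestimates the wall shear by 50–90% at *any*
resolution.  Wall stresses are therefore reported per boundary cell from
the fluid-cell strain field sampled at 1.5 and 3.0 cells along the inward
normal from the wall point and extrapolated linearly to the wall (the
first fluid ring, itself ~3% low, is thereby avoided).  The naive local
evaluation remains available (`method="local"`) as a diagnostic.

## The pulsatile-pipe validation

The reference flow is pressure-gradient-driven pulsatile laminar flow in a
rigid circular pipe: `P(t) = P_s + Re(P_o e^{iωt})` (Pa/m) gives the exact
axial velocity in terms of the complex Bessel function `J₀` and the
Womersley number `α = R√(ω/ν)`; the analytic shear uses `J₀′ = −J₁`.  The
oracle exposes both the tensor-convention wall shear `μ ∂u/∂r` (default;
the steady part is `−P_s R/2`) and the doubled variant `2μ ∂u/∂r` that some
references print.

Benchmark conditions (the study defaults): pipe `R = 9.525 mm`,
`L = 19.05 mm`; laminar run `P_s = 0.3`, `P_o = 1.8` Pa/m, `ω = 1.57 s⁻¹`,
`ρ = 10³ kg/m³`, and `α = 6.89` — the stated kinematic viscosity
(1.0e-6 m²/s) is inconsistent with that Womersley number at these R and ω,
so the driver honors α and infers `ν = (R/α)² ω ≈ 3.0e-6 m²/s`.
Grid-convergence and order-of-accuracy runs use the low-amplitude flow
`P_s = P_o = 0.02` Pa/m, `ω = 6.28 s⁻¹`, `ν = 1.0e-6 m²/s`.

Discretization: `N_D` cells across the diameter (benchmark default 150),
`δx = D/N_D`, relaxation time targeted at `τ = 0.95` (within the reference
range 0.55–0.95; lowering τ to 0.7 was measured to *worsen* the velocity
error at fixed N_D), then `δt` rounded so a pulsation is an integer number
of steps and τ re-derived.  The simulation exploits the axial invariance of
fully developed pipe flow: a 4-cell-thick mid-pipe slab with periodic ends
reproduces the infinite pipe at a small fraction of the cost of a
full-length run (a full-length, velocity-profile-driven run is exercised
separately in the test suite).

Start-up: populations are initialized at equilibrium with the analytic
velocity field (`init="analytic"`), which only shortens the approach to the
unique limit cycle of this linear problem; `init="rest"` (constant pressure,
zero velocity) is the library default outside the benchmark driver.
Convergence to the limit cycle is declared when the relative L2 change of
the eight phase snapshots between successive cycles falls below
`cycle_tol`.  The benchmark drivers use 3e-5 (laminar benchmark) and 1e-4
(grid-convergence runs, whose transient decays only ~6% per cycle); both
bound the metric contamination at least two orders below the errors being
measured — tightening to 1e-6 changes the reported velocity error from
1.173% to 1.176% while nearly doubling the run length.

Comparisons use the relative L2 norm `√(Σ(f_num−f_ana)²/Σf_ana²)` at eight
equally spaced phases starting at phase 0:

* **velocity**: over the lumen fluid cells of one cross-section, analytic
  values at each cell center's exact radius;
* **WSS**: the en-route wall-shear magnitude at the section's boundary
  cells against the analytic wall value.  Phases whose analytic wall shear
  is below 10% of its cycle maximum are reported N/A — near the zero
  crossing a relative error measures the denominator, not the solution (the
  reference comparison likewise reports N/A at its near-zero instant);
* **centerline velocity** (the streaming-operator comparison): the
  velocity at the fluid cell nearest the pipe axis.  The reference
  comparison is phrased both as "spatial mean" and as "centerline" velocity;
  the center-point reading reproduces both the magnitude and the
  phase-flatness of the reference per-phase values, whereas a
  diameter-row L2 (also computed and reported) is dominated by the
  near-wall cells and fluctuates strongly over the cycle.

Order of accuracy: three runs at 3×-related resolutions (21/63/189 across
the diameter — a desk-scale version of the reference 31/93/279 triple);
the velocity at phase 0, interpolated along the diameter to fixed `r/R`
stations, enters `b = log((φ_3h − φ_9h)/(φ_h − φ_3h))/log 3`.  Near-wall
bounce-back limits the scheme to roughly first order there and pulls the
global exponent to ~1.1–1.3.

## Synthetic measured-style inputs

`make_synthetic_pcmra_profiles` emulates a phase-contrast MRA acquisition:
analytic pulsatile-pipe velocities sampled on a coarse in-plane grid at 10
axial slices × 20 time points per cycle, with optional seeded zero-mean
Gaussian noise (default 0).  Driving a simulation from such profiles uses
monotone piecewise-cubic (PCHIP) interpolation in time with periodic wrap —
chosen over classical cubics to avoid ringing on 20-point waveforms — and
bilinear interpolation in space, imposed at the inlet/outlet slices through
a Guo-style non-equilibrium extrapolation scaled by the cell fluid
fraction.  What the generator does *not* emulate: velocity aliasing,
partial-volume effects at the lumen edge, slice-dependent noise
correlation, or wall motion; passing tests therefore demonstrate the
correctness of the interpolation/boundary machinery, not robustness to
real scanner artifacts.

## Problem sizes and determinism

Desk-scale defaults used by the validation scripts: geometry accuracy at
`N_D = 127` (`q = 8` and 16), the laminar benchmark at `N_D = 150` on the
periodic slab, grid convergence at `N_D = 153 vs 181`, order of accuracy at
21/63/189.  Every generator and driver is deterministic given its
arguments; the only random source (profile noise) takes an explicit seed.

## Known limitations

* Rigid, static walls only: no moving-boundary migration step, no wall
  elasticity, no Windkessel/impedance outlets.
* Single-relaxation-time collision; no turbulence closure — high-Reynolds
  runs are direct simulation and stability near `τ → 1/2` is not
  guaranteed.
* Far-field signed distances are approximate (documented bound above);
  exact values are guaranteed only in the interface band the solver
  actually consumes.
* WNS includes the reference-pressure offset `p₀`; only pressure
  *differences* are physical in this weakly compressible formulation.
* The wall-stress extrapolation assumes the strain field is resolved within
  ~3 cells of the wall; at very coarse resolution (Stokes layer thinner
  than the sampling offsets) WSS errors grow accordingly.
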