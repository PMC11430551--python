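# Methods

## Model

cardiotet solves the monodomain reaction–diffusion equation on a
tetrahedral mesh,

    dV/dt = ∇·(D ∇V) − I_ion/C_m − I_stim/C_m,

where `V` (mV) is the transmembrane voltage, `D` (mm²/ms) a scalar
(isotropic) propagation coefficient, `C_m` (µF/cm²) the membrane
capacitance, and `I_ion` the total ionic current of the Luo–Rudy 1991
(LR91) guinea-pig ventricular myocyte model.  LR91 contributes six
currents — fast sodium `I_Na` (gates m, h, j), slow inward calcium-like
`I_si` (gates d, f, with dynamic intracellular calcium `Ca_i`),
time-dependent potassium `I_K` (gate X and inactivation factor Xi),
time-independent `I_K1`, plateau `I_Kp`, and a linear background `I_b` —
and eight state fields per node.  Gates follow the Hodgkin–Huxley form
`du/dt = α(V)(1−u) − β(V)u` with the published rate functions; the two
removable 0/0 singularities (α_m at V = −47.13 mV, Xi at V = −77 mV) are
replaced by their analytic limits so exact grid voltages never produce
NaN.

The resting state is not hard-coded: `init_resting` solves for the root of
the steady-state total current (gates at α/(α+β), calcium at its fixed
point) with Brent's method, giving V_rest ≈ −84.6 mV for default constants
and a residual current ~1e−15 µA/cm².  This makes "resting tissue is a
fixed point" exact to solver precision, which the resting-skip optimization
relies on.

### Short-plateau variant

The textbook LR91 action potential lasts ~360 ms.  The tissue validation
scenario, however, expects full activation by ~40 ms and full
repolarization inside a 150 ms window, which implies a much shorter
plateau.  `CellConstants.short_apd()` therefore zeroes the slow-inward
conductance `g_si`, shortening the action potential to ~55 ms while
leaving the upstroke, peak (≈ +42 mV) and resting potential essentially
unchanged.  Tissue-level experiments default to this variant; single-cell
defaults keep the full published constants.  (The simulated peak slightly
exceeds the nominal −100…+40 mV envelope usually quoted for the model;
tests assert the physiological band −100…+60 mV.)

## Spatial discretization

The diffusion operator is a graph Laplacian on the mesh's edge graph:

    (L V)_i = Σ_{j ∈ N(i)} w_ij (V_j − V_i),   w_ij = D / |x_i − x_j|².

The inverse-square distance coefficient reduces to the standard
finite-difference `D/h²` stencil on a regular grid, is symmetric (so
Σ_i (L V)_i = 0 exactly and total voltage is conserved under pure
diffusion), homogeneous of degree one in D, and vanishes with D.  No
published formula exists for the distance coefficients, so the weight
scheme is pluggable (`compute_diffusion_weights(..., scheme=...)`); a
row-normalized variant can be swapped in without touching the solvers.
Boundary nodes simply have fewer neighbors, which realizes the no-flux
condition.

Neighbor structure is the *enhanced adjacency list*: per-node fixed-width
arrays of neighbor indices (padded with −1, weights padded with 0) plus a
degree vector, built in one vectorized pass over the tetrahedra with
duplicate edges removed.  Fixed-width rows are what the vectorized backend
gathers from; access per node touches only `degree[i]` entries.  BFS
renumbering (`bfs_renumber`) relabels nodes in first-in-first-out dequeue
order, enqueueing neighbors in ascending old-index order for determinism;
disconnected components are appended from the lowest unvisited index so
the permutation stays total.  On shuffled structured slabs this reliably
reduces graph bandwidth, the locality proxy the reordering targets.

## Time stepping

Operator splitting advances reaction and diffusion separately inside each
Δt.  The reaction sub-step uses forward Euler or classic RK4; the
diffusion sub-step is always forward Euler (a first-order fused update —
applying RK4 to the stiff gate equations is what buys accuracy; the
diffusion term is comparatively benign at these step sizes).

* **coupled** (reference): reaction produces V*, then
  `V_{t+1} = V* + Δt · L V*`.  The diffusion phase reads the *current*
  step's reaction output of every node, so all nodes must finish reacting
  first.
* **decoupled** (delayed PDE): `V_{t+1} = V* + Δt · L V_t`, with the
  Laplacian evaluated entirely on the previous step's committed voltages.
  Each node then needs only its own state plus already-final neighbor
  values: updates are order-independent (tested bitwise under permuted
  update order) and no intra-step synchronization exists.  The price is an
  O(Δt) consistency error; the error study measures it directly.  The
  Laplacian is lagged as a whole (not only its neighbor terms) so a
  spatially uniform field still has exactly zero diffusion.

Both schemes read from one buffer of a `BufferPair` and write the other,
alternating by step parity (`t & 1` compute, `(t+1) & 1` transfer), which
is what allows the output stage to stream the committed buffer while the
next step computes.

**Stability.** Explicit integration of LR91 is limited by the sodium
activation gate: at rest β_m ≈ 175 ms⁻¹, so forward Euler requires
Δt ≲ 0.011 ms and RK4 Δt ≲ 0.016 ms.  The default Δt = 0.005 ms sits
safely inside; Δt = 0.02 ms diverges for any explicit scheme here.  A
guard aborts the run (with the step index) if any voltage exceeds 200 mV
in magnitude or turns non-finite.  The diffusion constraint
Δt·Σ_j w_ij ≲ 1 is far from binding at default D and spacing
(≈ 0.11 at Δt = 0.005 ms).

**Resting-node skip.** A node skips its reaction sub-step when it carries
no stimulus, its previous-step neighbor-difference sum is below
ε_ΔV = 1e−6 mV, and its voltage is within ε_V = 1e−3 mV of rest.  Because
the initial state is the exact equilibrium, skipped and unskipped
trajectories agree to well below 1e−6 mV.  The skip defaults to on for the
scalar backend and off for the vectorized one, where data-dependent
branching would defeat whole-array execution.

## Backends and the output pipeline

Two engines implement identical semantics: `vectorized` (whole-array numpy
updates, the stand-in for SIMD kernels) and `scalar_reference` (a per-node
loop applying the same kernels to length-1 slices, the stand-in for the
serial program).  They agree bitwise on the tested meshes; the suite
enforces ≤ 1e−9 mV.  The mathematical correctness of the LR91 kernels is
checked separately against a pure-Python implementation of the published
formulas and against an adaptive `scipy.integrate.solve_ivp` reference.

Cell state lives in structure-of-arrays layout: one contiguous float64 row
per field in an (8, n) block, with zero-copy named views.  Of the ~60
quantities the model touches per node, 20 are run-constant and stored once
(`CONSTANT_PARAMETERS`); `parameter_accounting` turns the 60/20/40
partition into per-node byte counts (480 → 320 bytes at 8 bytes each, a
33% saving).  The published account gives only these totals, so the
enumeration itself (8 state fields, 8 currents, 12 rates, 6 steady states,
6 derived/bookkeeping quantities; 20 constants) is this package's own,
asserted in tests to reproduce the totals.

The snapshot writer emulates the asynchronous transfer pipeline: committed
voltages are copied at submit time, placed on a bounded queue (a full
queue blocks the producer — backpressure, never data loss) and drained by
a writer thread.  Pipelined and synchronous modes produce byte-identical
files; sink failures surface on the simulation thread.

## Synthetic meshes and calibrated defaults

`generate_synthetic_mesh` builds structured slabs of nx·ny·nz nodes with
each cubic cell split into six tetrahedra (Kuhn triangulation), optionally
with a seeded node-index shuffle to emulate poorly ordered meshes.  The
16×16×17 slab (4352 nodes, 0.25 mm spacing) is sized like a small
anatomical ventricular mesh; because its geometry, stimulus footprint and
conductivity are idealized, scheme-error magnitudes measured on it are
meaningful in order of magnitude and trend, not to the digit.

Calibrated once and then fixed:

* `D = 0.1 mm²/ms` (= 0.001 cm²/ms, a standard monodomain value): corner
  or top-patch stimulation fully activates the 4352-node slab in ~8 ms,
  comfortably inside the ~40 ms budget the validation scenario targets.
* Tissue stimulus: −80 µA/cm² for 2 ms.  The single-cell default pulse
  (0.5 ms) fails in tissue because diffusion drains the stimulated patch
  below threshold before the sodium current ignites.
* Long-duration error studies pace the tissue periodically (250 ms cycle)
  — without re-stimulation everything rests after one beat and the
  per-sample error would dilute trivially with duration.

What the synthetic slab does *not* capture: anatomical geometry and wall
curvature, fiber-orientation anisotropy (D is scalar), heterogeneous cell
types, and graded element sizes.  Passing tests demonstrate the numerics
and the scheme contracts, not predictive accuracy for any real heart.

## Problem sizes used in the studies

The scheme-error study runs the 4352-node slab for 100 ms at
Δt ∈ {0.005, 0.001} ms (forward Euler, so the measured discrepancy
isolates the delayed-PDE term rather than integrator differences),
sampling every 0.5 ms and pooling all nodes; the duration-stability study
runs a 216-node slab for 0.5 s and 1 s under pacing; the validation run
uses RK4 at Δt = 0.005 ms for 150 ms (the package's default
configuration).

## Known limitations

* Explicit integrators only; no implicit/semi-implicit diffusion, so Δt
  is stability-limited rather than accuracy-limited.
* Scalar conductivity; no bidomain equations; single cell model (though
  any model exposing `init_resting`/`ode_rhs`/`parameter_accounting`-style
  kernels can plug into the stepping layer).
* The scalar reference backend is a semantic reference, not a fast path:
  it is ~100× slower than the vectorized engine and intended for
  equivalence testing on small meshes.
* Wall-clock speedup ratios reported by `speedup_ratio` compare runs on
  whatever hardware executes them; they are bookkeeping, not a
  reproduction of any published hardware benchmark.
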