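# Methods

`cellsqueeze` simulates a single deformable cancer cell carried by a
pressure-driven flow into a constricted microchannel, measures the entry
time and elongation index that deformability-cytometry experiments report,
and identifies the five dimensionless membrane parameters of the cell model
from such measurements by a genetic algorithm.  This note records the
models, the numerical choices, and the limits of what the test suite
demonstrates.

## Fluid solver

The suspending medium is an incompressible Newtonian fluid solved with the
lattice-Boltzmann method on a D3Q19 lattice with the single-relaxation-time
(BGK) collision operator,

    n_i(x + e_i Δt, t + Δt) = n_i(x, t) − (1/τ)[n_i − n_i^eq] + f_i ,

with the standard second-order low-Mach equilibrium and Guo forcing
(half-force velocity shift).  Macroscopic density and momentum are the
zeroth and first moments of the populations.  Walls are realized by
half-way bounce-back, which places the no-slip plane midway between the
last fluid and first solid lattice site and conserves mass locally.

Default physical constants (one lattice unit = Δx = 1 µm, Δt = 0.01 µs):
kinematic viscosity ν = 1.1×10⁻⁶ m²/s, density ρ = 1025 kg/m³, giving a
fluid relaxation time τ = 3 ν Δt/Δx² + ½ = 0.533.  Configurations with
τ ∉ (0.5, 2) are rejected: below the lower bound the implied viscosity is
non-positive; above 2 the bounce-back wall location degrades.

**Flow driving.**  The channel is driven by a constant density (pressure)
difference between equilibrium inlet/outlet layers, calibrated cell-free so
the steady flow rate matches the pump setting (20 µL/h nominal).  A
constant-head condition, not an imposed flux, is essential: an entering
cell occludes the constriction, and the flow rate must be free to collapse
and recover — the simulated flow-rate dip during squeezing is one of the
model's characteristic outputs.  Calibration exploits Stokes-regime
linearity (flow rate ∝ head), so a proportional update converges in one or
two short steady runs to within 1%.

**Interior viscosity.**  The cell interior is VR times more viscous than
the exterior.  This is realized through a per-site relaxation-time map:
lattice sites strictly inside the membrane (even-odd ray parity, retagged
every 10 steps — the membrane moves far less than one lattice spacing per
step) collide with τ_in = 3·VR·ν_lat + ½.

**Validation.**  Steady pressure-gradient-driven flow in a rectangular duct
is compared against the classic Fourier-series solution (100 terms); on an
18×18 cross-section the maximum profile error is below 2% (measured ≈0.2%).
Mass is conserved to ~10⁻¹⁴ per thousand steps; the rest equilibrium is a
machine-precision fixed point; a uniform body force accelerates the fluid
by exactly f/ρ per step.

## Membrane model

The cell is a closed icosphere (642 vertices / 1280 triangles / 1920 edges
at the standard resolution; coarser or finer subdivision levels are
available) with four constitutive nodal force families, each proportional
to the thermal energy k_BT and a dimensionless modulus:

* **link** (per edge): −(K_l k_BT / P) · ε · [1 + 1/(τ_l² − ε²)], with
  strain ε = (L−L₀)/L₀, persistence length P = 7.5 nm, τ_l = 3;
* **bending** (per adjacent-triangle pair): −(K_b k_BT / L₀) · δθ ·
  [1 + 1/(τ_b² − δθ²)], δθ the change of the signed dihedral angle between
  outward normals, τ_b = π/6;
* **local area** (per triangle): −(K_a k_BT / L₀) · α ·
  [1 + 1/(τ_a² − α²)], α = (A−A₀)/A₀, τ_a = 0.3;
* **global volume**: −(K_v k_BT / L₀) · β · [1/(τ_v² − β²)],
  β = (V−V₀)/V₀, τ_v = 0.01.  This law's bracket has no "1 +" term; it is
  implemented exactly as published (the constant offsets only rescale the
  effective modulus far from the singularity).

The reference configuration is the freshly constructed sphere, captured
with the same floating-point expressions used during force evaluation so
the reference state is a bit-exact zero of every law.

**Force distribution choices** (the published laws specify magnitudes
only):

* bending forces act along the analytic gradient of the dihedral angle
  with respect to the four hinge vertices (verified against finite
  differences to 10⁻⁹), scaled by the hinge reference length; this yields
  zero net force *and* zero net torque per hinge and is restoring by
  construction;
* area forces act along centroid-to-vertex vectors weighted by centroid
  distance, making the per-triangle net force identically zero;
* the volume force acts along area-weighted vertex normals (one third of
  each incident face normal), whose closed-surface sum is identically
  zero;
* the dihedral sign convention orients the shared edge along the first
  face's winding, so convex and concave deviations are distinguished
  consistently between reference and deformed states.

**Limiting factors abort, never clamp.**  A deviation at or beyond its
limiting factor raises a diagnostic error identifying the offending
edge/hinge/triangle.  Exceeding a limit signals a broken time step;
clamping would silently corrupt parameter identification.  During GA
evaluation such an abort is treated like a capped (non-completing) run.

The inner-loop evaluation is a fused compiled kernel; a test asserts it
matches the sum of the four reference implementations to ~10⁻¹² relative.

## Fluid–structure coupling

Immersed-boundary coupling with a tensor-product Peskin kernel: the
4-point cosine kernel by default, the 2-point tent kernel selectable.
Membrane forces are spread to the lattice, f(x) = Σ_q F(q) δ(x − X(q));
vertex velocities are interpolated with the same kernel and vertices are
advected by forward Euler (massless membrane; the membrane carries no
inertia and moves with the local fluid).  Sharing one kernel makes the
momentum transfer exactly conservative, which a test asserts at the
10⁻¹² level over random configurations.

Cell–wall contact is a pairwise repulsion between membrane vertices and
wall-surface lattice sites closer than d_cut = 0.8 µm:
F = κ_rep (d_cut/d) m̂, κ_rep = 0.004, m̂ pointing from the wall site into
the fluid.  Since d_cut is below one lattice spacing, only each vertex's
immediate lattice neighbourhood is scanned (linear cost; equivalent to a
cell-list at this cutoff).  Exact contact (d = 0) aborts.

## Entry simulation

A run computes the steady cell-free flow first, then inserts the cell on
the channel axis with its centroid 1.5 radii upstream of the taper start
(so the insertion transient settles before the entry measurement), and
loops: membrane + wall forces → spread → fluid step → interpolate →
advect.  The trace records time, centroid, leading/trailing vertex
positions, axial length, instantaneous flow rate (measured at a plane near
the outlet), and enclosed volume.

Entry metrics follow the experimental definitions: entry starts when the
leading vertex crosses the constriction entrance plane (the downstream end
of the 45° taper) and ends when the trailing vertex does; crossing times
are linearly interpolated between recorded frames to remove stride
quantization.  L₀ is the axial length at the last frame before entry
starts, L₁ the length at completion; the elongation index is L₁/L₀.  Runs
continue 25% beyond completion so the flow-rate recovery is visible, and a
time cap (in identification: twice the experimental entry time) returns an
explicit no-entry result.

## Device geometry

Each device is a straight channel with one constriction: upstream width
3× the constriction width, a 45° tapered entrance, and heights measured at
28 µm for the fabricated devices (8/10/12 µm presets).  Axial lengths
upstream and downstream of the taper are not part of the published
geometry; the defaults (40 µm each) are long enough for an 18 µm cell to
complete entry and are configurable.  Voxelization marks a site fluid when
its voxel centre lies strictly inside the fluid region (half-open
intervals), which makes open areas exact: e.g. the 10 µm preset gives
10×28 = 280 µm² in the constriction and 30×28 = 840 µm² upstream.

## Genetic-algorithm identification

The five unknowns (K_l, K_b, K_a, K_v, VR) are encoded in a 640-bit
string, 128 bits per parameter, decoded linearly between bounds (moduli
0–10⁶, VR 0–40); the all-zero/all-one strings hit the bounds exactly.
Per generation: 60 parents → consecutive pairing → single-point crossover
with probability 0.8 → per-bit mutation (flip when a uniform draw exceeds
the 0.6 threshold, i.e. a 0.4 flip rate) → 120 candidates, each evaluated
by running the forward model in the three devices (360 runs per
generation) with a time cap of twice the experimental entry time; a capped
run contributes |1 − 2| = 1 to the error

    Error = Σ_devices |1 − ET_sim/ET_exp| .

The best 20 candidates seed the next population (elitism ⇒ the best error
is non-increasing); remaining seats are refilled randomly; the loop stops
when the best error is unchanged for 20 generations.  All randomness flows
through one seeded generator, making identification reproducible
bit-for-bit; evaluations are memoized on the bit string so elites are not
re-simulated.

The crossover/mutation thresholds follow the conventional reading of the
published procedure (crossover *with* probability 0.8; mutation flip when
the draw exceeds 0.6) and are configurable.  The 0.4 per-bit flip rate
makes the algorithm behave like elitist random search — adequate for the
published identification protocol, but for quantitative optimum-recovery
studies a low flip rate (e.g. mutation threshold 0.95) is the appropriate
configuration and is what the recovery experiment uses.

## Synthetic data and the surrogate forward model

No raw experimental scatter is deposited, so the generator emulates its
published statistical structure: entry times exponential in diameter,
ET(d) = a·exp(b·d), diameters uniform on 13–21 µm, multiplicative
lognormal noise (entry times are positive and right-skewed; default
σ_log = 0.15), and per-device curves ordered so narrower constrictions are
slower and more size-sensitive.  Cell-line presets are calibrated to pass
through the published fitted values at d = 18 µm (device #2: 10.6 / 16.2 /
27.4 ms for the three lines; 15.1 / 10.6 / 6.4 ms across devices for the
most invasive line); the exponential rates b (0.12–0.30 µm⁻¹) are chosen
to reproduce the published ordering of diameter sensitivity, not fitted to
unpublished raw data.  Elongation indices are anchored to the published
18 µm values (1.27/1.18/1.11 across devices).  Every dataset is
regenerable bit-exactly from its recorded seed.

The surrogate forward model is a deterministic closed form (documented in
its docstring) standing in for the full FSI simulation in GA tests:
strictly increasing in every modulus and in VR, increasing in diameter,
decreasing in constriction width.  Its parameter sensitivities vary with
(diameter, width) through five linearly independent weight functions, so a
grid of device/diameter targets makes all five parameters observable —
without this conditioning, entry times alone leave a sloppy parameter
manifold and optimum recovery would be meaningless.  The recovery
experiment manufactures ground-truth targets at a known optimum (three
devices × six diameters), restricts the search to a ±25% box around it
(the identifiable regime), and demands the GA reproduce the entry times to
an error below 0.05 and every parameter within 10%.

## Problem sizes used by the test suite and acceptance script

Full-scale transit at the fabricated geometry (≈10⁵ lattice sites,
≈10⁵–10⁶ steps per entry) is supported by the same code path but takes
hours per run on one CPU.  The suite therefore exercises the complete
coupled physics on a reduced device family chosen as this package's
standard desk-scale study: constrictions 5/6/7 µm wide (integer multiples
of the lattice spacing — a half-lattice width cannot be voxelized), 10 µm
high, upstream length 10 µm and constriction length 16 µm (domain
≈31×17×12 sites), cells 5.75–6.75 µm in diameter (162-vertex meshes; the
same cell/constriction mismatch range ≈1.1–1.35 as the experiments), flow
rate 20 µL/h, and a stiff parameter set (K_l = K_a = 10⁵, K_b = 5×10⁴,
K_v = 2×10⁴, VR = 3).  At this scale one entry takes a few ×10⁴ steps
(≈1–2 min).  The physics checks assert the experimentally established
*orderings* — entry time increasing with diameter, decreasing with
constriction width, the flow-rate dip during squeezing (deeper for
tighter squeezes), post-transit recovery in a device with a wide
downstream section, and volume drift below 1% — not absolute millisecond
values, which depend on the absolute scale.  Narrower desk-scale devices
(≤4.75 µm, mismatch ≳1.3 at this resolution) push local dihedral or area
deviations past their limiting factors: the wall layer smeared by the
immersed-boundary kernel then spans most of the gap, a resolution effect,
not a property of the constitutive model.

Known stability envelope of the explicit coupling: the volume constraint
is the stiffest law (its bracket is O(1/τ_v²) = 10⁴); with forward-Euler
coupling its modulus must satisfy roughly K_v·k_BT,lat ≲ 10⁻⁵ lattice
units (K_v ≲ a few ×10⁴ at the default Δt), and the product K·k_BT,lat
grows as Δt², so raising the time step proportionally lowers the stable
moduli.  The limiting-factor aborts make violations loud rather than
silent.

## Known limitations

* No nucleus, no membrane viscosity, no thermal fluctuations, no
  adhesion, one cell at a time — matching the published model's scope.
* The forcing scheme, boundary-condition family, and axial domain lengths
  are not published; the choices here (Guo forcing, equilibrium pressure
  layers, 40 µm segments) are standard but not guaranteed identical, so
  full-scale entry times should be compared with tolerance, not
  bit-exactly.
* The synthetic generator reproduces curve shapes and orderings, not the
  unpublished raw scatter; passing synthetic-data tests demonstrates the
  pipeline's correctness, not agreement with any particular laboratory's
  cells.
* At desk scale the constriction is only ~5 lattice sites wide; the
  immersed-boundary kernel then smears the wall layer across a
  significant fraction of the gap, so absolute entry times at that scale
  are not quantitative — only orderings are asserted.
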