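# Methods

Formulation and numerical choices of the coupled folding / pathfinding
model.  Units: length mm, time day, stress Pa.

## 1. Tissue mechanics

### Geometry

A rectangular plane-strain slice of width `w` holds a white-matter
substrate of depth `h` topped by a cortical plate of thickness `t_c`
(reference pial surface at `y = h + t_c`).  The domain is meshed with
structured bilinear quads of edge `elem_size`; elements are labelled
`CORTEX`, `ECM` (unconverted white matter) or `FIBER` (white matter
traversed by a bundle).  Boundary conditions: mirror-symmetric lateral
walls (`u_x = 0`), fixed base (`u_y = 0`), traction-free top.

### Morphoelastic growth

The deformation gradient decomposes multiplicatively into elastic and
growth parts, `F = Fe · Fg`.  With `n0` the referential pial normal:

- cortex (tangential/area growth):
  `Fg = √θ I + (1 − √θ) n0 ⊗ n0`, so `det Fg = θ`;
- substrate (isotropic/volume growth): `Fg = θ^(1/3) I`.

Growth kinetics are linear, `θ̇ = G`, with cortical rate
`G_ctx = 0.02 /day` and substrate rate `G_sub = G_ctx / growth_ratio`
(ratio 6 by default).  The dimensionless simulation time is
`T = G_ctx · t`; a standard run spans `T ∈ [0, 1]` (50 days), over which
the cortical multiplier doubles.  An exponential law (`θ̇ = Gθ`) is
available as a switch.

### Constitutive law

Both layers are compressible neo-Hookean with energy

```
W(Fe) = μ/2 (J^(−2/3) tr(FeᵀFe) − 3) + k/2 (J − 1)²,  J = det Fe,
```

with `k/μ = 50` (near-incompressible) and shear moduli
`μ_s = 100 Pa` (ECM), `μ_c = 2 μ_s` (cortex), `μ_f = 2 μ_s` (fiber) by
default.  Plane strain is realised by carrying full 3×3 tensors with
`F_33 = 1`, so tangential growth naturally produces out-of-plane elastic
stress.

### Discretisation and quasi-statics

Elements use one-point reduced integration with Flanagan–Belytschko
hourglass control (viscous-stiffness form, coefficient 0.2, calibrated
so the hourglass energy stays negligible against the strain energy while
suppressing spurious modes at the post-buckling amplitudes reached here).

The equilibrium path is followed by explicit central-difference dynamics:

- **Time increment.**  `dt = t_end / (agent_steps · substeps)`.
- **Mass scaling.**  The nodal density is a numerical device chosen from
  the dilatational-wave stability condition for the stiffest admitted
  material, with a safety margin of 6 on the tangent stiffness:
  `ρ = 6 (k/μ + 4/3) μ_max (dt / (dt_safety · elem_size))²`.
- **Damping.**  Mass-proportional damping `c = 20 /day`, calibrated so
  the post-buckling response is overdamped but the fold pattern still
  develops within the run.
- **Validity.**  A run is quasi-static only if the kinetic-to-internal
  energy ratio stays ≤ 5 % for all `T > 0.1`; the maximum ratio is
  tracked and reported, and a `quasi_static_violation` flag is raised
  otherwise.  Kinetic blow-up (KE > 10× IE) and element inversion abort
  the run.

### The damping × mass-scaling artifact and the substep count

Mass-proportional damping acts on the *scaled* mass.  The steadily
rising growing column therefore feels a spurious body force
`ρ c v_y` — a "numerical gravity" proportional to the scaled density,
i.e. to `dt²`.  Left uncontrolled it produces an artificial compressive
prestress of tens of Pa in the substrate, which delays folding onset and
stalls slowly growing bundles (the towed term `a·σ` turns negative).
The artifact was verified to scale linearly with `ρ`: doubling the
substep count four-fold reduces the spurious base stress from ≈ −27 Pa
to ≈ −1.7 Pa.  Defaults therefore use `substeps = 160` at
`elem_size = 0.5` (artifact ≈ −2 Pa ≪ the ~10–100 Pa physical stresses),
and reduced-scale test configurations use `substeps = 80` at
`elem_size = 0.75`.  When refining the mesh, scale the substep count
accordingly (e.g. 320 at 0.25 mm).

### Optional pial self-contact

Off by default.  When enabled, a node-to-segment linear penalty acts on
the pial polyline (range `0.5·elem_size`, stiffness `5 μ_c`), mitigating
interpenetration of deep sulci.  Without it, fold flanks may overlap
late in a run; the condition is detected (shapely `is_simple` on the
pial line) and flagged in the report.

## 2. Axon-bundle agents

`n_fibers` bundles are seeded at `t = 0`, uniform over `x ∈ [0, w]`,
`y ∈ [0, seed_band]`, with initial headings uniform in `π/2 ± 10 %`.
Each bundle carries its own random stream (seeded reproducibly from the
run seed), so trajectories are reproducible per agent.

Each agent step (`Δt = t_end / agent_steps = 0.1 day`):

1. **Advection.**  Tips are material points (element + parent
   coordinates); every tip moves with the tissue.
2. **Stress probe.**  The element-centred Cauchy stress at the tip is
   decomposed in-plane; the state is *degenerate* if the two principal
   values coincide within `1e-6 · max(|σ₁|, μ_s)`.
3. **Noise.**  Gaussian heading noise, std `noise_std = 0.025 rad`.
4. **Reorientation.**  Unless disabled, degenerate, or the leading
   principal stress is compressive, the heading `n^A` rotates toward the
   sign-aligned MTPS direction with angular rate
   `ω = π/(2 t*) ‖n^A × n_max‖` (`t* = 300` steps), applied as an exact
   rotation (never overshoots; preserves `‖n^A‖ = 1` to machine
   precision).  The gap angle follows the closed-form tan-half-angle
   decay used as a test oracle.
5. **Elongation.**  `ΔL = [a (σ_axial − σ₀) + G_axn] Δt` with
   `a = 0.015 (mm/day)/Pa`, `σ₀ = 0`, intrinsic rate `G_axn` (default
   0.8 mm/day); compressive increments are clamped at zero.
6. **Domain.**  A tip stepping through a symmetry wall or the base is
   mirrored back (position and heading) — walls are mirror-symmetry
   planes of the mechanical model.
7. **Conversion.**  Every ECM element whose deformed footprint the step
   segment traverses converts irreversibly to fiber material
   (`μ_f`, same `k/μ`), effective from the next force evaluation.
8. **Termination.**  A tip entering a cortex element settles; a tip that
   cannot be located in the deformed domain stalls (terminal, flagged).

The stress sensitivity `a` is bracketed by published towing
measurements, converted to (mm/day)/Pa either from a growth-rate /
elastic-modulus pair (`a = G/E`) or from a force-rate threshold `b`
(mm/h per nN) and axon diameter `D` (µm):
`a = b · (π D²/4) · 24 / 1000` (nN/µm² = kPa).

## 3. Metrics

- **Gyrification index.**  Pial arc length divided by the length of the
  upper convex-hull chain of the pial polyline (flat line → GI = 1).
- **Gyral/sulcal classification.**  The mid-surface is the pointwise
  mean of matched pial and interface columns; a column is *gyral* iff
  its mid-surface height is at or above the mean mid-surface level
  (flat geometry ties to gyral).
- **Fiber densities.**  Settled tips are assigned to the nearest
  interface point; counts per class are normalised by the class arc
  length (half of each segment attributed to each endpoint) and
  expressed as percentages summing to 100.
- **Volume fractions.**  Deformed-area fractions of fiber vs ECM within
  the white matter (`V_f + V_ecm = 1`), and the equivalent stiffness
  `V_f · μ_f/μ_s + V_ecm`.
- **Local stiffness map.**  Area-weighted mean stiffness ratio in a
  disc neighbourhood (shapely STRtree).
- **Angular distribution.**  Tip headings folded into `[0, π)`,
  histogrammed to unit mass.

## 4. Ensembles and statistics

`run_ensemble` derives per-replicate integer seeds from a master seed
(`numpy.random.SeedSequence.spawn`), so the same master seed yields the
same replicate seeds across scenarios — common random numbers, making
cross-scenario comparisons paired and deterministic.  `run_sweep`
stacks ensembles over one parameter and optionally applies a pairwise
Tukey HSD (statsmodels).  Reported summaries are mean, SD and SEM over
replicates.

## 5. Reproducibility and I/O

Runs are deterministic given a config (hashable; YAML/JSON round-trip).
Outputs are text-only: legacy ASCII VTK (17 significant digits, lossless
round-trip), tidy CSV trajectories and series, JSON reports and surface
polylines.
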