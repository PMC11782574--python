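# foldax

Coupled simulation of cortical folding and axon-bundle pathfinding in a
two-dimensional brain-tissue slice.

During fetal development the cortical plate grows tangentially faster than
the white matter beneath it; the mechanical mismatch buckles the bilayer
into gyri (outward folds) and sulci (inward folds).  At the same time,
axon bundles grow up from the deep white matter toward the cortex.  `foldax`
models the hypothesis that these two processes are mechanically coupled:

- **Folding drives wiring.**  Growing axon tips sense the local stress
  state, gradually reorient toward the maximum tensile principal stress
  (MTPS) direction, and elongate faster under axial tension (towed growth).
  The developing folds shape the stress field, so fibers are steered
  preferentially into gyri.
- **Wiring stiffens tissue.**  Elements of the extracellular matrix
  traversed by a bundle are irreversibly converted into stiffer fiber
  material, which feeds back on the folding mechanics.

The model reproduces the characteristic observations: fibers accumulate
under gyral crowns rather than sulcal fundi, weaker intrinsic tip growth
(stronger relative stress guidance) increases that bias, and stiffer
cortex or fiber material changes fold wavelength and fiber targeting.

## Model summary

- **Tissue mechanics** — plane-strain morphoelasticity.  The deformation
  gradient is decomposed as `F = Fe · Fg`; the cortex grows tangentially
  (`det Fg = θ`, area growth), the substrate isotropically (`θ^(1/3) I`),
  with linear kinetics `θ̇ = G` and a cortex-to-substrate rate ratio of 6.
  Both layers are compressible neo-Hookean (`k/μ = 50`).  The bilayer is
  discretised with bilinear quads (one-point integration plus hourglass
  control) and driven to quasi-static equilibrium by explicit dynamics
  with mass scaling and mass-proportional damping; runs are valid only if
  the kinetic-to-internal energy ratio stays below 5 %.
- **Axon agents** — discrete bundles seeded near the base grow by
  `ΔL = [a·(σ − σ₀) + G_axn] Δt`, where `σ` is the axial normal stress at
  the tip; the growth direction receives Gaussian angle noise and relaxes
  toward the MTPS direction with time constant `t*`.  Tips advect with the
  tissue as material points; traversed elements convert to fiber material;
  a bundle settles when it reaches the cortex.
- **Metrics** — gyrification index (pial arc length over its upper convex
  hull), gyral/sulcal classification against the mid-surface, normalized
  fiber densities per unit interface length, fiber volume fraction, local
  and equivalent stiffness ratios, tip-angle distributions.

Units throughout: mm, day, Pa.

See [docs/methods.md](docs/methods.md) for the full formulation and the
numerical choices (damping, mass scaling, substep counts).

## Worked example

A reduced-scale run (24 mm slice, 0.75 mm elements, 12 bundles, ~5 s):

```python
from foldax.config import SimulationConfig
from foldax.driver import run_simulation

cfg = SimulationConfig(w=24.0, h=30.0, t_c=1.5, elem_size=0.75,
                       substeps=80, agent_steps=500, n_fibers=12, seed=0)
res = run_simulation(cfg, record_trajectories=False)
r = res.report
print(f"GI = {r.GI:.3f}")
print(f"gyral density = {r.gyral_density_pct:.1f}%  sulcal = {r.sulcal_density_pct:.1f}%")
print(f"arrivals = {r.n_reached}/{r.n_fibers}")
print(f"fiber volume fraction = {r.V_f:.3f}")
print(f"max KE/IE = {res.max_energy_ratio:.4f}")
```

Output:

```
GI = 1.766
gyral density = 100.0%  sulcal = 0.0%
arrivals = 11/12
fiber volume fraction = 0.332
max KE/IE = 0.0366
```

The bilayer folds (GI well above 1), all settled fibers end under gyral
crowns, and the energy ratio confirms the run stayed quasi-static.

The same from the command line, writing VTK fields, trajectories and a
JSON report:

```bash
foldax run --set w=24.0 --set elem_size=0.75 --set substeps=80 \
           --set n_fibers=12 --seed 0 --out out/demo
```

Ensembles and parameter sweeps (with optional Tukey post-hoc tests):

```bash
foldax ensemble --set n_fibers=20 --replicates 10 --out ens.csv
foldax sweep --param G_axn --values 0.6,0.8,1.2 --tukey --out sweep.csv
```

Published axon elongation-rate measurements converted to the model's
stress-sensitivity parameter `a` in (mm/day)/Pa:

```bash
$ foldax table1
         system conversion  a_lower  a_upper  a_lower_2dp  a_upper_2dp
        rat DRG    modulus 0.000435 0.020000         0.00         0.02
rat hippocampal force_rate 0.311018 0.311018         0.31         0.31
chick forebrain force_rate 0.000942 0.009425         0.00         0.01
      chick DRG force_rate 0.001508 0.041469         0.00         0.04
```

The default `a = 0.015` sits inside the span of these measurements.

## Reproduction

- `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
  recomputes the headline targets: the four elongation-rate conversions
  and the maximum kinetic-to-internal energy ratio of the default coarse
  coupled baseline (must be ≤ 5 %).  Budget: well under 20 minutes on one
  CPU.
- `pytest -q` runs the full suite, including one acceptance test per
  criterion (`tests/test_acceptance.py`): the rate targets, the
  quasi-static baseline, the guidance-strength effect on gyral density
  (10-replicate paired ensembles), desk-checkable model properties
  against independent oracles, and a trend battery over stiffness ratios,
  noise and the reorientation switch.  The whole suite takes ~15 minutes
  on one CPU.

Defaults reproduce the coarse baseline (60 mm slice, 0.5 mm elements,
100 bundles).  For full-fidelity runs, refine with
`--set elem_size=0.25 --set substeps=320` (the substep count scales with
mesh refinement to keep the damping/mass-scaling artifact bounded; see
docs/methods.md).

## Package layout

| module | contents |
| --- | --- |
| `foldax.kinematics` | growth tensors, neo-Hookean law, principal decompositions |
| `foldax.mesh` | structured bilayer quad mesh |
| `foldax.solver` | explicit quasi-static FE solver (+ optional pial self-contact) |
| `foldax.agents` | axon-bundle agents: seeding, guidance, elongation |
| `foldax.driver` | coupled runs, ensembles, sweeps |
| `foldax.metrics` | GI, gyral/sulcal classification, densities, stiffness |
| `foldax.elongation` | literature elongation-rate conversions |
| `foldax.fields` | analytic stress fields + agent sandbox (test fixtures) |
| `foldax.io` | ASCII VTK, CSV and JSON readers/writers |
| `foldax.cli` | `foldax` command-line interface |
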