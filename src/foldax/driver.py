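"""Coupled folding / pathfinding simulation driver.

One run interleaves, per agent step: (1) growth + explicit quasi-static
substeps of the bilayer, (2) advection of every bundle tip with the tissue
(tips are material points), (3) for each growing bundle a stress probe at
its tip, angle noise, reorientation toward the signed maximum tensile
principal stress, stress-modulated elongation, conversion of traversed ECM
elements into fiber elements, and a termination check at the cortex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from foldax.agents import (
    AxonBundle,
    BundleStatus,
    add_angle_noise,
    advance_tip,
    axial_stress,
    check_termination,
    elements_crossed_by_segment,
    elongation_increment,
    material_point_position,
    reflect_into_domain,
    reorient,
    seed_bundles,
    stall,
)
from foldax.config import SimulationConfig
from foldax.kinematics import Region
from foldax.metrics import (
    MetricsReport,
    compute_report,
    gyrification_index,
    volume_fractions,
)
from foldax.solver import BilayerSolver, PointLocationError, make_solver

__all__ = [
    "SimulationResult",
    "EnsembleResult",
    "SweepResult",
    "run_simulation",
    "run_ensemble",
    "run_sweep",
]


@dataclass
class SimulationResult:
    """Everything produced by one coupled run."""

    config: SimulationConfig
    solver: BilayerSolver
    bundles: list[AxonBundle]
    report: MetricsReport
    series: pd.DataFrame  # per agent step: t, T, GI, V_f, KE, IE, ratio, ...
    records: pd.DataFrame  # per agent per step: agent, step, x, y, theta, ...
    flags: list = field(default_factory=list)

    @property
    def GI(self) -> float:
        return self.report.GI

    @property
    def max_energy_ratio(self) -> float:
        """Max kinetic/internal energy ratio over T in (0.1, 1]."""
        return self.solver.max_energy_ratio

    def save(self, out_dir) -> Path:
        """Write VTK fields, trajectories CSV and report JSON to a directory."""
        from foldax import io as fio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        m = self.solver.mesh
        fio.write_vtk(
            out / "final_fields.vtk",
            m.nodes,
            m.quads,
            cell_data={"region": self.solver.region, "mu": self.solver.mu},
            point_data={"displacement": self.solver.state.u},
        )
        fio.write_trajectories_csv(out / "trajectories.csv", self.records)
        fio.write_report_json(
            out / "report.json",
            {
                "config": self.config.to_dict(),
                "metrics": self.report.to_dict(),
                "max_energy_ratio": self.max_energy_ratio,
                "flags": list(self.flags),
            },
        )
        fio.write_polyline_json(
            out / "surfaces.json",
            {
                "pial": self.solver.pial_polyline(),
                "interface": self.solver.interface_polyline(),
            },
        )
        self.series.to_csv(out / "series.csv", index=False)
        return out


def _init_material_coords(bundle: AxonBundle, mesh) -> None:
    """Set (elem, xi, eta) from the undeformed seed position."""
    e = mesh.elem_of_reference_point(bundle.tip)
    ix, iy = mesh.elem_grid_coords(e)
    es = mesh.elem_size
    bundle.elem = e
    bundle.xi = 2.0 * (bundle.tip[0] / es - ix) - 1.0
    bundle.eta = 2.0 * (bundle.tip[1] / es - iy) - 1.0


def run_simulation(
    config: SimulationConfig, record_trajectories: bool = True
) -> SimulationResult:
    """Run one coupled folding/pathfinding simulation to T = 1."""
    solver = make_solver(config)
    mesh = solver.mesh
    bundles = seed_bundles(config.n_fibers, config, config.seed)
    for b in bundles:
        _init_material_coords(b, mesh)

    rec: list[tuple] = []
    series_rows: list[dict] = []
    mu_ratio = config.mu_f_over_mu_s

    for k in range(config.agent_steps):
        solver.step_explicit(config.substeps)
        u = solver.state.u

        # tips are material points: all of them advect with the tissue
        for b in bundles:
            b.tip = material_point_position(mesh, u, b.elem, b.xi, b.eta)

        for b in bundles:
            sigma = math.nan
            if b.status is BundleStatus.GROWING:
                try:
                    T, ps, e = solver.probe_stress(b.tip, hint_elem=b.elem)
                except PointLocationError:
                    stall(b, "tip left the deformed domain")
                else:
                    b.theta = add_angle_noise(b.theta, config.noise_std, b.rng)
                    if (
                        config.reorientation_enabled
                        and not ps.degenerate
                        and ps.sigma[0] >= 0.0
                    ):
                        b.set_direction(reorient(b.nA, ps.n_max, config.t_star))
                    sigma = axial_stress(T, b.nA)
                    dL = elongation_increment(sigma, config, config.agent_dt)
                    p0 = b.tip.copy()
                    advance_tip(b, dL)
                    new_tip, new_theta = reflect_into_domain(
                        b.tip, b.theta, config.w
                    )
                    if new_theta != b.theta or new_tip[0] != b.tip[0] or new_tip[1] != b.tip[1]:
                        b.tip = new_tip
                        b.theta = new_theta
                        b.path[-1] = new_tip.copy()
                    try:
                        crossed = elements_crossed_by_segment(
                            solver, p0, b.tip, hint=b.elem
                        )
                        e2, xi, eta = solver.locate_deformed(b.tip, hint_elem=e)
                    except PointLocationError:
                        b.tip = p0
                        b.path[-1] = p0.copy()
                        stall(b, "tip advanced outside the deformed domain")
                    else:
                        b.occupied.extend(solver.convert_to_fiber(crossed))
                        b.elem, b.xi, b.eta = e2, xi, eta
                        check_termination(b, int(solver.region[e2]))
            if record_trajectories:
                rec.append(
                    (b.id, k, b.tip[0], b.tip[1], b.theta, sigma, b.status.value)
                )

        vf, _ = volume_fractions(mesh, solver.region, u)
        series_rows.append(
            {
                "step": k,
                "t": solver.state.t,
                "T": solver.state.T_dimless(config.G_ctx),
                "theta_c": solver.state.theta_c,
                "GI": gyrification_index(solver.pial_polyline()),
                "V_f": vf,
                "equivalent_stiffness": vf * mu_ratio + (1.0 - vf),
                "kinetic_energy": solver.state.kinetic_energy,
                "internal_energy": solver.state.internal_energy,
                "energy_ratio": solver.energy_ratio(),
                "n_settled": sum(
                    1 for b in bundles if b.status is BundleStatus.SETTLED
                ),
            }
        )

    solver.check_pial_simple()
    flags = list(solver.flags)
    if solver.max_energy_ratio > 0.05:
        flags.append("quasi_static_violation")
    report = compute_report(
        mesh, solver.region, solver.state.u, bundles, mu_ratio, flags=flags
    )
    records = pd.DataFrame(
        rec, columns=["agent", "step", "x", "y", "theta", "sigma", "status"]
    )
    return SimulationResult(
        config=config,
        solver=solver,
        bundles=bundles,
        report=report,
        series=pd.DataFrame(series_rows),
        records=records,
        flags=flags,
    )


# --------------------------------------------------------------------- #
# ensembles and parameter sweeps
# --------------------------------------------------------------------- #

_METRIC_COLS = [
    "GI",
    "gyral_density_pct",
    "sulcal_density_pct",
    "n_reached",
    "V_f",
    "equivalent_stiffness",
    "max_energy_ratio",
]


def replicate_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-replicate integer seeds derived from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0]) for child in ss.spawn(n)]


@dataclass
class EnsembleResult:
    """Per-replicate metrics table plus summary statistics."""

    config: SimulationConfig
    table: pd.DataFrame  # one row per replicate
    results: list | None = None  # full SimulationResults when kept

    def summary(self) -> pd.DataFrame:
        """Mean, SD and SEM of each metric over replicates."""
        num = self.table[_METRIC_COLS]
        return pd.DataFrame(
            {
                "mean": num.mean(),
                "sd": num.std(ddof=1),
                "sem": num.sem(ddof=1),
            }
        )

    def convergence(self, column: str = "GI") -> pd.DataFrame:
        """Running mean/SD of one metric versus replicate count."""
        x = self.table[column].to_numpy(dtype=float)
        n = np.arange(1, len(x) + 1)
        running_mean = np.cumsum(x) / n
        running_sd = np.array(
            [np.std(x[: i + 1], ddof=1) if i > 0 else np.nan for i in range(len(x))]
        )
        return pd.DataFrame(
            {"n": n, "running_mean": running_mean, "running_sd": running_sd}
        )


def run_ensemble(
    config: SimulationConfig,
    n_replicates: int | None = None,
    keep_results: bool = False,
) -> EnsembleResult:
    """Run ``n_replicates`` independent replicates (distinct derived seeds)."""
    n = config.n_replicates if n_replicates is None else n_replicates
    if n < 1:
        raise ValueError("need at least one replicate")
    rows = []
    results = [] if keep_results else None
    for i, s in enumerate(replicate_seeds(config.seed, n)):
        res = run_simulation(config.replace(seed=s), record_trajectories=False)
        row = {"replicate": i, "seed": s}
        d = res.report.to_dict()
        for c in _METRIC_COLS:
            row[c] = res.max_energy_ratio if c == "max_energy_ratio" else d.get(c)
        rows.append(row)
        if keep_results:
            results.append(res)
    return EnsembleResult(config=config, table=pd.DataFrame(rows), results=results)


@dataclass
class SweepResult:
    """Tidy per-replicate table across a parameter sweep + post-hoc tests."""

    param: str
    table: pd.DataFrame
    tukey: pd.DataFrame | None = None

    def group_means(self, response: str) -> pd.Series:
        return self.table.groupby("value")[response].mean()


def run_sweep(
    config: SimulationConfig,
    param: str,
    values,
    n_replicates: int | None = None,
    response: str = "gyral_density_pct",
    tukey: bool = False,
) -> SweepResult:
    """Ensemble at each value of one config parameter.

    The same derived replicate seeds are reused across values (common random
    numbers), so cross-value comparisons are paired.  With ``tukey=True`` a
    pairwise Tukey HSD on ``response`` across values is included.
    """
    frames = []
    for v in values:
        ens = run_ensemble(config.replace(**{param: v}), n_replicates)
        t = ens.table.copy()
        t.insert(0, "value", v)
        t.insert(0, "param", param)
        frames.append(t)
    table = pd.concat(frames, ignore_index=True)
    tk = None
    if tukey:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        sub = table.dropna(subset=[response])
        res = pairwise_tukeyhsd(
            sub[response].to_numpy(dtype=float),
            sub["value"].astype(str).to_numpy(),
        )
        tk = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    return SweepResult(param=param, table=table, tukey=tk)
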