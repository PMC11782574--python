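"""Explicit quasi-static solver for the growth-driven bilayer folding problem.

Quasi-statics is reached through explicit central-difference dynamics with
mass scaling and mass-proportional damping: the nodal mass is a numerical
device chosen from the stable-increment condition, and validity of every run
is judged by the kinetic-to-internal energy ratio, which must stay below 5%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from foldax import _kernels
from foldax.config import SimulationConfig
from foldax.kinematics import (
    PrincipalStress,
    Region,
    principal_decomposition,
    principal_decomposition_2d,
)
from foldax.mesh import Mesh, build_bilayer_mesh

__all__ = ["SolverState", "BilayerSolver", "SolverError", "PointLocationError"]

# margin on the dilatational-wave stability estimate: covers stiffening of the
# tangent moduli under deformation and element-edge shortening in compression
_STIFFNESS_MARGIN = 6.0


class SolverError(RuntimeError):
    pass


class PointLocationError(ValueError):
    """Requested probe point lies outside the deformed domain."""


@dataclass
class SolverState:
    """Mutable solver state: displacements, velocities, growth, energies."""

    u: np.ndarray
    v: np.ndarray
    t: float = 0.0
    theta_c: float = 1.0
    theta_s: float = 1.0
    kinetic_energy: float = 0.0
    internal_energy: float = 0.0

    def T_dimless(self, G_ctx: float) -> float:
        return G_ctx * self.t


class BilayerSolver:
    """Coupled mesh + material state + explicit time integrator.

    Parameters
    ----------
    mesh : Mesh
    config : SimulationConfig
        Supplies moduli, growth rates and the time-discretisation choices.
    """

    def __init__(self, mesh: Mesh, config: SimulationConfig):
        self.mesh = mesh
        self.config = config
        E = mesh.n_elems

        self.region = mesh.elem_region.copy()
        self.mu = np.where(
            self.region == int(Region.CORTEX), config.mu_c, config.mu_s
        ).astype(float)
        self.kbulk = config.k_over_mu * self.mu

        self.dNdX, self.area, self.gamma = _kernels.precompute_gradients(
            mesh.nodes, mesh.quads
        )
        if np.any(self.area <= 0):
            raise SolverError("non-positive reference Jacobian in mesh")

        # time increment from the agent-step discretisation, nodal mass from
        # the stable-increment condition for the stiffest material admitted
        # (mass scaling): dt_stable = L * sqrt(rho / M_eff)
        self.dt = config.t_end / (config.agent_steps * config.substeps)
        mu_max = max(config.mu_c, config.mu_f, config.mu_s)
        m_eff = _STIFFNESS_MARGIN * (config.k_over_mu + 4.0 / 3.0) * mu_max
        self.density = m_eff * (self.dt / (config.dt_safety * config.elem_size)) ** 2

        self.mass = np.zeros(mesh.n_nodes)
        elem_mass = self.density * self.area / 4.0
        np.add.at(self.mass, mesh.quads.ravel(), np.repeat(elem_mass, 4))

        self.fix_x = np.zeros(mesh.n_nodes, dtype=bool)
        self.fix_y = np.zeros(mesh.n_nodes, dtype=bool)
        self.apply_boundary_conditions()

        self.state = SolverState(
            u=np.zeros((mesh.n_nodes, 2)), v=np.zeros((mesh.n_nodes, 2))
        )
        self.stress = np.zeros((E, 4))  # per element: T11, T22, T12, T33
        # optional pial self-contact: linear penalty, range half an element
        self.contact_r = 0.5 * config.elem_size if config.contact_enabled else 0.0
        self.contact_k = 5.0 * config.mu_c
        self._f_int = np.zeros((mesh.n_nodes, 2))
        self.max_energy_ratio = 0.0  # over T in [ratio_window_start, end]
        self.energy_series: list[tuple[float, float, float]] = []  # (t, KE, IE)
        self.flags: list[str] = []

    # ------------------------------------------------------------------ #
    # boundary conditions
    # ------------------------------------------------------------------ #
    def apply_boundary_conditions(self) -> None:
        """Symmetric walls (u_x = 0 left/right), fixed base (u_y = 0), free top."""
        self.fix_x[:] = False
        self.fix_y[:] = False
        self.fix_x[self.mesh.sets["left"]] = True
        self.fix_x[self.mesh.sets["right"]] = True
        self.fix_y[self.mesh.sets["bottom"]] = True

    # ------------------------------------------------------------------ #
    # forces and stepping
    # ------------------------------------------------------------------ #
    def internal_forces(self) -> np.ndarray:
        """Assembled nodal internal force vector at the current state."""
        ie, bad = _kernels.internal_forces(
            self.mesh.quads,
            self.dNdX,
            self.area,
            self.gamma,
            self.region,
            self.mu,
            self.kbulk,
            self.state.theta_c,
            self.state.theta_s,
            self.state.u,
            self._f_int,
            self.stress,
            self.config.hourglass_coef,
        )
        if bad >= 0:
            raise SolverError(
                f"element {bad} inverted at t = {self.state.t:.4f} d"
            )
        self.state.internal_energy = ie
        return self._f_int.copy()

    def step_explicit(self, n_steps: int = 1, dt: float | None = None) -> SolverState:
        """Advance ``n_steps`` central-difference increments.

        Growth multipliers advance per increment at the configured region
        rates before each force evaluation.  Raises on element inversion or
        kinetic-energy blow-up (KE > 10x IE).
        """
        dt = self.dt if dt is None else dt
        cfg = self.config
        ke = np.empty(n_steps)
        ie = np.empty(n_steps)
        theta_c, theta_s, status, bad = _kernels.run_substeps(
            n_steps,
            dt,
            self.mesh.nodes,
            self.mesh.quads,
            self.dNdX,
            self.area,
            self.gamma,
            self.region,
            self.mu,
            self.kbulk,
            self.state.u,
            self.state.v,
            self.mass,
            self.fix_x,
            self.fix_y,
            cfg.damping,
            cfg.G_ctx,
            cfg.G_sub,
            self.state.theta_c,
            self.state.theta_s,
            cfg.exponential_kinetics,
            self._f_int,
            self.stress,
            cfg.hourglass_coef,
            self.mesh.pial,
            self.contact_r,
            self.contact_k,
            ke,
            ie,
        )
        self.state.theta_c = theta_c
        self.state.theta_s = theta_s
        self.state.t += n_steps * dt
        self.state.kinetic_energy = float(ke[-1])
        self.state.internal_energy = float(ie[-1])
        self.energy_series.append((self.state.t, float(ke[-1]), float(ie[-1])))
        T = self.state.T_dimless(cfg.G_ctx)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(ie > 0, ke / np.maximum(ie, 1e-300), 0.0)
        if T > 0.1:  # quasi-static validity window starts after growth onset
            self.max_energy_ratio = max(self.max_energy_ratio, float(ratios.max()))
        if status == _kernels.STATUS_INVERTED:
            raise SolverError(f"element {bad} inverted at t = {self.state.t:.4f} d")
        if status == _kernels.STATUS_BLOWUP:
            raise SolverError(
                f"kinetic energy blow-up (> 10x internal) at t = {self.state.t:.4f} d"
            )
        return self.state

    def energy_ratio(self) -> float:
        """Kinetic / internal energy at the current step (0 when IE = 0)."""
        if self.state.internal_energy <= 0.0:
            return 0.0
        return self.state.kinetic_energy / self.state.internal_energy

    # ------------------------------------------------------------------ #
    # material conversion (ECM element -> fiber element)
    # ------------------------------------------------------------------ #
    def convert_to_fiber(self, elems) -> list[int]:
        """Relabel ECM elements as fiber and assign mu_f (irreversible).

        Cortex and already-fiber elements are left unchanged.  The new
        modulus takes effect from the next force evaluation.
        """
        converted = []
        for e in np.atleast_1d(elems):
            if self.region[e] == int(Region.ECM):
                self.region[e] = int(Region.FIBER)
                self.mu[e] = self.config.mu_f
                self.kbulk[e] = self.config.k_over_mu * self.config.mu_f
                converted.append(int(e))
        return converted

    # ------------------------------------------------------------------ #
    # field queries
    # ------------------------------------------------------------------ #
    def locate_deformed(self, x, hint_elem: int | None = None) -> tuple[int, float, float]:
        """Element of the deformed domain containing point ``x``.

        Returns (element, xi, eta); raises PointLocationError when the point
        is outside the deformed domain.
        """
        x = np.asarray(x, dtype=float)
        m = self.mesh
        if hint_elem is None:
            hint_elem = m.elem_of_reference_point(x)
        hx, hy = m.elem_grid_coords(hint_elem)
        max_ring = max(m.nx, m.ny)
        e, xi, eta = _kernels.locate_deformed_point(
            x[0], x[1], m.nodes, m.quads, self.state.u, m.nx, m.ny, hx, hy, max_ring
        )
        if e < 0:
            raise PointLocationError(f"point {x} outside deformed domain")
        return int(e), float(xi), float(eta)

    def element_stress(self, e: int) -> np.ndarray:
        """Stored 3x3 Cauchy stress at the centre of element ``e``."""
        s = self.stress[e]
        return np.array(
            [[s[0], s[2], 0.0], [s[2], s[1], 0.0], [0.0, 0.0, s[3]]]
        )

    def probe_stress(self, x, hint_elem: int | None = None):
        """Cauchy stress + principal decomposition at a deformed-domain point.

        Locates the containing element and returns its (centre-integrated)
        stress together with the in-plane principal decomposition.
        """
        e, _, _ = self.locate_deformed(x, hint_elem)
        T = self.element_stress(e)
        ps = principal_decomposition_2d(T, mu_scale=self.config.mu_s)
        return T, ps, e

    def probe_stress_3d(self, x) -> tuple[np.ndarray, PrincipalStress]:
        T, _, e = self.probe_stress(x)
        return T, principal_decomposition(T, mu_scale=self.config.mu_s)

    # ------------------------------------------------------------------ #
    # geometry helpers
    # ------------------------------------------------------------------ #
    def pial_polyline(self) -> np.ndarray:
        return self.mesh.polyline_coords(self.mesh.pial, self.state.u)

    def interface_polyline(self) -> np.ndarray:
        return self.mesh.polyline_coords(self.mesh.interface, self.state.u)

    def deformed_element_polygon(self, e: int) -> np.ndarray:
        return self.mesh.elem_polygon(e, self.state.u)

    def check_pial_simple(self) -> bool:
        """Flag pial self-intersection (deep sulci touching without contact)."""
        from shapely.geometry import LineString

        simple = LineString(self.pial_polyline()).is_simple
        if not simple and "pial_self_intersection" not in self.flags:
            self.flags.append("pial_self_intersection")
        return simple


def make_solver(config: SimulationConfig) -> BilayerSolver:
    """Convenience constructor: build the bilayer mesh and its solver."""
    mesh = build_bilayer_mesh(
        config.w,
        config.h,
        config.t_c,
        config.elem_size,
        node_perturbation=config.node_perturbation,
        perturbation_modes=config.perturbation_modes,
    )
    return BilayerSolver(mesh, config)
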