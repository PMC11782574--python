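"""Analytic stress fields and an agent sandbox for pathfinding tests.

These fixtures exercise the agent dynamics (noise, reorientation toward the
maximum tensile principal stress, stress-modulated elongation) against
closed-form stress fields whose principal decompositions are known exactly,
without running the finite-element solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from foldax.agents import (
    AxonBundle,
    add_angle_noise,
    advance_tip,
    axial_stress,
    elongation_increment,
    reorient,
)
from foldax.kinematics import principal_decomposition_2d

__all__ = ["AnalyticStressField", "make_field", "agent_sandbox"]


@dataclass
class AnalyticStressField:
    """A closed-form in-plane Cauchy stress field T(x, y).

    ``kind`` selects the field; ``params`` hold its coefficients.  Calling
    the instance at a point returns the 2x2 in-plane stress tensor.
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __call__(self, p) -> np.ndarray:
        x, y = float(p[0]), float(p[1])
        q = self.params
        if self.kind == "uniform":
            return np.asarray(q["T"], dtype=float)
        if self.kind == "rotated_uniaxial":
            ang = q["angle"]
            s = q["magnitude"]
            n = np.array([np.cos(ang), np.sin(ang)])
            return s * np.outer(n, n)
        if self.kind == "spatially_varying":
            # uniaxial field whose principal direction rotates linearly in x
            ang = q["angle0"] + q["dangle_dx"] * x
            s = q["magnitude"] + q.get("dmag_dy", 0.0) * y
            n = np.array([np.cos(ang), np.sin(ang)])
            return s * np.outer(n, n)
        if self.kind == "degenerate":
            return q["magnitude"] * np.eye(2)
        raise ValueError(f"unknown field kind {self.kind!r}")

    def principal_direction(self, p) -> np.ndarray:
        """Exact maximum-principal direction at ``p`` (for oracles)."""
        if self.kind == "uniform":
            w, v = np.linalg.eigh(np.asarray(self.params["T"], dtype=float))
            return v[:, int(np.argmax(w))]
        if self.kind == "rotated_uniaxial":
            ang = self.params["angle"]
            return np.array([np.cos(ang), np.sin(ang)])
        if self.kind == "spatially_varying":
            ang = self.params["angle0"] + self.params["dangle_dx"] * float(p[0])
            return np.array([np.cos(ang), np.sin(ang)])
        raise ValueError(f"no unique principal direction for {self.kind!r}")


def make_field(kind: str, **params) -> AnalyticStressField:
    """Build an analytic field; validates the parameter set for the kind."""
    required = {
        "uniform": {"T"},
        "rotated_uniaxial": {"angle", "magnitude"},
        "spatially_varying": {"angle0", "dangle_dx", "magnitude"},
        "degenerate": {"magnitude"},
    }
    if kind not in required:
        raise ValueError(f"unknown field kind {kind!r}")
    missing = required[kind] - set(params)
    if missing:
        raise ValueError(f"field {kind!r} missing parameters {sorted(missing)}")
    return AnalyticStressField(kind=kind, params=dict(params))


def agent_sandbox(
    field_obj: AnalyticStressField,
    config,
    bundles: list[AxonBundle],
    n_steps: int,
) -> dict:
    """Run agent dynamics against an analytic stress field.

    No mesh, no advection, no element conversion, no termination: each step
    applies angle noise, reorientation toward the signed MTPS direction
    (skipped for degenerate or compressive principal states or when
    reorientation is disabled), and the stress-modulated tip advance.
    Returns per-agent trajectories and angle histories.
    """
    traj = {b.id: [b.tip.copy()] for b in bundles}
    angles = {b.id: [b.theta] for b in bundles}
    for _ in range(n_steps):
        for b in bundles:
            T = field_obj(b.tip)
            ps = principal_decomposition_2d(T, mu_scale=config.mu_s)
            b.theta = add_angle_noise(b.theta, config.noise_std, b.rng)
            if (
                config.reorientation_enabled
                and not ps.degenerate
                and ps.sigma[0] >= 0.0
            ):
                b.set_direction(
                    reorient(b.nA, ps.n_max, config.t_star, dt=1.0)
                )
            sigma = axial_stress(T, b.nA)
            dL = elongation_increment(sigma, config, config.agent_dt)
            advance_tip(b, dL)
            traj[b.id].append(b.tip.copy())
            angles[b.id].append(b.theta)
    return {
        "trajectories": {i: np.array(v) for i, v in traj.items()},
        "angles": {i: np.array(v) for i, v in angles.items()},
        "bundles": bundles,
    }
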