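"""Growth-tensor kinematics and the neo-Hookean stress law at material points.

The deformation gradient is decomposed multiplicatively, F = F_e . F_g, into
an irreversible growth part and a stress-generating elastic part.  Cortical
growth is tangential (area growth normal to the pial normal n0), substrate
growth is isotropic (volume growth).  Plane strain is realised by carrying
full 3x3 tensors with F_33 = 1, so the out-of-plane elastic compression that
tangential growth induces arises naturally.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = [
    "Region",
    "MaterialPointState",
    "PrincipalStress",
    "cortical_growth_tensor",
    "subcortical_growth_tensor",
    "advance_growth_multiplier",
    "elastic_part",
    "cauchy_stress",
    "strain_energy_density",
    "principal_decomposition",
    "principal_decomposition_2d",
    "DEGENERACY_REL_TOL",
]

_I3 = np.eye(3)

#: relative tolerance for declaring the two leading principal stresses equal;
#: scaled by max(|sigma_1|, mu_scale) so a near-zero stress state is treated
#: as degenerate (no meaningful tensile direction).
DEGENERACY_REL_TOL = 1e-6


class Region(IntEnum):
    """Material region of an element / integration point."""

    CORTEX = 0
    ECM = 1
    FIBER = 2


class ElementInversionError(RuntimeError):
    """det(F_e) <= 0 at an integration point."""


@dataclass
class MaterialPointState:
    """Per-integration-point state (growth, moduli, kinematics, stress)."""

    region: Region
    theta_g: float = 1.0
    n0: np.ndarray | None = None
    mu: float = 100.0
    k: float = 5000.0
    F: np.ndarray | None = None
    Fg: np.ndarray | None = None
    Fe: np.ndarray | None = None
    T: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.theta_g < 1.0:
            raise ValueError("growth multiplier must be >= 1")
        if self.n0 is not None:
            n0 = np.asarray(self.n0, dtype=float)
            if abs(np.linalg.norm(n0) - 1.0) > 1e-12:
                raise ValueError("n0 must be a unit vector")
            self.n0 = n0

    def growth_tensor(self) -> np.ndarray:
        if self.region is Region.CORTEX:
            n0 = self.n0 if self.n0 is not None else np.array([0.0, 1.0, 0.0])
            return cortical_growth_tensor(self.theta_g, n0)
        return subcortical_growth_tensor(self.theta_g)

    def update(self, F: np.ndarray) -> np.ndarray:
        """Set the total gradient; recompute Fg, Fe and the Cauchy stress."""
        self.F = np.asarray(F, dtype=float)
        self.Fg = self.growth_tensor()
        self.Fe = elastic_part(self.F, self.Fg)
        self.T = cauchy_stress(self.Fe, self.mu, self.k)
        return self.T


@dataclass
class PrincipalStress:
    """Ordered principal values and orthonormal directions of a Cauchy stress.

    ``degenerate`` is set when the two leading values coincide within
    tolerance; consumers of the guidance field must then skip any
    stress-induced reorientation.
    """

    sigma: np.ndarray
    n: np.ndarray  # columns are the unit directions
    degenerate: bool

    @property
    def n_max(self) -> np.ndarray:
        return self.n[:, 0]


def _embed3(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape == (2,):
        return np.array([v[0], v[1], 0.0])
    if v.shape == (3,):
        return v
    raise ValueError("direction must be a 2- or 3-vector")


def cortical_growth_tensor(theta_g: float, n0: np.ndarray) -> np.ndarray:
    """Tangential (area) growth tensor sqrt(theta) I + (1 - sqrt(theta)) n0 x n0.

    Growth stretches the plane orthogonal to the referential surface normal
    ``n0`` by sqrt(theta) and leaves the normal direction unstretched; the
    determinant equals ``theta_g`` (the areal growth multiplier).
    """
    if theta_g < 1.0:
        raise ValueError(f"growth multiplier must be >= 1, got {theta_g}")
    n0 = _embed3(n0)
    if abs(np.linalg.norm(n0) - 1.0) > 1e-9:
        raise ValueError("n0 must be a unit vector")
    s = np.sqrt(theta_g)
    return s * _I3 + (1.0 - s) * np.outer(n0, n0)


def subcortical_growth_tensor(theta_g: float) -> np.ndarray:
    """Isotropic (volume) growth tensor theta^(1/3) I with det = theta_g."""
    if theta_g < 1.0:
        raise ValueError(f"growth multiplier must be >= 1, got {theta_g}")
    return theta_g ** (1.0 / 3.0) * _I3


def advance_growth_multiplier(
    theta_g: float, rate: float, dt: float, exponential: bool = False
) -> float:
    """Forward-Euler step of the growth kinetics.

    Linear law (default): theta_dot = rate, so theta_{k+1} = theta_k + rate*dt.
    Exponential law:      theta_dot = rate * theta.
    """
    if rate < 0:
        raise ValueError("growth rate must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if exponential:
        return theta_g * (1.0 + rate * dt)
    return theta_g + rate * dt


def elastic_part(F: np.ndarray, Fg: np.ndarray) -> np.ndarray:
    """Elastic deformation gradient F_e = F . F_g^-1."""
    F = np.asarray(F, dtype=float)
    Fg = np.asarray(Fg, dtype=float)
    det = np.linalg.det(Fg)
    if abs(det) < 1e-300:
        raise np.linalg.LinAlgError("growth tensor is singular")
    return F @ np.linalg.inv(Fg)


def cauchy_stress(Fe: np.ndarray, mu: float, k: float) -> np.ndarray:
    """Cauchy stress of the compressible neo-Hookean law.

    The free energy is W = mu/2 (J^(-2/3) tr(Fe^T Fe) - 3) + k/2 (J - 1)^2,
    giving T = (mu / J) J^(-2/3) dev(b) + k (J - 1) I with b = Fe Fe^T.
    """
    Fe = np.asarray(Fe, dtype=float)
    J = np.linalg.det(Fe)
    if J <= 0:
        raise ElementInversionError(f"det(Fe) = {J} <= 0")
    b = Fe @ Fe.T
    dev_b = b - (np.trace(b) / 3.0) * _I3
    T = (mu / J) * J ** (-2.0 / 3.0) * dev_b + k * (J - 1.0) * _I3
    return 0.5 * (T + T.T)


def strain_energy_density(Fe: np.ndarray, mu: float, k: float) -> float:
    """Neo-Hookean free energy per unit intermediate (grown) volume."""
    Fe = np.asarray(Fe, dtype=float)
    J = np.linalg.det(Fe)
    if J <= 0:
        raise ElementInversionError(f"det(Fe) = {J} <= 0")
    I1 = np.trace(Fe.T @ Fe)
    return 0.5 * mu * (J ** (-2.0 / 3.0) * I1 - 3.0) + 0.5 * k * (J - 1.0) ** 2


def principal_decomposition(
    T: np.ndarray, mu_scale: float = 1.0, tol_rel: float = DEGENERACY_REL_TOL
) -> PrincipalStress:
    """Eigen-decomposition of a symmetric Cauchy stress, values descending."""
    T = np.asarray(T, dtype=float)
    vals, vecs = np.linalg.eigh(0.5 * (T + T.T))
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    tol = tol_rel * max(abs(vals[0]), mu_scale)
    degenerate = abs(vals[0] - vals[1]) <= tol
    return PrincipalStress(sigma=vals, n=vecs, degenerate=degenerate)


def principal_decomposition_2d(
    T: np.ndarray, mu_scale: float = 1.0, tol_rel: float = DEGENERACY_REL_TOL
) -> PrincipalStress:
    """In-plane (2x2 block) principal decomposition used for agent guidance."""
    T = np.asarray(T, dtype=float)
    T2 = T[:2, :2]
    vals, vecs = np.linalg.eigh(0.5 * (T2 + T2.T))
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    tol = tol_rel * max(abs(vals[0]), mu_scale)
    degenerate = abs(vals[0] - vals[1]) <= tol
    return PrincipalStress(sigma=vals, n=vecs, degenerate=degenerate)
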