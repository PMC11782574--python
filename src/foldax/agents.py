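"""Discrete axon-bundle agents.

Each bundle is a growth-cone-tipped agent that elongates stochastically
(tip growth with Gaussian angle noise), accelerates under axial tension
(towed growth), and gradually reorients its preferred direction n^A toward
the maximum tensile principal stress (MTPS) direction of the surrounding
matrix.  Tips are tracked in the deformed frame as material points (element
+ parent coordinates), so settled and embedded segments advect with the
tissue; conversion of traversed ECM elements into stiffer fiber elements is
how bundles feed back on the folding mechanics.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BundleStatus",
    "AxonBundle",
    "seed_bundles",
    "orient_sign",
    "rotation_vector",
    "reorient",
    "add_angle_noise",
    "axial_stress",
    "elongation_increment",
    "advance_tip",
    "check_termination",
    "elements_crossed_by_segment",
    "material_point_position",
]


class BundleStatus(enum.Enum):
    GROWING = "growing"
    SETTLED = "settled"
    STALLED = "stalled"


@dataclass
class AxonBundle:
    """One growing axon-bundle agent."""

    id: int
    tip: np.ndarray  # current deformed-frame position, mm
    theta: float  # angle of n^A from +x, rad
    rng: np.random.Generator
    length: float = 0.0
    status: BundleStatus = BundleStatus.GROWING
    path: list = field(default_factory=list)
    occupied: list = field(default_factory=list)  # converted element ids
    # material coordinates of the tip (containing element + parent coords)
    elem: int = -1
    xi: float = 0.0
    eta: float = 0.0

    def __post_init__(self) -> None:
        self.tip = np.asarray(self.tip, dtype=float)
        if not self.path:
            self.path = [self.tip.copy()]

    @property
    def nA(self) -> np.ndarray:
        return np.array([math.cos(self.theta), math.sin(self.theta)])

    def set_direction(self, n: np.ndarray) -> None:
        self.theta = math.atan2(n[1], n[0])


def seed_bundles(n: int, config, rng) -> list[AxonBundle]:
    """Seed ``n`` bundles at t = 0.

    Tips are uniform over x in [0, w] and y in [0, seed_band] mm; initial
    angles are uniform within pi/2 +/- 10%.  ``rng`` may be an integer seed,
    a SeedSequence, or a Generator-producing SeedSequence; each bundle gets
    its own child stream so trajectories are reproducible per agent.
    """
    if n < 1:
        raise ValueError("need at least one bundle")
    if isinstance(rng, (int, np.integer)):
        ss = np.random.SeedSequence(int(rng))
    elif isinstance(rng, np.random.SeedSequence):
        ss = rng
    else:
        raise TypeError("rng must be an int seed or a SeedSequence")
    children = ss.spawn(n + 1)
    master = np.random.default_rng(children[0])
    xs = master.uniform(0.0, config.w, size=n)
    ys = master.uniform(0.0, config.seed_band, size=n)
    half_pi = 0.5 * math.pi
    thetas = master.uniform(0.9 * half_pi, 1.1 * half_pi, size=n)
    return [
        AxonBundle(
            id=i,
            tip=np.array([xs[i], ys[i]]),
            theta=float(thetas[i]),
            rng=np.random.default_rng(children[i + 1]),
        )
        for i in range(n)
    ]


def orient_sign(nA: np.ndarray, n_max: np.ndarray) -> np.ndarray:
    """Resolve the +/- ambiguity of a principal direction toward n^A."""
    return -n_max if float(np.dot(nA, n_max)) < 0.0 else np.asarray(n_max, float)


def rotation_vector(nA: np.ndarray, n_max: np.ndarray, t_star: float) -> float:
    """Signed angular velocity (rad per agent step) about the out-of-plane axis.

    Magnitude pi/(2 t*) * ||n^A x n_max||; the sign is the z-component of the
    cross product, i.e. the sense that rotates n^A toward n_max.
    """
    if t_star <= 0:
        raise ValueError("t_star must be positive")
    cross_z = nA[0] * n_max[1] - nA[1] * n_max[0]
    return math.pi / (2.0 * t_star) * cross_z


def reorient(
    nA: np.ndarray,
    n_max: np.ndarray,
    t_star: float,
    dt: float = 1.0,
    degenerate: bool = False,
) -> np.ndarray:
    """One exponential-scheme update of n^A toward the (sign-aligned) MTPS.

    In 2-D the closed-form rotation reduces to a planar rotation by
    dt * omega; for dt * omega below the angle gap the update never
    overshoots.  Degenerate principal states leave the direction unchanged.
    """
    nA = np.asarray(nA, dtype=float)
    if degenerate:
        return nA.copy()
    n_max = orient_sign(nA, np.asarray(n_max, dtype=float))
    w = rotation_vector(nA, n_max, t_star)
    ang = dt * w
    c, s = math.cos(ang), math.sin(ang)
    out = np.array([c * nA[0] - s * nA[1], s * nA[0] + c * nA[1]])
    return out / np.linalg.norm(out)


def add_angle_noise(theta: float, std: float, rng: np.random.Generator) -> float:
    """Gaussian angle noise, applied once per agent step."""
    if std < 0:
        raise ValueError("std must be non-negative")
    if std == 0.0:
        return theta
    return theta + rng.normal(0.0, std)


def axial_stress(T: np.ndarray, nA: np.ndarray) -> float:
    """Normal stress nA . T . nA experienced along the bundle direction, Pa."""
    T = np.asarray(T, dtype=float)
    n = np.asarray(nA, dtype=float)
    if T.shape[0] == 3 and n.shape == (2,):
        T = T[:2, :2]
    return float(n @ T @ n)


def elongation_increment(sigma: float, config, dt: float) -> float:
    """Length increment Delta L = [a (sigma - sigma_0) + G_axn] dt, mm.

    With the clamp enabled (default) the increment is floored at zero:
    compressive axial stress pauses growth but never retracts the tip.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rate = config.a * (sigma - config.sigma_0) + config.G_axn
    dL = rate * dt
    if config.clamp_negative_growth and dL < 0.0:
        return 0.0
    return dL


def advance_tip(bundle: AxonBundle, dL: float) -> AxonBundle:
    """Move the tip by dL along n^A and append to the path polyline."""
    if bundle.status is not BundleStatus.GROWING:
        raise ValueError("only growing bundles advance")
    if dL != 0.0:
        bundle.tip = bundle.tip + dL * bundle.nA
        bundle.path.append(bundle.tip.copy())
        bundle.length += abs(dL)
    return bundle


def reflect_into_domain(tip: np.ndarray, theta: float, w: float) -> tuple[np.ndarray, float]:
    """Mirror a tip that stepped through a symmetry wall back inside.

    The lateral walls (x = 0, x = w) and the base (y = 0) are mirror-symmetry
    planes of the mechanical model, so an agent crossing one is re-entered at
    the mirrored position with the mirrored heading.
    """
    x, y = float(tip[0]), float(tip[1])
    for _ in range(8):  # repeated reflections for (unphysical) large steps
        if x < 0.0:
            x, theta = -x, math.pi - theta
        elif x > w:
            x, theta = 2.0 * w - x, math.pi - theta
        elif y < 0.0:
            y, theta = -y, -theta
        else:
            break
    return np.array([x, y]), theta


def check_termination(bundle: AxonBundle, region_of_tip: int) -> BundleStatus:
    """Settle the bundle when its tip has crossed into a cortex element."""
    from foldax.kinematics import Region

    if bundle.status is BundleStatus.GROWING and region_of_tip == int(Region.CORTEX):
        bundle.status = BundleStatus.SETTLED
    return bundle.status


def stall(bundle: AxonBundle, reason: str = "") -> None:
    if bundle.status is BundleStatus.GROWING:
        bundle.status = BundleStatus.STALLED
        warnings.warn(f"bundle {bundle.id} stalled: {reason}", stacklevel=2)


# --------------------------------------------------------------------- #
# geometry: material-point advection and segment/element traversal
# --------------------------------------------------------------------- #

_SX = np.array([-1.0, 1.0, 1.0, -1.0])
_SY = np.array([-1.0, -1.0, 1.0, 1.0])


def material_point_position(mesh, u: np.ndarray, elem: int, xi: float, eta: float) -> np.ndarray:
    """Deformed position of a material point given element + parent coords."""
    N = 0.25 * (1.0 + _SX * xi) * (1.0 + _SY * eta)
    x = mesh.nodes[mesh.quads[elem]] + u[mesh.quads[elem]]
    return N @ x


def elements_crossed_by_segment(solver, p0, p1, hint: int | None = None) -> list[int]:
    """All elements whose deformed footprint the segment p0 -> p1 traverses.

    Candidates are taken from the element-grid neighbourhood spanned by the
    two endpoints (padded), and tested exactly with a segment/quad
    intersection predicate; deformation is smooth at the element scale, so
    the padded neighbourhood covers every crossed element.
    """
    from foldax import _kernels

    m = solver.mesh
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    e0, _, _ = solver.locate_deformed(p0, hint)
    e1, _, _ = solver.locate_deformed(p1, e0)
    ix0, iy0 = m.elem_grid_coords(e0)
    ix1, iy1 = m.elem_grid_coords(e1)
    pad = 2
    ix_lo = max(0, min(ix0, ix1) - pad)
    ix_hi = min(m.nx - 1, max(ix0, ix1) + pad)
    iy_lo = max(0, min(iy0, iy1) - pad)
    iy_hi = min(m.ny - 1, max(iy0, iy1) + pad)
    buf = np.empty((ix_hi - ix_lo + 1) * (iy_hi - iy_lo + 1), dtype=np.int64)
    count = _kernels.elements_crossed_window(
        p0[0], p0[1], p1[0], p1[1],
        m.nodes, m.quads, solver.state.u, m.nx,
        ix_lo, ix_hi, iy_lo, iy_hi, buf,
    )
    return [int(e) for e in buf[:count]]
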