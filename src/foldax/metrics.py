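"""Quantitative readouts of a folding/pathfinding run.

Gyrification index (pial arc length over its upper convex-hull chain),
gyral/sulcal classification against the mid-surface, normalized fiber
densities per unit interface arc length, fiber/ECM area fractions, local and
equivalent stiffness ratios, and tip-angle distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from foldax.kinematics import Region

__all__ = [
    "MetricsReport",
    "gyrification_index",
    "upper_hull_length",
    "classify_gyri_sulci",
    "fiber_density",
    "volume_fractions",
    "local_stiffness_map",
    "equivalent_stiffness",
    "angular_distribution",
    "count_reached",
    "compute_report",
]


@dataclass
class MetricsReport:
    """Summary metrics of one run (densities in %, fractions in [0, 1])."""

    GI: float
    gyral_density_pct: float | None
    sulcal_density_pct: float | None
    n_reached: int
    n_fibers: int
    V_f: float
    V_ecm: float
    equivalent_stiffness: float
    angular_hist: np.ndarray | None = None
    angular_bin_edges: np.ndarray | None = None
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "GI": self.GI,
            "gyral_density_pct": self.gyral_density_pct,
            "sulcal_density_pct": self.sulcal_density_pct,
            "n_reached": self.n_reached,
            "n_fibers": self.n_fibers,
            "V_f": self.V_f,
            "V_ecm": self.V_ecm,
            "equivalent_stiffness": self.equivalent_stiffness,
            "flags": list(self.flags),
        }
        if self.angular_hist is not None:
            d["angular_hist"] = list(map(float, self.angular_hist))
            d["angular_bin_edges"] = list(map(float, self.angular_bin_edges))
        return d


def _arc_length(poly: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)))


def upper_hull_length(points: np.ndarray) -> float:
    """Length of the upper convex-hull chain spanning the x-extent of points.

    Only the chain between the leftmost and rightmost points that passes over
    the top is used, so a flat line has hull length equal to its chord and
    GI of a flat pial line is exactly 1.
    """
    pts = np.asarray(points, dtype=float)
    # collinear input: hull degenerates to the chord
    d = pts - pts[0]
    e = d[-1] - d[1:-1]
    cross = d[1:-1, 0] * e[:, 1] - d[1:-1, 1] * e[:, 0]
    if len(pts) < 3 or np.allclose(cross, 0.0, atol=1e-12):
        return float(np.linalg.norm(pts[-1] - pts[0]))
    try:
        hull = ConvexHull(pts)
    except QhullError:
        # near-degenerate (machine-precision deflections off a line)
        return float(np.linalg.norm(pts[-1] - pts[0]))
    verts = hull.vertices  # counter-clockwise
    i_left = int(np.argmin(pts[verts][:, 0] - 1e-12 * pts[verts][:, 1]))
    i_right = int(np.argmax(pts[verts][:, 0] + 1e-12 * pts[verts][:, 1]))
    # walk ccw from rightmost to leftmost: that traversal is the upper chain
    chain = []
    k = i_right
    while True:
        chain.append(verts[k])
        if k == i_left:
            break
        k = (k + 1) % len(verts)
    return _arc_length(pts[chain])


def gyrification_index(pial: np.ndarray) -> float:
    """Pial arc length divided by its upper convex-hull chain length (>= 1)."""
    pial = np.asarray(pial, dtype=float)
    if len(pial) < 2:
        raise ValueError("pial polyline needs at least 2 points")
    hull_len = upper_hull_length(pial)
    if hull_len <= 0:
        raise ValueError("degenerate pial polyline")
    return _arc_length(pial) / hull_len


def classify_gyri_sulci(interface: np.ndarray, pial: np.ndarray) -> np.ndarray:
    """Label interface points as gyral (True) / sulcal (False).

    The mid-surface is the pointwise mean of the pial and interface heights
    at matched samples (the two polylines share column-matched points on the
    structured mesh); it is an intermediate cortical curve whose mean height
    approximates the average position of the cortical surface.  Regions where
    the mid-surface lies at or above that average level are gyral, the rest
    sulcal.  Flat geometry therefore ties everywhere and is gyral by the
    ``>=`` convention.
    """
    interface = np.asarray(interface, dtype=float)
    pial = np.asarray(pial, dtype=float)
    if len(interface) != len(pial):
        raise ValueError("interface and pial must have matched samples")
    mid_y = 0.5 * (interface[:, 1] + pial[:, 1])
    return mid_y >= mid_y.mean()


def _region_lengths(interface: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Arc length of the gyral and sulcal parts (half-segment attribution)."""
    seg = np.linalg.norm(np.diff(interface, axis=0), axis=1)
    point_len = np.zeros(len(interface))
    point_len[:-1] += 0.5 * seg
    point_len[1:] += 0.5 * seg
    return float(point_len[labels].sum()), float(point_len[~labels].sum())


def fiber_density(
    settled_tips: np.ndarray, labels: np.ndarray, interface: np.ndarray
) -> tuple[float, float] | tuple[None, None]:
    """Normalized gyral/sulcal fiber densities in percent (sum to 100).

    Each settled tip is assigned the label of its nearest interface point;
    per-region raw density is count per unit interface arc length, and the
    two densities are normalized by their sum.  Returns (None, None) when no
    tip has settled.
    """
    settled_tips = np.atleast_2d(np.asarray(settled_tips, dtype=float))
    if settled_tips.size == 0:
        return None, None
    interface = np.asarray(interface, dtype=float)
    d2 = (
        (settled_tips[:, None, 0] - interface[None, :, 0]) ** 2
        + (settled_tips[:, None, 1] - interface[None, :, 1]) ** 2
    )
    nearest = np.argmin(d2, axis=1)
    tip_labels = labels[nearest]
    len_g, len_s = _region_lengths(interface, labels)
    rho_g = tip_labels.sum() / len_g if len_g > 0 else 0.0
    rho_s = (~tip_labels).sum() / len_s if len_s > 0 else 0.0
    total = rho_g + rho_s
    if total == 0:
        return None, None
    return 100.0 * rho_g / total, 100.0 * rho_s / total


def _deformed_areas(mesh, u: np.ndarray | None) -> np.ndarray:
    p = mesh.nodes[mesh.quads] if u is None else (mesh.nodes + u)[mesh.quads]
    x, y = p[..., 0], p[..., 1]
    return 0.5 * np.abs(
        x[:, 0] * y[:, 1] - x[:, 1] * y[:, 0]
        + x[:, 1] * y[:, 2] - x[:, 2] * y[:, 1]
        + x[:, 2] * y[:, 3] - x[:, 3] * y[:, 2]
        + x[:, 3] * y[:, 0] - x[:, 0] * y[:, 3]
    )


def volume_fractions(mesh, region=None, u: np.ndarray | None = None) -> tuple[float, float]:
    """Deformed-area fractions (V_f, V_ecm) over the white-matter region."""
    region = mesh.elem_region if region is None else region
    areas = _deformed_areas(mesh, u)
    wm = region != int(Region.CORTEX)
    total = areas[wm].sum()
    vf = areas[wm & (region == int(Region.FIBER))].sum() / total
    return float(vf), float(1.0 - vf)


def local_stiffness_map(
    mesh,
    points: np.ndarray,
    mu_ratio: float,
    radius: float = 1.0,
    region=None,
    u: np.ndarray | None = None,
) -> np.ndarray:
    """Local stiffness ratio V_f * (mu_f/mu_s) + V_ecm at each query point.

    V_f is the fiber area fraction within a disc of ``radius`` mm centred on
    the point, evaluated over white-matter elements only; discs are clipped
    at the domain (white-matter) boundary.  For mu_f/mu_s = 2 the value
    reduces to V_f + 1.
    """
    from shapely.geometry import Point, Polygon
    from shapely.strtree import STRtree

    if radius <= 0:
        raise ValueError("radius must be positive")
    region = mesh.elem_region if region is None else region
    wm_ids = np.flatnonzero(region != int(Region.CORTEX))
    polys = [Polygon(mesh.elem_polygon(int(e), u)) for e in wm_ids]
    tree = STRtree(polys)
    is_fiber = region[wm_ids] == int(Region.FIBER)
    out = np.empty(len(points))
    for i, p in enumerate(np.atleast_2d(points)):
        disc = Point(p).buffer(radius, quad_segs=32)
        idx = tree.query(disc)
        a_f = 0.0
        a_tot = 0.0
        for j in idx:
            a = polys[j].intersection(disc).area
            a_tot += a
            if is_fiber[j]:
                a_f += a
        vf = a_f / a_tot if a_tot > 0 else 0.0
        out[i] = vf * mu_ratio + (1.0 - vf)
    return out


def equivalent_stiffness(mesh, mu_ratio: float, region=None, u: np.ndarray | None = None) -> float:
    """Global V_f * (mu_f/mu_s) + V_ecm over the entire white-matter region."""
    vf, vecm = volume_fractions(mesh, region, u)
    return vf * mu_ratio + vecm


def angular_distribution(bundles, n_bins: int = 18) -> tuple[np.ndarray, np.ndarray]:
    """Tip-direction histogram over [0, pi], normalized by the bundle count.

    Angles are folded into [0, pi]; each bin holds (count / N) so the bins
    sum to the fraction of agents with a defined tip direction (<= 1).
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    thetas = np.array([b.theta for b in bundles], dtype=float)
    folded = np.mod(thetas, np.pi)
    hist, edges = np.histogram(folded, bins=n_bins, range=(0.0, np.pi))
    n = max(len(bundles), 1)
    return hist / n, edges


def count_reached(bundles) -> int:
    """Number of bundles settled at the cortex at the end of the run."""
    from foldax.agents import BundleStatus

    return sum(1 for b in bundles if b.status is BundleStatus.SETTLED)


def compute_report(
    mesh,
    region,
    u: np.ndarray,
    bundles,
    mu_f_over_mu_s: float,
    interface_ids=None,
    pial_ids=None,
    n_bins: int = 18,
    flags: list | None = None,
) -> MetricsReport:
    """Assemble the full MetricsReport from final fields and agents."""
    from foldax.agents import BundleStatus

    interface_ids = mesh.interface if interface_ids is None else interface_ids
    pial_ids = mesh.pial if pial_ids is None else pial_ids
    pial = mesh.polyline_coords(pial_ids, u)
    interface = mesh.polyline_coords(interface_ids, u)
    gi = gyrification_index(pial)
    labels = classify_gyri_sulci(interface, pial)
    settled = np.array(
        [b.tip for b in bundles if b.status is BundleStatus.SETTLED], dtype=float
    ).reshape(-1, 2)
    dg, ds = fiber_density(settled, labels, interface) if len(settled) else (None, None)
    vf, vecm = volume_fractions(mesh, region, u)
    hist, edges = angular_distribution(bundles, n_bins) if bundles else (None, None)
    return MetricsReport(
        GI=gi,
        gyral_density_pct=dg,
        sulcal_density_pct=ds,
        n_reached=count_reached(bundles),
        n_fibers=len(bundles),
        V_f=vf,
        V_ecm=vecm,
        equivalent_stiffness=vf * mu_f_over_mu_s + vecm,
        angular_hist=hist,
        angular_bin_edges=edges,
        flags=list(flags or []),
    )
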