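"""Structured quadrilateral mesh of the 2-D bilayer brain slice.

The reference configuration is a w x (h + t_c) rectangle: the white-matter
substrate occupies y in [0, h] and the cortical plate the strip
y in [h, h + t_c].  Elements with centroid above y = h are labelled cortex;
everything else starts as ECM and may later be converted to fiber.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from foldax.config import ConfigError
from foldax.kinematics import Region

__all__ = ["Mesh", "build_bilayer_mesh"]


@dataclass
class Mesh:
    """Nodes, connectivity, region labels and named boundary/interface sets.

    Attributes
    ----------
    nodes : (n_nodes, 2) float array, reference coordinates in mm
    quads : (n_elems, 4) int array, counter-clockwise connectivity
    elem_region : (n_elems,) int array of :class:`~foldax.kinematics.Region`
    sets : named boundary node sets ("left", "right", "bottom", "top")
    interface : ordered node indices of the cortex/white-matter interface
    pial : ordered node indices of the top (pial) surface
    nx, ny : element grid dimensions
    elem_size : element edge length in mm
    """

    nodes: np.ndarray
    quads: np.ndarray
    elem_region: np.ndarray
    sets: dict
    interface: np.ndarray
    pial: np.ndarray
    nx: int
    ny: int
    elem_size: float
    h: float
    t_c: float

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elems(self) -> int:
        return len(self.quads)

    @property
    def w(self) -> float:
        return self.nx * self.elem_size

    def elem_index(self, ix: int, iy: int) -> int:
        return iy * self.nx + ix

    def elem_grid_coords(self, e: int) -> tuple[int, int]:
        return e % self.nx, e // self.nx

    def elem_of_reference_point(self, X: np.ndarray) -> int:
        """Element containing a reference-configuration point (clamped)."""
        ix = min(max(int(X[0] / self.elem_size), 0), self.nx - 1)
        iy = min(max(int(X[1] / self.elem_size), 0), self.ny - 1)
        return self.elem_index(ix, iy)

    def deformed_nodes(self, u: np.ndarray) -> np.ndarray:
        return self.nodes + u

    def elem_polygon(self, e: int, u: np.ndarray | None = None) -> np.ndarray:
        """(4, 2) corner coordinates, deformed if displacements are given."""
        x = self.nodes if u is None else self.nodes + u
        return x[self.quads[e]]

    def reference_jacobians(self) -> np.ndarray:
        """Signed area of every element in the reference configuration."""
        p = self.nodes[self.quads]  # (E, 4, 2)
        x, y = p[..., 0], p[..., 1]
        return 0.5 * np.abs(
            (x[:, 0] * y[:, 1] - x[:, 1] * y[:, 0])
            + (x[:, 1] * y[:, 2] - x[:, 2] * y[:, 1])
            + (x[:, 2] * y[:, 3] - x[:, 3] * y[:, 2])
            + (x[:, 3] * y[:, 0] - x[:, 0] * y[:, 3])
        ) * np.sign(
            (x[:, 1] - x[:, 0]) * (y[:, 3] - y[:, 0])
            - (x[:, 3] - x[:, 0]) * (y[:, 1] - y[:, 0])
        )

    def polyline_coords(self, node_ids: np.ndarray, u: np.ndarray | None = None) -> np.ndarray:
        x = self.nodes if u is None else self.nodes + u
        return x[node_ids]


def build_bilayer_mesh(
    w: float,
    h: float,
    t_c: float,
    elem_size: float,
    node_perturbation: float = 0.0,
    perturbation_modes: int = 6,
) -> Mesh:
    """Build the structured bilayer mesh.

    ``elem_size`` must divide ``w`` and ``h + t_c`` within rounding and be at
    most ``t_c`` so the cortical plate is at least one element thick.  An
    optional mirror-symmetric vertical perturbation of the interior nodes
    (amplitude ``node_perturbation`` mm) is available for agent-free folding
    tests; the production route breaks symmetry through fiber conversion
    instead and leaves it at zero.
    """
    if min(w, h, t_c, elem_size) <= 0:
        raise ConfigError("all mesh dimensions must be positive")
    if t_c < elem_size - 1e-9:
        raise ConfigError("t_c must be >= elem_size")
    nx = int(round(w / elem_size))
    ny = int(round((h + t_c) / elem_size))
    if abs(nx * elem_size - w) > 1e-6 * w or abs(ny * elem_size - (h + t_c)) > 1e-6:
        raise ConfigError("elem_size must divide w and h + t_c")

    xs = np.linspace(0.0, w, nx + 1)
    ys = np.linspace(0.0, h + t_c, ny + 1)
    X, Y = np.meshgrid(xs, ys)  # row-major: node = j * (nx + 1) + i
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    if node_perturbation > 0.0:
        # symmetric about x = w/2; zero on all boundaries
        interior = (
            (nodes[:, 0] > 1e-12)
            & (nodes[:, 0] < w - 1e-12)
            & (nodes[:, 1] > 1e-12)
            & (nodes[:, 1] < h + t_c - 1e-12)
        )
        bump = np.zeros(len(nodes))
        for m in range(1, perturbation_modes + 1):
            bump += np.cos(2.0 * np.pi * m * nodes[:, 0] / w) / m
        bump *= np.sin(np.pi * nodes[:, 1] / (h + t_c))
        nodes[interior, 1] += node_perturbation * bump[interior]

    i = np.arange(nx)
    j = np.arange(ny)
    II, JJ = np.meshgrid(i, j)
    n0 = (JJ * (nx + 1) + II).ravel()
    quads = np.column_stack([n0, n0 + 1, n0 + nx + 2, n0 + nx + 1])

    centroid_y = nodes[quads, 1].mean(axis=1)
    elem_region = np.where(centroid_y > h, int(Region.CORTEX), int(Region.ECM)).astype(
        np.int64
    )

    all_ids = np.arange(len(nodes))
    left = all_ids[np.isclose(nodes[:, 0], 0.0)]
    right = all_ids[np.isclose(nodes[:, 0], w)]
    bottom = all_ids[all_ids < nx + 1]
    top = all_ids[all_ids >= ny * (nx + 1)]
    sets = {"left": left, "right": right, "bottom": bottom, "top": top}

    j_int = int(round(h / elem_size))
    interface = np.arange(j_int * (nx + 1), (j_int + 1) * (nx + 1))
    pial = np.arange(ny * (nx + 1), (ny + 1) * (nx + 1))

    return Mesh(
        nodes=nodes,
        quads=quads,
        elem_region=elem_region,
        sets=sets,
        interface=interface,
        pial=pial,
        nx=nx,
        ny=ny,
        elem_size=elem_size,
        h=h,
        t_c=t_c,
    )
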