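"""Axisymmetric core-shell-box geometry and graded triangular meshing.

The computational domain is the r-z half-plane (r >= 0) of a square box of
half-side ``box_half_side`` centred on the particle, with the symmetry axis
at r = 0.  The mesh is a structured polar grid: concentric circular rings
resolve the core, the shell and the near field (so the core/shell and
shell/surroundings interfaces are exact polygonal circles), and an outer
zone of rings blends smoothly from the last circle to the square box
boundary.  Quads between consecutive rings are split into triangles with
alternating diagonals, which keeps the triangulation exactly symmetric
under z -> -z.

The semi-corona sampling regions used for the electric-field statistics
are annuli between the particle surface (r_MENP) and radii 5/10/20 nm
further out, sampled either uniformly in revolved (3-D) volume measure
(default) or uniformly in half-plane area measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import CoreShellGeometry

__all__ = [
    "AxisymMesh", "CoronaRegion", "MeshError", "build_mesh", "corona_region",
    "RESOLUTION_SHELL_SIZE",
]


class MeshError(RuntimeError):
    """Raised when mesh generation fails an internal consistency check."""


#: target element size across the shell per resolution level, metres
RESOLUTION_SHELL_SIZE = {"coarse": 5e-9, "default": 2e-9, "fine": 1e-9}

REGION_CORE, REGION_SHELL, REGION_SURROUNDINGS = 0, 1, 2
REGION_NAMES = {0: "core", 1: "shell", 2: "surroundings"}


@dataclass
class AxisymMesh:
    """Triangulated r-z half-plane with region labels and node sets.

    Attributes
    ----------
    points : (n_nodes, 2) float array of (r, z) coordinates, metres.
    tris : (n_elems, 3) int connectivity, positively oriented.
    region : (n_elems,) int8 labels (0 core, 1 shell, 2 surroundings).
    node_sets : boundary/interface node index arrays with keys
        ``axis``, ``outer_box``, ``core_shell_interface``,
        ``shell_outer_surface``.
    """

    points: np.ndarray
    tris: np.ndarray
    region: np.ndarray
    node_sets: dict[str, np.ndarray]
    geometry: CoreShellGeometry
    resolution: str
    # structured metadata for O(1) point location and mirror mapping
    _nphi: int = 0
    _circ_radii: np.ndarray = field(default_factory=lambda: np.empty(0))
    _row_tris: np.ndarray = field(default_factory=lambda: np.empty(0))

    # -- derived element quantities ---------------------------------------

    def element_geometry(self):
        """Signed areas, P1 shape-function gradients and centroid radii.

        Returns ``(area, grads, r_c, z_c)`` with ``grads`` of shape
        (n_elems, 3, 2): gradient (d/dr, d/dz) of each of the three nodal
        shape functions.
        """
        p = self.points[self.tris]              # (ne, 3, 2)
        x1, x2, x3 = p[:, 0], p[:, 1], p[:, 2]
        det = ((x2[:, 0] - x1[:, 0]) * (x3[:, 1] - x1[:, 1])
               - (x3[:, 0] - x1[:, 0]) * (x2[:, 1] - x1[:, 1]))
        area = 0.5 * det
        b = np.empty((len(det), 3, 2))
        b[:, 0, 0] = x2[:, 1] - x3[:, 1]
        b[:, 1, 0] = x3[:, 1] - x1[:, 1]
        b[:, 2, 0] = x1[:, 1] - x2[:, 1]
        b[:, 0, 1] = x3[:, 0] - x2[:, 0]
        b[:, 1, 1] = x1[:, 0] - x3[:, 0]
        b[:, 2, 1] = x2[:, 0] - x1[:, 0]
        b /= det[:, None, None]
        centroid = p.mean(axis=1)
        return area, b, centroid[:, 0], centroid[:, 1]

    def region_area(self, label: int) -> float:
        """Half-plane area of a region (plain r-z measure)."""
        area, _, _, _ = self.element_geometry()
        return float(area[self.region == label].sum())

    def region_volume(self, label: int) -> float:
        """Revolved volume of a region (2*pi*r_c weighted)."""
        area, _, rc, _ = self.element_geometry()
        m = self.region == label
        return float((2.0 * math.pi * rc[m] * area[m]).sum())

    # -- structured helpers ------------------------------------------------

    def mirror_map(self) -> np.ndarray:
        """Node index permutation realizing z -> -z (exact mesh symmetry)."""
        nphi = self._nphi
        n_rings = (len(self.points) - 1) // (nphi + 1)
        perm = np.empty(len(self.points), dtype=np.int64)
        perm[0] = 0
        for i in range(n_rings):
            base = 1 + i * (nphi + 1)
            perm[base:base + nphi + 1] = base + np.arange(nphi, -1, -1)
        return perm

    def locate(self, pts: np.ndarray) -> np.ndarray:
        """Element index containing each (r, z) point.

        Exact O(1) lookup inside the circular-ring zone (which covers the
        particle and the near field, hence all corona samples); points
        outside it raise.
        """
        pts = np.asarray(pts, dtype=float)
        s = np.hypot(pts[:, 0], pts[:, 1])
        if np.any(s >= self._circ_radii[-1]):
            raise MeshError("point outside the structured circular zone")
        phi = np.arctan2(pts[:, 0], pts[:, 1])  # 0 at +z axis, pi at -z
        dphi = math.pi / self._nphi
        j = np.clip((phi / dphi).astype(np.int64), 0, self._nphi - 1)
        row = np.searchsorted(self._circ_radii, s, side="left")
        out = np.empty(len(pts), dtype=np.int64)
        tri_pts = self.points
        for idx in range(len(pts)):
            cands = self._row_tris[row[idx], j[idx]]
            chosen = -1
            for t in cands:
                if t < 0:
                    continue
                a, b, c = tri_pts[self.tris[t]]
                d = ((b[0] - a[0]) * (c[1] - a[1])
                     - (c[0] - a[0]) * (b[1] - a[1]))
                l1 = ((b[0] - pts[idx, 0]) * (c[1] - pts[idx, 1])
                      - (c[0] - pts[idx, 0]) * (b[1] - pts[idx, 1])) / d
                l2 = ((pts[idx, 0] - a[0]) * (c[1] - a[1])
                      - (c[0] - a[0]) * (pts[idx, 1] - a[1])) / d
                if l1 >= -1e-12 and l2 >= -1e-12 and l1 + l2 <= 1 + 1e-12:
                    chosen = t
                    break
            if chosen < 0:
                # numerically on an edge: fall back to the nearest candidate
                chosen = cands[0] if cands[0] >= 0 else cands[1]
            out[idx] = chosen
        return out


def _ring_radii(geom: CoreShellGeometry, h_shell: float):
    """Radii of the circular rings and the blend-zone nominal radii."""
    r_core, r_p, L = geom.core_radius, geom.outer_radius, geom.box_half_side
    n_core = max(4, round(r_core / (2.5 * h_shell)))
    n_shell = max(5, math.ceil(geom.shell_thickness / h_shell))
    core = np.linspace(0.0, r_core, n_core + 1)[1:]
    shell = r_core + np.linspace(0.0, geom.shell_thickness, n_shell + 1)[1:]

    # near field + far field: geometric growth, capped step size
    r_blend = min(5.0 * r_p, 0.35 * L)
    step = 1.25 * h_shell
    growth, cap = 1.28, 0.08 * L
    radii, r = [], r_p
    while r < L - 1e-15:
        step = min(step * growth, cap, )
        r = min(r + step, L)
        if L - r < 0.45 * step:
            r = L
        radii.append(r)
    outer = np.asarray(radii)
    n_circ_outer = int(np.searchsorted(outer, r_blend, side="right"))
    n_circ_outer = min(n_circ_outer, len(outer) - 2)
    circ = np.concatenate([core, shell, outer[:n_circ_outer]])
    blend = outer[n_circ_outer:]
    return circ, blend, n_core, n_shell


def build_mesh(geometry: CoreShellGeometry, resolution: str = "default") -> AxisymMesh:
    """Build the graded axisymmetric mesh for a core-shell-box geometry.

    ``resolution`` maps to target element sizes across the shell of 5, 2
    and 1 nm for ``coarse``, ``default`` and ``fine``; element sizes grade
    geometrically away from the particle up to ~8% of the box half-side.
    """
    geometry.validate()
    if resolution not in RESOLUTION_SHELL_SIZE:
        raise MeshError(f"unknown resolution level {resolution!r}")
    h_shell = RESOLUTION_SHELL_SIZE[resolution]
    circ, blend, n_core, n_shell = _ring_radii(geometry, h_shell)
    r_p, L = geometry.outer_radius, geometry.box_half_side

    nphi = math.ceil(math.pi * r_p / h_shell)
    nphi += nphi % 2                      # even: node row exactly on z = 0
    phi = np.linspace(0.0, math.pi, nphi + 1)
    d = np.stack([np.sin(phi), np.cos(phi)], axis=1)   # (nphi+1, 2)
    d[0] = (0.0, 1.0)
    d[-1] = (0.0, -1.0)

    # nodes: center + one row per ring
    r_blend0 = circ[-1]
    rho_box = L / np.maximum(np.sin(phi), np.abs(np.cos(phi)))
    rows = [a * d for a in circ]
    for a in blend:
        t = (a - r_blend0) / (L - r_blend0)
        s = (1.0 - t) * r_blend0 + t * rho_box
        rows.append(s[:, None] * d)
    points = np.vstack([np.zeros((1, 2))] + rows)
    n_rings = len(circ) + len(blend)

    def nid(i: int, j: int) -> int:
        return 1 + i * (nphi + 1) + j

    tris, region, row_of = [], [], []
    # center fan (row 0, core)
    for j in range(nphi):
        tris.append((0, nid(0, j), nid(0, j + 1)))
        region.append(REGION_CORE)
        row_of.append((0, j))
    # quad rows
    for i in range(n_rings - 1):
        row = i + 1
        if row <= n_core - 1:
            lab = REGION_CORE
        elif row <= n_core + n_shell - 1:
            lab = REGION_SHELL
        else:
            lab = REGION_SURROUNDINGS
        for j in range(nphi):
            a, b = nid(i, j), nid(i, j + 1)
            c, dd = nid(i + 1, j + 1), nid(i + 1, j)
            if (i + j) % 2 == 0:
                quad = [(a, b, c), (a, c, dd)]
            else:
                quad = [(a, b, dd), (b, c, dd)]
            tris.extend(quad)
            region.extend([lab, lab])
            row_of.extend([(row, j), (row, j)])
    tris = np.asarray(tris, dtype=np.int64)
    region = np.asarray(region, dtype=np.int8)

    mesh = AxisymMesh(
        points=points, tris=tris, region=region, node_sets={},
        geometry=geometry, resolution=resolution,
        _nphi=nphi, _circ_radii=circ,
    )
    # fix orientation: positive signed area everywhere
    area, _, _, _ = mesh.element_geometry()
    flip = area < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    area, _, _, _ = mesh.element_geometry()
    if np.any(area <= 0):
        raise MeshError("mesh generation produced inverted elements")

    # structured row -> triangle lookup (circular zone only)
    n_circ = len(circ)
    row_tris = np.full((n_circ, nphi, 2), -1, dtype=np.int64)
    for t, (row, j) in enumerate(row_of):
        if row < n_circ:
            if row_tris[row, j, 0] < 0:
                row_tris[row, j, 0] = t
            else:
                row_tris[row, j, 1] = t
    mesh._row_tris = row_tris

    # node sets
    r = points[:, 0]
    axis = np.where(r < 1e-16)[0]
    last = n_rings - 1
    outer_box = np.arange(nid(last, 0), nid(last, nphi) + 1)
    iface = np.arange(nid(n_core - 1, 0), nid(n_core - 1, nphi) + 1)
    surf = np.arange(nid(n_core + n_shell - 1, 0),
                     nid(n_core + n_shell - 1, nphi) + 1)
    mesh.node_sets = {
        "axis": axis,
        "outer_box": outer_box,
        "core_shell_interface": iface,
        "shell_outer_surface": surf,
    }
    return mesh


# --------------------------------------------------------------------------
# semi-corona sampling regions
# --------------------------------------------------------------------------

#: supported corona distances (m) mapping to the outer radii 75/80/90 nm for
#: the default 70 nm particle
CORONA_DISTANCES = (5e-9, 10e-9, 20e-9)


@dataclass
class CoronaRegion:
    """Annular sampling region just outside the particle surface."""

    inner_radius: float
    outer_radius: float
    distance: float
    points: np.ndarray          # (n, 2) sample coordinates (r, z)
    weights: np.ndarray         # (n,) weights summing to the region measure
    mode: str                   # "volume" (revolved 3-D) or "area" (half-plane)
    seed: int

    @property
    def measure(self) -> float:
        return float(self.weights.sum())

    def to_csv(self, path) -> None:
        """Write samples as CSV columns (r_m, z_m, weight)."""
        import pandas as pd

        pd.DataFrame({
            "r_m": self.points[:, 0], "z_m": self.points[:, 1],
            "weight": self.weights,
        }).to_csv(path, index=False, float_format="%.10g")


def corona_region(mesh: AxisymMesh, distance: float, n_samples: int = 20000,
                  seed: int = 0, mode: str = "volume") -> CoronaRegion:
    """Sample points in the semi-corona at a given distance from the shell.

    ``distance`` must be one of 5, 10 or 20 nm (outer radii 75/80/90 nm for
    the default geometry).  ``mode='volume'`` distributes samples uniformly
    with respect to the revolved spherical-shell volume (default);
    ``mode='area'`` uses plain half-plane area measure.  Weights are equal
    and sum to the corresponding region measure.
    """
    if not any(math.isclose(distance, d_) for d_ in CORONA_DISTANCES):
        raise ValueError(
            "corona distance must be one of 5, 10 or 20 nm "
            f"(got {distance*1e9:.6g} nm)"
        )
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000")
    if mode not in ("volume", "area"):
        raise ValueError("mode must be 'volume' or 'area'")
    s_in = mesh.geometry.outer_radius
    s_out = s_in + distance
    rng = np.random.default_rng(seed)
    u = rng.random(n_samples)
    if mode == "volume":
        s = (s_in ** 3 + u * (s_out ** 3 - s_in ** 3)) ** (1.0 / 3.0)
        cos_t = 2.0 * rng.random(n_samples) - 1.0
        sin_t = np.sqrt(1.0 - cos_t ** 2)
        pts = np.stack([s * sin_t, s * cos_t], axis=1)
        measure = 4.0 * math.pi / 3.0 * (s_out ** 3 - s_in ** 3)
    else:
        s = np.sqrt(s_in ** 2 + u * (s_out ** 2 - s_in ** 2))
        ang = math.pi * rng.random(n_samples)
        pts = np.stack([s * np.sin(ang), s * np.cos(ang)], axis=1)
        measure = 0.5 * math.pi * (s_out ** 2 - s_in ** 2)
    w = np.full(n_samples, measure / n_samples)
    return CoronaRegion(
        inner_radius=s_in, outer_radius=s_out, distance=distance,
        points=pts, weights=w, mode=mode, seed=seed,
    )
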