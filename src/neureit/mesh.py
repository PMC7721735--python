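"""Triangular cross-section mesh of a nerve inside a conductive bath.

The domain is a disk: an inner "nerve" region (radius ~0.7 mm) surrounded by
an "external" annulus standing in for the conductive medium at the cuff
edges.  Cuff electrode pads sit on the single closed outer boundary, so the
mesh is graded: fine in the nerve, coarser through the mid-annulus, and fine
again near the outer boundary where the electrode arcs are.

Nodes are laid out on concentric rings and triangulated with a Delaunay
triangulation (the domain is convex, so the hull triangulation covers it
exactly); this keeps the generator dependency-free and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from .conventions import theta_from_xy

REGION_NERVE = 0
REGION_EXTERNAL = 1


class GeometryError(ValueError):
    """Raised for degenerate or infeasible mesh geometry requests."""


@dataclass
class TriMesh:
    """2D triangle mesh with region labels and boundary metadata.

    nodes : (N, 2) float, metres
    elements : (M, 3) int, CCW node triples (all signed areas > 0)
    region : (M,) int, REGION_NERVE or REGION_EXTERNAL
    boundary_edges : (B, 2) int node pairs on the single closed outer loop
    boundary_edge_angles : (B,) float deg, angle of each edge midpoint
        (clockwise from 12 o'clock)
    """

    nodes: np.ndarray
    elements: np.ndarray
    region: np.ndarray
    boundary_edges: np.ndarray
    boundary_edge_angles: np.ndarray
    nerve_radius: float = 0.0
    external_radius: float = 0.0
    _areas: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_areas(self) -> np.ndarray:
        if self._areas is None:
            p = self.nodes[self.elements]
            self._areas = 0.5 * np.abs(
                (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
            )
        return self._areas

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def signed_areas(self) -> np.ndarray:
        p = self.nodes[self.elements]
        return 0.5 * (
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )


def _local_h(r: float, nerve_radius: float, external_radius: float, h: float) -> float:
    """Target spacing: h in the nerve, up to 3h mid-annulus, h/2 at the
    outer (electrode-bearing) boundary."""
    if r <= nerve_radius:
        return h
    t = (r - nerve_radius) / (external_radius - nerve_radius)
    if t < 0.5:
        return h + 2.0 * h * np.sin(np.pi * t)
    return 3.0 * h + (0.5 * h - 3.0 * h) * (t - 0.5) / 0.5


def _ring_radii(nerve_radius: float, external_radius: float, h: float) -> np.ndarray:
    radii = [0.0]
    r = 0.0
    while r < nerve_radius - 1e-12:
        r = min(r + _local_h(r, nerve_radius, external_radius, h), nerve_radius)
        radii.append(r)
    # force an exact ring on the region interface
    radii[-1] = nerve_radius
    while r < external_radius - 1e-12:
        r = min(r + _local_h(r, nerve_radius, external_radius, h), external_radius)
        radii.append(r)
    radii[-1] = external_radius
    return np.asarray(radii)


def build_mesh(
    nerve_radius: float = 0.7e-3,
    external_radius: float = 0.75e-3,
    target_element_size: float = 60e-6,
) -> TriMesh:
    """Build the graded disk mesh. Lengths in metres.

    Raises
    ------
    GeometryError
        For degenerate geometry or an element budget outside [500, 50000].
    """
    if not (0.0 < nerve_radius < external_radius):
        raise GeometryError(
            f"need 0 < nerve_radius < external_radius, got {nerve_radius}, {external_radius}"
        )
    if target_element_size <= 0:
        raise GeometryError("target_element_size must be > 0")

    radii = _ring_radii(nerve_radius, external_radius, target_element_size)
    pts = [np.zeros((1, 2))]
    for k, r in enumerate(radii[1:], start=1):
        # angular spacing follows the local size target (not the ring gap,
        # which a thin annulus caps), so pad-edge resolution refines with h
        hloc = _local_h(r, nerve_radius, external_radius, target_element_size)
        n_theta = max(6, int(round(2.0 * np.pi * r / min(hloc, 1.5 * (r - radii[k - 1])))))
        offs = 0.5 * (k % 2)  # stagger alternate rings
        th = 2.0 * np.pi * (np.arange(n_theta) + offs) / n_theta
        pts.append(np.column_stack([r * np.sin(th), r * np.cos(th)]))
    nodes = np.vstack(pts)

    tri = Delaunay(nodes)
    elements = tri.simplices.copy()

    # enforce CCW orientation -> positive signed areas
    p = nodes[elements]
    sa = 0.5 * (
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    flip = sa < 0
    elements[flip] = elements[flip][:, [0, 2, 1]]
    # drop exactly-degenerate slivers (collinear ring points)
    keep = np.abs(sa) > 1e-6 * target_element_size**2
    elements = elements[keep]

    n_el = elements.shape[0]
    if not (500 <= n_el <= 50_000):
        raise GeometryError(
            f"element budget violated: {n_el} elements for size {target_element_size}"
        )

    cent = nodes[elements].mean(axis=1)
    region = np.where(
        np.hypot(cent[:, 0], cent[:, 1]) < nerve_radius, REGION_NERVE, REGION_EXTERNAL
    ).astype(np.int32)

    boundary_edges = _boundary_edges(elements)
    mids = 0.5 * (nodes[boundary_edges[:, 0]] + nodes[boundary_edges[:, 1]])
    angles = theta_from_xy(mids[:, 0], mids[:, 1])

    return TriMesh(
        nodes=nodes,
        elements=elements,
        region=region,
        boundary_edges=boundary_edges,
        boundary_edge_angles=angles,
        nerve_radius=nerve_radius,
        external_radius=external_radius,
    )


def _boundary_edges(elements: np.ndarray) -> np.ndarray:
    """Edges belonging to exactly one triangle, i.e. the outer loop."""
    edges = np.vstack(
        [elements[:, [0, 1]], elements[:, [1, 2]], elements[:, [2, 0]]]
    )
    key = np.sort(edges, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return edges[idx[counts == 1]]


def boundary_loop_is_closed(mesh: TriMesh) -> bool:
    """True iff the boundary edges form one closed loop (every node degree 2)."""
    nodes, counts = np.unique(mesh.boundary_edges, return_counts=True)
    if not np.all(counts == 2):
        return False
    # walk the loop
    adj: dict[int, list[int]] = {}
    for a, b in mesh.boundary_edges:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    start = int(nodes[0])
    prev, cur, seen = None, start, 1
    while True:
        nxt = [n for n in adj[cur] if n != prev]
        prev, cur = cur, nxt[0]
        if cur == start:
            break
        seen += 1
        if seen > len(nodes):
            return False
    return seen == len(nodes)


# ---------------------------------------------------------------------------
# Gmsh 2.2 ASCII I/O (minimal dialect: triangles tagged by region, boundary
# edges as line elements with tag 100)
# ---------------------------------------------------------------------------

def write_gmsh(mesh: TriMesh, path) -> None:
    with open(path, "w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        f.write("$Nodes\n%d\n" % mesh.n_nodes)
        for i, (x, y) in enumerate(mesh.nodes, start=1):
            f.write(f"{i} {x:.12e} {y:.12e} 0\n")
        f.write("$EndNodes\n$Elements\n%d\n" % (mesh.n_elements + len(mesh.boundary_edges)))
        eid = 1
        for (a, b), _ang in zip(mesh.boundary_edges, mesh.boundary_edge_angles):
            f.write(f"{eid} 1 2 100 100 {a + 1} {b + 1}\n")
            eid += 1
        for (a, b, c), reg in zip(mesh.elements, mesh.region):
            f.write(f"{eid} 2 2 {reg + 1} {reg + 1} {a + 1} {b + 1} {c + 1}\n")
            eid += 1
        f.write("$EndElements\n")
        f.write("$NerveRadius\n%.12e\n$EndNerveRadius\n" % mesh.nerve_radius)
        f.write("$ExternalRadius\n%.12e\n$EndExternalRadius\n" % mesh.external_radius)


def read_gmsh(path) -> TriMesh:
    with open(path) as f:
        lines = f.read().splitlines()
    i = 0

    def section(name):
        nonlocal i
        while lines[i].strip() != f"${name}":
            i += 1
        i += 1

    section("Nodes")
    n_nodes = int(lines[i]); i += 1
    nodes = np.empty((n_nodes, 2))
    for k in range(n_nodes):
        parts = lines[i + k].split()
        nodes[k] = [float(parts[1]), float(parts[2])]
    i += n_nodes
    section("Elements")
    n_el = int(lines[i]); i += 1
    tris, regs, bedges = [], [], []
    for k in range(n_el):
        parts = lines[i + k].split()
        etype = int(parts[1])
        ntags = int(parts[2])
        conn = [int(v) - 1 for v in parts[3 + ntags:]]
        if etype == 1:
            bedges.append(conn)
        elif etype == 2:
            tris.append(conn)
            regs.append(int(parts[3]) - 1)
    i += n_el
    section("NerveRadius")
    nerve_radius = float(lines[i])
    section("ExternalRadius")
    external_radius = float(lines[i])
    bedges = np.asarray(bedges, dtype=np.int64)
    mids = 0.5 * (nodes[bedges[:, 0]] + nodes[bedges[:, 1]])
    return TriMesh(
        nodes=nodes,
        elements=np.asarray(tris, dtype=np.int64),
        region=np.asarray(regs, dtype=np.int32),
        boundary_edges=bedges,
        boundary_edge_angles=theta_from_xy(mids[:, 0], mids[:, 1]),
        nerve_radius=nerve_radius,
        external_radius=external_radius,
    )
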