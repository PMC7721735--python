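"""Complete-electrode-model (CEM) forward solver and adjoint Jacobian.

The cross-sectional conduction problem ∇·(σ∇u) = 0 is discretized with
linear (P1) triangles.  Electrode pads on the outer boundary are modelled
with the complete electrode model: a lumped contact impedance couples the
tissue potential under each pad to a single terminal voltage, and current is
driven between terminal pairs.  The discrete system is

    [ K + (1/z)M_e   −(1/z)C   0 ] [u]   [0]
    [   −(1/z)Cᵀ      |e|/z    1 ] [U] = [I]
    [      0            1ᵀ     0 ] [λ]   [0]

where the last row pins the terminal-voltage gauge to mean(U) = 0 (the ring
reference electrode is abstracted to this mean reference).  The system is
symmetric, so reciprocity holds to solver precision.

The sensitivity of a measured terminal voltage to a per-element conductivity
perturbation is computed by the adjoint method,

    ∂V_(d,m)/∂σ_e = −area_e · ∇u_d · ∇w_m,

with u_d the drive field (at the protocol current) and w_m the field of a
unit mean-free current pattern on the measurement electrode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .conventions import signed_angle_diff_deg
from .mesh import REGION_NERVE, TriMesh

SIGMA_NERVE_DEFAULT = 0.3  # S/m, uniform nerve baseline
SIGMA_EXTERNAL_DEFAULT = 1.5  # S/m, saline-like external medium
PAD_WIDTH_DEG_DEFAULT = 360.0 * 0.14 / (np.pi * 1.4)  # 0.14 mm pad on 1.4 mm I.D.
# out-of-plane thickness of the 2D slab (≈ the 1 mm pad length): bulk
# conductance scales with it, the lumped contact impedance does not, so it
# sets the absolute voltage scale of the cross-section model
SLAB_THICKNESS_DEFAULT = 1e-3  # m


class ForwardModelError(RuntimeError):
    """Numerical failure of the CEM solve (e.g. singular system)."""


class ProtocolError(ValueError):
    """Invalid injection protocol request."""


@dataclass
class ElectrodeLayout:
    """Ring of equally spaced pads; angles in degrees clockwise from the
    fiducial (cuff opening) at 12 o'clock."""

    n_electrodes: int = 14
    pad_width_deg: float = PAD_WIDTH_DEG_DEFAULT
    contact_impedance_ohm: float = 1e3
    fiducial_deg: float = 0.0
    # "lumped": contact_impedance_ohm is a per-electrode Ω value, converted to
    # the CEM surface parameter by multiplying by pad arc length.
    # "surface": contact_impedance_ohm is already the surface value in Ω·m.
    contact_model: str = "lumped"

    def __post_init__(self):
        if self.n_electrodes < 2:
            raise ValueError("need at least two electrodes")
        if self.contact_impedance_ohm <= 0:
            raise ValueError("contact impedance must be > 0")
        if self.pad_width_deg * self.n_electrodes >= 360.0:
            raise ValueError("pads overlap")

    @property
    def spacing_deg(self) -> float:
        return 360.0 / self.n_electrodes

    @property
    def center_angles_deg(self) -> np.ndarray:
        # pads straddle the ring with the cuff opening (fiducial) between
        # the last and first pad
        return np.mod(
            self.fiducial_deg + (np.arange(self.n_electrodes) + 0.5) * self.spacing_deg,
            360.0,
        )


@dataclass
class ConductivityField:
    """Per-element conductivity in S/m."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0):
            raise ValueError("conductivity must be positive everywhere")

    @classmethod
    def baseline(
        cls,
        mesh: TriMesh,
        sigma_nerve: float = SIGMA_NERVE_DEFAULT,
        sigma_external: float = SIGMA_EXTERNAL_DEFAULT,
    ) -> "ConductivityField":
        v = np.where(mesh.region == REGION_NERVE, sigma_nerve, sigma_external)
        return cls(v)

    def perturbed(self, delta: np.ndarray) -> "ConductivityField":
        return ConductivityField(self.values + delta)


@dataclass
class InjectionProtocol:
    """Ordered drive pairs with a fixed electrode offset on the ring."""

    pairs: list[tuple[int, int]]
    current_a: float = 60e-6
    carrier_hz: float = 6e3
    n_electrodes: int = 14

    @property
    def n_injections(self) -> int:
        return len(self.pairs)

    @property
    def n_measurements(self) -> int:
        return self.n_injections * self.n_electrodes

    def measurement_index(self) -> list[tuple[int, int]]:
        """Row order of the Jacobian/measurement vector:
        injection-major, electrode-minor."""
        return [(d, m) for d in range(self.n_injections) for m in range(self.n_electrodes)]


def build_protocol(
    n_electrodes: int = 14,
    offset: int = 4,
    current: float = 60e-6,
    freq: float = 6e3,
) -> InjectionProtocol:
    """Ring drive protocol: pair i = (i, (i+offset) mod n), all electrodes
    measured for every injection."""
    if not (0 < offset < n_electrodes) or offset % n_electrodes == 0:
        raise ProtocolError(f"offset {offset} invalid for {n_electrodes} electrodes")
    pairs = [(i, (i + offset) % n_electrodes) for i in range(n_electrodes)]
    return InjectionProtocol(
        pairs=pairs, current_a=current, carrier_hz=freq, n_electrodes=n_electrodes
    )


@dataclass
class ForwardSolution:
    """Nodal potentials and terminal voltages per injection.

    Terminal voltages are referenced to mean(U) = 0 over the ring.
    """

    node_potentials: np.ndarray  # (n_injections, n_nodes)
    electrode_voltages: np.ndarray  # (n_injections, n_electrodes)
    electrode_currents: np.ndarray  # (n_injections, n_electrodes), recovered
    reference: str = "mean of electrode terminals"


@dataclass
class JacobianMatrix:
    """Sensitivity matrix, rows = (injection, electrode) measurements.

    kind == "element": one column per mesh element (column map = element ids).
    kind == "voxel": columns aggregated onto a square voxel grid inside the
    nerve mask; `voxel_centers` holds (x, y) in metres and `grid_index`
    (row, col) positions on the grid.
    """

    matrix: np.ndarray
    row_index: list[tuple[int, int]]
    kind: str = "element"
    col_elements: np.ndarray | None = None
    voxel_size: float | None = None
    voxel_centers: np.ndarray | None = None
    grid_index: np.ndarray | None = None
    grid_shape: tuple[int, int] | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("Jacobian contains non-finite entries")


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _element_gradients(mesh: TriMesh):
    """Per-element P1 shape-function gradients.

    Returns (gx, gy) arrays of shape (M, 3): gradient components of the three
    nodal shape functions on each element.
    """
    p = mesh.nodes[mesh.elements]
    x, y = p[..., 0], p[..., 1]
    area2 = (x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0]) - (x[:, 2] - x[:, 0]) * (
        y[:, 1] - y[:, 0]
    )
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    return b / area2[:, None], c / area2[:, None]


def _stiffness(mesh: TriMesh, sigma: np.ndarray) -> sp.csr_matrix:
    gx, gy = _element_gradients(mesh)
    areas = mesh.element_areas()
    M = mesh.n_elements
    # local 3x3 blocks: sigma * area * (gx gxT + gy gyT)
    local = sigma[:, None, None] * areas[:, None, None] * (
        gx[:, :, None] * gx[:, None, :] + gy[:, :, None] * gy[:, None, :]
    )
    rows = np.repeat(mesh.elements, 3, axis=1).reshape(M, 3, 3)
    cols = np.tile(mesh.elements[:, None, :], (1, 3, 1))
    K = sp.coo_matrix(
        (local.ravel(), (rows.ravel(), cols.ravel())),
        shape=(mesh.n_nodes, mesh.n_nodes),
    )
    return K.tocsr()


def electrode_edge_map(mesh: TriMesh, layout: ElectrodeLayout) -> list[np.ndarray]:
    """Boundary-edge indices under each pad (edge midpoint within pad arc)."""
    out = []
    for c in layout.center_angles_deg:
        d = np.abs(signed_angle_diff_deg(mesh.boundary_edge_angles, c))
        out.append(np.nonzero(d <= layout.pad_width_deg / 2.0)[0])
    return out


def _contact_coef(layout: ElectrodeLayout, pad_arc_length: float, thickness: float) -> float:
    """Per-unit-arc-length contact conductance coefficient (S/m).

    Lumped model: a per-electrode impedance Z over the whole pad
    (area = arc × thickness) gives t/z_s = 1/(Z · arc), independent of the
    slab thickness.  Surface model: contact_impedance_ohm is z_s in Ω·m².
    """
    if layout.contact_model == "lumped":
        return 1.0 / (layout.contact_impedance_ohm * pad_arc_length)
    if layout.contact_model == "surface":
        return thickness / layout.contact_impedance_ohm
    raise ValueError(f"unknown contact model {layout.contact_model!r}")


class CEMSystem:
    """Assembled and factorized CEM system for one conductivity field."""

    def __init__(
        self,
        mesh: TriMesh,
        sigma: ConductivityField,
        layout: ElectrodeLayout,
        thickness: float = SLAB_THICKNESS_DEFAULT,
    ):
        if sigma.values.shape[0] != mesh.n_elements:
            raise ValueError("conductivity field does not match mesh")
        if thickness <= 0:
            raise ValueError("slab thickness must be positive")
        self.mesh = mesh
        self.layout = layout
        self.thickness = thickness
        n, L = mesh.n_nodes, layout.n_electrodes

        K = _stiffness(mesh, sigma.values) * thickness
        edge_map = electrode_edge_map(mesh, layout)
        if any(len(e) == 0 for e in edge_map):
            raise ForwardModelError(
                "an electrode pad covers no boundary edges; refine the mesh"
            )
        self.edge_map = edge_map

        rows, cols, vals = [], [], []
        crows, ccols, cvals = [], [], []
        diag = np.zeros(L)
        self.contact_coef = np.empty(L)
        for l, edges in enumerate(edge_map):
            e = mesh.boundary_edges[edges]
            seg = mesh.nodes[e[:, 1]] - mesh.nodes[e[:, 0]]
            lengths = np.hypot(seg[:, 0], seg[:, 1])
            arc = lengths.sum()
            coef = _contact_coef(layout, arc, thickness)
            self.contact_coef[l] = coef
            # boundary mass: coef * le/6 * [[2,1],[1,2]]
            for (a, b), le in zip(e, lengths):
                for (i, j, w) in ((a, a, 2), (b, b, 2), (a, b, 1), (b, a, 1)):
                    rows.append(i); cols.append(j); vals.append(coef * le * w / 6.0)
                # coupling −coef ∫ φ ds = −coef·le/2 per node
                for i in (a, b):
                    crows.append(i); ccols.append(l); cvals.append(coef * le / 2.0)
            diag[l] = coef * arc

        Me = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        C = sp.coo_matrix((cvals, (crows, ccols)), shape=(n, L)).tocsr()

        ones = np.ones((L, 1))
        A = sp.bmat(
            [
                [K + Me, -C, None],
                [-C.T, sp.diags(diag), ones],
                [None, ones.T, None],
            ],
            format="csc",
        )
        try:
            self.lu = splu(A)
        except RuntimeError as exc:  # pragma: no cover - singular assembly
            raise ForwardModelError(f"CEM system factorization failed: {exc}") from exc
        self.n_nodes = n
        self.n_electrodes = L
        self.C = C

    def solve_currents(self, currents: np.ndarray):
        """Solve for one or more terminal current patterns.

        currents : (L,) or (n_patterns, L), amps per electrode (must sum ~0).
        Returns (u, U): nodal potentials and terminal voltages.
        """
        currents = np.atleast_2d(currents)
        n, L = self.n_nodes, self.n_electrodes
        rhs = np.zeros((currents.shape[0], n + L + 1))
        rhs[:, n : n + L] = currents
        sol = self.lu.solve(rhs.T).T
        if not np.all(np.isfinite(sol)):
            raise ForwardModelError("CEM solve produced non-finite values")
        return sol[:, :n], sol[:, n : n + L]

    def recovered_currents(self, u: np.ndarray, U: np.ndarray) -> np.ndarray:
        """Electrode currents implied by a solution, I_l = ∫ (U_l − u)/z ds."""
        mesh = self.mesh
        out = np.zeros((u.shape[0], self.n_electrodes))
        for l, edges in enumerate(self.edge_map):
            e = mesh.boundary_edges[edges]
            seg = mesh.nodes[e[:, 1]] - mesh.nodes[e[:, 0]]
            lengths = np.hypot(seg[:, 0], seg[:, 1])
            u_mid = 0.5 * (u[:, e[:, 0]] + u[:, e[:, 1]])
            out[:, l] = self.contact_coef[l] * (
                (U[:, l, None] - u_mid) * lengths[None, :]
            ).sum(axis=1)
        return out


def solve_forward(
    mesh: TriMesh,
    sigma: ConductivityField,
    layout: ElectrodeLayout,
    protocol: InjectionProtocol,
    thickness: float = SLAB_THICKNESS_DEFAULT,
) -> ForwardSolution:
    """Solve the CEM problem for every injection of the protocol."""
    if protocol.n_electrodes != layout.n_electrodes:
        raise ProtocolError("protocol/layout electrode counts differ")
    system = CEMSystem(mesh, sigma, layout, thickness=thickness)
    L = layout.n_electrodes
    currents = np.zeros((protocol.n_injections, L))
    for k, (src, snk) in enumerate(protocol.pairs):
        currents[k, src] = protocol.current_a
        currents[k, snk] = -protocol.current_a
    u, U = system.solve_currents(currents)
    I_rec = system.recovered_currents(u, U)
    return ForwardSolution(node_potentials=u, electrode_voltages=U, electrode_currents=I_rec)


def compute_jacobian(
    mesh: TriMesh,
    sigma: ConductivityField,
    layout: ElectrodeLayout,
    protocol: InjectionProtocol,
    system: CEMSystem | None = None,
    thickness: float = SLAB_THICKNESS_DEFAULT,
) -> JacobianMatrix:
    """Adjoint (sensitivity) Jacobian, rows injection-major / electrode-minor.

    Entry ((d, m), e) = −t·area_e ∇u_d·∇w_m with u_d at the protocol current,
    w_m the unit mean-free measurement pattern field and t the slab
    thickness, so entries are in V per (S/m) for the protocol's drive
    current.
    """
    if system is None:
        system = CEMSystem(mesh, sigma, layout, thickness=thickness)
    thickness = system.thickness
    L = layout.n_electrodes
    drive = np.zeros((protocol.n_injections, L))
    for k, (src, snk) in enumerate(protocol.pairs):
        drive[k, src] = protocol.current_a
        drive[k, snk] = -protocol.current_a
    u_d, _ = system.solve_currents(drive)
    meas = np.eye(L) - np.full((L, L), 1.0 / L)  # unit mean-free patterns
    w_m, _ = system.solve_currents(meas)

    gx, gy = _element_gradients(mesh)
    areas = mesh.element_areas()
    el = mesh.elements
    # per-element field gradients for each drive / measurement solution
    gux = u_d[:, el[:, 0]] * gx[:, 0] + u_d[:, el[:, 1]] * gx[:, 1] + u_d[:, el[:, 2]] * gx[:, 2]
    guy = u_d[:, el[:, 0]] * gy[:, 0] + u_d[:, el[:, 1]] * gy[:, 1] + u_d[:, el[:, 2]] * gy[:, 2]
    gwx = w_m[:, el[:, 0]] * gx[:, 0] + w_m[:, el[:, 1]] * gx[:, 1] + w_m[:, el[:, 2]] * gx[:, 2]
    gwy = w_m[:, el[:, 0]] * gy[:, 0] + w_m[:, el[:, 1]] * gy[:, 1] + w_m[:, el[:, 2]] * gy[:, 2]

    # J[(d,m), e] = -area_e (gux[d,e] gwx[m,e] + guy[d,e] gwy[m,e])
    J = -thickness * (
        np.einsum("de,me->dme", gux, gwx) + np.einsum("de,me->dme", guy, gwy)
    ) * areas[None, None, :]
    J = J.reshape(protocol.n_injections * L, mesh.n_elements)
    return JacobianMatrix(
        matrix=J,
        row_index=protocol.measurement_index(),
        kind="element",
        col_elements=np.arange(mesh.n_elements),
    )


def project_to_voxels(
    J: JacobianMatrix, mesh: TriMesh, voxel_size: float = 40e-6
) -> JacobianMatrix:
    """Aggregate element columns onto a square voxel grid inside the nerve.

    Each element's (area-integrated) sensitivity is split over the voxels it
    overlaps, with weights proportional to the overlap area (estimated by a
    barycentric supersampling of the triangle).  Voxels whose centers fall
    outside the nerve disk are dropped; sample points landing in a dropped
    voxel are snapped to the nearest retained one, so the total nerve-region
    sensitivity is preserved exactly.
    """
    if J.kind != "element":
        raise ValueError("expected an element-space Jacobian")
    R = mesh.nerve_radius
    if voxel_size > R:
        raise ValueError("voxel size larger than nerve radius")
    n = int(np.ceil(2 * R / voxel_size))
    centers_1d = (np.arange(n) - (n - 1) / 2.0) * voxel_size
    cx, cy = np.meshgrid(centers_1d, centers_1d, indexing="xy")
    mask = np.hypot(cx, cy) <= R
    vox_rc = np.argwhere(mask)  # (row=y index, col=x index)
    vox_centers = np.column_stack([cx[mask], cy[mask]])
    n_vox = vox_centers.shape[0]

    flat_to_vox = -np.ones((n, n), dtype=int)
    flat_to_vox[vox_rc[:, 0], vox_rc[:, 1]] = np.arange(n_vox)

    nerve_el = np.nonzero(mesh.region == REGION_NERVE)[0]
    tri = mesh.nodes[mesh.elements[nerve_el]]  # (M, 3, 2)

    # barycentric sample lattice (16 interior points per triangle)
    k = 4
    bary = []
    for i in range(k):
        for j in range(k - i):
            l1 = (i + 1.0 / 3.0) / k
            l2 = (j + 1.0 / 3.0) / k
            bary.append((l1, l2, 1.0 - l1 - l2))
    bary = np.asarray(bary)  # (S, 3)
    samples = np.einsum("sb,mbd->msd", bary, tri)  # (M, S, 2)
    S = bary.shape[0]

    ix = np.clip(
        np.round(samples[..., 0] / voxel_size + (n - 1) / 2.0).astype(int), 0, n - 1
    )
    iy = np.clip(
        np.round(samples[..., 1] / voxel_size + (n - 1) / 2.0).astype(int), 0, n - 1
    )
    vid = flat_to_vox[iy, ix]  # (M, S)
    missing = vid < 0
    if np.any(missing):
        pts = samples[missing]
        d2 = (
            (pts[:, 0, None] - vox_centers[None, :, 0]) ** 2
            + (pts[:, 1, None] - vox_centers[None, :, 1]) ** 2
        )
        vid[missing] = np.argmin(d2, axis=1)

    # each sample carries 1/S of its element's column
    Jv = np.zeros((J.matrix.shape[0], n_vox))
    cols = (J.matrix[:, nerve_el] / S).T  # (M, rows)
    for s in range(S):
        np.add.at(Jv.T, vid[:, s], cols)
    return JacobianMatrix(
        matrix=Jv,
        row_index=list(J.row_index),
        kind="voxel",
        voxel_size=voxel_size,
        voxel_centers=vox_centers,
        grid_index=vox_rc,
        grid_shape=(n, n),
    )
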