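"""Quasi-static complex-conductivity FEM with terminal current drives.

Solves ``div((sigma + j w eps0 epsr) grad phi) = 0`` on a labeled
tetrahedral mesh with piecewise-linear elements.  Outer boundaries are
insulating (natural).  Each electrode disc is an equipotential metal
terminal behind a distributed contact film of specific impedance z_s(w):
the normal current density entering the bath is (U_e - phi)/z_s, and the
terminal carries one extra unknown U_e constrained by its net current
(I_T for the drive pair, zero for floating recording electrodes).  The
cell membrane is an interior thin layer: the mesh carries duplicated
nodes on the membrane surface and the two sides are coupled by
(phi_med - phi_cyt)/z_m.

The potential gauge is fixed at one far-corner node (exact for balanced
terminal currents), so a single sparse LU factorization per frequency
serves every drive on that mesh; reported potentials are shifted so the
sink terminal reads zero, matching a grounded counter electrode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import AssemblyError, SolverError
from .geometry import Mesh, REGION_CYTOPLASM, REGION_MEDIUM
from .interface_models import (
    ElectrodeInterfaceParams,
    MaterialProps,
    MembraneParams,
    membrane_surface_impedance,
    surface_impedance_electrode,
)

__all__ = [
    "DriveSpec",
    "InterfaceSet",
    "FieldSolution",
    "FemModel",
    "AssembledSystem",
    "assemble",
    "solve_drive",
]

UM = 1e-6  # metres per micrometre

#: relative magnitude of an "ideal" contact film: its specific impedance is
#: this fraction of the patch's own spreading-resistance scale a_eff/sigma,
#: so the film drop is negligible at any geometry scale while the penalty
#: entries stay within a few decades of the stiffness entries
IDEAL_CONTACT_EPS = 1e-5

OUTER_GROUND_ID = "__outer__"


@dataclass(frozen=True)
class DriveSpec:
    """Terminal current drive: ``current`` amperes from source to sink."""

    source: str
    sink: str
    current: float = 1.0

    def __post_init__(self) -> None:
        if self.source == self.sink:
            raise ValueError("drive source and sink must differ")
        if self.current == 0:
            raise ValueError("drive current must be nonzero")


@dataclass(frozen=True)
class InterfaceSet:
    """Which films cover which surfaces.

    ``electrode=None`` makes every electrode an ideal contact (used for
    resistance verification); the membrane model must be present whenever
    the mesh contains membrane facets.
    """

    electrode: ElectrodeInterfaceParams | None = field(
        default_factory=ElectrodeInterfaceParams
    )
    membrane: MembraneParams | None = field(default_factory=MembraneParams)
    ideal_contact_eps: float = IDEAL_CONTACT_EPS

    @classmethod
    def ideal(cls) -> "InterfaceSet":
        return cls(electrode=None, membrane=MembraneParams())


@dataclass
class FieldSolution:
    """Complex potential/current-density fields for one drive at one frequency."""

    frequency: float
    drive: DriveSpec
    phi: np.ndarray                      # (N,) complex, V; sink terminal = 0
    J: np.ndarray                        # (M, 3) complex, A/m², element centroids
    terminal_voltages: dict[str, complex]
    terminal_currents: dict[str, complex]
    mesh: Mesh
    residual: float
    sigma_star: np.ndarray | None = None  # (M,) element complex conductivity

    @property
    def impedance(self) -> complex:
        """(U_source - U_sink) / I_T."""
        u = self.terminal_voltages
        return (u[self.drive.source] - u[self.drive.sink]) / self.drive.current

    def transfer_impedance(self, pos: str, neg: str) -> complex:
        """(U_pos - U_neg) / I_T for any electrode pair (Eq. of the
        tetrapolar measurement when pos/neg are the recording electrodes)."""
        u = self.terminal_voltages
        return (u[pos] - u[neg]) / self.drive.current

    def conservation_error(self) -> float:
        """|sum of all terminal currents| / |I_T| (discrete KCL)."""
        total = sum(self.terminal_currents.values())
        return abs(total) / abs(self.drive.current)


# ---------------------------------------------------------------------------
# model: frequency-independent geometric matrices
# ---------------------------------------------------------------------------

def _facet_matrices(nodes_m: np.ndarray, faces: np.ndarray, n: int,
                    weights: np.ndarray | None = None):
    """Boundary-facet mass matrix, load vector and total area (SI units).

    ``weights`` scales each facet's area by its covered fraction (partial
    rim facets of disc electrodes)."""
    p = nodes_m[faces]
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    area = 0.5 * np.linalg.norm(cross, axis=1)
    if weights is not None:
        area = area * weights
    m_local = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]) / 12.0
    data = area[:, None, None] * m_local[None]
    rows = np.repeat(faces, 3, axis=1).reshape(-1)
    cols = np.tile(faces, (1, 3)).reshape(-1)
    m = sp.coo_matrix((data.reshape(-1), (rows, cols)), shape=(n, n)).tocsr()
    b = np.zeros(n)
    np.add.at(b, faces.reshape(-1), np.repeat(area / 3.0, 3))
    return m, b, float(area.sum())


class FemModel:
    """Geometric FEM operators for one mesh; assembles per-frequency systems."""

    def __init__(self, mesh: Mesh, materials: MaterialProps | None = None,
                 interfaces: InterfaceSet | None = None):
        self.mesh = mesh
        self.materials = materials or MaterialProps()
        self.interfaces = interfaces or InterfaceSet()
        if mesh.membrane_faces_med.shape[0] > 0 and self.interfaces.membrane is None:
            raise AssemblyError(
                "mesh has membrane facets but no membrane film model was supplied"
            )

        n = mesh.n_nodes
        nodes_m = mesh.nodes * UM
        tets = mesh.tets.astype(np.int64)

        # P1 gradients and volumes
        e = nodes_m[tets[:, 1:]] - nodes_m[tets[:, :1]]      # (M, 3, 3) edge rows
        det = np.linalg.det(e)
        if np.any(np.abs(det) < 1e-30):
            raise AssemblyError("degenerate tetrahedra in mesh")
        inv = np.linalg.inv(e)                               # columns = grad(lambda_i)
        g123 = np.transpose(inv, (0, 2, 1))                  # (M, 3, 3) rows = grads
        g0 = -g123.sum(axis=1, keepdims=True)
        self.grads = np.concatenate([g0, g123], axis=1)      # (M, 4, 3), 1/m
        self.volumes_m3 = np.abs(det) / 6.0

        # unit-conductivity stiffness per region
        local = np.einsum("mad,mbd->mab", self.grads, self.grads) * \
            self.volumes_m3[:, None, None]
        rows = np.repeat(tets, 4, axis=1).reshape(-1)
        cols = np.tile(tets, (1, 4)).reshape(-1)
        self.k_region = {}
        for region in (REGION_MEDIUM, REGION_CYTOPLASM):
            mask = mesh.region == region
            if not mask.any():
                self.k_region[region] = sp.csr_matrix((n, n))
                continue
            sel = np.repeat(mask, 16)
            self.k_region[region] = sp.coo_matrix(
                (local.reshape(-1)[sel], (rows[sel], cols[sel])), shape=(n, n)
            ).tocsr()

        # electrode facet operators (the outer ground, if any, is one more
        # ideal terminal)
        self.terminal_ids: list[str] = list(mesh.electrode_faces.keys())
        self.facet_ops: dict[str, tuple[sp.csr_matrix, np.ndarray, float]] = {}
        for eid, faces in mesh.electrode_faces.items():
            self.facet_ops[eid] = _facet_matrices(
                nodes_m, faces.astype(np.int64), n,
                mesh.electrode_face_weights.get(eid))
        if mesh.outer_ground_faces is not None:
            self.terminal_ids.append(OUTER_GROUND_ID)
            self.facet_ops[OUTER_GROUND_ID] = _facet_matrices(
                nodes_m, mesh.outer_ground_faces.astype(np.int64), n)

        # membrane coupling (unit 1/z_m coefficient)
        fm = mesh.membrane_faces_med.astype(np.int64)
        fc = mesh.membrane_faces_cyt.astype(np.int64)
        if fm.shape[0] > 0:
            mm, _, self.membrane_area = _facet_matrices(nodes_m, fm, n)
            p = nodes_m[fm]
            cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
            area = 0.5 * np.linalg.norm(cross, axis=1)
            m_local = np.array([[2., 1., 1.], [1., 2., 1.], [1., 1., 2.]]) / 12.0
            data = (area[:, None, None] * m_local[None]).reshape(-1)
            rm = np.repeat(fm, 3, axis=1).reshape(-1)
            cm_ = np.tile(fm, (1, 3)).reshape(-1)
            rc = np.repeat(fc, 3, axis=1).reshape(-1)
            cc = np.tile(fc, (1, 3)).reshape(-1)
            self.c_membrane = sp.coo_matrix(
                (np.concatenate([data, data, -data, -data]),
                 (np.concatenate([rm, rc, rm, rc]),
                  np.concatenate([cm_, cc, cc, cm_]))),
                shape=(n, n),
            ).tocsr()
        else:
            self.c_membrane = None
            self.membrane_area = 0.0

        # gauge node: the far corner (max x, max y, max z) — never under an
        # electrode or inside the cell
        corner = mesh.nodes[:, 0] + mesh.nodes[:, 1] + mesh.nodes[:, 2]
        self.gauge_node = int(np.argmax(corner))

        self._sigma_star_cache: dict[float, np.ndarray] = {}

    # -- per-frequency assembly --------------------------------------------

    def surface_impedances(self, f: float) -> dict[str, complex]:
        """z_s per terminal, Ω·m² (ideal contacts for missing film models)."""
        out = {}
        for eid in self.terminal_ids:
            if eid == OUTER_GROUND_ID or self.interfaces.electrode is None:
                # ideal contact: film at a fixed small fraction of the
                # patch's spreading-resistance scale
                area = self.facet_ops[eid][2]
                a_eff = np.sqrt(area / np.pi)
                out[eid] = complex(self.interfaces.ideal_contact_eps
                                   * a_eff / self.materials.sigma_medium)
            else:
                area_um2 = self.facet_ops[eid][2] / UM ** 2 * self.mesh.symmetry_factor
                out[eid] = surface_impedance_electrode(
                    f, self.interfaces.electrode, area_um2)
        return out

    def element_sigma_star(self, f: float,
                           delta_sigma: np.ndarray | None = None) -> np.ndarray:
        """Per-element complex conductivity, with optional perturbation."""
        mat = self.materials
        sig = np.where(
            self.mesh.region == REGION_CYTOPLASM,
            mat.complex_conductivity("cytoplasm", f),
            mat.complex_conductivity("medium", f),
        )
        if delta_sigma is not None:
            sig = sig + delta_sigma
        return sig

    def assemble(self, f: float,
                 delta_sigma: np.ndarray | None = None) -> "AssembledSystem":
        """Assemble the complex symmetric system at frequency ``f`` (Hz).

        ``delta_sigma`` optionally perturbs the per-element conductivity
        (used by the direct-difference oracle for the perturbation theorem).
        """
        mat = self.materials
        n = self.mesh.n_nodes
        if delta_sigma is None:
            a_nodes = (mat.complex_conductivity("medium", f) * self.k_region[REGION_MEDIUM]
                       + mat.complex_conductivity("cytoplasm", f) * self.k_region[REGION_CYTOPLASM])
        else:
            # rebuild the stiffness with per-element coefficients
            tets = self.mesh.tets.astype(np.int64)
            sig = self.element_sigma_star(f, delta_sigma)
            local = np.einsum("mad,mbd->mab", self.grads, self.grads) * \
                (self.volumes_m3 * sig)[:, None, None]
            rows = np.repeat(tets, 4, axis=1).reshape(-1)
            cols = np.tile(tets, (1, 4)).reshape(-1)
            a_nodes = sp.coo_matrix((local.reshape(-1), (rows, cols)),
                                    shape=(n, n)).tocsr()

        z_s = self.surface_impedances(f)
        if self.c_membrane is not None:
            z_m = membrane_surface_impedance(f, self.interfaces.membrane) * 1e-4  # Ω·m²
            a_nodes = a_nodes + self.c_membrane * (1.0 / z_m)

        t_of = {eid: i for i, eid in enumerate(self.terminal_ids)}
        nt = len(self.terminal_ids)
        blocks_r, blocks_c, blocks_d = [], [], []
        a_nodes = a_nodes.astype(complex).tocoo()
        blocks_r.append(a_nodes.row)
        blocks_c.append(a_nodes.col)
        blocks_d.append(a_nodes.data)
        for eid in self.terminal_ids:
            m_e, b_e, area_e = self.facet_ops[eid]
            y = 1.0 / z_s[eid]
            me = (m_e * y).tocoo()
            blocks_r.append(me.row)
            blocks_c.append(me.col)
            blocks_d.append(me.data)
            t = n + t_of[eid]
            nz = np.flatnonzero(b_e)
            coup = -(b_e[nz] * y)
            blocks_r.extend([nz, np.full(nz.size, t)])
            blocks_c.extend([np.full(nz.size, t), nz])
            blocks_d.extend([coup, coup])
            blocks_r.append(np.array([t]))
            blocks_c.append(np.array([t]))
            blocks_d.append(np.array([area_e * y]))
        a_full = sp.coo_matrix(
            (np.concatenate(blocks_d).astype(complex),
             (np.concatenate(blocks_r), np.concatenate(blocks_c))),
            shape=(n + nt, n + nt),
        ).tocsc()

        keep = np.ones(n + nt, dtype=bool)
        keep[self.gauge_node] = False
        return AssembledSystem(
            model=self, frequency=f, matrix=a_full, keep=keep,
            terminal_index=t_of, z_s=z_s,
            sigma_star=self.element_sigma_star(f, delta_sigma),
        )


def _nd_order(ids: np.ndarray, pts: np.ndarray, leaf: int = 64) -> list[np.ndarray]:
    """Geometric nested dissection with grid-plane separators.

    The structured mesh places nodes on axis-aligned planes, so a whole
    coordinate plane is an exact graph separator; ordering separators last
    keeps the sparse LU fill near the O(n^{4/3}) optimum for 3-D grids
    (SuperLU's built-in orderings do far worse on these meshes).
    """
    if ids.size <= leaf:
        return [ids]
    ax = int(np.argmax(pts.max(axis=0) - pts.min(axis=0)))
    vals = np.unique(pts[:, ax])
    if vals.size < 3:
        return [ids]
    med = vals[vals.size // 2]
    left = pts[:, ax] < med
    right = pts[:, ax] > med
    sep = pts[:, ax] == med
    out = _nd_order(ids[left], pts[left], leaf) + _nd_order(ids[right], pts[right], leaf)
    out.append(ids[sep])
    return out


@dataclass
class AssembledSystem:
    """Assembled complex system at one frequency (opaque solver handle)."""

    model: FemModel
    frequency: float
    matrix: sp.csc_matrix
    keep: np.ndarray
    terminal_index: dict[str, int]
    z_s: dict[str, complex]
    sigma_star: np.ndarray
    _lu: spla.SuperLU | None = None
    _reduced: sp.csc_matrix | None = None
    _perm: np.ndarray | None = None

    def _factorize(self):
        if self._lu is None:
            idx = np.flatnonzero(self.keep)
            reduced = self.matrix[np.ix_(idx, idx)].tocsc()
            # terminal unknowns get a far-away pseudo-coordinate: they are
            # coupled to whole electrode patches and belong in the top
            # separator
            pts = np.vstack([
                self.model.mesh.nodes,
                np.full((len(self.terminal_index), 3), 1e12),
            ])[idx]
            self._perm = np.concatenate(_nd_order(np.arange(idx.size), pts))
            self._reduced = reduced[np.ix_(self._perm, self._perm)].tocsc()
            try:
                self._lu = spla.splu(
                    self._reduced, permc_spec="NATURAL",
                    options=dict(SymmetricMode=True, DiagPivotThresh=0.01),
                )
            except RuntimeError as exc:  # singular
                raise SolverError(f"sparse factorization failed: {exc}") from exc
        return self._lu

    def solve(self, rhs_full: np.ndarray, rtol: float = 1e-10) -> tuple[np.ndarray, float]:
        lu = self._factorize()
        idx = np.flatnonzero(self.keep)
        b = rhs_full[idx][self._perm]
        x = lu.solve(b)
        bnorm = np.linalg.norm(b)
        res = np.linalg.norm(self._reduced @ x - b) / bnorm
        for _ in range(3):
            if res <= rtol:
                break
            x = x + lu.solve(b - self._reduced @ x)
            res = np.linalg.norm(self._reduced @ x - b) / bnorm
        if res > max(rtol, 1e-8):
            raise SolverError(
                f"linear solve did not reach the requested residual: "
                f"relative residual {res:.3e} at f = {self.frequency} Hz"
            )
        full = np.zeros(self.matrix.shape[0], dtype=complex)
        full[idx[self._perm]] = x
        return full, float(res)


def assemble(mesh: Mesh, materials: MaterialProps | None,
             interfaces: InterfaceSet | None, f: float) -> AssembledSystem:
    """One-shot assembly (builds a :class:`FemModel` and assembles at ``f``)."""
    return FemModel(mesh, materials, interfaces).assemble(f)


def solve_drive(system: AssembledSystem, drive: DriveSpec,
                rtol: float = 1e-10) -> FieldSolution:
    """Solve one terminal drive and post-process fields.

    Currents are fed per the drive spec (scaled for half-domain symmetry
    internally); reported terminal voltages are referenced to the sink.
    """
    model = system.model
    mesh = model.mesh
    n = mesh.n_nodes
    for eid in (drive.source, drive.sink):
        if eid not in system.terminal_index:
            raise SolverError(f"drive references unknown electrode {eid!r}; "
                              f"known terminals: {sorted(system.terminal_index)}")
    i_eff = drive.current / mesh.symmetry_factor
    rhs = np.zeros(model.mesh.n_nodes + len(system.terminal_index), dtype=complex)
    rhs[n + system.terminal_index[drive.source]] = i_eff
    rhs[n + system.terminal_index[drive.sink]] = -i_eff

    x, res = system.solve(rhs, rtol=rtol)
    phi = x[:n]
    u = {eid: x[n + t] for eid, t in system.terminal_index.items()}

    # reference potentials to the sink terminal (grounded counter electrode)
    shift = u[drive.sink]
    phi = phi - shift
    u = {eid: v - shift for eid, v in u.items()}

    # terminal currents through the films (scaled back to full-domain values)
    currents = {}
    for eid, t in system.terminal_index.items():
        m_e, b_e, area_e = model.facet_ops[eid]
        i_e = (u[eid] * area_e - b_e @ phi) / system.z_s[eid]
        currents[eid] = i_e * mesh.symmetry_factor

    tets = mesh.tets.astype(np.int64)
    grad_phi = np.einsum("mad,ma->md", model.grads, phi[tets])
    j = -system.sigma_star[:, None] * grad_phi

    return FieldSolution(
        frequency=system.frequency, drive=drive, phi=phi, J=j,
        terminal_voltages=u, terminal_currents=currents,
        mesh=mesh, residual=res, sigma_star=system.sigma_star,
    )
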