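"""MEA layouts, cell shapes, simulation domains and labeled tetrahedral meshes.

All lengths are micrometres.  The MEA substrate is the plane y = 0 with the
bath extending to y > 0; the electrode line runs along x and z completes the
right-handed system.  Adherent cells are spherical caps whose volume equals
that of the free sphere; the cap rests a small gap above the substrate.

The mesher produces a deterministic, graded, structured tetrahedral mesh:
each axis is subdivided with fine spacing inside refinement windows (around
electrodes and cell positions) and geometric coarsening elsewhere, every
hexahedral grid cell is split into six tetrahedra (Kuhn subdivision, which is
conforming when every cell is split identically), elements are labeled
medium/cytoplasm by centroid membership in the cell shape, and the cell
membrane is represented by duplicating the interface nodes so that a
thin-layer impedance can couple the two sides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, InvalidGeometryError, MeshingError

__all__ = [
    "CellGeometry",
    "Electrode",
    "MEALayout",
    "SimulationDomain",
    "MeshResolution",
    "Mesh",
    "make_cell_shape",
    "build_mea_layout",
    "two_electrode_layout",
    "four_electrode_layout",
    "generate_mesh",
    "structured_box_mesh",
]

#: default cell-substrate gap, µm (500 nm)
DEFAULT_GAP_UM = 0.5

ROLES = ("excitation", "counter", "recording_pos", "recording_neg", "passive")


# ---------------------------------------------------------------------------
# cell geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellGeometry:
    """Sphere or volume-conserving spherical-cap model of a single cell.

    ``r0`` is the free-sphere radius and ``(x0, y0, z0)`` the sphere-centre
    position, with ``y0`` the orthogonal distance of the centre from the MEA
    base plate.  For an adherent cell the shape is a spherical cap of height
    ``h = r0 + y0`` and cap-sphere radius ``r_cap = 4 r0^3 / (3 h^2) + h / 3``,
    which conserves the free-sphere volume exactly.  The cap is lifted off the
    substrate by ``gap`` (excluded from the radius computation).
    """

    r0: float
    x0: float = 0.0
    y0: float = 0.0
    z0: float = 0.0
    shape: str = "sphere"
    h: float | None = None
    r_cap: float | None = None
    gap: float = DEFAULT_GAP_UM

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise InvalidGeometryError(f"cell radius r0 must be positive, got {self.r0}")
        if self.shape not in ("sphere", "spherical_cap"):
            raise InvalidGeometryError(f"unknown cell shape {self.shape!r}")
        if self.shape == "spherical_cap" and (self.h is None or self.r_cap is None):
            raise InvalidGeometryError("spherical_cap requires h and r_cap")

    @property
    def volume(self) -> float:
        """Cell volume, µm³ (identical for sphere and cap by construction)."""
        return 4.0 / 3.0 * np.pi * self.r0 ** 3

    @property
    def cap_volume(self) -> float:
        """Cap volume from the cap formula h²π/3 (3 r − h), µm³."""
        if self.shape != "spherical_cap":
            return self.volume
        return self.h ** 2 * np.pi / 3.0 * (3.0 * self.r_cap - self.h)

    @property
    def cap_centre_y(self) -> float:
        """Height of the cap-sphere centre above the base plate, µm."""
        return self.gap + self.h - self.r_cap

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box (lo, hi), µm."""
        if self.shape == "sphere":
            c = np.array([self.x0, self.y0, self.z0])
            return c - self.r0, c + self.r0
        # lateral extent is the full cap-sphere radius when the cap is taller
        # than a hemisphere, otherwise the footprint radius
        w = self.r_cap if self.h > self.r_cap else self.base_radius()
        lo = np.array([self.x0 - w, self.gap, self.z0 - w])
        hi = np.array([self.x0 + w, self.gap + self.h, self.z0 + w])
        return lo, hi

    def base_radius(self) -> float:
        """Radius of the circular footprint of the cap on its base plane, µm."""
        if self.shape == "sphere":
            return 0.0
        d = self.h - self.r_cap  # centre height above the base plane
        return float(np.sqrt(max(self.r_cap ** 2 - d ** 2, 0.0)))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership mask for an (N, 3) array of points in µm."""
        p = np.atleast_2d(points)
        if self.shape == "sphere":
            c = np.array([self.x0, self.y0, self.z0])
            return np.einsum("ij,ij->i", p - c, p - c) <= self.r0 ** 2
        c = np.array([self.x0, self.cap_centre_y, self.z0])
        inside = np.einsum("ij,ij->i", p - c, p - c) <= self.r_cap ** 2
        return inside & (p[:, 1] >= self.gap)


def make_cell_shape(
    r0: float,
    y0: float,
    adherent: bool,
    *,
    x0: float = 0.0,
    z0: float = 0.0,
    gap: float = DEFAULT_GAP_UM,
) -> CellGeometry:
    """Build the cell model for a free-sphere radius ``r0`` at height ``y0``.

    Adherent cells (``0 < y0 <= r0``) become volume-conserving spherical caps
    with height ``h = r0 + y0``; at ``y0 = r0`` the cap degenerates exactly to
    the full sphere.  A requested adherent cell with ``y0 > r0`` is detached:
    a warning is emitted and the free sphere is returned.
    """
    if r0 <= 0:
        raise InvalidGeometryError(f"cell radius r0 must be positive, got {r0}")
    if adherent:
        if y0 <= 0:
            raise InvalidGeometryError(
                f"adherent cell requires y0 > 0 (centre above the base plate), got y0={y0}"
            )
        if y0 > r0:
            warnings.warn(
                f"y0={y0} > r0={r0}: cell is detached from the substrate; "
                "falling back to the free sphere",
                stacklevel=2,
            )
            return CellGeometry(r0=r0, x0=x0, y0=y0, z0=z0, shape="sphere", gap=gap)
        h = r0 + y0
        r_cap = 4.0 * r0 ** 3 / (3.0 * h ** 2) + h / 3.0
        return CellGeometry(
            r0=r0, x0=x0, y0=y0, z0=z0, shape="spherical_cap", h=h, r_cap=r_cap, gap=gap
        )
    return CellGeometry(r0=r0, x0=x0, y0=y0, z0=z0, shape="sphere", gap=gap)


# ---------------------------------------------------------------------------
# MEA layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Electrode:
    """Planar disc microelectrode on the substrate (zero thickness)."""

    id: str
    center: tuple[float, float]  # (x, z) in the MEA plane, µm
    diameter: float  # µm
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigurationError(f"unknown electrode role {self.role!r}")
        if self.diameter <= 0:
            raise ConfigurationError(f"electrode {self.id}: diameter must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class MEALayout:
    """Collection of labeled disc electrodes on the y = 0 substrate plane."""

    electrodes: tuple[Electrode, ...]

    def __post_init__(self) -> None:
        if not self.electrodes:
            raise ConfigurationError("layout contains no electrodes")
        ids = [e.id for e in self.electrodes]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"duplicate electrode ids in {ids}")
        for role in ("excitation", "counter", "recording_pos", "recording_neg"):
            n = sum(e.role == role for e in self.electrodes)
            if n > 1:
                raise ConfigurationError(f"duplicate role {role!r} ({n} electrodes)")
        if not any(e.role == "excitation" for e in self.electrodes):
            raise ConfigurationError("layout needs an excitation electrode")
        if not any(e.role == "counter" for e in self.electrodes):
            raise ConfigurationError("layout needs a counter electrode")
        for i, a in enumerate(self.electrodes):
            for b in self.electrodes[i + 1:]:
                d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d < a.radius + b.radius:
                    raise ConfigurationError(
                        f"electrodes {a.id} and {b.id} overlap (centre distance {d} µm)"
                    )

    @property
    def is_four_electrode(self) -> bool:
        roles = {e.role for e in self.electrodes}
        return {"recording_pos", "recording_neg"} <= roles

    def by_role(self, role: str) -> Electrode:
        for e in self.electrodes:
            if e.role == role:
                return e
        raise ConfigurationError(f"layout has no electrode with role {role!r}")

    def __getitem__(self, eid: str) -> Electrode:
        for e in self.electrodes:
            if e.id == eid:
                return e
        raise KeyError(eid)


def two_electrode_layout(diameter: float = 30.0, half_spacing: float = 50.0) -> MEALayout:
    """Default bipolar layout: discs at x = ±half_spacing, excitation at −x."""
    return MEALayout((
        Electrode("E2", (-half_spacing, 0.0), diameter, "excitation"),
        Electrode("E3", (+half_spacing, 0.0), diameter, "counter"),
    ))


def four_electrode_layout(diameter: float = 30.0) -> MEALayout:
    """Default tetrapolar layout: drive discs at ±150 µm, sense discs at ±50 µm."""
    return MEALayout((
        Electrode("E1", (-150.0, 0.0), diameter, "excitation"),
        Electrode("E2", (-50.0, 0.0), diameter, "recording_pos"),
        Electrode("E3", (+50.0, 0.0), diameter, "recording_neg"),
        Electrode("E4", (+150.0, 0.0), diameter, "counter"),
    ))


def build_mea_layout(config: Mapping | str | None = None) -> MEALayout:
    """Build a layout from a config mapping or a named preset.

    ``config`` may be ``"two_electrode"``/``"four_electrode"`` (or a mapping
    with a ``preset`` key), or a mapping with an ``electrodes`` list of
    ``{id, center: [x, z], diameter, role}`` entries.
    """
    if config is None:
        config = "two_electrode"
    if isinstance(config, str):
        config = {"preset": config}
    if "preset" in config:
        preset = config["preset"]
        diameter = float(config.get("diameter", 30.0))
        if preset == "two_electrode":
            return two_electrode_layout(diameter=diameter)
        if preset == "four_electrode":
            return four_electrode_layout(diameter=diameter)
        raise ConfigurationError(f"unknown layout preset {preset!r}")
    entries = config.get("electrodes")
    if not entries:
        raise ConfigurationError("layout config lists no electrodes")
    electrodes = tuple(
        Electrode(
            id=str(e.get("id", f"E{i + 1}")),
            center=(float(e["center"][0]), float(e["center"][1])),
            diameter=float(e.get("diameter", 30.0)),
            role=str(e["role"]),
        )
        for i, e in enumerate(entries)
    )
    return MEALayout(electrodes)


# ---------------------------------------------------------------------------
# simulation domain and mesh resolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationDomain:
    """Bath box, µm.  The substrate is y = 0; the bath fills y > 0.

    ``outer_bc`` is ``"insulating"`` (zero normal current on all outer faces,
    the default) or ``"ground"`` (top and side faces held at the reference
    potential through an ideal contact — used for spreading-resistance
    verification against the half-space closed form).

    ``symmetry="z"`` meshes only z >= 0 with an insulating symmetry plane,
    valid whenever the electrode line and every cell centre lie on z = 0.
    """

    x_extent: tuple[float, float] = (-400.0, 400.0)
    y_extent: tuple[float, float] = (0.0, 400.0)
    z_extent: tuple[float, float] = (-200.0, 200.0)
    outer_bc: str = "insulating"
    symmetry: str = "z"

    def __post_init__(self) -> None:
        if self.outer_bc not in ("insulating", "ground"):
            raise ConfigurationError(f"unknown outer boundary condition {self.outer_bc!r}")
        if self.symmetry not in ("z", "none"):
            raise ConfigurationError(f"unknown symmetry option {self.symmetry!r}")
        if self.y_extent[0] != 0.0:
            raise ConfigurationError("the bath must start at the substrate plane y = 0")


@dataclass(frozen=True)
class MeshResolution:
    """Grading control for the structured mesher.

    ``h_fine`` is the target spacing (µm) inside refinement windows —
    automatically placed around every electrode disc and, via
    ``refine_x_windows``, around scanned cell positions.  Away from the
    windows the spacing grows geometrically (factor ``growth``) up to
    ``h_coarse``.  ``extra_y_planes`` inserts explicit grid planes, by default
    one at the 500 nm cell-substrate gap so the medium film under an adherent
    cell is resolved.
    """

    h_fine: float = 2.5
    h_coarse: float = 40.0
    growth: float = 1.35
    y_fine_top: float = 30.0
    z_fine_halfwidth: float = 20.0
    refine_x_windows: tuple[tuple[float, float], ...] = ()
    extra_y_planes: tuple[float, ...] = (DEFAULT_GAP_UM,)
    electrode_margin: float = 10.0

    def refined(self, levels: int = 1) -> "MeshResolution":
        """Return a uniformly refined copy (each level shrinks spacings ~25%)."""
        f = 1.25 ** levels
        return replace(
            self,
            h_fine=self.h_fine / f,
            h_coarse=self.h_coarse / f,
        )


# ---------------------------------------------------------------------------
# 1-D graded subdivision
# ---------------------------------------------------------------------------

def _run_spacings(length: float, h0: float, h1: float, growth: float) -> np.ndarray:
    """Spacings filling ``length`` exactly, starting near ``h0`` and growing
    geometrically (factor <= growth) toward at most ``h1``;  h0 <= h1."""
    if length <= h0 * 1.5:
        return np.array([length])
    s: list[float] = []
    h = h0
    total = 0.0
    while total < length - 1e-12:
        s.append(h)
        total += h
        h = min(h * growth, h1)
    arr = np.asarray(s)
    arr *= length / arr.sum()
    return arr


def _grade_interval(length: float, h_left: float, h_right: float, growth: float) -> np.ndarray:
    """Spacings over ``length`` transitioning from ``h_left`` to ``h_right``.

    Mirror-consistent by construction:
    ``_grade_interval(L, a, b) == _grade_interval(L, b, a)[::-1]``.
    """
    if h_left <= h_right:
        return _run_spacings(length, h_left, h_right, growth)
    return _run_spacings(length, h_right, h_left, growth)[::-1]


def _gap_spacings(length: float, h_left: float, h_right: float,
                  h_cap: float, growth: float) -> np.ndarray:
    """Spacings for a gap between two fine regions, coarsening toward the
    middle (capped at ``h_cap``) and refining again on the far side."""
    if h_left >= h_cap or h_right >= h_cap or length <= 2.0 * max(h_left, h_right):
        return _grade_interval(length, h_left, h_right, growth)
    half = length / 2.0
    left = _grade_interval(half, h_left, h_cap, growth)
    right = _grade_interval(half, h_cap, h_right, growth)
    return np.concatenate([left, right])


def _merge_windows(windows: Iterable[tuple[float, float, float]],
                   lo: float, hi: float) -> list[tuple[float, float, float]]:
    clipped = []
    for a, b, h in windows:
        a, b = max(a, lo), min(b, hi)
        if b - a > 1e-9:
            clipped.append((a, b, h))
    clipped.sort()
    merged: list[list[float]] = []
    for a, b, h in clipped:
        if merged and a <= merged[-1][1] + 1e-9:
            merged[-1][1] = max(merged[-1][1], b)
            merged[-1][2] = min(merged[-1][2], h)
        else:
            merged.append([a, b, h])
    return [tuple(m) for m in merged]


def grade_axis(lo: float, hi: float,
               windows: Sequence[tuple[float, float, float]],
               h_coarse: float, growth: float,
               extra_planes: Sequence[float] = ()) -> np.ndarray:
    """1-D graded node array over [lo, hi] with uniform fine windows."""
    merged = _merge_windows(windows, lo, hi)
    pts = [lo]
    cursor, h_edge = lo, h_coarse
    for a, b, h in merged:
        if a - cursor > 0.25 * min(h_edge, h):
            sp = _gap_spacings(a - cursor, h_edge, h, h_coarse, growth)
            pts.extend(cursor + np.cumsum(sp))
        else:
            a = cursor
        n = max(1, int(round((b - a) / h)))
        pts.extend(a + (b - a) * np.arange(1, n + 1) / n)
        cursor, h_edge = b, h
    if hi - cursor > 1e-9:
        sp = _gap_spacings(hi - cursor, h_edge, h_coarse, h_coarse, growth)
        pts.extend(cursor + np.cumsum(sp))
    xs = np.asarray(pts)
    xs[-1] = hi
    for p in extra_planes:
        if p <= lo or p >= hi:
            continue
        i = int(np.searchsorted(xs, p))
        if min(xs[i] - p, p - xs[i - 1]) > 1e-9:  # explicit planes always inserted
            xs = np.insert(xs, i, p)
    return xs


# ---------------------------------------------------------------------------
# mesh container
# ---------------------------------------------------------------------------

REGION_MEDIUM = 0
REGION_CYTOPLASM = 1


@dataclass
class Mesh:
    """Labeled tetrahedral mesh (coordinates in µm).

    ``membrane_faces_med``/``membrane_faces_cyt`` are matching (F, 3) node
    triples on the two sides of the duplicated membrane surface; facet f
    couples medium nodes ``membrane_faces_med[f]`` to cytoplasm nodes
    ``membrane_faces_cyt[f]`` through the membrane film.
    ``symmetry_factor`` is 2 for half-domain (z >= 0) meshes.
    """

    nodes: np.ndarray                    # (N, 3) float64, µm
    tets: np.ndarray                     # (M, 4) int32
    region: np.ndarray                   # (M,) uint8
    electrode_faces: dict[str, np.ndarray] = field(default_factory=dict)
    #: per-facet covered-area fraction (rim facets are partially covered so
    #: the represented disc area is resolution-independent); missing key = 1
    electrode_face_weights: dict[str, np.ndarray] = field(default_factory=dict)
    outer_ground_faces: np.ndarray | None = None
    membrane_faces_med: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), np.int32))
    membrane_faces_cyt: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), np.int32))
    symmetry_factor: float = 1.0
    provenance: dict = field(default_factory=dict)

    _volumes: np.ndarray | None = None
    _centroids: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    def element_volumes(self) -> np.ndarray:
        """Per-element volumes, µm³."""
        if self._volumes is None:
            x = self.nodes[self.tets]
            v = np.abs(np.linalg.det(x[:, 1:] - x[:, :1])) / 6.0
            self._volumes = v
        return self._volumes

    def element_centroids(self) -> np.ndarray:
        """Per-element centroids, µm."""
        if self._centroids is None:
            self._centroids = self.nodes[self.tets].mean(axis=1)
        return self._centroids

    def membrane_is_closed(self) -> bool:
        """Topology audit: every edge of the membrane surface is shared by
        exactly two membrane facets (i.e. the surface is closed).  On
        half-domain meshes, edges lying in the symmetry plane are closed by
        the mirror image and may carry a single facet."""
        faces = self.membrane_faces_med
        if faces.shape[0] == 0:
            return False
        edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [0, 2]]])
        edges = np.sort(edges, axis=1)
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        if self.symmetry_factor > 1:
            on_plane = np.all(np.abs(self.nodes[uniq][:, :, 2]) < 1e-9, axis=1)
            return bool(np.all((counts == 2) | ((counts == 1) & on_plane)))
        return bool(np.all(counts == 2))


# ---------------------------------------------------------------------------
# mesh generation
# ---------------------------------------------------------------------------

# Kuhn subdivision: the six tetrahedra per hexahedron, as paths from corner
# (0,0,0) to (1,1,1); corners are bit triples (dx, dy, dz).
_KUHN_PATHS = (
    ((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)),
    ((0, 0, 0), (1, 0, 0), (1, 0, 1), (1, 1, 1)),
    ((0, 0, 0), (0, 1, 0), (1, 1, 0), (1, 1, 1)),
    ((0, 0, 0), (0, 1, 0), (0, 1, 1), (1, 1, 1)),
    ((0, 0, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1)),
    ((0, 0, 0), (0, 0, 1), (0, 1, 1), (1, 1, 1)),
)


def _axis_windows_x(layout: MEALayout, resolution: MeshResolution) -> list[tuple[float, float, float]]:
    m = resolution.electrode_margin
    wins = [
        (e.center[0] - e.radius - m, e.center[0] + e.radius + m, resolution.h_fine)
        for e in layout.electrodes
    ]
    wins += [(a, b, resolution.h_fine) for a, b in resolution.refine_x_windows]
    return wins


def _disc_coverage(nodes: np.ndarray, tris: np.ndarray,
                   center: tuple[float, float], radius: float,
                   nsub: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Select substrate facets covered by a disc, with rim facets weighted
    by their covered-area fraction (estimated on an nsub² barycentric
    subdivision)."""
    p = nodes[tris][:, :, [0, 2]]  # (F, 3, 2) in the substrate plane
    c = np.asarray(center)
    d = np.sqrt(((p - c) ** 2).sum(axis=2))  # (F, 3) vertex distances
    all_in = (d <= radius).all(axis=1)
    diam = np.sqrt(((p.max(axis=1) - p.min(axis=1)) ** 2).sum(axis=1))
    near = ~all_in & (d.min(axis=1) <= radius + diam)
    # barycentric subdivision sample points
    bc = []
    for i in range(nsub):
        for j in range(nsub - i):
            k = nsub - 1 - i - j
            bc.append(((i + 1.0 / 3), (j + 1.0 / 3), (k + 1.0 / 3)))
    bc = np.asarray(bc) / nsub  # (S, 3) barycentric coordinates of subtri centroids
    weights = np.zeros(tris.shape[0])
    weights[all_in] = 1.0
    idx = np.flatnonzero(near)
    if idx.size:
        pts = np.einsum("sv,fvd->fsd", bc, p[idx])  # (F', S, 2)
        frac = (((pts - c) ** 2).sum(axis=2) <= radius ** 2).mean(axis=1)
        weights[idx] = frac
    keep = weights > 0
    return tris[keep], weights[keep]


def _boundary_quad_tris(ij_shape: tuple[int, int], node_of: np.ndarray) -> np.ndarray:
    """Triangulate a logically rectangular boundary patch along the (+,+)
    index diagonal (matching the Kuhn tet faces).  ``node_of`` is the
    (n0, n1) array of global node ids on the patch."""
    n0, n1 = ij_shape
    a = node_of[:-1, :-1].ravel()
    b = node_of[1:, :-1].ravel()
    c = node_of[1:, 1:].ravel()
    d = node_of[:-1, 1:].ravel()
    return np.concatenate([np.stack([a, b, c], 1), np.stack([a, c, d], 1)]).astype(np.int32)


def generate_mesh(
    layout: MEALayout,
    cell: CellGeometry | None,
    domain: SimulationDomain | None = None,
    resolution: MeshResolution | None = None,
    seed: int = 0,
) -> Mesh:
    """Build the labeled tetrahedral mesh for a layout and optional cell.

    Deterministic for a fixed resolution control (the seed is recorded in the
    provenance but the construction involves no randomness).
    """
    domain = domain or SimulationDomain()
    resolution = resolution or MeshResolution()

    if cell is not None:
        lo, hi = cell.bounds()
        y_min = lo[1]
        if y_min < -1e-9:
            raise MeshingError(
                f"cell at ({cell.x0}, {cell.y0}, {cell.z0}) penetrates the substrate plane "
                f"(lowest point y = {y_min:.3f} µm)"
            )
        if (lo[0] < domain.x_extent[0] or hi[0] > domain.x_extent[1]
                or hi[1] > domain.y_extent[1]
                or lo[2] < domain.z_extent[0] or hi[2] > domain.z_extent[1]):
            raise MeshingError("cell lies (partly) outside the simulation domain")
        if domain.symmetry == "z" and abs(cell.z0) > 1e-9:
            raise MeshingError(
                "half-domain (symmetry='z') meshes require the cell on the z = 0 plane; "
                "use SimulationDomain(symmetry='none')"
            )

    g, hc = resolution.growth, resolution.h_coarse
    x_wins = _axis_windows_x(layout, resolution)
    if cell is not None:
        lo, hi = cell.bounds()
        x_wins.append((lo[0] - 4.0, hi[0] + 4.0, resolution.h_fine))
    xs = grade_axis(domain.x_extent[0], domain.x_extent[1], x_wins, hc, g)

    y_top_fine = resolution.y_fine_top
    if cell is not None:
        y_top_fine = max(y_top_fine, cell.bounds()[1][1] + 4.0)
    ys = grade_axis(domain.y_extent[0], domain.y_extent[1],
                    [(0.0, y_top_fine, resolution.h_fine)], hc, g,
                    extra_planes=resolution.extra_y_planes)

    zw = resolution.z_fine_halfwidth
    z_lo = 0.0 if domain.symmetry == "z" else domain.z_extent[0]
    zs = grade_axis(z_lo, domain.z_extent[1], [(-zw, zw, resolution.h_fine)], hc, g)

    nx, ny, nz = len(xs), len(ys), len(zs)
    node_id = np.arange(nx * ny * nz, dtype=np.int64).reshape(nx, ny, nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    # six tets per hex, vectorized over the (nx-1, ny-1, nz-1) cells
    corner = {
        (dx, dy, dz): node_id[dx:nx - 1 + dx, dy:ny - 1 + dy, dz:nz - 1 + dz].ravel()
        for dx in (0, 1) for dy in (0, 1) for dz in (0, 1)
    }
    tets = np.concatenate([
        np.stack([corner[c] for c in path], axis=1) for path in _KUHN_PATHS
    ]).astype(np.int64)

    # enforce positive orientation
    x = nodes[tets]
    det = np.linalg.det(x[:, 1:] - x[:, :1])
    flip = det < 0
    tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()

    centroids = nodes[tets].mean(axis=1)
    region = np.zeros(tets.shape[0], dtype=np.uint8)
    if cell is not None:
        region[cell.contains(centroids)] = REGION_CYTOPLASM
        if not region.any():
            raise MeshingError(
                "cell volume captured no element centroids; refine the mesh "
                f"(h_fine={resolution.h_fine} µm vs cell r0={cell.r0} µm)"
            )

    # electrode boundary facets on y = 0 (triangulated along the Kuhn
    # diagonal); rim facets carry fractional coverage weights so the
    # represented disc area converges quadratically to pi r^2
    bottom = node_id[:, 0, :]
    bottom_tris = _boundary_quad_tris((nx, nz), bottom)
    electrode_faces: dict[str, np.ndarray] = {}
    electrode_face_weights: dict[str, np.ndarray] = {}
    for e in layout.electrodes:
        sel, w = _disc_coverage(nodes, bottom_tris, e.center, e.radius)
        if sel.shape[0] == 0:
            raise MeshingError(f"electrode {e.id} is not covered by any boundary facet")
        electrode_faces[e.id] = sel.astype(np.int32)
        electrode_face_weights[e.id] = w

    outer_ground = None
    if domain.outer_bc == "ground":
        patches = [
            _boundary_quad_tris((nx, nz), node_id[:, -1, :]),          # top
            _boundary_quad_tris((ny, nz), node_id[0, :, :]),           # x min
            _boundary_quad_tris((ny, nz), node_id[-1, :, :]),          # x max
            _boundary_quad_tris((nx, ny), node_id[:, :, -1]),          # z max
        ]
        if domain.symmetry != "z":
            patches.append(_boundary_quad_tris((nx, ny), node_id[:, :, 0]))  # z min
        outer_ground = np.concatenate(patches)

    # membrane: faces shared between a cytoplasm and a medium element, then
    # node duplication so the two sides can differ in potential
    mem_med = np.zeros((0, 3), np.int32)
    mem_cyt = np.zeros((0, 3), np.int32)
    if cell is not None:
        faces = np.concatenate([
            tets[:, [0, 1, 2]], tets[:, [0, 1, 3]], tets[:, [0, 2, 3]], tets[:, [1, 2, 3]]
        ])
        owner_region = np.tile(region, 4)
        key = np.sort(faces, axis=1)
        order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
        ks = key[order]
        same = np.all(ks[1:] == ks[:-1], axis=1)
        pair_first = np.flatnonzero(same)
        r1 = owner_region[order][pair_first]
        r2_ = owner_region[order][pair_first + 1]
        is_mem = r1 != r2_
        mem_faces = ks[pair_first[is_mem]]

        nodes_cyt = np.unique(tets[region == REGION_CYTOPLASM])
        nodes_med = np.unique(tets[region == REGION_MEDIUM])
        shared = np.intersect1d(nodes_cyt, nodes_med)
        n0 = nodes.shape[0]
        dup_of = np.full(n0, -1, dtype=np.int64)
        dup_of[shared] = n0 + np.arange(shared.size)
        nodes = np.concatenate([nodes, nodes[shared]])
        cyt_mask = region == REGION_CYTOPLASM
        ct = tets[cyt_mask]
        remap = dup_of[ct]
        tets[cyt_mask] = np.where(remap >= 0, remap, ct)

        mem_med = mem_faces.astype(np.int32)
        mem_cyt = dup_of[mem_faces].astype(np.int32)
        if (mem_cyt < 0).any():
            raise MeshingError("internal error: membrane face node missing a duplicate")

    mesh = Mesh(
        nodes=nodes,
        tets=tets.astype(np.int32),
        region=region,
        electrode_faces=electrode_faces,
        electrode_face_weights=electrode_face_weights,
        outer_ground_faces=outer_ground,
        membrane_faces_med=mem_med,
        membrane_faces_cyt=mem_cyt,
        symmetry_factor=2.0 if domain.symmetry == "z" else 1.0,
        provenance={
            "seed": seed,
            "h_fine": resolution.h_fine,
            "h_coarse": resolution.h_coarse,
            "grid": (nx, ny, nz),
            "n_nodes": int(nodes.shape[0]),
            "n_elements": int(tets.shape[0]),
        },
    )
    return mesh


def structured_box_mesh(
    xs: np.ndarray, ys: np.ndarray, zs: np.ndarray,
    terminal_axis: str = "x",
) -> Mesh:
    """Homogeneous box mesh with two full opposite faces as ideal terminals.

    A verification utility: the lumped resistance between the plate
    terminals of a homogeneous box has the closed form L/(sigma*A).
    Terminals are labeled ``T0`` (min face) and ``T1`` (max face).
    """
    xs, ys, zs = (np.asarray(a, dtype=float) for a in (xs, ys, zs))
    nx, ny, nz = len(xs), len(ys), len(zs)
    node_id = np.arange(nx * ny * nz, dtype=np.int64).reshape(nx, ny, nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    corner = {
        (dx, dy, dz): node_id[dx:nx - 1 + dx, dy:ny - 1 + dy, dz:nz - 1 + dz].ravel()
        for dx in (0, 1) for dy in (0, 1) for dz in (0, 1)
    }
    tets = np.concatenate([
        np.stack([corner[c] for c in path], axis=1) for path in _KUHN_PATHS
    ]).astype(np.int64)
    x = nodes[tets]
    det = np.linalg.det(x[:, 1:] - x[:, :1])
    flip = det < 0
    tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()

    if terminal_axis == "x":
        f0 = _boundary_quad_tris((ny, nz), node_id[0, :, :])
        f1 = _boundary_quad_tris((ny, nz), node_id[-1, :, :])
    elif terminal_axis == "y":
        f0 = _boundary_quad_tris((nx, nz), node_id[:, 0, :])
        f1 = _boundary_quad_tris((nx, nz), node_id[:, -1, :])
    else:
        f0 = _boundary_quad_tris((nx, ny), node_id[:, :, 0])
        f1 = _boundary_quad_tris((nx, ny), node_id[:, :, -1])

    return Mesh(
        nodes=nodes,
        tets=tets.astype(np.int32),
        region=np.zeros(tets.shape[0], dtype=np.uint8),
        electrode_faces={"T0": f0, "T1": f1},
        provenance={"grid": (nx, ny, nz)},
    )
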