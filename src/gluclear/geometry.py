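"""Synapse scene geometry: meshes, simplified scene builder, neuropil descriptors.

Builds the simplified synaptic-contact scenes used by the particle engine
(two apposed terminals separated by a 20 nm cleft inside a 1 μm³ world,
surrounded by thin astrocytic processes covered with glutamate transporters),
measures triangulated meshes (surface area, volume, nearest distances) and
computes scalar neuropil descriptors such as the local uptake capacity.

Units: lengths in μm, areas in μm², volumes in μm³, surface densities in
μm⁻²; distances returned by :func:`nearest_surface_distance` are in nm.
Coordinates: the synapse axis is +z from the presynaptic to the postsynaptic
terminal and the world box is centered on the middle of the cleft.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy.optimize import brentq

__all__ = [
    "GeometryError",
    "FeasibilityError",
    "TriMesh",
    "SceneSpec",
    "SurfacePopulation",
    "SceneSolids",
    "Scene",
    "load_mesh_obj",
    "write_mesh_obj",
    "mesh_surface_area",
    "mesh_volume",
    "nearest_surface_distance",
    "place_surface_molecules",
    "build_simplified_scene",
    "occupied_volume_fraction",
    "local_uptake_capacity",
    "capacity_ratio",
    "CONTROL_SPEC",
    "TFLLR_SPEC",
    "CONTROL_SPEC_TABLE2",
    "TFLLR_SPEC_TABLE2",
]

ROLES = ("presynaptic", "postsynaptic", "psd", "astrocyte", "world")


class GeometryError(ValueError):
    """Invalid mesh or scene specification."""


class FeasibilityError(GeometryError):
    """The requested compartments cannot be packed inside the world box."""


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------


@dataclass
class TriMesh:
    """A triangulated surface with a compartment role label.

    vertices : (n, 3) float64, μm
    faces    : (m, 3) int, indices into ``vertices``
    role     : one of presynaptic | postsynaptic | psd | astrocyte | world
    """

    vertices: np.ndarray
    faces: np.ndarray
    role: str = "world"
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be (m, 3) triangles")
        if self.role not in ROLES:
            raise GeometryError(f"unknown role {self.role!r}")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @property
    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    def triangle_areas(self) -> np.ndarray:
        t = self.triangles
        cross = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)


def load_mesh_obj(path, role: str = "world") -> TriMesh:
    """Read a triangles-only Wavefront OBJ file.

    Only ``v`` and ``f`` records are interpreted; ``f`` entries may carry
    texture/normal slots (``a/b/c``) which are ignored.  Non-triangular faces
    are rejected with the offending face index.  Round-trips written by
    :func:`write_mesh_obj` are bit-identical.
    """
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    name = ""
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                vertices.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(p.split("/")[0]) for p in parts[1:]]
                if len(idx) != 3:
                    raise GeometryError(
                        f"face {len(faces)} has {len(idx)} vertices; "
                        "only triangles are supported"
                    )
                faces.append([i - 1 for i in idx])
            elif parts[0] in ("o", "g") and len(parts) > 1:
                name = parts[1]
    if not vertices:
        raise GeometryError(f"no vertices found in {path}")
    r = role
    if name and name in ROLES:
        r = name
    return TriMesh(np.array(vertices), np.array(faces), role=r, name=name)


def write_mesh_obj(mesh: TriMesh, path) -> None:
    """Write a triangles-only OBJ; floats use ``repr`` so re-reading is exact."""
    with open(path, "w") as fh:
        obj_name = mesh.name or mesh.role
        fh.write(f"o {obj_name}\n")
        for v in mesh.vertices:
            fh.write(f"v {float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        for f in mesh.faces:
            fh.write(f"f {int(f[0]) + 1} {int(f[1]) + 1} {int(f[2]) + 1}\n")


def mesh_surface_area(mesh: TriMesh) -> float:
    """Total triangle area in μm² (additive over disjoint submeshes)."""
    if len(mesh.faces) == 0:
        raise GeometryError("empty mesh")
    return float(mesh.triangle_areas().sum())


def mesh_volume(mesh: TriMesh) -> float:
    """Divergence-theorem volume in μm³, returned positive.

    The mesh must be watertight (every edge shared by exactly two faces);
    an inward-oriented mesh yields its volume with a warning.
    """
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        edges = trimesh.grouping.group_rows(tm.edges_sorted, require_count=1)
        boundary = tm.edges_sorted[edges][:20].tolist()
        raise GeometryError(
            f"mesh is not watertight; boundary edges (first 20): {boundary}"
        )
    vol = float(tm.volume)
    if vol < 0:
        warnings.warn("mesh is inward-oriented; returning |volume|")
        vol = -vol
    return vol


def _point_triangle_distances(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Min distance from each point to a set of triangles (vectorized).

    points: (p, 3); tri: (m, 3, 3).  Returns (p,) minima.  Standard
    closest-point-on-triangle region classification (Ericson).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    p = points[:, None, :]  # (p, 1, 3)
    ap = p - a[None]
    d1 = np.einsum("mk,pmk->pm", ab, ap)
    d2 = np.einsum("mk,pmk->pm", ac, ap)
    bp = p - b[None]
    d3 = np.einsum("mk,pmk->pm", ab, bp)
    d4 = np.einsum("mk,pmk->pm", ac, bp)
    cp = p - c[None]
    d5 = np.einsum("mk,pmk->pm", ab, cp)
    d6 = np.einsum("mk,pmk->pm", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(np.abs(denom) > 0, vb / denom, 0.0)
        w = np.where(np.abs(denom) > 0, vc / denom, 0.0)
    closest = a[None] + v[..., None] * ab[None] + w[..., None] * ac[None]

    # vertex regions
    reg_a = (d1 <= 0) & (d2 <= 0)
    reg_b = (d3 >= 0) & (d4 <= d3)
    reg_c = (d6 >= 0) & (d5 <= d6)
    # edge regions
    v_ab = np.where(np.abs(d1 - d3) > 0, d1 / (d1 - d3), 0.0)
    reg_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    w_ac = np.where(np.abs(d2 - d6) > 0, d2 / (d2 - d6), 0.0)
    reg_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    num = d4 - d3
    den = (d4 - d3) + (d5 - d6)
    w_bc = np.where(np.abs(den) > 0, num / den, 0.0)
    reg_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)

    closest = np.where(
        reg_bc[..., None], b[None] + w_bc[..., None] * (c - b)[None], closest
    )
    closest = np.where(reg_ac[..., None], a[None] + w_ac[..., None] * ac[None], closest)
    closest = np.where(reg_ab[..., None], a[None] + v_ab[..., None] * ab[None], closest)
    closest = np.where(reg_c[..., None], c[None] * np.ones_like(closest), closest)
    closest = np.where(reg_b[..., None], b[None] * np.ones_like(closest), closest)
    closest = np.where(reg_a[..., None], a[None] * np.ones_like(closest), closest)

    d = np.linalg.norm(p - closest, axis=2)
    return d.min(axis=1)


def _sample_points(mesh: TriMesh) -> np.ndarray:
    """Vertices plus edge midpoints and face centroids, as query points."""
    tri = mesh.triangles
    mids = np.concatenate(
        [
            (tri[:, 0] + tri[:, 1]) / 2,
            (tri[:, 1] + tri[:, 2]) / 2,
            (tri[:, 0] + tri[:, 2]) / 2,
            tri.mean(axis=1),
        ]
    )
    return np.concatenate([mesh.vertices, mids])


def nearest_surface_distance(a: TriMesh, b: TriMesh, chunk: int = 2048) -> float:
    """Minimum Euclidean distance between two triangle sets, in nm.

    Symmetric; 0 if the surfaces touch.  Query points are the vertices, edge
    midpoints and centroids of each mesh against the full triangle set of the
    other, which is exact for plane/plane contacts and accurate to the mesh
    resolution for curved surfaces.
    """
    if len(a.faces) == 0 or len(b.faces) == 0:
        raise GeometryError("empty mesh")
    best = np.inf
    for src, dst in ((a, b), (b, a)):
        pts = _sample_points(src)
        tri = dst.triangles
        for i in range(0, len(pts), chunk):
            d = _point_triangle_distances(pts[i : i + chunk], tri)
            best = min(best, float(d.min()))
    return best * 1000.0  # μm -> nm


# ---------------------------------------------------------------------------
# Surface molecule placement
# ---------------------------------------------------------------------------


@dataclass
class SurfacePopulation:
    """Molecules pinned to a host mesh surface.

    Positions are stored both as (triangle index, barycentric coords) and as
    resolved 3D points; ``state`` is an integer kinetic-state index per
    molecule (0 = outward-facing free at creation).
    """

    species: str
    mesh: TriMesh
    tri_index: np.ndarray
    barycentric: np.ndarray
    positions: np.ndarray
    state: np.ndarray

    @property
    def count(self) -> int:
        return len(self.tri_index)


def place_surface_molecules(
    mesh: TriMesh, density: float, species: str, seed: int = 0
) -> SurfacePopulation:
    """Place ``round(density × area)`` molecules uniformly over a surface.

    Triangles are chosen with probability proportional to area and positions
    are uniform in barycentric coordinates; deterministic for a fixed seed.
    """
    if density < 0:
        raise GeometryError("density must be >= 0")
    areas = mesh.triangle_areas()
    total = areas.sum()
    n = int(round(density * total))
    rng = np.random.default_rng(seed)
    if n == 0:
        z = np.zeros((0,), dtype=np.int64)
        return SurfacePopulation(
            species, mesh, z, np.zeros((0, 3)), np.zeros((0, 3)), z.copy()
        )
    tri_idx = rng.choice(len(areas), size=n, p=areas / total)
    u = rng.random(n)
    v = rng.random(n)
    flip = u + v > 1
    u[flip] = 1 - u[flip]
    v[flip] = 1 - v[flip]
    w = 1 - u - v
    bary = np.column_stack([w, u, v])
    tri = mesh.triangles[tri_idx]
    pos = np.einsum("nk,nkj->nj", bary, tri)
    return SurfacePopulation(
        species, mesh, tri_idx, bary, pos, np.zeros(n, dtype=np.int64)
    )


# ---------------------------------------------------------------------------
# Scene specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneSpec:
    """Scalar description of a simplified synaptic scene.

    Volumes/areas in μm³/μm², radii in μm, cleft height and PSD–astrocyte
    distance in nm, surface densities in μm⁻².
    """

    world_edge: float = 1.0
    pre_volume: float = 0.079
    pre_radius: float = 0.27
    post_volume: float = 0.040
    post_radius: float = 0.27
    cleft_height_nm: float = 20.0
    psd_area: float = 0.10
    n_astro: int = 2
    astro_area_per_process: float = 0.69
    psd_astro_distance_nm: float = 116.0
    transporter_density: float = 10800.0
    glua_psd_density: float = 200.0
    glun_psd_density: float = 300.0
    glua_extra_density: float = 40.0
    glun_extra_density: float = 60.0

    def validate(self) -> None:
        for name in (
            "world_edge",
            "pre_volume",
            "pre_radius",
            "post_volume",
            "post_radius",
            "psd_area",
            "astro_area_per_process",
        ):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be > 0")
        for name in (
            "cleft_height_nm",
            "psd_astro_distance_nm",
            "transporter_density",
            "glua_psd_density",
            "glun_psd_density",
            "glua_extra_density",
            "glun_extra_density",
        ):
            if getattr(self, name) < 0:
                raise GeometryError(f"{name} must be >= 0")
        if self.n_astro < 0:
            raise GeometryError("n_astro must be >= 0")
        h = self.cleft_height_nm * 1e-3
        if h >= self.pre_radius or h >= self.post_radius:
            raise GeometryError("cleft height must be smaller than both radii")


# Methods-narrative control and PAR1-activated (TFLLR) specifications.
CONTROL_SPEC = SceneSpec()
TFLLR_SPEC = SceneSpec(
    pre_volume=0.065,
    pre_radius=0.24,
    post_volume=0.029,
    post_radius=0.24,
    n_astro=4,
    astro_area_per_process=0.54,
    psd_astro_distance_nm=190.0,
)
# Variants following the per-simulation table instead of the narrative text.
CONTROL_SPEC_TABLE2 = replace(
    CONTROL_SPEC, pre_volume=0.07, astro_area_per_process=0.89
)
TFLLR_SPEC_TABLE2 = replace(
    TFLLR_SPEC, pre_volume=0.06, post_volume=0.03, astro_area_per_process=0.60
)


# ---------------------------------------------------------------------------
# Analytic solids (shared with the particle engine)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneSolids:
    """Exact parametric solids backing a simplified scene.

    Terminals are spheres truncated by the cleft planes (flat apposition
    face of radius ``apposition_radius``); astrocytic processes are thin
    rectangular slabs whose inner faces sit at ``astro_rho_in`` from the
    cleft axis, rotated to ``astro_angles`` about +z.
    """

    world_half: float
    cleft_hh: float  # half cleft height, μm
    cleft_radius: float
    pre_center_z: float
    pre_radius: float
    post_center_z: float
    post_radius: float
    apposition_radius: float
    psd_radius: float
    astro_angles: tuple[float, ...]
    astro_rho_in: float
    astro_thickness: float
    astro_half_width: float
    astro_half_height: float

    @property
    def n_astro(self) -> int:
        return len(self.astro_angles)


def _truncated_sphere(volume: float, face_radius: float, kind: str) -> tuple[float, float]:
    """Solve (R, cap_height) for a sphere truncated by a plane.

    kind='ball': solid is the sphere minus a cap of height h (presynaptic
    terminal; flat face radius ``face_radius``).  kind='cap': solid is the
    cap itself of height h (postsynaptic terminal).  Returns (R, h).
    """
    a = face_radius

    if kind == "cap":
        # V = pi*h*(3a^2 + h^2)/6, monotone in h
        def g(h):
            return math.pi * h * (3 * a * a + h * h) / 6.0 - volume

        h = brentq(g, 1e-9, 10.0)
    else:
        vmin = 2.0 / 3.0 * math.pi * a**3  # hemisphere limit (h = a)
        if volume <= vmin:
            raise FeasibilityError(
                f"presynaptic volume {volume} too small for apposition radius {a}"
            )

        def g(h):
            R = (a * a + h * h) / (2 * h)
            cap = math.pi * h * h * (3 * R - h) / 3.0
            return 4.0 / 3.0 * math.pi * R**3 - cap - volume

        h = brentq(g, 1e-6, a)
    R = (a * a + h * h) / (2 * h)
    return R, h


def _sphere_section_mesh(
    center_z: float,
    radius: float,
    theta_lo: float,
    theta_hi: float,
    face_z: float,
    face_up: bool,
    resolution: float,
    role: str,
) -> TriMesh:
    """Lat-long mesh of a sphere section closed by a flat disc at ``face_z``.

    theta is the polar angle from +z of the sphere frame; the section spans
    [theta_lo, theta_hi] and is capped by a fan disc whose normal points
    along +z when ``face_up``.
    """
    n_phi = max(24, int(math.ceil(2 * math.pi * radius / resolution)))
    n_theta = max(6, int(math.ceil(radius * (theta_hi - theta_lo) / resolution)))
    thetas = np.linspace(theta_lo, theta_hi, n_theta + 1)
    phis = np.linspace(0, 2 * math.pi, n_phi, endpoint=False)

    verts: list[np.ndarray] = []
    rings: list[np.ndarray] = []
    for th in thetas:
        s, c = math.sin(th), math.cos(th)
        start = sum(len(v) for v in verts)
        if s < 1e-12:  # pole collapses to one vertex
            verts.append(np.array([[0.0, 0.0, center_z + radius * c]]))
            rings.append(np.array([start]))
        else:
            ring = np.column_stack(
                [
                    radius * s * np.cos(phis),
                    radius * s * np.sin(phis),
                    np.full(n_phi, center_z + radius * c),
                ]
            )
            verts.append(ring)
            rings.append(np.arange(start, start + n_phi))

    faces: list[list[int]] = []
    for r0, r1 in zip(rings[:-1], rings[1:]):
        if len(r0) == 1:
            a = r0[0]
            for j in range(n_phi):
                faces.append([a, r1[j], r1[(j + 1) % n_phi]])
        elif len(r1) == 1:
            a = r1[0]
            for j in range(n_phi):
                faces.append([r0[j], a, r0[(j + 1) % n_phi]])
        else:
            for j in range(n_phi):
                jn = (j + 1) % n_phi
                faces.append([r0[j], r1[j], r0[jn]])
                faces.append([r1[j], r1[jn], r0[jn]])

    # close with a fan over the open boundary ring (flat face)
    boundary = rings[0] if len(rings[0]) > 1 and abs(
        center_z + radius * math.cos(theta_lo) - face_z
    ) < abs(center_z + radius * math.cos(theta_hi) - face_z) else rings[-1]
    vcount = sum(len(v) for v in verts)
    center_idx = vcount
    verts.append(np.array([[0.0, 0.0, face_z]]))
    for j in range(n_phi):
        jn = (j + 1) % n_phi
        if face_up:
            faces.append([center_idx, boundary[j], boundary[jn]])
        else:
            faces.append([center_idx, boundary[jn], boundary[j]])

    mesh = TriMesh(np.concatenate(verts), np.array(faces), role=role, name=role)
    tm = mesh.to_trimesh()
    if tm.volume < 0:
        mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1], role=role, name=role)
    return mesh


def _disc_mesh(radius: float, z: float, resolution: float, role: str) -> TriMesh:
    n = max(24, int(math.ceil(2 * math.pi * radius / resolution)))
    phis = np.linspace(0, 2 * math.pi, n, endpoint=False)
    rim = np.column_stack(
        [radius * np.cos(phis), radius * np.sin(phis), np.full(n, z)]
    )
    verts = np.vstack([[0.0, 0.0, z], rim])
    faces = [[0, 1 + j, 1 + (j + 1) % n] for j in range(n)]
    return TriMesh(verts, np.array(faces), role=role, name=role)


def _box_mesh(extents, transform, role: str, name: str) -> TriMesh:
    box = trimesh.creation.box(extents=extents, transform=transform)
    return TriMesh(np.asarray(box.vertices), np.asarray(box.faces), role=role, name=name)


@dataclass
class Scene:
    """A populated simplified synapse scene.

    ``meshes`` maps role -> list of :class:`TriMesh`; ``populations`` holds
    the surface molecules; ``solids`` carries the exact parametric shapes
    the particle engine collides against.
    """

    spec: SceneSpec
    solids: SceneSolids
    meshes: dict[str, list[TriMesh]]
    populations: list[SurfacePopulation]
    seed: int = 0

    def compartment_meshes(self) -> list[TriMesh]:
        out = []
        for role in ("presynaptic", "postsynaptic", "astrocyte"):
            out.extend(self.meshes.get(role, []))
        return out

    def total_astro_area(self) -> float:
        return sum(mesh_surface_area(m) for m in self.meshes.get("astrocyte", []))

    def transporter_count(self) -> int:
        return sum(p.count for p in self.populations if p.species == "transporter")


def build_simplified_scene(
    spec: SceneSpec,
    mesh_resolution: float = 0.02,
    seed: int = 0,
    astro_height: float = 0.5,
    astro_thickness: float = 0.05,
) -> Scene:
    """Build the simplified synapse scene from its scalar specification.

    Terminals are spheres truncated by the cleft planes; their flat
    apposition faces share the PSD-disc radius and their radii are solved so
    the mesh volumes match the stated volumes within 1%.  Astrocytic
    processes are 50 nm slabs placed symmetrically around the cleft axis
    with their inner face at the stated nearest distance from the PSD edge.

    Raises :class:`FeasibilityError` when the processes cannot be packed at
    the stated distance inside the world box.
    """
    spec.validate()
    Lh = spec.world_edge / 2.0
    hh = spec.cleft_height_nm * 1e-3 / 2.0
    r_psd = math.sqrt(spec.psd_area / math.pi)
    a = r_psd  # apposition face radius = PSD disc radius

    R_pre, h_pre = _truncated_sphere(spec.pre_volume, a, kind="ball")
    R_post, h_post = _truncated_sphere(spec.post_volume, a, kind="cap")
    pre_cz = -hh - (R_pre - h_pre)
    post_cz = hh + h_post - R_post

    if pre_cz - R_pre < -Lh or post_cz + R_post > Lh:
        raise FeasibilityError("terminal spheres extend beyond the world box")

    meshes: dict[str, list[TriMesh]] = {r: [] for r in ROLES}
    # presynaptic: sphere section below the flat face (theta from face ring to pi)
    th_face_pre = math.acos((R_pre - h_pre) / R_pre)
    meshes["presynaptic"].append(
        _sphere_section_mesh(
            pre_cz, R_pre, th_face_pre, math.pi, -hh, True, mesh_resolution,
            "presynaptic",
        )
    )
    th_face_post = math.acos((R_post - h_post) / R_post)
    meshes["postsynaptic"].append(
        _sphere_section_mesh(
            post_cz, R_post, 0.0, th_face_post, hh, False, mesh_resolution,
            "postsynaptic",
        )
    )
    meshes["psd"].append(_disc_mesh(r_psd, hh, mesh_resolution, "psd"))
    world = _box_mesh(
        (spec.world_edge,) * 3, np.eye(4), "world", "world"
    )
    meshes["world"].append(world)

    # astrocytic slabs
    d = spec.psd_astro_distance_nm * 1e-3
    t = astro_thickness
    H = min(astro_height, spec.world_edge - 2 * mesh_resolution)
    rho_in = r_psd + d
    angles: tuple[float, ...] = ()
    Wh = 0.0
    if spec.n_astro > 0:
        A = spec.astro_area_per_process
        W = (A - 2 * t * H) / (2 * H + 2 * t)
        if W <= 0:
            raise FeasibilityError(
                "per-process area too small for slab height; reduce astro_height"
            )
        Wh = W / 2.0
        # packing checks
        if rho_in + t > Lh:
            raise FeasibilityError(
                f"astro processes at distance {spec.psd_astro_distance_nm} nm "
                "do not fit inside the world box"
            )
        if spec.n_astro >= 2 and Wh >= rho_in * math.tan(math.pi / spec.n_astro):
            raise FeasibilityError("astro slabs would intersect each other")
        r_solid_max = max(
            R_pre if pre_cz + R_pre > -H / 2 else 0.0,
            R_post if post_cz - R_post < H / 2 else 0.0,
        )
        if rho_in <= r_solid_max:
            raise FeasibilityError(
                "astro processes at the stated distance would intersect a terminal"
            )
        angles = tuple(2 * math.pi * k / spec.n_astro for k in range(spec.n_astro))
        for k, ang in enumerate(angles):
            corners = np.array(
                [
                    [rho_in + t, Wh],
                    [rho_in + t, -Wh],
                    [rho_in, Wh],
                    [rho_in, -Wh],
                ]
            )
            rot = np.array(
                [
                    [math.cos(ang), -math.sin(ang)],
                    [math.sin(ang), math.cos(ang)],
                ]
            )
            world_xy = corners @ rot.T
            if np.any(np.abs(world_xy) > Lh) or H / 2 > Lh:
                raise FeasibilityError("astro slab extends beyond the world box")
            tf = np.eye(4)
            tf[:2, :2] = rot
            tf[:2, 3] = rot @ np.array([rho_in + t / 2, 0.0])
            meshes["astrocyte"].append(
                _box_mesh((t, W, H), tf, "astrocyte", f"astrocyte_{k}")
            )

    solids = SceneSolids(
        world_half=Lh,
        cleft_hh=hh,
        cleft_radius=a,
        pre_center_z=pre_cz,
        pre_radius=R_pre,
        post_center_z=post_cz,
        post_radius=R_post,
        apposition_radius=a,
        psd_radius=r_psd,
        astro_angles=angles,
        astro_rho_in=rho_in,
        astro_thickness=t,
        astro_half_width=Wh,
        astro_half_height=H / 2.0,
    )

    populations: list[SurfacePopulation] = []
    for k, m in enumerate(meshes["astrocyte"]):
        populations.append(
            place_surface_molecules(
                m, spec.transporter_density, "transporter", seed=seed * 1000 + k
            )
        )
    psd = meshes["psd"][0]
    if spec.glua_psd_density > 0:
        populations.append(
            place_surface_molecules(psd, spec.glua_psd_density, "GluA", seed=seed * 1000 + 101)
        )
    if spec.glun_psd_density > 0:
        populations.append(
            place_surface_molecules(psd, spec.glun_psd_density, "GluN", seed=seed * 1000 + 102)
        )

    scene = Scene(spec=spec, solids=solids, meshes=meshes,
                  populations=populations, seed=seed)

    # contract check: mesh-measured quantities match the spec within 1%
    for role, target in (
        ("presynaptic", spec.pre_volume),
        ("postsynaptic", spec.post_volume),
    ):
        v = mesh_volume(meshes[role][0])
        if abs(v - target) / target > 0.01:
            raise GeometryError(
                f"{role} mesh volume {v:.4f} deviates >1% from spec {target}"
            )
    if spec.n_astro:
        a_meas = scene.total_astro_area() / spec.n_astro
        if abs(a_meas - spec.astro_area_per_process) / spec.astro_area_per_process > 0.01:
            raise GeometryError("astro mesh area deviates >1% from spec")
    return scene


def occupied_volume_fraction(scene: Scene) -> float:
    """Fraction of the world volume occupied by solid compartments."""
    total = sum(mesh_volume(m) for m in scene.compartment_meshes())
    frac = total / scene.spec.world_edge**3
    if not 0.0 <= frac <= 1.0 + 1e-9:
        raise GeometryError(f"occupied fraction {frac} outside [0, 1]")
    return min(frac, 1.0)


def local_uptake_capacity(density: float, total_astro_area: float) -> float:
    """Transporter count = surface density × total astrocytic area."""
    if density < 0 or total_astro_area < 0:
        raise GeometryError("density and area must be >= 0")
    return density * total_astro_area


def capacity_ratio(capacity_a: float, capacity_b: float) -> float:
    """Percent change of b relative to a: 100 × (b/a − 1)."""
    if capacity_a == 0:
        raise GeometryError("reference capacity is zero; ratio undefined")
    return 100.0 * (capacity_b / capacity_a - 1.0)
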