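"""Parametric lattice-reinforcement design for tissue-mimicking prints.

Four unit-cell families are supported -- chain, knitted, diamond crystal and
Miura-ori origami -- together with tessellation into a rectangular matrix
slab, two-material embedding, volume fractions, conformal tessellation onto a
tubular vessel wall, wall offsetting and STL export.

All solid geometry is built from signed-distance fields (SDFs, negative
inside) polygonised with marching cubes, so every emitted mesh is closed and
consistently oriented without an external boolean kernel.  Units are mm
throughout; the frame is right-handed with x the tensile/length axis and z
the print/height axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import trimesh
from scipy.optimize import brentq
from skimage import measure

__all__ = [
    "GeometryError",
    "UnsupportedCellError",
    "EmptyLatticeError",
    "MeshError",
    "UnitCellSpec",
    "TessellationConfig",
    "MatrixSlab",
    "LatticeMesh",
    "CompositeSample",
    "TubeWallSpec",
    "build_unit_cell",
    "tessellate",
    "embed_lattice",
    "volume_fraction",
    "conformal_tessellate",
    "offset_wall",
    "export_stl",
    "published_design",
    "PUBLISHED_DESIGNS",
    "voxelized_volume",
]

# Vertex-merge tolerance for repaired meshes (mm).
MERGE_TOL = 1e-6


class GeometryError(ValueError):
    """A geometric precondition failed (degenerate or self-intersecting input)."""


class UnsupportedCellError(GeometryError):
    """Unknown unit-cell kind."""


class EmptyLatticeError(GeometryError):
    """No unit cell fits inside the target volume."""


class MeshError(GeometryError):
    """A mesh operation produced or received an invalid mesh."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

CELL_KINDS = ("chain", "knitted", "diamond_crystal", "origami")


@dataclass(frozen=True)
class UnitCellSpec:
    """Parametric definition of one unit cell.

    ``size`` is the hexagonal-prism circumradius for chain/knitted cells and
    the cube side for origami/diamond-crystal cells; ``height`` is the prism
    or cube height (the nominal z-extent of the cell).  ``strut_thickness``
    is the full strut/sheet thickness (a diameter or side, not a radius).
    """

    kind: str
    strut_thickness: float
    size: float = 5.0
    height: float | None = None
    link_gap_ratio: float = 1.0 / 3.0  # chain only: d / L
    fold_angle_deg: float = 60.0  # origami only: in-plane parallelogram angle

    def __post_init__(self):
        if self.kind not in CELL_KINDS:
            raise UnsupportedCellError(
                f"unknown unit-cell kind {self.kind!r}; expected one of {CELL_KINDS}"
            )
        if self.height is None:
            object.__setattr__(self, "height", self.size)
        if self.size <= 0 or self.height <= 0:
            raise GeometryError("cell dimensions must be positive")
        if self.strut_thickness <= 0:
            raise GeometryError("strut thickness must be positive")
        if self.strut_thickness >= min(self.size, self.height):
            raise GeometryError(
                "degenerate thickness: strut thickness "
                f"{self.strut_thickness} >= cell size {min(self.size, self.height)}"
            )
        if not 0.0 < self.link_gap_ratio < 1.0:
            raise GeometryError("link_gap_ratio must lie in (0, 1)")
        if not 0.0 < self.fold_angle_deg < 90.0:
            raise GeometryError("fold_angle_deg must lie in (0, 90)")


@dataclass(frozen=True)
class TessellationConfig:
    """How a unit cell is rescaled and tiled across the matrix slab.

    ``size_z`` is the target z-extent of the (uniformly rescaled) cell;
    ``spacing`` inserts empty space between cell bounding boxes per axis;
    ``thickness`` records the lattice strut thickness of the design.  An
    optional ``pitch`` overrides the default grid pitch (cell extent +
    spacing) per axis, which interlocking cells such as the chain need in
    order to stay connected; ``None`` entries keep the default.
    """

    size_z: float
    spacing: tuple[float, float, float] = (0.0, 0.0, 0.0)
    thickness: float = 0.5
    keep_aspect_ratio: bool = True
    pitch: tuple[float | None, float | None, float | None] = (None, None, None)

    def __post_init__(self):
        if self.size_z <= 0:
            raise GeometryError("size_z must be positive")
        if any(s < 0 for s in self.spacing):
            raise GeometryError("spacing components must be >= 0")
        if self.thickness <= 0:
            raise GeometryError("thickness must be positive")


@dataclass(frozen=True)
class MatrixSlab:
    """Rectangular base sample the lattice is embedded in (mm)."""

    length: float = 64.10
    width: float = 10.13
    height: float = 2.60
    material_id: str = "SHA30"

    def __post_init__(self):
        if min(self.length, self.width, self.height) <= 0:
            raise GeometryError("slab dimensions must be positive")

    @property
    def dims(self) -> np.ndarray:
        return np.array([self.length, self.width, self.height])

    @property
    def volume(self) -> float:
        return self.length * self.width * self.height


@dataclass
class LatticeMesh:
    """A tessellated lattice: watertight triangle soup plus provenance."""

    mesh: trimesh.Trimesh
    cell_count: int
    spec: UnitCellSpec | None = None
    config: TessellationConfig | None = None
    grid_shape: tuple[int, int, int] | None = None

    @property
    def is_empty(self) -> bool:
        return len(self.mesh.faces) == 0

    @property
    def volume(self) -> float:
        return 0.0 if self.is_empty else float(self.mesh.volume)


@dataclass
class CompositeSample:
    """Two-material assembly: matrix slab with the lattice subtracted."""

    matrix_mesh: trimesh.Trimesh
    lattice: LatticeMesh
    slab: MatrixSlab
    matrix_material: str = "SHA30"
    lattice_material: str = "SHA70"

    @property
    def matrix_volume(self) -> float:
        return float(self.matrix_mesh.volume)


@dataclass(frozen=True)
class TubeWallSpec:
    """Parametric tubular vessel wall.

    ``centerline`` is an (N, 3) polyline; ``inner_radius`` is either a scalar
    or one radius per station.  The wall solid is the inner surface offset
    outward by ``wall_offset``.  ``uv_factor`` is the UV-map scale (mm of
    surface arc length per UV unit cell), ``lattice_thickness`` the strut
    thickness of the conformal lattice and ``height_offset`` the fractional
    radial position of the lattice mid-surface within the wall.
    """

    centerline: np.ndarray
    inner_radius: float | np.ndarray = 9.0
    wall_offset: float = 2.0
    uv_factor: float = 2.75
    lattice_thickness: float = 0.5
    height_offset: float = 0.5

    def __post_init__(self):
        cl = np.asarray(self.centerline, dtype=float)
        if cl.ndim != 2 or cl.shape[1] != 3 or cl.shape[0] < 2:
            raise GeometryError("centerline must be an (N>=2, 3) polyline")
        object.__setattr__(self, "centerline", cl)
        r = np.asarray(self.inner_radius, dtype=float)
        if r.ndim == 0:
            r = np.full(cl.shape[0], float(r))
        if r.shape[0] != cl.shape[0] or np.any(r <= 0):
            raise GeometryError("need one positive inner radius per station")
        object.__setattr__(self, "inner_radius", r)
        if self.wall_offset <= 0:
            raise GeometryError("wall_offset must be positive")
        if self.uv_factor <= 0 or self.lattice_thickness <= 0:
            raise GeometryError("uv_factor and lattice_thickness must be positive")
        if self.wall_offset <= 2.0 * self.lattice_thickness:
            raise GeometryError(
                "wall_offset must exceed twice the lattice thickness so the "
                "lattice fits strictly inside the wall"
            )


# ---------------------------------------------------------------------------
# SDF primitives
# ---------------------------------------------------------------------------


def _sd_box(points: np.ndarray, half: np.ndarray, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    q = np.abs(points - np.asarray(center)) - np.asarray(half)
    outside = np.linalg.norm(np.maximum(q, 0.0), axis=-1)
    inside = np.minimum(np.max(q, axis=-1), 0.0)
    return outside + inside


def _dist_segments(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Min distance from each point to a set of segments (a[i] -> b[i])."""
    best = np.full(points.shape[0], np.inf)
    for ai, bi in zip(a, b):
        d = bi - ai
        L2 = float(d @ d)
        if L2 == 0.0:
            dist = np.linalg.norm(points - ai, axis=1)
        else:
            t = np.clip((points - ai) @ d / L2, 0.0, 1.0)
            dist = np.linalg.norm(points - ai - t[:, None] * d, axis=1)
        np.minimum(best, dist, out=best)
    return best


def _dist_polygon_2d(u: np.ndarray, v: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Unsigned distance from 2-D points to a closed polygon outline."""
    best = np.full(u.shape, np.inf)
    n = len(verts)
    for i in range(n):
        ax, ay = verts[i]
        bx, by = verts[(i + 1) % n]
        dx, dy = bx - ax, by - ay
        L2 = dx * dx + dy * dy
        t = np.clip(((u - ax) * dx + (v - ay) * dy) / L2, 0.0, 1.0)
        d = np.hypot(u - ax - t * dx, v - ay - t * dy)
        np.minimum(best, d, out=best)
    return best


def _hexagon_vertices(circumradius: float) -> np.ndarray:
    ang = np.arange(6) * (np.pi / 3.0)  # vertex on the +u axis
    return np.column_stack([circumradius * np.cos(ang), circumradius * np.sin(ang)])


# ---------------------------------------------------------------------------
# Marching-cubes polygonisation
# ---------------------------------------------------------------------------


def mesh_from_sdf(
    sdf: Callable[[np.ndarray], np.ndarray],
    bounds: tuple[np.ndarray, np.ndarray],
    resolution: float = 0.025,
) -> trimesh.Trimesh:
    """Polygonise the zero level set of ``sdf`` inside ``bounds``.

    The sampling grid is padded so the surface never touches the grid
    boundary, which guarantees a closed output surface.
    """
    lo = np.asarray(bounds[0], dtype=float) - 2.5 * resolution
    hi = np.asarray(bounds[1], dtype=float) + 2.5 * resolution
    ns = np.maximum(np.ceil((hi - lo) / resolution).astype(int) + 1, 4)
    axes = [np.linspace(lo[i], hi[i], ns[i]) for i in range(3)]
    spacing = tuple((hi[i] - lo[i]) / (ns[i] - 1) for i in range(3))
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()]).astype(np.float64)
    # Chunk the SDF evaluation to bound peak memory on large grids.
    vals = np.empty(pts.shape[0], dtype=np.float32)
    chunk = 2_000_000
    for i in range(0, pts.shape[0], chunk):
        vals[i : i + chunk] = sdf(pts[i : i + chunk])
    vol = vals.reshape(ns)
    if not (vol.min() < 0.0 < vol.max()):
        raise MeshError("SDF has no zero crossing inside the sampling bounds")
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0, spacing=spacing)
    verts = verts + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def voxelized_volume(
    sdf: Callable[[np.ndarray], np.ndarray],
    bounds: tuple[np.ndarray, np.ndarray],
    voxel: float = 0.05,
    subsamples: int = 2,
) -> float:
    """Independent volume estimate by voxelization at the given pitch.

    Each voxel contributes its occupied fraction, estimated by sampling the
    signed distance on a ``subsamples``^3 sub-grid with a clipped linear
    slab rule.  The fractional occupancy removes the grid-phase bias that
    plain in/out counting suffers on struts only a few voxels across.
    """
    h = voxel / subsamples
    lo = np.asarray(bounds[0], dtype=float) - voxel
    hi = np.asarray(bounds[1], dtype=float) + voxel
    ns = np.maximum(np.ceil((hi - lo) / h).astype(int), 2)
    axes = [lo[i] + (np.arange(ns[i]) + 0.5) * h for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    occupied = 0.0
    chunk = 2_000_000
    for i in range(0, pts.shape[0], chunk):
        d = sdf(pts[i : i + chunk])
        occupied += float(np.sum(np.clip(0.5 - d / h, 0.0, 1.0)))
    return occupied * h**3


# ---------------------------------------------------------------------------
# Unit-cell SDF constructions
# ---------------------------------------------------------------------------


def _chain_tilt_angle(u_max: float, half_t: float, half_height: float) -> float:
    """Tilt about y so the thickened ring's z half-extent equals half_height."""

    def f(phi):
        return u_max * math.sin(phi) + half_t * math.cos(phi) - half_height

    if f(math.pi / 2 - 1e-9) < 0:
        raise GeometryError("chain ring cannot reach the requested cell height")
    if f(0.0) > 0:
        raise GeometryError("chain strut thickness exceeds the cell height")
    return brentq(f, 0.0, math.pi / 2 - 1e-9)


def _chain_cell(spec: UnitCellSpec):
    """One hexagonal chain link, tilted so interlocked neighbours clear.

    The link is a mitred hexagonal annulus (square strut cross-section of
    side ``strut_thickness``) whose path circumradius is half the prism
    radius -- the ring drawn at the prism's mid-height mark.  All links in a
    row share the tilt; consecutive links overlap along x by L/3 so the gap
    between same-orientation links is ``link_gap_ratio * L``.
    """
    t = spec.strut_thickness
    ring_r = spec.size / 2.0
    hexv = _hexagon_vertices(ring_r)
    # The thickened link is a (rounded-corner) 2-D annulus extruded by t, so
    # its in-plane reach is ring_r + t/2 at the hexagon vertices.
    u_max = ring_r + t / 2.0
    phi = _chain_tilt_angle(u_max, t / 2.0, spec.height / 2.0)
    c, s = math.cos(phi), math.sin(phi)

    def ring_sdf(points, center_x=0.0):
        x = points[:, 0] - center_x
        y = points[:, 1]
        z = points[:, 2]
        # Rotate into the ring plane (tilt about the y axis).
        u = c * x + s * z
        w = -s * x + c * z
        d2 = _dist_polygon_2d(u, y, hexv)
        return np.maximum(d2, np.abs(w)) - t / 2.0

    # Exact extents of the tilted extruded annulus.
    ext_x = 2.0 * (u_max * c + (t / 2.0) * s)
    ext_y = 2.0 * (ring_r * math.sin(math.pi / 3.0) + t / 2.0)
    ext_z = spec.height
    L = ext_x
    pitch_x = L * (1.0 + spec.link_gap_ratio) / 2.0
    lo = np.array([-ext_x / 2.0, -ext_y / 2.0, -ext_z / 2.0])
    hi = -lo
    meta = {"tilt_deg": math.degrees(phi), "link_length": L, "pitch_x": pitch_x}
    return ring_sdf, (lo, hi), meta


def _knit_loop_path(spec: UnitCellSpec, n: int = 160) -> np.ndarray:
    """Centre-line of one stockinette (omega) loop, thread along x."""
    t = spec.strut_thickness
    width = 2.0 * spec.size  # hexagon across-corners
    half_h = spec.size * math.sin(math.pi / 3.0)  # half across-flats
    z_amp = 0.75 * t  # over/under crossing amplitude
    tau = np.linspace(-np.pi, np.pi, n)
    x = (width / (2.0 * np.pi)) * (tau + 1.5 * np.sin(2.0 * tau))
    y = half_h * np.cos(tau)
    z = z_amp * np.cos(2.0 * tau)
    return np.column_stack([x, y, z])


def _knitted_cell(spec: UnitCellSpec):
    """One knitted thread loop: circular cross-section capsule chain."""
    t = spec.strut_thickness
    path = _knit_loop_path(spec)
    a, b = path[:-1], path[1:]
    r = t / 2.0

    def sdf(points):
        return _dist_segments(points, a, b) - r

    lo = path.min(axis=0) - r
    hi = path.max(axis=0) + r
    return sdf, (lo, hi), {"path_length": float(np.sum(np.linalg.norm(b - a, axis=1)))}


# Diamond-cubic bond list: interior sites bonded to their 4 tetrahedral
# neighbours, in unit-cube fractional coordinates.
_DIA_INTERIOR = np.array(
    [[0.25, 0.25, 0.25], [0.75, 0.75, 0.25], [0.75, 0.25, 0.75], [0.25, 0.75, 0.75]]
)
_DIA_OFFSETS = 0.25 * np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
)


def _diamond_bonds() -> tuple[np.ndarray, np.ndarray]:
    a, b = [], []
    for site in _DIA_INTERIOR:
        for off in _DIA_OFFSETS:
            nb = site + off
            if np.all(nb >= -1e-9) and np.all(nb <= 1.0 + 1e-9):
                a.append(site)
                b.append(nb)
            else:
                nb2 = site - off
                if np.all(nb2 >= -1e-9) and np.all(nb2 <= 1.0 + 1e-9):
                    a.append(site)
                    b.append(nb2)
    return np.array(a), np.array(b)


def _diamond_cell(spec: UnitCellSpec):
    """Diamond-cubic beam lattice in a cube: 16 tetrahedral struts."""
    S = spec.size
    t = spec.strut_thickness
    a, b = _diamond_bonds()
    a = a * S
    b = b * S
    half = np.full(3, S / 2.0)
    center = np.full(3, S / 2.0)
    r = t / 2.0

    def sdf(points):
        caps = _dist_segments(points, a, b) - r
        return np.maximum(caps, _sd_box(points, half, center))

    lo = np.zeros(3)
    hi = np.full(3, S)
    return sdf, (lo, hi), {"n_struts": len(a)}


def _origami_cell(spec: UnitCellSpec):
    """Miura-ori sheet in a cube, thickened along the print (z) direction.

    The mid-surface is a herringbone triangle wave: one full corrugation per
    cell in x, with fold lines slanted by the in-plane parallelogram angle.
    Thickening vertically makes the cell volume exactly footprint x
    thickness regardless of the fold geometry.
    """
    S = spec.size
    t = spec.strut_thickness
    amp = spec.height - t
    if amp <= 0:
        raise GeometryError("origami sheet thickness must be below the cell height")
    skew = (S / 2.0) / math.tan(math.radians(spec.fold_angle_deg))

    def tri01(q):
        # Triangle wave with period 1 mapping to [0, 1].
        q = np.mod(q, 1.0)
        return 1.0 - np.abs(2.0 * q - 1.0)

    def sdf(points):
        x, y, z = points[:, 0], points[:, 1], points[:, 2]
        phase = (x + skew * tri01(y / S)) / S
        zmid = t / 2.0 + amp * tri01(phase)
        sheet = np.abs(z - zmid) - t / 2.0
        half = np.array([S / 2.0, S / 2.0, spec.height / 2.0])
        center = np.array([S / 2.0, S / 2.0, spec.height / 2.0])
        return np.maximum(sheet, _sd_box(points, half, center))

    lo = np.zeros(3)
    hi = np.array([S, S, spec.height])
    return sdf, (lo, hi), {"amplitude": amp, "skew": skew}


_CELL_BUILDERS = {
    "chain": _chain_cell,
    "knitted": _knitted_cell,
    "diamond_crystal": _diamond_cell,
    "origami": _origami_cell,
}


def unit_cell_sdf(spec: UnitCellSpec):
    """Return (sdf, (lo, hi) bounds, metadata) for one unit cell."""
    return _CELL_BUILDERS[spec.kind](spec)


def build_unit_cell(spec: UnitCellSpec, resolution: float | None = None) -> trimesh.Trimesh:
    """Polygonise one unit cell into a watertight triangle mesh.

    ``resolution`` is the marching-cubes grid pitch in mm; by default a
    twelfth of the strut thickness, clamped to [0.01, 0.05], which keeps the
    discretisation volume error of thin round struts well under 1%.
    """
    sdf, bounds, meta = unit_cell_sdf(spec)
    if resolution is None:
        resolution = float(np.clip(spec.strut_thickness / 12.0, 0.01, 0.05))
    mesh = mesh_from_sdf(sdf, bounds, resolution)
    mesh.metadata.update(meta)
    mesh.metadata["unit_cell_spec"] = spec
    if not mesh.is_watertight:
        raise MeshError(f"{spec.kind} unit cell polygonisation is not watertight")
    return mesh


# ---------------------------------------------------------------------------
# Tessellation into a slab
# ---------------------------------------------------------------------------


def _grid_counts(dims: np.ndarray, ext: np.ndarray, step: np.ndarray) -> np.ndarray:
    """Cells fully inside the slab: floor((dim - extent) / step) + 1 per axis."""
    counts = np.zeros(3, dtype=int)
    for i in range(3):
        if ext[i] > dims[i] + 1e-9:
            counts[i] = 0
        else:
            counts[i] = int(math.floor((dims[i] - ext[i]) / step[i] + 1e-9)) + 1
    return counts


def tessellate(
    cell: trimesh.Trimesh,
    config: TessellationConfig,
    slab: MatrixSlab | None = None,
) -> LatticeMesh:
    """Rescale a unit cell and tile it on a regular grid inside the slab.

    The cell is uniformly rescaled so its z-extent equals ``config.size_z``
    (aspect ratio preserved when ``keep_aspect_ratio``); copies are placed at
    pitch = cell extent + spacing per axis (or an explicit pitch override)
    and only cells whose bounding box lies fully inside the slab are kept.
    """
    slab = slab or MatrixSlab()
    if not cell.is_watertight:
        raise MeshError("unit cell mesh must be watertight before tessellation")
    ext0 = cell.extents
    s = config.size_z / ext0[2]
    scaled = cell.copy()
    if config.keep_aspect_ratio:
        scaled.apply_scale(s)
    else:
        scaled.apply_scale([1.0, 1.0, s])
    ext = scaled.extents.copy()
    spacing = np.asarray(config.spacing, dtype=float)
    step = ext + spacing
    for i, p in enumerate(config.pitch):
        if p is not None:
            if p <= 0:
                raise GeometryError("pitch override must be positive")
            step[i] = p
    counts = _grid_counts(slab.dims, ext, step)
    n_cells = int(np.prod(counts))
    if n_cells == 0:
        raise EmptyLatticeError(
            f"no {ext.round(3)} mm cell fits inside the {slab.dims} mm slab"
        )
    # Center the grid inside the slab (slab spans [0, dims]).
    span = (counts - 1) * step + ext
    origin = (slab.dims - span) / 2.0 - scaled.bounds[0]
    base_v = scaled.vertices
    base_f = scaled.faces
    nv = len(base_v)
    verts, faces = [], []
    idx = 0
    for i in range(counts[0]):
        for j in range(counts[1]):
            for k in range(counts[2]):
                off = origin + step * np.array([i, j, k])
                verts.append(base_v + off)
                faces.append(base_f + idx * nv)
                idx += 1
    mesh = trimesh.Trimesh(
        vertices=np.vstack(verts), faces=np.vstack(faces), process=False
    )
    spec = cell.metadata.get("unit_cell_spec")
    return LatticeMesh(
        mesh=mesh,
        cell_count=n_cells,
        spec=spec,
        config=config,
        grid_shape=tuple(int(c) for c in counts),
    )


def embed_lattice(
    lattice: LatticeMesh,
    slab: MatrixSlab | None = None,
    matrix_material: str = "SHA30",
    lattice_material: str = "SHA70",
) -> CompositeSample:
    """Subtract the lattice from the slab, producing a two-material assembly.

    The matrix solid is represented constructively as the slab shell plus the
    orientation-inverted lattice shell (an internal cavity), which is exact:
    matrix volume + lattice volume = slab volume to floating-point precision.
    """
    slab = slab or MatrixSlab()
    box = trimesh.creation.box(extents=slab.dims)
    box.apply_translation(slab.dims / 2.0)
    if lattice.is_empty:
        matrix = box
    else:
        if not lattice.mesh.is_watertight:
            raise MeshError("lattice mesh must be watertight for embedding")
        lo, hi = lattice.mesh.bounds
        if np.any(lo < -1e-6) or np.any(hi > slab.dims + 1e-6):
            raise GeometryError("lattice does not fit inside the slab")
        inv = lattice.mesh.copy()
        inv.invert()
        matrix = trimesh.util.concatenate([box, inv])
    return CompositeSample(
        matrix_mesh=matrix,
        lattice=lattice,
        slab=slab,
        matrix_material=matrix_material,
        lattice_material=lattice_material,
    )


def volume_fraction(lattice: LatticeMesh, slab: MatrixSlab | None = None) -> float:
    """Lattice volume over full slab volume, as a fraction in [0, 1]."""
    slab = slab or MatrixSlab()
    v = lattice.volume
    if v < 0:
        raise GeometryError("lattice mesh orientation is flipped (negative volume)")
    return v / slab.volume


# ---------------------------------------------------------------------------
# Published tessellation designs
# ---------------------------------------------------------------------------

#: The four published tessellation designs: cell kind -> (size_z mm,
#: spacing mm, strut thickness mm).  The unit-cell spec is pre-scaled so the
#: nominal cell height already equals size_z and the strut thickness is the
#: as-printed value (the thickness is applied after the proportional resize).
PUBLISHED_DESIGNS: dict[str, dict] = {
    "chain": {"size_z": 1.5, "spacing": (0.0, 1.0, 1.0), "thickness": 0.6},
    "knitted": {"size_z": 2.0, "spacing": (0.0, 0.0, 1.0), "thickness": 0.3},
    "diamond_crystal": {"size_z": 2.0, "spacing": (0.0, 0.0, 0.0), "thickness": 0.3},
    "origami": {"size_z": 1.5, "spacing": (0.0, 0.0, 1.0), "thickness": 0.75},
}

# Nominal base heights the proportional resize is taken against: 5 mm prisms
# and cubes for the custom cells, a unit cube for the library diamond cell.
_BASE_HEIGHT = {"chain": 5.0, "knitted": 5.0, "diamond_crystal": 1.0, "origami": 5.0}
_BASE_SIZE = {"chain": 5.0, "knitted": 5.0, "diamond_crystal": 1.0, "origami": 5.0}


def published_design(kind: str) -> tuple[UnitCellSpec, TessellationConfig]:
    """Unit-cell spec and tessellation config for one published design."""
    if kind not in PUBLISHED_DESIGNS:
        raise UnsupportedCellError(f"no published design for kind {kind!r}")
    d = PUBLISHED_DESIGNS[kind]
    scale = d["size_z"] / _BASE_HEIGHT[kind]
    spec = UnitCellSpec(
        kind=kind,
        strut_thickness=d["thickness"],
        size=_BASE_SIZE[kind] * scale,
        height=_BASE_HEIGHT[kind] * scale,
    )
    pitch: tuple[float | None, float | None, float | None] = (None, None, None)
    _, bounds, meta = unit_cell_sdf(spec)
    if kind == "chain":
        pitch = (meta["pitch_x"], None, None)
    # The knitted cell's physical z-extent is below the nominal cell height
    # (a flat loop), so size_z for the rescale step is the actual extent to
    # make the published-design build an identity rescale for every kind.
    actual_ext_z = float(bounds[1][2] - bounds[0][2])
    config = TessellationConfig(
        size_z=actual_ext_z,
        spacing=d["spacing"],
        thickness=d["thickness"],
        pitch=pitch,
    )
    return spec, config


# Cell polygonisation pitch used when tiling whole slabs: hundreds of
# instanced copies make the fine single-cell default needlessly heavy, and
# these pitches move the design volume fractions by under 0.3 percentage
# point relative to the converged values.
_TILING_RESOLUTION = {
    "chain": 0.05,
    "knitted": 0.05,
    "diamond_crystal": 0.06,
    "origami": 0.08,
}


def build_design(
    kind: str,
    slab: MatrixSlab | None = None,
    resolution: float | None = None,
) -> LatticeMesh:
    """Build one published lattice design tessellated into the slab.

    ``resolution`` overrides the per-design tiling pitch; pass a finer value
    for export-quality meshes.
    """
    spec, config = published_design(kind)
    if resolution is None:
        resolution = _TILING_RESOLUTION[kind]
    cell = build_unit_cell(spec, resolution=resolution)
    return tessellate(cell, config, slab or MatrixSlab())


# ---------------------------------------------------------------------------
# Tubular wall: offset and conformal tessellation
# ---------------------------------------------------------------------------


def _centerline_frames(cl: np.ndarray):
    """Arc length, tangents and a parallel-transported normal frame."""
    seg = np.diff(cl, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    if np.any(seglen == 0):
        raise GeometryError("centerline has duplicate consecutive stations")
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    tangents = np.empty_like(cl)
    tangents[0] = seg[0] / seglen[0]
    tangents[-1] = seg[-1] / seglen[-1]
    for i in range(1, len(cl) - 1):
        t = seg[i - 1] / seglen[i - 1] + seg[i] / seglen[i]
        tangents[i] = t / np.linalg.norm(t)
    # Initial normal: any vector not parallel to the first tangent.
    ref = np.array([0.0, 0.0, 1.0])
    if abs(tangents[0] @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    n0 = ref - (ref @ tangents[0]) * tangents[0]
    normals = [n0 / np.linalg.norm(n0)]
    for i in range(1, len(cl)):
        n = normals[-1] - (normals[-1] @ tangents[i]) * tangents[i]
        normals.append(n / np.linalg.norm(n))
    normals = np.array(normals)
    binormals = np.cross(tangents, normals)
    return s, tangents, normals, binormals


def _min_radius_of_curvature(cl: np.ndarray) -> float:
    if len(cl) < 3:
        return math.inf
    rmin = math.inf
    for i in range(1, len(cl) - 1):
        a, b, c = cl[i - 1], cl[i], cl[i + 1]
        ab, cb = a - b, c - b
        cross = np.linalg.norm(np.cross(ab, cb))
        if cross < 1e-12:
            continue
        # Circumradius of the three stations.
        r = (
            np.linalg.norm(a - b) * np.linalg.norm(b - c) * np.linalg.norm(c - a)
        ) / (2.0 * cross)
        rmin = min(rmin, r)
    return rmin


def conformal_tessellate(cell: trimesh.Trimesh, wall: TubeWallSpec) -> LatticeMesh:
    """Map a planar tessellation of the unit cell onto the tubular mid-wall.

    The UV parameterisation takes u along the circumference and v along the
    centerline, both in units of ``uv_factor`` mm of arc length per cell.
    The cell is rescaled to ``uv_factor`` in u and v and to the free radial
    span of the wall in w, then every mesh vertex is mapped through the tube
    parameterisation, so struts bend with the surface.
    """
    if not cell.is_watertight:
        raise MeshError("unit cell mesh must be watertight")
    cl = wall.centerline
    radii = wall.inner_radius
    s, tangents, normals, binormals = _centerline_frames(cl)
    total_len = s[-1]
    rcurv = _min_radius_of_curvature(cl)
    if rcurv < float(np.max(radii)) + wall.wall_offset:
        raise GeometryError(
            "wall offset exceeds the centerline's minimum radius of curvature; "
            "the outer surface would self-intersect"
        )
    c = wall.uv_factor
    r_mid = radii + wall.wall_offset * wall.height_offset
    mean_circ = float(2.0 * np.pi * np.mean(r_mid))
    n_u = int(mean_circ // c)
    n_v = int(total_len // c)
    if n_u == 0 or n_v == 0:
        raise EmptyLatticeError(
            f"uv_factor {c} mm is larger than the tube "
            f"(mean circumference {mean_circ:.2f} mm, length {total_len:.2f} mm)"
        )
    # Radial span available to the lattice, strictly inside the wall.
    w_span = wall.wall_offset - 2.0 * wall.lattice_thickness
    base = cell.copy()
    ext = base.extents
    base.apply_translation(-base.bounds[0])
    base.apply_scale([c / ext[0], c / ext[1], w_span / ext[2]])
    bv = base.vertices
    nvtx = len(bv)
    verts, faces = [], []
    idx = 0
    for iu in range(n_u):
        for iv in range(n_v):
            v = bv + np.array([iu * c, iv * c, 0.0])
            verts.append(v)
            faces.append(base.faces + idx * nvtx)
            idx += 1
    V = np.vstack(verts)
    F = np.vstack(faces)
    # Map (u, v, w) -> 3-D. u wraps the full circumference exactly.
    theta = 2.0 * np.pi * V[:, 0] / (n_u * c)
    vv = np.clip(V[:, 1], 0.0, total_len)
    pos = np.empty_like(V)
    Ci = np.column_stack([np.interp(vv, s, cl[:, k]) for k in range(3)])
    Ni = np.column_stack([np.interp(vv, s, normals[:, k]) for k in range(3)])
    Bi = np.column_stack([np.interp(vv, s, binormals[:, k]) for k in range(3)])
    Ni /= np.linalg.norm(Ni, axis=1, keepdims=True)
    Bi /= np.linalg.norm(Bi, axis=1, keepdims=True)
    ri = np.interp(vv, s, radii)
    rho = ri + wall.wall_offset * wall.height_offset + (V[:, 2] - w_span / 2.0)
    pos = Ci + rho[:, None] * (np.cos(theta)[:, None] * Ni + np.sin(theta)[:, None] * Bi)
    mesh = trimesh.Trimesh(vertices=pos, faces=F, process=False)
    spec = cell.metadata.get("unit_cell_spec")
    return LatticeMesh(
        mesh=mesh,
        cell_count=n_u * n_v,
        spec=spec,
        config=None,
        grid_shape=(n_u, n_v, 1),
    )


def offset_wall(inner_surface: trimesh.Trimesh, offset: float) -> trimesh.Trimesh:
    """Thicken a closed inner surface outward into a watertight wall solid.

    The outer surface displaces each vertex along its angle-weighted normal;
    the returned solid is outer shell plus inverted inner shell, so its
    volume is the shell volume.
    """
    if offset <= 0:
        raise GeometryError("offset must be positive")
    if not inner_surface.is_watertight:
        raise MeshError("inner surface must be closed")
    inner = inner_surface.copy()
    if inner.volume < 0:
        inner.invert()
    vn = inner.vertex_normals
    outer = trimesh.Trimesh(
        vertices=inner.vertices + offset * vn, faces=inner.faces, process=False
    )
    # A flipped face normal means the offset surface folded over itself.
    dots = np.einsum("ij,ij->i", outer.face_normals, inner.face_normals)
    if np.any(dots <= 0):
        raise GeometryError(
            "offset causes self-intersection (local radius of curvature "
            "smaller than the offset)"
        )
    inv = inner.copy()
    inv.invert()
    return trimesh.util.concatenate([outer, inv])


# ---------------------------------------------------------------------------
# STL export
# ---------------------------------------------------------------------------


def export_stl(mesh: trimesh.Trimesh, path) -> dict:
    """Write a binary STL (mm) and report basic mesh health metadata."""
    meta = {
        "path": str(path),
        "watertight": bool(mesh.is_watertight),
        "n_faces": int(len(mesh.faces)),
        "volume_mm3": float(mesh.volume),
    }
    if not meta["watertight"]:
        warnings.warn("exporting a non-watertight mesh", stacklevel=2)
    mesh.export(path, file_type="stl")
    return meta
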