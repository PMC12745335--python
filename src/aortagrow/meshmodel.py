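"""Structured cylindrical parameterization of the aortic wall.

The outer aortic wall is re-sampled onto a cylinder-topology grid of 200
circumferential layers x 50 nodes per layer.  This structured grid is the
common coordinate system of the whole pipeline: local aortic frames
(radial / circumferential / axial), per-layer diameters, region
partitioning, and the solid wall mesh are all derived from it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

N_LAYERS_DEFAULT = 200
N_CIRC_DEFAULT = 50
N_REGIONS_DEFAULT = 50
N_PROXIMAL_REGIONS = 12  # ascending aorta + arch regions; descending = the rest

__all__ = [
    "StructuredSurface",
    "ThicknessSpec",
    "SolidMesh",
    "RegionPartition",
    "parameterize_surface",
    "local_frames",
    "layer_diameters",
    "partition_regions",
    "build_solid_mesh",
    "avg_descending_growth",
    "structured_triangles",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class StructuredSurface:
    """Cylinder-topology resampling of the outer wall.

    Attributes
    ----------
    nodes : ndarray, shape (n_layers, n_circ, 3)
        Node positions in mm.  Layer 0 is the most proximal (inlet) layer.
    layer_centers : ndarray, shape (n_layers, 3)
        Mean of the circumferential nodes of each layer.
    landmark_layer : int
        1-based index of the layer anchored just distal to the left
        subclavian artery; start of the first descending region.
    frames : ndarray or None, shape (n_layers, n_circ, 3, 3)
        Per-node orthonormal triads, rows = (radial, circumferential,
        axial).  Filled by :func:`local_frames`.
    """

    nodes: np.ndarray
    landmark_layer: int = 49
    layer_centers: np.ndarray = field(default=None)  # type: ignore[assignment]
    frames: np.ndarray | None = None
    layer_arclengths: np.ndarray | None = None   # mm along the centerline

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.ndim != 3 or self.nodes.shape[2] != 3:
            raise ValueError("nodes must have shape (n_layers, n_circ, 3)")
        if self.layer_centers is None:
            self.layer_centers = self.nodes.mean(axis=1)
        if not (1 <= self.landmark_layer <= self.n_layers):
            raise ValueError("landmark_layer outside the layer range")

    @property
    def n_layers(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_circ(self) -> int:
        return self.nodes.shape[1]

    def points(self) -> np.ndarray:
        """All nodes as a flat (n_layers*n_circ, 3) array."""
        return self.nodes.reshape(-1, 3)


@dataclass(frozen=True)
class ThicknessSpec:
    """Transmural wall build-up used when extruding the solid mesh (mm).

    In the acute dissection the flap has just separated from the false
    lumen wall, so ``flap + false_lumen_wall == true_lumen_wall``.
    """

    true_lumen_wall: float = 2.0
    false_lumen_wall: float = 1.0
    flap: float = 1.0
    n_hex_layers: int = 4

    def __post_init__(self) -> None:
        for name in ("true_lumen_wall", "false_lumen_wall", "flap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_hex_layers < 1:
            raise ValueError("n_hex_layers must be >= 1")
        if not np.isclose(self.flap + self.false_lumen_wall, self.true_lumen_wall):
            raise ValueError(
                "flap + false_lumen_wall must equal true_lumen_wall "
                "(acute-dissection wall build-up)"
            )


@dataclass
class SolidMesh:
    """Hexahedral wall mesh with material / region labels.

    ``hexes`` follow the usual trilinear node ordering (bottom quad
    counter-clockwise, then top quad).  ``load_facets`` are quads on the
    lumen surfaces ordered so their normal points from the lumen into the
    solid, i.e. along the direction of the pressure force;
    ``facet_lumen`` is 0 for the true and 1 for the false lumen.
    """

    nodes: np.ndarray                 # (N, 3) mm
    hexes: np.ndarray                 # (E, 8) int
    material: np.ndarray              # (E,) str in {"wall", "thrombus"}
    region: np.ndarray                # (E,) str in {"tl_wall","fl_wall","flap","thrombus"}
    load_facets: np.ndarray           # (F, 4) int
    facet_lumen: np.ndarray           # (F,) int, 0 = true lumen, 1 = false lumen
    facet_hint: np.ndarray            # (F, 3) approximate lumen-to-solid direction
    fixed_nodes: np.ndarray           # (K,) int, clamped in all directions
    grid_shape: tuple[int, int] | None = None  # (n_axial, n_circ) of the wall grid

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.hexes)


@dataclass(frozen=True)
class RegionPartition:
    """50 contiguous layer ranges; regions 13..50 are the descending aorta.

    ``starts[k]`` / ``stops[k]`` are 1-based inclusive layer bounds of
    region k+1.
    """

    starts: tuple[int, ...]
    stops: tuple[int, ...]
    landmark_layer: int
    n_layers: int = N_LAYERS_DEFAULT

    def __post_init__(self) -> None:
        if len(self.starts) != len(self.stops):
            raise ValueError("starts and stops differ in length")
        if self.starts[0] != 1 or self.stops[-1] != self.n_layers:
            raise ValueError("regions must tile the full layer range")
        for k in range(len(self.starts)):
            if self.stops[k] < self.starts[k]:
                raise ValueError("empty region")
            if k and self.starts[k] != self.stops[k - 1] + 1:
                raise ValueError("regions must be contiguous and disjoint")

    @property
    def n_regions(self) -> int:
        return len(self.starts)

    @property
    def descending_regions(self) -> range:
        """1-based indices of the descending-aorta regions."""
        return range(N_PROXIMAL_REGIONS + 1, self.n_regions + 1)

    @property
    def n_descending(self) -> int:
        return len(self.descending_regions)

    def layers(self, region: int) -> np.ndarray:
        """0-based layer indices of a 1-based region index."""
        return np.arange(self.starts[region - 1] - 1, self.stops[region - 1])

    def descending_layer_slice(self) -> slice:
        """0-based slice covering all descending layers."""
        return slice(self.landmark_layer - 1, self.n_layers)

    def to_json(self) -> str:
        payload = {
            "convention": "layers and regions are 1-based; bounds inclusive",
            "landmark_layer": self.landmark_layer,
            "n_layers": self.n_layers,
            "regions": {
                str(k + 1): [self.starts[k], self.stops[k]]
                for k in range(self.n_regions)
            },
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# parameterization
# ---------------------------------------------------------------------------

def _section_polyline(vertices: np.ndarray, faces: np.ndarray,
                      origin: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Intersect a triangle mesh with a plane; return unordered segment
    endpoints (2k, 3) of the section loop nearest ``origin``.

    A cutting plane through a curved (e.g. arched) tube can intersect
    the far limb as well; the intersection segments are therefore
    clustered into connected loops and only the loop whose centroid is
    closest to the origin is kept.
    """
    d = (vertices - origin) @ normal
    dv = d[faces]                       # (n_faces, 3) signed distances
    pos = dv > 0
    crossing = ~(pos.all(axis=1) | (~pos).all(axis=1))
    pts = []
    for tri, dist in zip(faces[crossing], dv[crossing]):
        seg = []
        for a, b in ((0, 1), (1, 2), (2, 0)):
            da, db = dist[a], dist[b]
            if (da > 0) != (db > 0):
                t = da / (da - db)
                seg.append(vertices[tri[a]] + t * (vertices[tri[b]] - vertices[tri[a]]))
        if len(seg) == 2:
            pts.append(seg)
    pts = np.asarray(pts, dtype=float)           # (k, 2, 3) segments
    if len(pts) == 0:
        return pts.reshape(0, 3)
    flat = pts.reshape(-1, 3)
    if len(pts) < 3:
        return flat
    # single-linkage clustering of segments into loops
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial import cKDTree

    seg_len = np.linalg.norm(pts[:, 0] - pts[:, 1], axis=1)
    thresh = max(1.5 * float(seg_len.max()), 1e-6)
    tree = cKDTree(flat)
    pairs = tree.query_pairs(thresh, output_type="ndarray")
    k = len(pts)
    # endpoints of the same segment are always linked
    own = np.column_stack([2 * np.arange(k), 2 * np.arange(k) + 1])
    edges = np.vstack([pairs, own])
    adj = coo_matrix((np.ones(len(edges)), (edges[:, 0], edges[:, 1])),
                     shape=(2 * k, 2 * k))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp == 1:
        return flat
    best, best_d = None, np.inf
    for c in range(n_comp):
        sel = labels == c
        if sel.sum() < 6:
            continue
        dist = np.linalg.norm(flat[sel].mean(axis=0) - origin)
        if dist < best_d:
            best, best_d = sel, dist
    return flat[best] if best is not None else flat


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane basis: projection of a fixed global axis.

    The angular origin of the 50 circumferential nodes is the projection
    of the global +x axis onto the cross-section (global +y when the
    section is nearly orthogonal to x)."""
    normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ normal) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ normal) * normal
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return e1, e2


def parameterize_surface(outer, centerline=None, n_layers: int = N_LAYERS_DEFAULT,
                         n_circ: int = N_CIRC_DEFAULT,
                         landmark_arclength: float | None = None) -> StructuredSurface:
    """Resample a tube-topology outer wall onto the structured grid.

    Layer ``j`` lies on the cross-section at the j-th of ``n_layers``
    equally spaced arclengths along the centerline; within each layer the
    50 nodes sit at equally spaced polar angles about the section center.

    Parameters
    ----------
    outer
        Either an ``AortaScene`` (its centerline and outer surface are
        used) or a triangle mesh given as ``(vertices, faces)`` /
        trimesh.Trimesh, in which case ``centerline`` must be supplied as
        an ordered (n, 3) polyline.
    """
    if hasattr(outer, "outer_trimesh"):          # AortaScene
        scene = outer
        mesh = scene.outer_trimesh()
        vertices, faces = mesh.vertices.view(np.ndarray), mesh.faces.view(np.ndarray)
        centerline = scene.centerline
        if landmark_arclength is None:
            landmark_arclength = scene.landmark_arclength
    elif hasattr(outer, "vertices"):
        vertices = np.asarray(outer.vertices, dtype=float)
        faces = np.asarray(outer.faces)
    else:
        vertices, faces = (np.asarray(a) for a in outer)
        vertices = vertices.astype(float)
    if centerline is None:
        raise ValueError("a centerline polyline is required")
    centerline = np.asarray(centerline, dtype=float)
    if len(centerline) < 2:
        raise ValueError("degenerate centerline")

    seg = np.diff(centerline, axis=0)
    s_cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(seg, axis=1))])
    total = s_cum[-1]
    # keep half a layer spacing clear of the end caps
    margin = total / n_layers / 2.0
    s_layers = np.linspace(margin, total - margin, n_layers)

    grid = np.empty((n_layers, n_circ, 3))
    theta = 2.0 * np.pi * np.arange(n_circ) / n_circ
    for j, s in enumerate(s_layers):
        origin = np.array([np.interp(s, s_cum, centerline[:, k]) for k in range(3)])
        k = min(np.searchsorted(s_cum, s, side="right"), len(seg))
        tangent = seg[k - 1] / np.linalg.norm(seg[k - 1])
        pts = _section_polyline(vertices, faces, origin, tangent)
        if len(pts) < 6:
            raise ValueError(f"surface is not tube-topology at arclength {s:.1f} mm")
        e1, e2 = _plane_basis(tangent)
        rel = pts - pts.mean(axis=0)
        ang = np.arctan2(rel @ e2, rel @ e1)
        rad = np.hypot(rel @ e2, rel @ e1)
        order = np.argsort(ang)
        ang_s, rad_s = ang[order], rad[order]
        # periodic interpolation of radius over angle about the section centroid
        ang_ext = np.concatenate([ang_s - 2 * np.pi, ang_s, ang_s + 2 * np.pi])
        rad_ext = np.concatenate([rad_s, rad_s, rad_s])
        wrapped = np.mod(theta + np.pi, 2 * np.pi) - np.pi
        r_t = np.interp(wrapped, ang_ext, rad_ext)
        center = pts.mean(axis=0)
        grid[j] = (center[None, :]
                   + np.outer(r_t * np.cos(theta), e1)
                   + np.outer(r_t * np.sin(theta), e2))

    if landmark_arclength is None:
        landmark_layer = 49
    else:
        landmark_layer = int(np.argmin(np.abs(s_layers - landmark_arclength))) + 1
    structured = StructuredSurface(grid, landmark_layer=landmark_layer,
                                   layer_arclengths=s_layers)
    local_frames(structured)
    return structured


def structured_triangles(structured: StructuredSurface,
                         layer_step: int = 1, circ_step: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate the (optionally decimated) structured grid.

    Returns (vertices, faces); the grid wraps circumferentially, ends are
    open.  Triangles are oriented with outward normals."""
    nodes = structured.nodes[::layer_step, ::circ_step]
    nl, nc = nodes.shape[:2]
    vid = np.arange(nl * nc).reshape(nl, nc)
    quads = []
    for j in range(nl - 1):
        for i in range(nc):
            i2 = (i + 1) % nc
            a, b, c, d = vid[j, i], vid[j, i2], vid[j + 1, i2], vid[j + 1, i]
            quads.append((a, b, c))
            quads.append((a, c, d))
    return nodes.reshape(-1, 3), np.array(quads, dtype=np.int64)


# ---------------------------------------------------------------------------
# local frames / diameters / growth
# ---------------------------------------------------------------------------

def local_frames(structured: StructuredSurface) -> np.ndarray:
    """Per-node right-handed orthonormal (radial, circumferential, axial).

    The axial direction of layer j points to the center of layer j+1 (the
    last layer copies the penultimate one); the radial direction is the
    outward surface normal, and the circumferential direction completes
    the triad by cross products.
    """
    nodes, centers = structured.nodes, structured.layer_centers
    nl, nc = structured.n_layers, structured.n_circ

    ax = np.empty((nl, 3))
    d = np.diff(centers, axis=0)
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("coincident layer centers; degenerate centerline")
    ax[:-1] = d / norms[:, None]
    ax[-1] = ax[-2]

    # surface normal from grid tangents (circumferential wraps)
    t_c = np.roll(nodes, -1, axis=1) - np.roll(nodes, 1, axis=1)
    t_a = np.empty_like(nodes)
    t_a[1:-1] = nodes[2:] - nodes[:-2]
    t_a[0] = nodes[1] - nodes[0]
    t_a[-1] = nodes[-1] - nodes[-2]
    n = np.cross(t_c, t_a)
    n /= np.linalg.norm(n, axis=2, keepdims=True)
    # enforce outward orientation
    out = nodes - centers[:, None, :]
    flip = np.sign(np.einsum("jic,jic->ji", n, out))
    flip[flip == 0] = 1.0
    n *= flip[:, :, None]

    axial = np.broadcast_to(ax[:, None, :], nodes.shape)
    circ = np.cross(axial, n)
    circ /= np.linalg.norm(circ, axis=2, keepdims=True)
    radial = np.cross(circ, axial)

    frames = np.stack([radial, circ, axial], axis=2)  # (nl, nc, 3 vectors, 3)
    structured.frames = frames
    return frames


def layer_diameters(structured: StructuredSurface) -> np.ndarray:
    """Per-layer diameter = 2 x mean node-to-layer-center distance (mm)."""
    d = np.linalg.norm(structured.nodes - structured.layer_centers[:, None, :], axis=2)
    return 2.0 * d.mean(axis=1)


def node_radii(structured: StructuredSurface) -> np.ndarray:
    """Per-node distance to the node's layer center (mm)."""
    return np.linalg.norm(structured.nodes - structured.layer_centers[:, None, :], axis=2)


def avg_descending_growth(base: StructuredSurface, follow: StructuredSurface,
                          years: float) -> float:
    """Spatially averaged diameter growth rate of the descending aorta
    (mm/year): mean descending diameter change divided by the interval."""
    if years <= 0:
        raise ValueError("years must be positive")
    if base.n_layers != follow.n_layers:
        raise ValueError("surfaces must share the layer count")
    lo = base.landmark_layer - 1
    d0 = layer_diameters(base)[lo:]
    d1 = layer_diameters(follow)[lo:]
    return float((d1.mean() - d0.mean()) / years)


# ---------------------------------------------------------------------------
# region partition
# ---------------------------------------------------------------------------

def _rounded_boundaries(lo: int, hi: int, n: int) -> np.ndarray:
    """n+1 integer boundaries tiling [lo, hi] into n near-equal blocks."""
    b = np.rint(np.linspace(lo, hi, n + 1)).astype(int)
    if np.any(np.diff(b) < 1):
        raise ValueError(f"cannot split layers {lo}..{hi - 1} into {n} regions")
    return b


def partition_regions(structured_or_landmark, landmark_layer: int | None = None,
                      n_layers: int = N_LAYERS_DEFAULT,
                      n_regions: int = N_REGIONS_DEFAULT,
                      n_proximal: int = N_PROXIMAL_REGIONS) -> RegionPartition:
    """Partition the layers into 50 near-equal contiguous regions.

    Region ``n_proximal + 1`` (the 13th) starts exactly at the landmark
    layer, so regions 13..50 tile the descending aorta.  With the
    landmark at layer 49 every region contains exactly 4 layers.
    """
    if isinstance(structured_or_landmark, StructuredSurface):
        s = structured_or_landmark
        n_layers = s.n_layers
        if landmark_layer is None:
            landmark_layer = s.landmark_layer
    else:
        if landmark_layer is None:
            landmark_layer = int(structured_or_landmark)
    landmark_layer = int(landmark_layer)
    n_descending = n_regions - n_proximal
    if landmark_layer - 1 < n_proximal:
        raise ValueError("landmark too proximal: fewer layers than proximal regions")
    if n_layers - landmark_layer + 1 < n_descending:
        raise ValueError("landmark too distal: fewer layers than descending regions")

    asc = _rounded_boundaries(1, landmark_layer, n_proximal)
    desc = _rounded_boundaries(landmark_layer, n_layers + 1, n_descending)
    starts = np.concatenate([asc[:-1], desc[:-1]])
    stops = np.concatenate([asc[1:] - 1, desc[1:] - 1])
    return RegionPartition(tuple(int(x) for x in starts),
                           tuple(int(x) for x in stops),
                           landmark_layer=landmark_layer, n_layers=n_layers)


# ---------------------------------------------------------------------------
# solid wall mesh
# ---------------------------------------------------------------------------

def _grid_normals(grid: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Outward per-node averaged normals of an (nl, nc, 3) tube grid."""
    t_c = np.roll(grid, -1, axis=1) - np.roll(grid, 1, axis=1)
    t_a = np.empty_like(grid)
    t_a[1:-1] = grid[2:] - grid[:-2]
    t_a[0] = grid[1] - grid[0]
    t_a[-1] = grid[-1] - grid[-2]
    n = np.cross(t_c, t_a)
    n /= np.linalg.norm(n, axis=2, keepdims=True)
    out = grid - centers[:, None, :]
    flip = np.sign(np.einsum("jic,jic->ji", n, out))
    flip[flip == 0] = 1.0
    return n * flip[:, :, None]


def _hex_block(node_id: np.ndarray) -> np.ndarray:
    """Hexes of a structured (n_axial, n_circ_or_chord, n_trans) id block.

    The second index wraps only if ``node_id`` was built with wrapping
    columns; callers pass an id array whose second axis already includes
    the closing column where needed."""
    na, nc, nt = node_id.shape
    hexes = []
    for j in range(na - 1):
        for i in range(nc - 1):
            for k in range(nt - 1):
                n0 = node_id[j, i, k]
                n1 = node_id[j, i + 1, k]
                n2 = node_id[j + 1, i + 1, k]
                n3 = node_id[j + 1, i, k]
                n4 = node_id[j, i, k + 1]
                n5 = node_id[j, i + 1, k + 1]
                n6 = node_id[j + 1, i + 1, k + 1]
                n7 = node_id[j + 1, i, k + 1]
                hexes.append((n0, n1, n2, n3, n4, n5, n6, n7))
    return np.array(hexes, dtype=np.int64)


def build_solid_mesh(scene, thickness: ThicknessSpec = ThicknessSpec()) -> SolidMesh:
    """Extrude the scene's outer wall (and flap / thrombus) into hexes.

    The reference (image-derived) surface is offset outward by the false
    lumen wall thickness and inward, on the true lumen side, by
    ``true_lumen_wall - false_lumen_wall`` so that the true lumen wall is
    2 mm thick, the false lumen wall 1 mm, and flap + false lumen wall
    add up to the intact wall.  The flap is extruded symmetrically about
    its mid-surface and shares nodes with the wall at the junction
    columns.  Thrombus, when present, is a hex block attached to the
    false-lumen inner wall surface.
    """
    grid = scene.grid                     # (na, nc, 3)
    na, nc = grid.shape[:2]
    centers = grid.mean(axis=1)
    normals = _grid_normals(grid, centers)
    nt = thickness.n_hex_layers + 1

    out_off = thickness.false_lumen_wall
    in_off_tl = thickness.true_lumen_wall - thickness.false_lumen_wall

    # lumen side per wall node: 0 = true, 1 = false (junction columns -> true)
    side = np.zeros((na, nc), dtype=int)
    flap = getattr(scene, "flap", None)
    if flap is not None:
        for j_ax in flap.axial_indices:
            for i in flap.false_side_columns:
                side[j_ax, i] = 1

    inner_off = np.where(side == 1, 0.0, -in_off_tl)
    # local curvature guard: offsets must stay below the section radius
    radii = np.linalg.norm(grid - centers[:, None, :], axis=2)
    if np.any(in_off_tl >= radii):
        bad = np.argwhere(in_off_tl >= radii)[:5]
        raise ValueError(f"inward offset exceeds local radius at grid nodes {bad.tolist()}")

    frac = np.linspace(0.0, 1.0, nt)
    # wall node block: (na, nc, nt, 3)
    offsets = inner_off[:, :, None] + (out_off - inner_off)[:, :, None] * frac[None, None, :]
    wall_nodes = grid[:, :, None, :] + normals[:, :, None, :] * offsets[..., None]
    wall_ids = np.arange(na * nc * nt).reshape(na, nc, nt)

    nodes = [wall_nodes.reshape(-1, 3)]
    next_id = na * nc * nt

    # wall hexes, wrapping circumferentially
    wrap_ids = np.concatenate([wall_ids, wall_ids[:, :1]], axis=1)
    hexes = [_hex_block(wrap_ids)]
    # region label per wall element follows the element's base column side
    el_side = np.concatenate([side, side[:, :1]], axis=1)
    wall_regions = []
    for j in range(na - 1):
        for i in range(nc):
            lab = "fl_wall" if el_side[j, i] == 1 and el_side[j, i + 1] == 1 else "tl_wall"
            wall_regions.extend([lab] * (nt - 1))
    region = [np.array(wall_regions, dtype=object)]
    material = [np.full(len(hexes[0]), "wall", dtype=object)]

    # inner-surface load facets (normal from lumen into the wall = +offset direction)
    load_facets, facet_lumen, facet_hint = [], [], []
    thrombus = getattr(scene, "thrombus", None)
    th_cols = set()
    th_layers = set()
    if thrombus is not None:
        th_cols = set(int(i) for i in thrombus.columns)
        th_layers = set(int(j) for j in thrombus.axial_indices)
    for j in range(na - 1):
        for i in range(nc):
            i2 = (i + 1) % nc
            covered = (j in th_layers and (j + 1) in th_layers
                       and i in th_cols and i2 in th_cols)
            if covered:
                continue    # lumen pressure acts on the thrombus surface there
            quad = (wall_ids[j, i, 0], wall_ids[j, i2, 0],
                    wall_ids[j + 1, i2, 0], wall_ids[j + 1, i, 0])
            lum = 1 if (side[j, i] == 1 and side[j, i2] == 1) else 0
            load_facets.append(quad)
            facet_lumen.append(lum)
            facet_hint.append(normals[j, i])

    # ---- flap ---------------------------------------------------------
    if flap is not None:
        fgrid = flap.points                    # (nf_ax, n_chord, 3) mid-surface
        nfa, nch = fgrid.shape[:2]
        fnorm = flap.normals                   # (nf_ax, n_chord, 3) unit
        half = thickness.flap / 2.0
        # flap thickness is half the true-lumen wall, so half the hex
        # layers keeps the transmural element size uniform and makes the
        # flap-wall junction map onto distinct wall transmural nodes
        nft = max(1, thickness.n_hex_layers // 2) + 1
        ffrac = np.linspace(-half, half, nft)
        flap_nodes = fgrid[:, :, None, :] + fnorm[:, :, None, :] * ffrac[None, None, :, None]
        flap_ids = np.full((nfa, nch, nft), -1, dtype=np.int64)

        # junction columns (chord ends) reuse wall transmural nodes
        for a, j_ax in enumerate(flap.axial_indices):
            for end, col in ((0, flap.column_a), (nch - 1, flap.column_b)):
                wall_off = offsets[j_ax, col]          # (nt,) offsets of wall nodes
                for k, f_off in enumerate(ffrac):
                    k_wall = int(np.argmin(np.abs(wall_off - f_off)))
                    flap_ids[a, end, k] = wall_ids[j_ax, col, k_wall]
        interior = flap_ids < 0
        n_new = int(interior.sum())
        flap_ids[interior] = next_id + np.arange(n_new)
        nodes.append(flap_nodes[interior])
        next_id += n_new

        fhex = _hex_block(flap_ids)
        keep = np.array([flap.face_alive[j, i]
                         for j in range(nfa - 1) for i in range(nch - 1)
                         for _ in range(nft - 1)])
        fhex = fhex[keep]
        hexes.append(fhex)
        region.append(np.full(len(fhex), "flap", dtype=object))
        material.append(np.full(len(fhex), "wall", dtype=object))

        # flap is loaded from both lumens; the sheet at -half faces the
        # true lumen iff the flap normal points toward the false lumen
        for j in range(nfa - 1):
            for i in range(nch - 1):
                if not flap.face_alive[j, i]:
                    continue
                qa = (flap_ids[j, i, 0], flap_ids[j + 1, i, 0],
                      flap_ids[j + 1, i + 1, 0], flap_ids[j, i + 1, 0])
                qb = (flap_ids[j, i, nft - 1], flap_ids[j, i + 1, nft - 1],
                      flap_ids[j + 1, i + 1, nft - 1], flap_ids[j + 1, i, nft - 1])
                # the -half sheet faces the true lumen (flap normal points
                # toward the false lumen): TL pressure pushes along +normal,
                # FL pressure along -normal
                load_facets.append(qa)
                facet_lumen.append(0)
                facet_hint.append(fnorm[j, i])
                load_facets.append(qb)
                facet_lumen.append(1)
                facet_hint.append(-fnorm[j, i])

    # ---- thrombus -----------------------------------------------------
    if thrombus is not None:
        cols = np.asarray(sorted(th_cols))
        lays = np.asarray(sorted(th_layers))
        ntr = thrombus.n_radial + 1
        th_ids = np.full((len(lays), len(cols), ntr), -1, dtype=np.int64)
        th_pts = np.empty((len(lays), len(cols), ntr, 3))
        # transmural index k runs outward (deep/free surface -> wall) so
        # the hex handedness matches the wall elements
        for a, j_ax in enumerate(lays):
            for b, i in enumerate(cols):
                surf = wall_nodes[j_ax, i, 0]          # inner wall node (offset 0, FL side)
                inward = -normals[j_ax, i]
                depth = thrombus.depth(j_ax, i)
                for k in range(ntr):
                    th_pts[a, b, k] = surf + inward * depth * (ntr - 1 - k) / (ntr - 1)
                th_ids[a, b, ntr - 1] = wall_ids[j_ax, i, 0]  # conforming with wall
        interior = th_ids < 0
        n_new = int(interior.sum())
        th_ids[interior] = next_id + np.arange(n_new)
        nodes.append(th_pts[interior])
        next_id += n_new

        thex = _hex_block(th_ids)
        hexes.append(thex)
        region.append(np.full(len(thex), "thrombus", dtype=object))
        material.append(np.full(len(thex), "thrombus", dtype=object))
        # FL pressure loads the free (inner, k = 0) thrombus surface
        for a in range(len(lays) - 1):
            for b in range(len(cols) - 1):
                quad = (th_ids[a, b, 0], th_ids[a, b + 1, 0],
                        th_ids[a + 1, b + 1, 0], th_ids[a + 1, b, 0])
                load_facets.append(quad)
                facet_lumen.append(1)
                facet_hint.append(normals[lays[a], cols[b]])

    all_nodes = np.vstack(nodes)
    all_hexes = np.vstack(hexes)
    all_region = np.concatenate(region)
    all_material = np.concatenate(material)
    fixed = np.concatenate([wall_ids[0].ravel(), wall_ids[-1].ravel()])

    return SolidMesh(
        nodes=all_nodes, hexes=all_hexes,
        material=all_material, region=all_region,
        load_facets=np.array(load_facets, dtype=np.int64),
        facet_lumen=np.array(facet_lumen, dtype=np.int64),
        facet_hint=np.array(facet_hint, dtype=float),
        fixed_nodes=np.unique(fixed),
        grid_shape=(na, nc),
    )
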