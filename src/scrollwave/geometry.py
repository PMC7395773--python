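"""Synthetic labeled cardiac geometries.

Stand-ins for image-derived anatomies: uniform cables/sheets/slabs for
desk-scale propagation studies and an idealized truncated-ellipsoid
biventricle with rule-based fibers.  Meshes carry per-node fiber
vectors, the healthy-volume-fraction field h(x) (0 = infarct core,
1 = healthy, in between = gray zone), transmural layer labels obtained
by Laplace interpolation with an epi:mid:endo thickness ratio of 2:3:3,
anatomical region labels, and per-element gel flags marking solidified
biomaterial injections.

Coordinates are mm; node indices 0-based; axes right-handed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import fem

__all__ = [
    "LabeledMesh",
    "Surface",
    "InjectionPattern",
    "LAYER_NAMES",
    "REGION_NAMES",
    "make_cable",
    "make_sheet",
    "make_slab",
    "make_idealized_biventricle",
    "assign_transmural_layers",
    "make_infarct_map",
    "place_gel_injections",
    "compute_gzr",
]

LAYER_NAMES = ("endo", "mid", "epi")
LAYER_ENDO, LAYER_MID, LAYER_EPI = 0, 1, 2
REGION_NAMES = ("other", "LV", "RV", "EPI", "LVMM")
REGION_CODES = {name: i for i, name in enumerate(REGION_NAMES)}

# Laplace-coordinate thresholds giving epi:mid:endo = 2:3:3
# (phi = 0 on endocardium, 1 on epicardium).
_ENDO_MID_PHI = 3.0 / 8.0
_MID_EPI_PHI = 6.0 / 8.0


@dataclass
class Surface:
    """A set of (dim-1 or dim)-simplices referencing parent-mesh nodes."""

    name: str
    simplices: np.ndarray        # (k, nloc) node indices into the parent mesh
    mesh: "LabeledMesh"

    def areas(self) -> np.ndarray:
        return fem.simplex_volumes(self.mesh.nodes, self.simplices)

    @property
    def node_indices(self) -> np.ndarray:
        return np.unique(self.simplices)


@dataclass
class LabeledMesh:
    """Simplicial mesh with the labels required by the monodomain model."""

    nodes: np.ndarray                 # (n, dim) mm
    elements: np.ndarray              # (m, dim+1) int
    fibers: np.ndarray | None = None  # (n, dim) unit vectors
    h: np.ndarray | None = None       # (n,) in [0, 1]
    layer: np.ndarray | None = None   # (n,) int codes into LAYER_NAMES
    region: np.ndarray | None = None  # (n,) int codes into REGION_NAMES
    gel: np.ndarray | None = None     # (m,) bool per element
    transmural_phi: np.ndarray | None = None  # (n,) Laplace coordinate
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=np.float64)
        if self.nodes.ndim != 2:
            raise ValueError("nodes must be (n, dim)")
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.fibers is None:
            self.fibers = np.zeros_like(self.nodes)
            self.fibers[:, 0] = 1.0
        if self.h is None:
            self.h = np.ones(self.n_nodes)
        if self.layer is None:
            self.layer = np.full(self.n_nodes, LAYER_EPI, dtype=np.int64)
        if self.region is None:
            self.region = np.zeros(self.n_nodes, dtype=np.int64)
        if self.gel is None:
            self.gel = np.zeros(self.n_elements, dtype=bool)
        if np.any((self.h < 0) | (self.h > 1)):
            raise ValueError("h(x) must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def dim(self) -> int:
        return self.nodes.shape[1]

    def element_volumes(self) -> np.ndarray:
        return fem.simplex_volumes(self.nodes, self.elements)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def element_h(self) -> np.ndarray:
        return self.h[self.elements].mean(axis=1)

    def element_layer(self) -> np.ndarray:
        """Layer code per element from the Laplace coordinate at centroids."""
        if self.transmural_phi is None:
            return self.layer[self.elements[:, 0]]
        phi_c = self.transmural_phi[self.elements].mean(axis=1)
        return _phi_to_layer(phi_c)

    def characteristic_spacing(self) -> float:
        """Median edge length of the first few hundred elements."""
        elems = self.elements[: min(500, self.n_elements)]
        x = self.nodes[elems]
        e = x[:, 1:, :] - x[:, :1, :]
        return float(np.median(np.linalg.norm(e, axis=2)))

    def conductive_volume(self) -> float:
        """Total measure of non-gel elements with h > 0."""
        vols = self.element_volumes()
        keep = (~self.gel) & (self.element_h() > 0)
        return float(vols[keep].sum())

    def extract_surface(self, name: str) -> Surface:
        """Named analysis surface (boundary faces in a region, or stored)."""
        if name in self.metadata.get("surfaces", {}):
            return Surface(name, self.metadata["surfaces"][name], self)
        code = REGION_CODES.get(name)
        if code is None:
            raise ValueError(f"unknown surface {name!r}")
        faces = fem.boundary_faces(self.elements)
        on = np.all(self.region[faces] == code, axis=1)
        if not np.any(on):
            raise ValueError(f"surface {name!r} is empty on this mesh")
        return Surface(name, faces[on], self)

    def copy(self) -> "LabeledMesh":
        return LabeledMesh(
            nodes=self.nodes.copy(), elements=self.elements.copy(),
            fibers=None if self.fibers is None else self.fibers.copy(),
            h=None if self.h is None else self.h.copy(),
            layer=None if self.layer is None else self.layer.copy(),
            region=None if self.region is None else self.region.copy(),
            gel=None if self.gel is None else self.gel.copy(),
            transmural_phi=(None if self.transmural_phi is None
                            else self.transmural_phi.copy()),
            metadata=dict(self.metadata),
        )


def _phi_to_layer(phi: np.ndarray) -> np.ndarray:
    layer = np.full(phi.shape, LAYER_MID, dtype=np.int64)
    layer[phi < _ENDO_MID_PHI] = LAYER_ENDO
    layer[phi >= _MID_EPI_PHI] = LAYER_EPI
    return layer


# ---------------------------------------------------------------------------
# Structured fixtures
# ---------------------------------------------------------------------------

def _check_dims(spacing: float, *dims: float) -> None:
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    for L in dims:
        if L <= 0:
            raise ValueError("dimensions must be positive")
        if spacing > L:
            raise ValueError("spacing exceeds a mesh dimension")


def make_cable(length: float, spacing: float = 0.8) -> LabeledMesh:
    """1D cable: segments along x, fibers along the axis, h = 1."""
    _check_dims(spacing, length)
    n = int(round(length / spacing)) + 1
    x = np.linspace(0.0, length, n)[:, None]
    elems = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    return LabeledMesh(nodes=x, elements=elems)


def make_sheet(Lx: float, Ly: float, spacing: float = 0.8) -> LabeledMesh:
    """2D rectangular sheet of right triangles; fibers along +x; h = 1."""
    _check_dims(spacing, Lx, Ly)
    nx = int(round(Lx / spacing)) + 1
    ny = int(round(Ly / spacing)) + 1
    X, Y = np.meshgrid(np.linspace(0, Lx, nx), np.linspace(0, Ly, ny),
                       indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])
    idx = np.arange(nx * ny).reshape(nx, ny)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    tris = np.concatenate([np.column_stack([a, b, c]),
                           np.column_stack([a, c, d])], axis=0)
    mesh = LabeledMesh(nodes=nodes, elements=tris)
    mesh.metadata["grid_shape"] = (nx, ny)
    return mesh


_CUBE_TETS = np.array([
    [0, 1, 3, 7], [0, 1, 7, 5], [0, 5, 7, 4],
    [0, 3, 2, 7], [0, 2, 6, 7], [0, 6, 4, 7],
])


def make_slab(Lx: float, Ly: float, Lz: float, spacing: float = 0.8) -> LabeledMesh:
    """3D slab of tetrahedra (6 per lattice cell); fibers along +x; h = 1."""
    _check_dims(spacing, Lx, Ly, Lz)
    nx = int(round(Lx / spacing)) + 1
    ny = int(round(Ly / spacing)) + 1
    nz = int(round(Lz / spacing)) + 1
    nodes, tets, idx = _lattice_tets(
        np.linspace(0, Lx, nx), np.linspace(0, Ly, ny), np.linspace(0, Lz, nz))
    mesh = LabeledMesh(nodes=nodes, elements=tets)
    mesh.metadata["grid_shape"] = (nx, ny, nz)
    return mesh


def _lattice_tets(xs, ys, zs, keep_cell: Callable | None = None):
    """Tetrahedralize a (masked) structured lattice; returns nodes, tets, index."""
    nx, ny, nz = len(xs), len(ys), len(zs)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    idx = np.arange(nx * ny * nz).reshape(nx, ny, nz)
    corners = [idx[:-1, :-1, :-1], idx[1:, :-1, :-1], idx[:-1, 1:, :-1],
               idx[1:, 1:, :-1], idx[:-1, :-1, 1:], idx[1:, :-1, 1:],
               idx[:-1, 1:, 1:], idx[1:, 1:, 1:]]
    cells = np.stack([c.ravel() for c in corners], axis=1)   # (ncell, 8)
    if keep_cell is not None:
        centers = nodes[cells].mean(axis=1)
        cells = cells[keep_cell(centers)]
    tets = cells[:, _CUBE_TETS].reshape(-1, 4)
    # compact node numbering
    used, inv = np.unique(tets, return_inverse=True)
    tets = inv.reshape(-1, 4)
    return nodes[used], tets, used


# ---------------------------------------------------------------------------
# Idealized biventricle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiventricleParams:
    """Truncated-ellipsoid LV with an attached thinner-walled RV shell.

    Default dimensions are a desk-scale miniature; the construction is
    scale-free.  The base plane is z = 0, the apex points toward -z.
    """

    lv_epi_axes: tuple = (16.0, 16.0, 26.0)
    lv_wall: float = 6.0
    rv_epi_axes: tuple = (22.0, 14.0, 20.0)
    rv_wall: float = 3.0
    rv_offset: tuple = (6.0, 0.0, 0.0)
    base_z: float = 0.0
    fiber_rotation: tuple = (-60.0, 60.0)   # endo -> epi, degrees


def _ellipsoid_val(x: np.ndarray, axes, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    d = (x - np.asarray(center)) / np.asarray(axes)
    return np.sum(d * d, axis=-1) - 1.0


def make_idealized_biventricle(params: BiventricleParams | None = None,
                               spacing: float = 2.0) -> LabeledMesh:
    """Idealized biventricular mesh with rule-based rotating fibers.

    The LV is a truncated thick-walled ellipsoid; the RV a thinner
    partial shell fused to its free wall.  Fibers rotate linearly with
    transmural depth (default -60 deg at endo to +60 deg at epi) in the
    local circumferential-longitudinal frame.  Transmural layers, the
    LVMM mid-surface and region labels (LV / RV / EPI) are assigned.
    """
    p = params or BiventricleParams()
    a, b, c = p.lv_epi_axes
    lv_endo_axes = (a - p.lv_wall, b - p.lv_wall, c - p.lv_wall)
    rv_endo_axes = tuple(max(q - p.rv_wall, 1.0) for q in p.rv_epi_axes)
    if min(lv_endo_axes) <= 0:
        raise ValueError("LV wall thicker than its epicardial axes")
    if p.lv_wall < 3 * spacing or p.rv_wall < 1.5 * spacing:
        raise ValueError(
            "wall too coarse for transmural layering; reduce spacing to "
            f"<= {min(p.lv_wall / 3, p.rv_wall / 1.5):.2f} mm")

    def lv_epi(x):
        return _ellipsoid_val(x, p.lv_epi_axes)

    def lv_endo(x):
        return _ellipsoid_val(x, lv_endo_axes)

    def rv_epi(x):
        return _ellipsoid_val(x, p.rv_epi_axes, p.rv_offset)

    def rv_endo(x):
        return _ellipsoid_val(x, rv_endo_axes, p.rv_offset)

    def in_tissue(x):
        below = x[:, 2] <= p.base_z
        lv = (lv_epi(x) <= 0) & (lv_endo(x) >= 0)
        rv = ((rv_epi(x) <= 0) & (rv_endo(x) >= 0)
              & (lv_endo(x) >= 0) & (x[:, 0] >= 0))
        return below & (lv | rv)

    ext = max(p.lv_epi_axes[0], p.rv_epi_axes[0] + p.rv_offset[0]) + spacing
    eyt = max(p.lv_epi_axes[1], p.rv_epi_axes[1]) + spacing
    ezb = -(max(p.lv_epi_axes[2], p.rv_epi_axes[2] - p.rv_offset[2])) - spacing
    xs = np.arange(-ext, ext + spacing / 2, spacing)
    ys = np.arange(-eyt, eyt + spacing / 2, spacing)
    zs = np.arange(ezb, p.base_z + spacing / 2, spacing)
    nodes, tets, _ = _lattice_tets(xs, ys, zs, keep_cell=in_tissue)
    mesh = LabeledMesh(nodes=nodes, elements=tets)

    # --- boundary classification: endo vs epi via the implicit surfaces
    faces = fem.boundary_faces(tets)
    bnodes = np.unique(faces)
    bx = nodes[bnodes]
    not_base = bx[:, 2] < p.base_z - 0.25 * spacing
    lv_endo_val = lv_endo(bx)
    rv_endo_val = rv_endo(bx)
    is_endo = not_base & ((np.abs(lv_endo_val) < _near_tol(bx, lv_endo_axes, spacing))
                          | ((np.abs(rv_endo_val) < _near_tol(bx, rv_endo_axes, spacing))
                             & (bx[:, 0] >= 0)))
    is_epi = not_base & ~is_endo
    endo_nodes = bnodes[is_endo]
    epi_nodes = bnodes[is_epi]
    mesh.metadata["endo_nodes"] = endo_nodes
    mesh.metadata["epi_nodes"] = epi_nodes

    assign_transmural_layers(mesh, endo_nodes=endo_nodes, epi_nodes=epi_nodes)

    # --- region labels on nodes
    region = np.zeros(mesh.n_nodes, dtype=np.int64)
    near_lv_cavity = np.zeros(mesh.n_nodes, dtype=bool)
    near_lv_cavity[endo_nodes] = np.abs(lv_endo(nodes[endo_nodes])) < \
        np.abs(rv_endo(nodes[endo_nodes]))
    region[endo_nodes] = np.where(near_lv_cavity[endo_nodes],
                                  REGION_CODES["LV"], REGION_CODES["RV"])
    region[epi_nodes] = REGION_CODES["EPI"]
    mesh.region = region

    # --- analysis surfaces: boundary faces split by label + LVMM level set
    surf = {}
    fl = region[faces]
    for name in ("LV", "RV", "EPI"):
        on = np.all(fl == REGION_CODES[name], axis=1)
        if np.any(on):
            surf[name] = faces[on]
    surf["LVMM"] = _lvmm_surface(mesh, lv_epi, p)
    mesh.metadata["surfaces"] = surf

    # --- rule-based fibers
    mesh.fibers = _rule_based_fibers(mesh, p)
    mesh.metadata["biventricle_params"] = p
    return mesh


def _near_tol(x, axes, spacing):
    # implicit-value tolerance equivalent to ~0.9 lattice spacings of distance
    r = np.linalg.norm(x / np.asarray(axes), axis=-1) + 1e-12
    return 2.0 * r * 0.9 * spacing / min(axes)


def _lvmm_surface(mesh: LabeledMesh, lv_epi, p) -> np.ndarray:
    """Faces approximating the central level set of the mid-myocardial layer.

    Takes the interior faces shared by LV-wall element pairs whose
    centroid transmural coordinates straddle the mid-layer centre, i.e.
    a piecewise-planar approximation of the level set lying strictly
    inside the mid-myocardial layer on any mesh resolving it.
    """
    phi = mesh.transmural_phi
    target = 0.5 * (_ENDO_MID_PHI + _MID_EPI_PHI)
    elems = mesh.elements
    phi_c = phi[elems].mean(axis=1)
    cx = mesh.element_centroids()
    in_lv = lv_epi(cx) <= 0
    side = phi_c > target
    # interior faces: build face -> (elem, side) map
    m = elems.shape[0]
    nloc = elems.shape[1]
    all_faces = []
    owners = []
    for drop in range(nloc):
        keep = [k for k in range(nloc) if k != drop]
        all_faces.append(elems[:, keep])
        owners.append(np.arange(m))
    all_faces = np.concatenate(all_faces, axis=0)
    owners = np.concatenate(owners)
    key = np.sort(all_faces, axis=1)
    order = np.lexsort(key.T[::-1])
    key_s = key[order]
    faces_s = all_faces[order]
    owners_s = owners[order]
    dup = np.all(key_s[1:] == key_s[:-1], axis=1)
    i = np.where(dup)[0]
    e1, e2 = owners_s[i], owners_s[i + 1]
    cross = (side[e1] != side[e2]) & in_lv[e1] & in_lv[e2]
    return faces_s[i[cross]]


def _rule_based_fibers(mesh: LabeledMesh, p: BiventricleParams) -> np.ndarray:
    """Linear transmural fiber rotation in the circumferential-longitudinal frame."""
    x = mesh.nodes
    phi = mesh.transmural_phi
    a0, a1 = np.deg2rad(p.fiber_rotation[0]), np.deg2rad(p.fiber_rotation[1])
    alpha = a0 + (a1 - a0) * phi
    # local frame: radial = horizontal direction from the LV long axis
    r_vec = x.copy()
    r_vec[:, 2] = 0.0
    r_norm = np.linalg.norm(r_vec, axis=1, keepdims=True)
    e_r = np.where(r_norm > 1e-9, r_vec / np.maximum(r_norm, 1e-9),
                   np.array([1.0, 0.0, 0.0]))
    z_hat = np.array([0.0, 0.0, 1.0])
    e_c = np.cross(z_hat, e_r)
    e_c /= np.linalg.norm(e_c, axis=1, keepdims=True)
    e_l = np.cross(e_r, e_c)
    e_l /= np.linalg.norm(e_l, axis=1, keepdims=True)
    f = np.cos(alpha)[:, None] * e_c + np.sin(alpha)[:, None] * e_l
    f /= np.linalg.norm(f, axis=1, keepdims=True)
    return f


# ---------------------------------------------------------------------------
# Transmural layering (Laplace interpolation)
# ---------------------------------------------------------------------------

def assign_transmural_layers(mesh: LabeledMesh,
                             endo_nodes: np.ndarray | None = None,
                             epi_nodes: np.ndarray | None = None) -> LabeledMesh:
    """Label endo/mid/epi layers with an epi:mid:endo thickness ratio of 2:3:3.

    Solves Laplace's equation with phi = 0 on the endocardial surface(s)
    and phi = 1 on the epicardium, then thresholds the transmural
    coordinate at 3/8 (endo|mid) and 6/8 (mid|epi).  The boundary node
    sets may be given explicitly; otherwise they are taken from the mesh
    metadata (as stored by the generators).
    """
    if endo_nodes is None:
        endo_nodes = mesh.metadata.get("endo_nodes")
    if epi_nodes is None:
        epi_nodes = mesh.metadata.get("epi_nodes")
    if endo_nodes is None or epi_nodes is None:
        raise ValueError("endocardial/epicardial boundary node sets required")
    endo_nodes = np.asarray(endo_nodes, dtype=np.int64)
    epi_nodes = np.asarray(epi_nodes, dtype=np.int64)
    if endo_nodes.size == 0 or epi_nodes.size == 0:
        raise ValueError("empty endo or epi boundary surface")
    if np.intersect1d(endo_nodes, epi_nodes).size:
        raise ValueError("endo and epi boundary sets overlap (no gradient)")
    dn = np.concatenate([endo_nodes, epi_nodes])
    dv = np.concatenate([np.zeros(endo_nodes.size), np.ones(epi_nodes.size)])
    phi = fem.solve_laplace(mesh.nodes, mesh.elements, dn, dv)
    mesh.transmural_phi = phi
    mesh.layer = _phi_to_layer(phi)
    return mesh


# ---------------------------------------------------------------------------
# Infarct / gray-zone map
# ---------------------------------------------------------------------------

def make_infarct_map(mesh: LabeledMesh,
                     core: Callable[[np.ndarray], np.ndarray] | tuple,
                     gray_zone_width: float) -> np.ndarray:
    """Healthy-volume-fraction field h(x) for an infarct with a gray zone.

    ``core`` is either a callable returning the signed distance to the
    core surface (negative inside) or a tuple ("sphere", center, radius).
    h = 0 inside the core, ramps linearly with distance to 1 across
    ``gray_zone_width``, and is 1 elsewhere.  The mesh's h field is
    updated in place (taking the minimum with any existing infarct).
    """
    if gray_zone_width < 0:
        raise ValueError("gray-zone width must be non-negative")
    if isinstance(core, tuple):
        kind = core[0]
        if kind != "sphere":
            raise ValueError(f"unknown core geometry {kind!r}")
        center = np.asarray(core[1], dtype=np.float64)
        radius = float(core[2])
        def sdist(x):
            return np.linalg.norm(x - center[: x.shape[1]], axis=1) - radius
    else:
        sdist = core
    d = np.asarray(sdist(mesh.nodes), dtype=np.float64)
    if gray_zone_width == 0:
        h = (d > 0).astype(np.float64)
    else:
        h = np.clip(d / gray_zone_width, 0.0, 1.0)
    mesh.h = np.minimum(mesh.h, h)
    return mesh.h


# ---------------------------------------------------------------------------
# Gel injections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InjectionPattern:
    """Clinical-style circumferential injection pattern.

    Defaults mirror the delivery protocol the generator emulates:
    12-14 intra-myocardial injections of 0.3 mL each (here 13), in two
    circumferential rows about 15 mm apart, solidifying into ellipsoids
    elongated along the local fiber direction.
    """

    n_injections: int = 13
    volume_ml: float = 0.3
    rows: int = 2
    spacing_mm: float = 15.0
    aspect: float = 2.0          # long-axis / short-axis of each injectate
    jitter_mm: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_injections < 0:
            raise ValueError("n_injections must be >= 0")
        if self.volume_ml <= 0:
            raise ValueError("volume_ml must be positive")
        if self.rows < 1:
            raise ValueError("rows must be >= 1")

    @property
    def volume_mm3(self) -> float:
        return self.volume_ml * 1000.0

    def semi_axes(self) -> tuple:
        """Ellipsoid semi-axes (long, short, short) from volume and aspect."""
        rb = (3.0 * self.volume_mm3 / (4.0 * np.pi * self.aspect)) ** (1.0 / 3.0)
        return (self.aspect * rb, rb, rb)


def place_gel_injections(mesh: LabeledMesh, pattern: InjectionPattern):
    """Flag gel elements for a circumferential mid-wall injection pattern.

    On the idealized biventricle the injections are centred in the LV
    free-wall mid-layer, in ``rows`` circumferential rows placed above
    and below the mid-ventricular level, with the stated in-row spacing;
    each solidified injectate is an ellipsoid with its long axis along
    the local fiber direction.  On slab/sheet fixtures the rows run
    along x at mid-depth.  Placement is deterministic given the seed.

    Returns ``(mesh, achieved_fraction)`` where the fraction is gel
    volume over the conductive (non-gel, h > 0) tissue volume.
    """
    import warnings

    mesh = mesh.copy()
    if pattern.n_injections == 0:
        return mesh, 0.0
    rng = np.random.default_rng(pattern.seed)
    centers, long_axes = _injection_sites(mesh, pattern, rng)

    ra, rb, _ = pattern.semi_axes()
    cx = mesh.element_centroids()
    gel = np.zeros(mesh.n_elements, dtype=bool)
    placed = 0
    for ctr, ax in zip(centers, long_axes):
        ax = ax / np.linalg.norm(ax)
        rel = cx - ctr[None, : cx.shape[1]]
        t = rel @ ax[: cx.shape[1]]
        perp2 = np.sum(rel * rel, axis=1) - t * t
        inside = (t / ra) ** 2 + perp2 / rb**2 <= 1.0
        if np.any(inside):
            placed += 1
        gel |= inside
    if placed < pattern.n_injections:
        warnings.warn(
            f"only {placed}/{pattern.n_injections} injections intersect the "
            "wall; requested volume not fully achieved", stacklevel=2)
    gel &= mesh.element_h() > 0  # do not convert infarct core to gel
    mesh.gel = gel
    vols = mesh.element_volumes()
    gel_vol = float(vols[gel].sum())
    cond_vol = float(vols[~gel & (mesh.element_h() > 0)].sum())
    frac = gel_vol / cond_vol if cond_vol > 0 else 0.0
    mesh.metadata["gel_fraction"] = frac
    mesh.metadata["gel_pattern"] = pattern
    return mesh, frac


def _injection_sites(mesh: LabeledMesh, pattern: InjectionPattern, rng):
    """Injection centres and long-axis directions for a mesh."""
    p = mesh.metadata.get("biventricle_params")
    n = pattern.n_injections
    per_row = int(np.ceil(n / pattern.rows))
    if p is not None:
        # LV free wall (x < 0 half, away from the RV fusion), mid-wall radius
        a, b, c = p.lv_epi_axes
        wall_mid = 1.0 - 0.5 * p.lv_wall / min(a, b)
        z_mid = -0.45 * c
        dz = pattern.spacing_mm / 2.0
        centers, axes = [], []
        k = 0
        for row in range(pattern.rows):
            z = z_mid + (row - (pattern.rows - 1) / 2.0) * 2 * dz
            # circumferential arc on the free wall
            rr = np.sqrt(max(1.0 - (z / c) ** 2, 0.05))
            radius = wall_mid * rr * min(a, b)
            arc_span = pattern.spacing_mm * (per_row - 1) / max(radius, 1e-6)
            th0 = np.pi - arc_span / 2.0   # centred on -x (free wall)
            for i in range(per_row):
                if k >= n:
                    break
                th = th0 + (i * pattern.spacing_mm / max(radius, 1e-6))
                ctr = np.array([radius * np.cos(th), radius * np.sin(th), z])
                ctr[:2] += rng.normal(0, pattern.jitter_mm, size=2)
                centers.append(ctr)
                axes.append(_local_fiber(mesh, ctr))
                k += 1
        return np.array(centers), np.array(axes)
    # slab / sheet fallback: rows along x at mid-depth
    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    span = hi - lo
    centers, axes = [], []
    k = 0
    for row in range(pattern.rows):
        frac_y = (row + 1) / (pattern.rows + 1)
        for i in range(per_row):
            if k >= n:
                break
            ctr = lo + span * 0.5
            ctr[0] = lo[0] + span[0] * (i + 1) / (per_row + 1)
            if mesh.dim >= 2:
                ctr[1] = lo[1] + span[1] * frac_y
            ctr[: mesh.dim] += rng.normal(0, pattern.jitter_mm, size=mesh.dim)
            centers.append(ctr[: mesh.dim])
            axes.append(_local_fiber(mesh, ctr[: mesh.dim]))
            k += 1
    return np.array(centers), np.array(axes)


def _local_fiber(mesh: LabeledMesh, point: np.ndarray) -> np.ndarray:
    i = int(np.argmin(np.linalg.norm(mesh.nodes - point[None, : mesh.dim], axis=1)))
    f = mesh.fibers[i]
    nrm = np.linalg.norm(f)
    return f / nrm if nrm > 0 else np.eye(mesh.dim)[0]


# ---------------------------------------------------------------------------
# Gray-zone ratio
# ---------------------------------------------------------------------------

def compute_gzr(mesh: LabeledMesh, surface: Surface | str | np.ndarray) -> float:
    """Gray-zone ratio: gray-zone area over total area of a surface.

    A surface simplex counts as gray zone when its mean h lies strictly
    in (0, 1).
    """
    if isinstance(surface, str):
        surface = mesh.extract_surface(surface)
    simplices = surface.simplices if isinstance(surface, Surface) else \
        np.asarray(surface, dtype=np.int64)
    if simplices.size == 0:
        raise ValueError("empty surface")
    areas = fem.simplex_volumes(mesh.nodes, simplices)
    total = float(areas.sum())
    if total <= 0:
        raise ValueError("surface has zero area")
    hmean = mesh.h[simplices].mean(axis=1)
    eps = 1e-12
    gray = (hmean > eps) & (hmean < 1.0 - eps)
    return float(areas[gray].sum() / total)
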