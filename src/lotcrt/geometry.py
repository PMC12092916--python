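"""Idealized biventricular anatomies with fibers, region labels and surface tags.

The generator builds a two-ventricle wall geometry from implicit surfaces: the
LV is a thick truncated-ellipsoid shell, and the RV is a thinner crescent shell
wrapped around the LV's septal side, obtained from a second, laterally offset
ellipsoid pair. The septum is the portion of the LV wall that faces the RV
cavity, so the two ventricles share it naturally and the RV septal endocardium
coincides with the LV "epicardial" level surface of the septal wall.

Meshing strategy: a regular point lattice at the target edge length is snapped
onto the nearest implicit surface (within half a spacing), jittered slightly in
the interior, Delaunay-tessellated, and filtered to tetrahedra whose centroid
lies inside the wall. This gives a deterministic, watertight-in-practice
tetrahedral mesh with clean surface samples at desk scale, without any external
meshing dependency.

Units are mm throughout; conduction velocities elsewhere in the package are in
m/s, and 1 m/s == 1 mm/ms.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import Delaunay, cKDTree

from .errors import FormatError, ParameterError

# region / surface label codes ------------------------------------------------

LV_MYO, RV_MYO, SEPTUM_LV, SEPTUM_RV, SCAR = 0, 1, 2, 3, 4
REGION_NAMES = {LV_MYO: "LV_MYO", RV_MYO: "RV_MYO", SEPTUM_LV: "SEPTUM_LV",
                SEPTUM_RV: "SEPTUM_RV", SCAR: "SCAR"}
REGION_CODES = {v: k for k, v in REGION_NAMES.items()}

LV_ENDO, RV_ENDO_SEPTAL, RV_ENDO_FREE, EPI, BASE = 0, 1, 2, 3, 4
SURFACE_NAMES = {LV_ENDO: "LV_ENDO", RV_ENDO_SEPTAL: "RV_ENDO_SEPTAL",
                 RV_ENDO_FREE: "RV_ENDO_FREE", EPI: "EPI", BASE: "BASE"}
SURFACE_CODES = {v: k for k, v in SURFACE_NAMES.items()}

#: regions attributed to the left ventricle for metric masks
LV_REGIONS = (LV_MYO, SEPTUM_LV)


@dataclass(frozen=True)
class AnatomyParams:
    """Parameters of the idealized biventricular anatomy.

    Lengths are mm. ``lv_length`` and ``lv_radius`` are the endocardial
    long-axis and equatorial semi-axes of the LV ellipsoid; the basal
    truncation plane sits at ``basal_cut_frac * lv_length`` above the
    equator. ``jitter`` is the fractional amplitude of seeded multiplicative
    shape variation used to build cohorts of distinct anatomies.
    """

    lv_length: float = 42.0
    lv_radius: float = 20.0
    lv_wall: float = 9.0
    rv_wall: float = 4.0
    rv_wrap_deg: float = 150.0
    basal_cut_frac: float = 0.8
    edge_length: float = 1.5
    jitter: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for name in ("lv_length", "lv_radius", "lv_wall", "rv_wall",
                     "rv_wrap_deg", "basal_cut_frac", "edge_length"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not (0.0 <= self.jitter <= 0.3):
            raise ParameterError("jitter must lie in [0, 0.3]")
        if self.lv_wall >= self.lv_radius:
            raise ParameterError("lv_wall must be smaller than lv_radius")
        if not (0.0 < self.basal_cut_frac < 1.0):
            raise ParameterError("basal_cut_frac must lie in (0, 1)")


@dataclass
class FiberField:
    """Per-element unit myofibre directions plus the helix-angle rule used."""

    vectors: np.ndarray            # (n_elem, 3)
    endo_angle: float = 60.0       # degrees at transmural depth 0
    epi_angle: float = -60.0       # degrees at transmural depth 1

    @classmethod
    def uniform(cls, mesh: "LabeledMesh", direction) -> "FiberField":
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        return cls(np.tile(d, (mesh.n_elements, 1)), 0.0, 0.0)


@dataclass
class LabeledMesh:
    """Tetrahedral biventricular anatomy with labels and normalized coordinates."""

    vertices: np.ndarray           # (n_vert, 3) mm
    tetrahedra: np.ndarray         # (n_elem, 4) int
    element_region: np.ndarray     # (n_elem,) region code
    boundary_faces: np.ndarray     # (n_face, 3) int, vertex triples
    face_tags: np.ndarray          # (n_face,) surface code
    face_owner: np.ndarray         # (n_face,) owning element index
    apicobasal: np.ndarray         # (n_vert,) in [0, 1], 0 = apex
    transmural: np.ndarray         # (n_vert,) in [0, 1], 0 = endo
    element_volume: np.ndarray     # (n_elem,) mm^3
    meta: dict = field(default_factory=dict)
    # per-element conduction-velocity scale (1 except inside scar regions)
    element_cv_scale: np.ndarray | None = None
    # region labels before any scar overwrote them (for metric masks)
    element_region_pre_scar: np.ndarray | None = None
    _node_to_elem: tuple | None = dataclasses.field(default=None, repr=False)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tetrahedra.shape[0]

    @property
    def element_centroid(self) -> np.ndarray:
        return self.vertices[self.tetrahedra].mean(axis=1)

    @property
    def base_region(self) -> np.ndarray:
        """Region labels ignoring scar relabelling (scar keeps its wall of origin)."""
        if self.element_region_pre_scar is not None:
            return self.element_region_pre_scar
        return self.element_region

    def cv_scale(self) -> np.ndarray:
        if self.element_cv_scale is None:
            return np.ones(self.n_elements)
        return self.element_cv_scale

    def node_to_elements(self):
        """CSR-style (indptr, indices) adjacency from vertices to tetrahedra."""
        if self._node_to_elem is None:
            tets = self.tetrahedra
            order = np.argsort(tets.ravel(), kind="stable")
            elems = np.repeat(np.arange(self.n_elements), 4)[order]
            counts = np.bincount(tets.ravel(), minlength=self.n_vertices)
            indptr = np.concatenate(([0], np.cumsum(counts)))
            self._node_to_elem = (indptr.astype(np.int64), elems.astype(np.int64))
        return self._node_to_elem

    def surface_nodes(self, *tags) -> np.ndarray:
        """Sorted unique vertex indices of boundary faces carrying any of ``tags``."""
        codes = [SURFACE_CODES[t] if isinstance(t, str) else t for t in tags]
        sel = np.isin(self.face_tags, codes)
        return np.unique(self.boundary_faces[sel])

    def copy(self) -> "LabeledMesh":
        return LabeledMesh(
            vertices=self.vertices.copy(),
            tetrahedra=self.tetrahedra.copy(),
            element_region=self.element_region.copy(),
            boundary_faces=self.boundary_faces.copy(),
            face_tags=self.face_tags.copy(),
            face_owner=self.face_owner.copy(),
            apicobasal=self.apicobasal.copy(),
            transmural=self.transmural.copy(),
            element_volume=self.element_volume.copy(),
            meta=dict(self.meta),
            element_cv_scale=None if self.element_cv_scale is None
            else self.element_cv_scale.copy(),
            element_region_pre_scar=None if self.element_region_pre_scar is None
            else self.element_region_pre_scar.copy(),
        )


# implicit-surface helpers ----------------------------------------------------


def _ellipsoid_level(p: np.ndarray, center, semi) -> np.ndarray:
    """Level-set value ((x-c)/a)^2 + ... ; 1 on the surface, <1 inside."""
    q = (p - np.asarray(center)) / np.asarray(semi)
    return np.einsum("ij,ij->i", q, q)


class _ImplicitAnatomy:
    """Effective (jittered) geometry of one anatomy, shared by build steps."""

    def __init__(self, params: AnatomyParams):
        params.validate()
        rng = np.random.default_rng(params.seed)
        j = params.jitter
        f = 1.0 + j * rng.uniform(-1.0, 1.0, size=5)
        self.params = params
        self.c_en = params.lv_length * f[0]
        self.a_en = params.lv_radius * f[1]
        self.t_lv = params.lv_wall * f[2]
        self.t_rv = params.rv_wall * f[3]
        self.wrap = math.radians(params.rv_wrap_deg) * f[4]
        self.rng = rng

        self.a_ep = self.a_en + self.t_lv
        self.c_ep = self.c_en + self.t_lv
        self.z_cut = params.basal_cut_frac * self.c_en
        # RV ellipsoid pair: center offset toward +x, sized so the cavity
        # crescent closes inside the LV epicardium on the far side.
        self.rv_cx = 0.35 * self.a_ep
        cavity_depth = 0.5 * self.a_en
        self.rv_ax = self.a_ep + cavity_depth - self.rv_cx
        self.rv_ay = self.a_ep * math.sin(min(self.wrap / 2.0, math.radians(80.0)))
        self.rv_cz = 0.85 * self.c_en
        self.lv_semi_en = np.array([self.a_en, self.a_en, self.c_en])
        self.lv_semi_ep = np.array([self.a_ep, self.a_ep, self.c_ep])
        self.rv_center = np.array([self.rv_cx, 0.0, 0.0])
        self.rv_semi_en = np.array([self.rv_ax, self.rv_ay, self.rv_cz])
        self.rv_semi_ep = self.rv_semi_en + self.t_rv

    # level sets
    def e_lven(self, p):
        return _ellipsoid_level(p, (0, 0, 0), self.lv_semi_en)

    def e_lvep(self, p):
        return _ellipsoid_level(p, (0, 0, 0), self.lv_semi_ep)

    def e_rven(self, p):
        return _ellipsoid_level(p, self.rv_center, self.rv_semi_en)

    def e_rvep(self, p):
        return _ellipsoid_level(p, self.rv_center, self.rv_semi_ep)

    def in_lv_wall(self, p, tol=0.0):
        return ((self.e_lvep(p) <= 1.0 + tol) & (self.e_lven(p) >= 1.0 - tol)
                & (p[:, 2] <= self.z_cut + tol * self.c_en))

    def in_rv_wall(self, p, tol=0.0):
        return ((self.e_rvep(p) <= 1.0 + tol) & (self.e_rven(p) >= 1.0 - tol)
                & (self.e_lvep(p) >= 1.0 - tol)
                & (p[:, 2] <= self.z_cut + tol * self.c_en))

    def in_solid(self, p, tol=0.0):
        return self.in_lv_wall(p, tol) | self.in_rv_wall(p, tol)

    def in_lv_cavity(self, p):
        return (self.e_lven(p) < 1.0) & (p[:, 2] < self.z_cut)

    def in_rv_cavity(self, p):
        return ((self.e_rven(p) < 1.0) & (self.e_lvep(p) > 1.0)
                & (p[:, 2] < self.z_cut))


def _radial_snap(p, center, semi):
    """Project points radially (about the ellipsoid center) onto its surface."""
    c = np.asarray(center)
    e = _ellipsoid_level(p, c, semi)
    s = 1.0 / np.sqrt(np.maximum(e, 1e-30))
    return c + (p - c) * s[:, None]


def build_idealized_biventricular_mesh(params: AnatomyParams | None = None) -> LabeledMesh:
    """Generate a seeded idealized biventricular tetrahedral mesh.

    Returns a :class:`LabeledMesh` with all region labels populated
    (LV free wall, RV free wall, transmurally split septum), tagged boundary
    faces, apicobasal/transmural normalized coordinates and element volumes.
    Identical parameters (including the seed) give bit-identical meshes.
    """
    params = params or AnatomyParams()
    geo = _ImplicitAnatomy(params)
    h = params.edge_length

    # candidate lattice over the bounding box
    xmin = min(-geo.a_ep, geo.rv_cx - geo.rv_ax - geo.t_rv) - h
    xmax = geo.rv_cx + geo.rv_ax + geo.t_rv + h
    ymax = max(geo.a_ep, geo.rv_ay + geo.t_rv) + h
    zmin, zmax = -geo.c_ep - h, geo.z_cut + h
    xs = np.arange(xmin, xmax + h, h)
    ys = np.arange(-ymax, ymax + h, h)
    zs = np.arange(zmin, zmax + h, h)
    pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)

    # coarse pre-filter: keep points within ~one spacing of the solid
    keep = geo.in_solid(pts, tol=0.0)
    near = np.zeros(len(pts), bool)
    # distance proxies to the five bounding surfaces
    surf_defs = [
        ("lven", (0, 0, 0), geo.lv_semi_en),
        ("lvep", (0, 0, 0), geo.lv_semi_ep),
        ("rven", geo.rv_center, geo.rv_semi_en),
        ("rvep", geo.rv_center, geo.rv_semi_ep),
    ]
    dists = []
    for _, c, semi in surf_defs:
        e = _ellipsoid_level(pts, c, semi)
        r = np.linalg.norm(pts - np.asarray(c), axis=1)
        # approximate distance to the surface along the radial ray
        d = np.abs(1.0 - 1.0 / np.sqrt(np.maximum(e, 1e-30))) * r
        dists.append(d)
    d_base = np.abs(pts[:, 2] - geo.z_cut)
    dists.append(d_base)
    dists = np.stack(dists, axis=1)
    dmin = dists.min(axis=1)
    near = dmin < 0.6 * h
    cand = pts[keep | near]
    dists = dists[keep | near]

    # snap near-surface points onto their nearest surface; jitter the rest
    nearest = np.argmin(dists, axis=1)
    dmin = dists[np.arange(len(cand)), nearest]
    snap = dmin < 0.45 * h
    snapped = cand.copy()
    for k, (_, c, semi) in enumerate(surf_defs):
        sel = snap & (nearest == k)
        if np.any(sel):
            snapped[sel] = _radial_snap(cand[sel], c, semi)
    sel = snap & (nearest == 4)
    snapped[sel, 2] = geo.z_cut
    interior = ~snap & (dmin > 0.55 * h)
    jit = geo.rng.uniform(-0.12 * h, 0.12 * h, size=(int(interior.sum()), 3))
    snapped[interior] += jit

    inside = geo.in_solid(snapped, tol=1e-7)
    points = snapped[inside]

    # merge points that snapped onto (nearly) the same location
    tree = cKDTree(points)
    pairs = tree.query_pairs(0.25 * h, output_type="ndarray")
    drop = np.zeros(len(points), bool)
    if len(pairs):
        drop[np.maximum(pairs[:, 0], pairs[:, 1])] = True
    points = points[~drop]

    tri = Delaunay(points)
    tets = tri.simplices.astype(np.int64)
    cent = points[tets].mean(axis=1)
    keep_t = geo.in_solid(cent, tol=0.0)
    tets = tets[keep_t]

    # positive orientation and degenerate-sliver removal
    v0 = points[tets[:, 0]]
    d1, d2, d3 = (points[tets[:, i]] - v0 for i in (1, 2, 3))
    vol6 = np.einsum("ij,ij->i", np.cross(d1, d2), d3)
    neg = vol6 < 0
    tets[neg, 1], tets[neg, 2] = tets[neg, 2].copy(), tets[neg, 1].copy()
    vol = np.abs(vol6) / 6.0
    ok = vol > 1e-9
    tets, vol = tets[ok], vol[ok]

    # keep the largest connected component
    n = len(points)
    rows = np.concatenate([tets[:, i] for i in (0, 0, 0, 1, 1, 2)])
    cols = np.concatenate([tets[:, j] for j in (1, 2, 3, 2, 3, 3)])
    g = sparse.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    ncomp, labels = sparse.csgraph.connected_components(g, directed=False)
    if ncomp > 1:
        used = labels[tets[:, 0]]
        main = np.bincount(used).argmax()
        sel = used == main
        tets, vol = tets[sel], vol[sel]

    used = np.unique(tets)
    remap = -np.ones(n, np.int64)
    remap[used] = np.arange(len(used))
    points = points[used]
    tets = remap[tets]

    mesh = _label_mesh(points, tets, vol, geo, params)
    return mesh


def _label_mesh(points, tets, vol, geo: _ImplicitAnatomy, params) -> LabeledMesh:
    cent = points[tets].mean(axis=1)

    # regions: LV wall (septal or free) vs RV wall
    in_lv = geo.in_lv_wall(cent, tol=1e-6)
    region = np.where(in_lv, LV_MYO, RV_MYO).astype(np.int32)
    # septal test: push the centroid just beyond the LV epicardial level
    # surface along the ray from the LV long axis; septal if it lands in
    # RV territory (cavity or free wall).
    e = geo.e_lvep(cent)
    s = 1.05 / np.sqrt(np.maximum(e, 1e-30))
    q = cent * s[:, None]
    septal = in_lv & (geo.e_rvep(q) <= 1.0)
    region[septal] = SEPTUM_LV

    faces, face_tags, face_owner = _boundary_faces(points, tets, region, geo,
                                                   params.edge_length)

    apico, trans = _normalized_coords(points, geo)

    mesh = LabeledMesh(
        vertices=points, tetrahedra=tets.astype(np.int32),
        element_region=region, boundary_faces=faces,
        face_tags=face_tags, face_owner=face_owner,
        apicobasal=apico, transmural=trans, element_volume=vol,
        meta={
            "kind": "idealized_biventricular",
            "lv_semi_en": geo.lv_semi_en.tolist(),
            "lv_semi_ep": geo.lv_semi_ep.tolist(),
            "rv_center": geo.rv_center.tolist(),
            "rv_semi_en": geo.rv_semi_en.tolist(),
            "rv_semi_ep": geo.rv_semi_ep.tolist(),
            "z_cut": geo.z_cut,
            "edge_length": params.edge_length,
            "params": dataclasses.asdict(params),
        },
    )
    return split_septum(mesh)


def _boundary_faces(points, tets, region, geo: _ImplicitAnatomy, h):
    f = np.concatenate([tets[:, idx] for idx in
                        ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3))])
    owner = np.tile(np.arange(len(tets)), 4)
    key = np.sort(f, axis=1)
    _, first, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    bidx = first[counts == 1]
    faces = f[bidx]
    owner = owner[bidx]

    fc = points[faces].mean(axis=1)
    # outward normal: away from the owning tet centroid
    n = np.cross(points[faces[:, 1]] - points[faces[:, 0]],
                 points[faces[:, 2]] - points[faces[:, 0]])
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    to_out = fc - points[tets[owner]].mean(axis=1)
    flip = np.einsum("ij,ij->i", n, to_out) < 0
    n[flip] *= -1.0

    probe = fc + 0.35 * h * n
    tags = np.full(len(faces), EPI, np.int32)
    base = (fc[:, 2] > geo.z_cut - 0.3 * h) & (n[:, 2] > 0.5)
    lv_endo = geo.in_lv_cavity(probe)
    rv_endo = geo.in_rv_cavity(probe)
    owner_region = region[owner]
    tags[rv_endo] = np.where(np.isin(owner_region[rv_endo], (SEPTUM_LV, SEPTUM_RV)),
                             RV_ENDO_SEPTAL, RV_ENDO_FREE)
    tags[lv_endo] = LV_ENDO
    tags[base] = BASE
    return faces.astype(np.int32), tags, owner.astype(np.int32)


def _normalized_coords(points, geo: _ImplicitAnatomy):
    z = points[:, 2]
    apico = np.clip((z - (-geo.c_ep)) / (geo.z_cut + geo.c_ep), 0.0, 1.0)

    trans = np.empty(len(points))
    lv_side = geo.e_lvep(points) <= 1.0 + 1e-6
    # LV wall (and septum): fractional radial position between the
    # endocardial and epicardial level surfaces along the ray from the center
    a = np.sqrt(np.maximum(geo.e_lven(points), 1e-30))
    b = np.sqrt(np.maximum(geo.e_lvep(points), 1e-30))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lv = (1.0 - 1.0 / a) / np.maximum(1.0 / b - 1.0 / a, 1e-12)
    a = np.sqrt(np.maximum(geo.e_rven(points), 1e-30))
    b = np.sqrt(np.maximum(geo.e_rvep(points), 1e-30))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_rv = (1.0 - 1.0 / a) / np.maximum(1.0 / b - 1.0 / a, 1e-12)
    trans = np.where(lv_side, t_lv, t_rv)
    return apico, np.clip(trans, 0.0, 1.0)


def split_septum(mesh: LabeledMesh) -> LabeledMesh:
    """Divide septal elements transmurally between the LV and the RV.

    Elements whose centroid transmural coordinate is on the LV side of the
    mid-surface (depth <= 0.5, measured from the LV endocardium) are labelled
    SEPTUM_LV; the rest SEPTUM_RV. The exact mid-surface tie goes to
    SEPTUM_LV. Returns a modified copy; the union of the two labels equals
    the original septum.
    """
    out = mesh.copy()
    sept = np.isin(out.element_region, (SEPTUM_LV, SEPTUM_RV))
    depth = out.transmural[out.tetrahedra].mean(axis=1)
    out.element_region[sept & (depth <= 0.5)] = SEPTUM_LV
    out.element_region[sept & (depth > 0.5)] = SEPTUM_RV
    return out


def assign_fibers(mesh: LabeledMesh, endo_angle: float = 60.0,
                  epi_angle: float = -60.0) -> FiberField:
    """Rule-based transversely-varying fiber field.

    The helix angle interpolates linearly in transmural depth from
    ``endo_angle`` to ``epi_angle``, measured from the local circumferential
    direction toward the local longitudinal (apex-to-base) direction in the
    wall tangent plane. All vectors are unit length.
    """
    if mesh.transmural is None:
        raise ParameterError("mesh lacks transmural coordinates")
    cent = mesh.element_centroid
    depth = mesh.transmural[mesh.tetrahedra].mean(axis=1)
    alpha = np.radians(endo_angle + depth * (epi_angle - endo_angle))

    meta = mesh.meta
    if meta.get("kind") == "idealized_biventricular":
        lv_semi = 0.5 * (np.asarray(meta["lv_semi_en"]) + np.asarray(meta["lv_semi_ep"]))
        rv_semi = 0.5 * (np.asarray(meta["rv_semi_en"]) + np.asarray(meta["rv_semi_ep"]))
        rv_c = np.asarray(meta["rv_center"])
        is_rv = mesh.base_region == RV_MYO
        centers = np.where(is_rv[:, None], rv_c, 0.0)
        semis = np.where(is_rv[:, None], rv_semi, lv_semi)
        nrm = (cent - centers) / semis**2
    else:
        # fallback for external meshes without stored implicit geometry:
        # radial direction from the z long axis
        nrm = cent.copy()
        nrm[:, 2] = 0.0
    bad = np.linalg.norm(nrm, axis=1) < 1e-9
    nrm[bad] = [1.0, 0.0, 0.0]
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)

    zhat = np.array([0.0, 0.0, 1.0])
    e_l = zhat - nrm * nrm[:, 2][:, None]
    deg = np.linalg.norm(e_l, axis=1) < 1e-9
    e_l[deg] = np.cross(nrm[deg], np.array([0.0, 1.0, 0.0]))
    e_l /= np.linalg.norm(e_l, axis=1, keepdims=True)
    e_c = np.cross(e_l, nrm)
    e_c /= np.linalg.norm(e_c, axis=1, keepdims=True)

    f = np.cos(alpha)[:, None] * e_c + np.sin(alpha)[:, None] * e_l
    f /= np.linalg.norm(f, axis=1, keepdims=True)
    return FiberField(f, endo_angle, epi_angle)


def valve_exclusion_mask(mesh: LabeledMesh, basal_cut: float = 0.9) -> np.ndarray:
    """Boolean element mask of the basal band excluded around the valves.

    True for elements whose centroid apicobasal coordinate exceeds
    ``basal_cut``; metric computations drop masked elements.
    """
    if not (0.0 < basal_cut < 1.0):
        raise ParameterError("basal_cut must lie in (0, 1)")
    apico = mesh.apicobasal[mesh.tetrahedra].mean(axis=1)
    return apico > basal_cut


def extract_epicardial_surface(mesh: LabeledMesh):
    """EPI triangle surface with a map from surface nodes to volume nodes.

    Returns ``(faces_local, node_map, coords)`` where ``faces_local`` indexes
    into ``node_map`` and ``node_map[i]`` is the volume vertex of surface
    node ``i``, so any nodal activation map restricts to the surface as
    ``lat[node_map]``.
    """
    sel = mesh.face_tags == EPI
    if not np.any(sel):
        raise FormatError("mesh has no EPI-tagged boundary faces")
    faces = mesh.boundary_faces[sel]
    node_map = np.unique(faces)
    remap = -np.ones(mesh.n_vertices, np.int64)
    remap[node_map] = np.arange(len(node_map))
    return remap[faces], node_map, mesh.vertices[node_map]


def build_slab_mesh(lx: float, ly: float, lz: float, h: float) -> LabeledMesh:
    """Structured rectangular tetrahedral slab for solver verification.

    Each lattice cube is split into six tetrahedra. All elements are
    labelled LV_MYO and all boundary faces EPI; normalized coordinates are
    zero so no valve exclusion applies.
    """
    nx, ny, nz = (max(1, round(l / h)) for l in (lx, ly, lz))
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    c = [nid(i + di, j + dj, k + dk).ravel()
         for di, dj, dk in ((0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
                            (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1))]
    # Kuhn subdivision of the cube into 6 tets around the main diagonal 0-7
    kuhn = [(0, 1, 3, 7), (0, 3, 2, 7), (0, 2, 6, 7),
            (0, 6, 4, 7), (0, 4, 5, 7), (0, 5, 1, 7)]
    tets = np.concatenate([np.stack([c[a], c[b], c[d], c[e]], axis=1)
                           for a, b, d, e in kuhn])

    v0 = pts[tets[:, 0]]
    d1, d2, d3 = (pts[tets[:, i]] - v0 for i in (1, 2, 3))
    vol6 = np.einsum("ij,ij->i", np.cross(d1, d2), d3)
    neg = vol6 < 0
    tets[neg, 1], tets[neg, 2] = tets[neg, 2].copy(), tets[neg, 1].copy()
    vol = np.abs(vol6) / 6.0

    f = np.concatenate([tets[:, idx] for idx in
                        ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3))])
    owner = np.tile(np.arange(len(tets)), 4)
    key = np.sort(f, axis=1)
    _, first, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    bidx = first[counts == 1]

    n = len(pts)
    return LabeledMesh(
        vertices=pts, tetrahedra=tets.astype(np.int32),
        element_region=np.full(len(tets), LV_MYO, np.int32),
        boundary_faces=f[bidx].astype(np.int32),
        face_tags=np.full(len(bidx), EPI, np.int32),
        face_owner=owner[bidx].astype(np.int32),
        apicobasal=np.zeros(n), transmural=np.zeros(n),
        element_volume=vol, meta={"kind": "slab", "extent": (lx, ly, lz),
                                  "edge_length": h},
    )
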