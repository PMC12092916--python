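"""His-Purkinje network generation, fascicle CV calibration, PMJs, block.

The conduction system is built directly on the mesh's endocardial surfaces:
the His trunk descends from above the basal septum, bifurcates into left and
right bundles, and each bundle feeds its fascicles — three in the LV
(anterior, posterior, septal) and two in the RV (septal and moderator band,
the latter crossing the cavity to the free wall). Distal to each fascicle
terminus a Purkinje arborization grows as the union of geodesic
(surface-graph shortest-path) branches to seeded junction sites, which keeps
the network a tree by construction and makes it reproducible under a fixed
seed. Every terminal couples to the myocardium through a PMJ with
anterograde and retrograde junction delays.

Fascicle CVs are calibrated in closed form so that a sinus beat reaches the
end of all three LV fascicles simultaneously and a fixed offset (default
10 ms) before the two RV fascicle ends, anchoring the common LV target time
at the latest unconstrained LV arrival so no calibrated CV exceeds the trunk
CV.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .errors import CalibrationError, ParameterError
from . import geometry as G
from .geometry import LabeledMesh

# edge classes
HIS, LEFT_BUNDLE, RIGHT_BUNDLE, FASCICLE, PURKINJE = 0, 1, 2, 3, 4
CLASS_NAMES = {HIS: "HIS", LEFT_BUNDLE: "LEFT_BUNDLE", RIGHT_BUNDLE: "RIGHT_BUNDLE",
               FASCICLE: "FASCICLE", PURKINJE: "PURKINJE"}

# fascicle labels
NONE, LV_ANT, LV_POST, LV_SEPT, RV_SEPT, RV_MOD_BAND = -1, 0, 1, 2, 3, 4
FASCICLE_NAMES = {NONE: "NONE", LV_ANT: "LV_ANT", LV_POST: "LV_POST",
                  LV_SEPT: "LV_SEPT", RV_SEPT: "RV_SEPT",
                  RV_MOD_BAND: "RV_MOD_BAND"}
LV_FASCICLE_LABELS = (LV_ANT, LV_POST, LV_SEPT)
RV_FASCICLE_LABELS = (RV_SEPT, RV_MOD_BAND)


@dataclass(frozen=True)
class TreeParams:
    """Generation parameters of the His-Purkinje network.

    ``pmj_density`` is the target number of Purkinje terminals per cm^2 of
    endocardium; ``max_apicobasal`` bounds the Purkinje-covered territory
    (the basal band above it is Purkinje-free). Identical params + seed
    reproduce the tree exactly.
    """

    pmj_density: float = 1.5          # terminals per cm^2
    left_bundle_length: float = 25.0  # mm of left bundle along the septum
    his_length: float = 8.0           # mm of trunk above the septal entry
    max_apicobasal: float = 0.7
    pmj_anterograde_ms: float = 10.0
    pmj_retrograde_ms: float = 5.0
    seed: int = 0

    def validate(self):
        if self.pmj_density <= 0:
            raise ParameterError("pmj_density must be positive")
        if not (0 < self.max_apicobasal <= 1):
            raise ParameterError("max_apicobasal must lie in (0, 1]")


@dataclass
class PurkinjeTree:
    """1-D conduction network rooted at the His."""

    nodes: np.ndarray               # (n, 3) mm
    edge_a: np.ndarray              # (m,) int
    edge_b: np.ndarray              # (m,) int
    edge_class: np.ndarray          # (m,) class code
    edge_fascicle: np.ndarray       # (m,) fascicle label (NONE allowed)
    conductive: np.ndarray          # (m,) bool
    his_root: int
    fascicle_end_nodes: dict        # label -> node index
    pmj_tree_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    pmj_mesh_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    pmj_anterograde: np.ndarray = field(default_factory=lambda: np.empty(0))
    pmj_retrograde: np.ndarray = field(default_factory=lambda: np.empty(0))
    node_mesh_vertex: np.ndarray | None = None   # tree node -> mesh vertex (-1)
    block_edge: int | None = None
    hbp_node: int | None = None
    lbbp_node: int | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_a.shape[0]

    @property
    def edge_length(self) -> np.ndarray:
        return np.linalg.norm(self.nodes[self.edge_a] - self.nodes[self.edge_b],
                              axis=1)

    def copy(self) -> "PurkinjeTree":
        return dataclasses.replace(
            self, nodes=self.nodes.copy(), edge_a=self.edge_a.copy(),
            edge_b=self.edge_b.copy(), edge_class=self.edge_class.copy(),
            edge_fascicle=self.edge_fascicle.copy(),
            conductive=self.conductive.copy(),
            fascicle_end_nodes=dict(self.fascicle_end_nodes),
            pmj_tree_nodes=self.pmj_tree_nodes.copy(),
            pmj_mesh_nodes=self.pmj_mesh_nodes.copy(),
            pmj_anterograde=self.pmj_anterograde.copy(),
            pmj_retrograde=self.pmj_retrograde.copy(),
            node_mesh_vertex=None if self.node_mesh_vertex is None
            else self.node_mesh_vertex.copy())

    def parents(self, ignore_conductive: bool = True) -> np.ndarray:
        """Parent of each node in the tree rooted at his_root (-1 at the root)."""
        n = self.n_nodes
        keep = slice(None) if ignore_conductive else self.conductive
        rows = np.concatenate([self.edge_a[keep], self.edge_b[keep]])
        cols = np.concatenate([self.edge_b[keep], self.edge_a[keep]])
        g = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        order, pred = sparse.csgraph.breadth_first_order(
            g, self.his_root, directed=False, return_predecessors=True)
        parent = np.full(n, -1, np.int64)
        parent[order] = pred[order]
        parent[self.his_root] = -1
        return parent

    def path_to_root(self, node: int) -> list:
        parent = self.parents()
        path = [node]
        while parent[path[-1]] >= 0:
            path.append(int(parent[path[-1]]))
        return path[::-1]

    def terminals(self) -> np.ndarray:
        """Leaf nodes of the conduction tree (degree-1, excluding the root)."""
        deg = np.bincount(np.concatenate([self.edge_a, self.edge_b]),
                          minlength=self.n_nodes)
        leaves = np.flatnonzero(deg == 1)
        return leaves[leaves != self.his_root]


class _TreeBuilder:
    def __init__(self):
        self.coords: list = []
        self.mesh_of: list = []
        self.tree_of_mesh: dict = {}
        self.ea: list = []
        self.eb: list = []
        self.ecls: list = []
        self.efas: list = []

    def add_free_node(self, p) -> int:
        self.coords.append(np.asarray(p, float))
        self.mesh_of.append(-1)
        return len(self.coords) - 1

    def node_for(self, mesh_v: int, verts) -> int:
        if mesh_v not in self.tree_of_mesh:
            self.coords.append(verts[mesh_v].astype(float))
            self.mesh_of.append(int(mesh_v))
            self.tree_of_mesh[mesh_v] = len(self.coords) - 1
        return self.tree_of_mesh[mesh_v]

    def add_edge(self, a, b, cls, fas):
        self.ea.append(a)
        self.eb.append(b)
        self.ecls.append(cls)
        self.efas.append(fas)

    def add_surface_path(self, mesh_path, verts, cls_of_edge):
        """Graft a mesh-vertex path (root side first) onto the tree.

        ``cls_of_edge(i)`` gives (class, fascicle) for the edge between
        mesh_path[i] and mesh_path[i+1]. The path is walked leaf-to-root and
        stops at the first node already present, so each new node acquires
        exactly one parent and the graph stays a tree. A path whose leaf is
        already in the tree adds nothing."""
        if mesh_path[-1] in self.tree_of_mesh:
            return
        for i in range(len(mesh_path) - 1, 0, -1):
            up_mesh, leaf_mesh = mesh_path[i - 1], mesh_path[i]
            attach = up_mesh in self.tree_of_mesh
            a = self.node_for(up_mesh, verts)
            bnode = self.node_for(leaf_mesh, verts)
            cls, fas = cls_of_edge(i - 1)
            self.add_edge(a, bnode, cls, fas)
            if attach:
                break


def _surface_graph(mesh: LabeledMesh, tags):
    faces = mesh.boundary_faces[np.isin(mesh.face_tags,
                                        [G.SURFACE_CODES[t] for t in tags])]
    e = np.concatenate([faces[:, (0, 1)], faces[:, (0, 2)], faces[:, (1, 2)]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    n = mesh.n_vertices
    g = sparse.csr_matrix(
        (np.concatenate([w, w]),
         (np.concatenate([e[:, 0], e[:, 1]]), np.concatenate([e[:, 1], e[:, 0]]))),
        shape=(n, n))
    return g, np.unique(faces), faces


def _walk_pred(pred, start):
    path = [start]
    while pred[path[-1]] >= 0:
        path.append(int(pred[path[-1]]))
    return path[::-1]


def _analytic_lv_endo_point(mesh, phi_deg, apico):
    a, _, c = mesh.meta["lv_semi_en"]
    z_cut = mesh.meta["z_cut"]
    c_ep = mesh.meta["lv_semi_ep"][2]
    z = apico * (z_cut + c_ep) - c_ep
    r = a * math.sqrt(max(0.0, 1.0 - (z / c) ** 2))
    phi = math.radians(phi_deg)
    return np.array([r * math.cos(phi), r * math.sin(phi), z])


def generate_his_purkinje(mesh: LabeledMesh,
                          params: TreeParams | None = None) -> PurkinjeTree:
    """Generate the five-fascicle His-Purkinje tree on a labelled mesh."""
    params = params or TreeParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    verts = mesh.vertices

    g_lv, lv_nodes, lv_faces = _surface_graph(mesh, ["LV_ENDO"])
    g_rvs, rvs_nodes, rvs_faces = _surface_graph(mesh, ["RV_ENDO_SEPTAL"])
    g_rvf, rvf_nodes, rvf_faces = _surface_graph(mesh, ["RV_ENDO_FREE"])
    if len(lv_nodes) < 10 or len(rvs_nodes) < 10 or len(rvf_nodes) < 10:
        raise ParameterError("endocardial surfaces too small to host the tree")

    b = _TreeBuilder()

    # --- trunk and bundles ---------------------------------------------------
    phi = np.degrees(np.arctan2(verts[:, 1], verts[:, 0]))
    septal_lv = lv_nodes[np.abs(phi[lv_nodes]) < 30.0]
    if len(septal_lv) == 0:
        septal_lv = lv_nodes
    entry = int(septal_lv[np.argmax(verts[septal_lv, 2])])

    his_root = b.add_free_node(verts[entry] + [0.0, 0.0, params.his_length])
    bif = b.add_free_node(verts[entry] + [0.0, 0.0, params.his_length / 2.0])
    b.add_edge(his_root, bif, HIS, NONE)

    # left bundle: from the bifurcation onto the LV septal endocardium and
    # down toward the apex along the septum
    entry_t = b.node_for(entry, verts)
    b.add_edge(bif, entry_t, LEFT_BUNDLE, NONE)     # the proximal block site
    block_edge = len(b.ea) - 1

    dist_lv, pred_lv = dijkstra(g_lv, indices=entry, return_predecessors=True)
    septal_mask = np.abs(phi) < 35.0
    cand = lv_nodes[septal_mask[lv_nodes] & np.isfinite(dist_lv[lv_nodes])]
    lb_end = int(cand[np.argmin(np.abs(dist_lv[cand] - params.left_bundle_length))])
    lb_path = _walk_pred(pred_lv, lb_end)
    b.add_surface_path(lb_path, verts, lambda i: (LEFT_BUNDLE, NONE))
    lbbp_node = b.node_for(lb_end, verts)
    hbp_node = entry_t

    # right bundle: chord through the septum, then down the RV septal surface
    kd_rvs = cKDTree(verts[rvs_nodes])
    _, i0 = kd_rvs.query(b.coords[bif])
    rb_entry = int(rvs_nodes[i0])
    rb_entry_t = b.node_for(rb_entry, verts)
    b.add_edge(bif, rb_entry_t, RIGHT_BUNDLE, NONE)

    dist_rvs, pred_rvs = dijkstra(g_rvs, indices=rb_entry,
                                  return_predecessors=True)
    fin = rvs_nodes[np.isfinite(dist_rvs[rvs_nodes])]
    rvsept_target = int(fin[np.argmin(
        np.abs(mesh.apicobasal[fin] - 0.20) + 0.01 * np.abs(phi[fin]) / 180.0)])
    rvs_path = _walk_pred(pred_rvs, rvsept_target)
    # proximal 40% of the path is right bundle, the rest the RV septal fascicle
    cut = max(1, int(0.4 * (len(rvs_path) - 1)))
    b.add_surface_path(rvs_path, verts,
                       lambda i: (RIGHT_BUNDLE, NONE) if i < cut
                       else (FASCICLE, RV_SEPT))
    rb_end = int(rvs_path[cut])

    # --- LV fascicles: geodesic paths from the left-bundle terminus ----------
    dist_f, pred_f = dijkstra(g_lv, indices=lb_end, return_predecessors=True)
    targets = {}
    for label, phi_t, apico_t in ((LV_ANT, 110.0, 0.5), (LV_POST, -110.0, 0.5),
                                  (LV_SEPT, 0.0, 0.25)):
        if mesh.meta.get("kind") == "idealized_biventricular":
            p_t = _analytic_lv_endo_point(mesh, phi_t, apico_t)
        else:
            p_t = verts[lv_nodes].mean(axis=0)
        fin = lv_nodes[np.isfinite(dist_f[lv_nodes])]
        targets[label] = int(fin[np.argmin(
            np.linalg.norm(verts[fin] - p_t, axis=1))])

    paths = {label: _walk_pred(pred_f, t) for label, t in targets.items()}
    edge_count: dict = {}
    for path in paths.values():
        for i in range(len(path) - 1):
            k = (min(path[i], path[i + 1]), max(path[i], path[i + 1]))
            edge_count[k] = edge_count.get(k, 0) + 1
    for label, path in paths.items():
        def cls(i, path=path, label=label):
            k = (min(path[i], path[i + 1]), max(path[i], path[i + 1]))
            return ((LEFT_BUNDLE, NONE) if edge_count[k] > 1
                    else (FASCICLE, label))
        b.add_surface_path(path, verts, cls)

    # --- moderator band: cavity chord from the right-bundle end --------------
    z_rb = verts[rvs_path[cut], 2]
    band = rvf_nodes[np.abs(verts[rvf_nodes, 2] - z_rb) < 10.0]
    if len(band) == 0:
        band = rvf_nodes
    if mesh.meta.get("kind") == "idealized_biventricular":
        rc = np.asarray(mesh.meta["rv_center"])
        rs = np.asarray(mesh.meta["rv_semi_en"])
        zz = np.clip(z_rb, -0.9 * rs[2], 0.9 * rs[2])
        p_t = rc + [rs[0] * math.sqrt(max(0.0, 1 - (zz / rs[2]) ** 2)), 0.0, zz]
    else:
        p_t = verts[band].mean(axis=0)
    mod_end = int(band[np.argmin(np.linalg.norm(verts[band] - p_t, axis=1))])
    rb_end_t = b.node_for(rvs_path[cut], verts)
    mod_end_t = b.node_for(mod_end, verts)
    b.add_edge(rb_end_t, mod_end_t, FASCICLE, RV_MOD_BAND)

    fascicle_ends = {LV_ANT: b.node_for(targets[LV_ANT], verts),
                     LV_POST: b.node_for(targets[LV_POST], verts),
                     LV_SEPT: b.node_for(targets[LV_SEPT], verts),
                     RV_SEPT: b.node_for(rvsept_target, verts),
                     RV_MOD_BAND: mod_end_t}

    # --- Purkinje arborization ------------------------------------------------
    def face_area(faces):
        p = verts[faces]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)

    def arborize(graph, surf_nodes, faces, sources_mesh, labels):
        area_cm2 = face_area(faces).sum() / 100.0
        eligible = surf_nodes[mesh.apicobasal[surf_nodes] < params.max_apicobasal]
        dist, pred, src_idx = dijkstra(
            graph, indices=sources_mesh, return_predecessors=True,
            min_only=True)
        eligible = eligible[np.isfinite(dist[eligible])]
        k = min(len(eligible), max(1, round(params.pmj_density * area_cm2)))
        sites = rng.choice(eligible, size=k, replace=False)
        for s in np.sort(sites):
            path = _walk_pred(pred, int(s))
            label = labels[int(np.flatnonzero(
                np.asarray(sources_mesh) == src_idx[s])[0])]
            b.add_surface_path(path, verts,
                               lambda i, label=label: (PURKINJE, label))

    arborize(g_lv, lv_nodes, lv_faces,
             [targets[LV_ANT], targets[LV_POST], targets[LV_SEPT]],
             [LV_ANT, LV_POST, LV_SEPT])
    arborize(g_rvs, rvs_nodes, rvs_faces, [rvsept_target], [RV_SEPT])
    arborize(g_rvf, rvf_nodes, rvf_faces, [mod_end], [RV_MOD_BAND])

    tree = PurkinjeTree(
        nodes=np.asarray(b.coords), edge_a=np.asarray(b.ea, np.int64),
        edge_b=np.asarray(b.eb, np.int64),
        edge_class=np.asarray(b.ecls, np.int32),
        edge_fascicle=np.asarray(b.efas, np.int32),
        conductive=np.ones(len(b.ea), bool),
        his_root=his_root, fascicle_end_nodes=fascicle_ends,
        node_mesh_vertex=np.asarray(b.mesh_of, np.int64),
        block_edge=block_edge, hbp_node=hbp_node, lbbp_node=lbbp_node)
    return place_pmjs(tree, mesh,
                      anterograde_ms=params.pmj_anterograde_ms,
                      retrograde_ms=params.pmj_retrograde_ms)


def place_pmjs(tree: PurkinjeTree, mesh: LabeledMesh,
               anterograde_ms: float = 10.0, retrograde_ms: float = 5.0,
               max_distance_mm: float = 3.0) -> PurkinjeTree:
    """Pair every Purkinje terminal with its nearest endocardial mesh node.

    Terminals are the leaves of the tree plus the fascicle end nodes. Raises
    if a terminal sits farther than ``max_distance_mm`` from the endocardium.
    Returns a modified copy with the PMJ table filled in.
    """
    out = tree.copy()
    term = set(int(t) for t in tree.terminals())
    term.update(int(n) for n in tree.fascicle_end_nodes.values())
    term = np.asarray(sorted(term), np.int64)

    endo = mesh.surface_nodes("LV_ENDO", "RV_ENDO_SEPTAL", "RV_ENDO_FREE")
    kd = cKDTree(mesh.vertices[endo])
    d, idx = kd.query(tree.nodes[term])
    if np.any(d > max_distance_mm):
        worst = term[int(np.argmax(d))]
        raise ParameterError(
            f"tree terminal {worst} is {d.max():.1f} mm from the endocardium "
            f"(limit {max_distance_mm} mm)")
    out.pmj_tree_nodes = term
    out.pmj_mesh_nodes = endo[idx].astype(np.int64)
    out.pmj_anterograde = np.full(len(term), float(anterograde_ms))
    out.pmj_retrograde = np.full(len(term), float(retrograde_ms))
    return out


def apply_proximal_lbbb(tree: PurkinjeTree) -> PurkinjeTree:
    """Flag the proximal left-bundle edge non-conductive (proximal LBBB).

    The block sits on the first left-bundle edge just distal to the His
    bifurcation; the distal left bundle (the LBBP pacing target) stays
    intact, so pacing it re-engages the whole LV Purkinje network.
    """
    out = tree.copy()
    if tree.block_edge is None:
        raise ParameterError("tree has no designated block edge")
    out.conductive[tree.block_edge] = False
    return out


def calibrate_fascicle_cv(tree: PurkinjeTree, model,
                          lv_rv_offset: float = 10.0):
    """Closed-form per-fascicle CVs reproducing physiological sinus timing.

    A sinus beat from the His root must reach the three LV fascicle ends at a
    common time T and the two RV fascicle ends at T + ``lv_rv_offset``.
    With the trunk/bundle CV fixed, each fascicle's CV is
    ``L_f / (t_target - t_origin)`` where ``L_f`` is the length of its
    exclusive (fascicle-class) path and ``t_origin`` the arrival at the start
    of that path. T is anchored at the latest unconstrained LV arrival so no
    calibrated CV exceeds the trunk CV. Returns a new conduction model.
    """
    from .eikonal import solve_network   # deferred: avoids circular import

    base = model.copy()
    base.fascicle_cv = {}
    base.lv_hps_factor = 1.0
    ref = tree.copy()
    ref.conductive = np.ones(tree.n_edges, bool)
    t_uncal = solve_network(ref, base, [(tree.his_root, 0.0)])

    parent = ref.parents()
    lengths = ref.edge_length
    edge_of = {}
    for i in range(ref.n_edges):
        edge_of[(int(ref.edge_a[i]), int(ref.edge_b[i]))] = i
        edge_of[(int(ref.edge_b[i]), int(ref.edge_a[i]))] = i

    def path_fascicle_length(label):
        node = tree.fascicle_end_nodes[label]
        L = 0.0
        while parent[node] >= 0:
            e = edge_of[(int(node), int(parent[node]))]
            if ref.edge_class[e] == FASCICLE and ref.edge_fascicle[e] == label:
                L += lengths[e]
            node = parent[node]
        return L

    info = {}
    for label in (*LV_FASCICLE_LABELS, *RV_FASCICLE_LABELS):
        if label not in tree.fascicle_end_nodes:
            raise CalibrationError(f"fascicle {FASCICLE_NAMES[label]} missing")
        t_end = float(t_uncal[tree.fascicle_end_nodes[label]])
        if not np.isfinite(t_end):
            raise CalibrationError(
                f"fascicle end {FASCICLE_NAMES[label]} unreachable from the His")
        L = path_fascicle_length(label)
        info[label] = (t_end, L, t_end - L / model.hps_cv)

    T = max(info[l][0] for l in LV_FASCICLE_LABELS)
    out = model.copy()
    for label, (t_end, L, t_origin) in info.items():
        target = T if label in LV_FASCICLE_LABELS else T + lv_rv_offset
        dt = target - t_origin
        if L <= 0:
            raise CalibrationError(
                f"fascicle {FASCICLE_NAMES[label]} has zero exclusive length")
        if dt <= 0:
            raise CalibrationError(
                f"fascicle {FASCICLE_NAMES[label]} cannot reach its target "
                f"time (needed interval {dt:.3f} ms)")
        cv = L / dt
        if cv > model.hps_cv * (1.0 + 1e-9):
            raise CalibrationError(
                f"fascicle {FASCICLE_NAMES[label]} would need CV {cv:.2f} m/s "
                f"above the trunk CV {model.hps_cv} m/s")
        out.fascicle_cv[label] = cv
    return out
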