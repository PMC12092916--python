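"""Local activation time computation.

Three solvers cooperate:

* :func:`solve_network` — earliest-arrival (Dijkstra) times on the 1-D
  His-Purkinje tree, edge traversal time = length / segment CV.
* :func:`solve_myocardium` — anisotropic Eikonal first arrival on the
  tetrahedral mesh via a numba fast-iterative method. The element travel-time
  metric is elliptical: time along a straight step d is ``sqrt(d^T M d)`` with
  ``M = vf^-2 f f^T + vt^-2 (I - f f^T)`` and ``vt = anisotropy_ratio * vf``,
  so the front moves at ``vf`` along the fiber and ``vt`` across it
  (transverse isotropy: sheet and normal-to-sheet speeds equal).
* :func:`solve_coupled` — bidirectional Purkinje-myocardium coupling through
  PMJs (anterograde and retrograde junction delays), iterated to the
  earliest-arrival fixed point. All operations are min-plus linear, so the
  fixed point from several stimuli equals the element-wise minimum of the
  single-stimulus fixed points; the pacing module exploits this for VVD
  sweeps.

Units: mm, ms, m/s (1 m/s = 1 mm/ms). Unreached tissue carries +inf.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

from ._fim import fim_solve
from .errors import ConvergenceError, ParameterError, SolverError
from .geometry import FiberField, LabeledMesh
from . import purkinje as _pk
from .purkinje import PurkinjeTree

LV_FASCICLES = (_pk.LV_ANT, _pk.LV_POST, _pk.LV_SEPT)


@dataclass
class ConductionModel:
    """All conduction velocities and coupling parameters.

    ``v_fiber`` is the myocardial along-fiber CV (m/s) and
    ``anisotropy_ratio`` the cross-fiber/along-fiber speed ratio. The
    His-Purkinje system is isotropic at ``hps_cv``; per-fascicle CVs are
    filled in by :func:`lotcrt.purkinje.calibrate_fascicle_cv`.
    ``region_multiplier`` scales myocardial CV per region label and
    ``lv_hps_factor`` scales the left-sided conduction system (left bundle,
    LV fascicles, LV Purkinje); both are the hooks the disease scenarios use.
    """

    v_fiber: float = 0.6                      # m/s along fiber
    anisotropy_ratio: float = 0.4             # cross-fiber / along-fiber
    hps_cv: float = 3.0                       # m/s, His/bundles/Purkinje
    fascicle_cv: dict = field(default_factory=dict)   # label -> m/s
    region_multiplier: dict = field(default_factory=dict)  # region code -> scale
    lv_hps_factor: float = 1.0
    pmj_anterograde_ms: float = 10.0
    pmj_retrograde_ms: float = 5.0
    max_coupling_iters: int = 20
    coupling_tol_ms: float = 0.01
    eikonal_tol_ms: float = 0.05
    retrograde_enabled: bool = True

    def __post_init__(self):
        if self.v_fiber <= 0 or self.hps_cv <= 0:
            raise ParameterError("conduction velocities must be positive")
        if not (0.0 < self.anisotropy_ratio <= 1.0):
            raise ParameterError("anisotropy_ratio must lie in (0, 1]")
        if any(v < 0 for v in self.region_multiplier.values()):
            raise ParameterError("region multipliers must be >= 0")

    def copy(self) -> "ConductionModel":
        return dataclasses.replace(
            self, fascicle_cv=dict(self.fascicle_cv),
            region_multiplier=dict(self.region_multiplier))


@dataclass
class ActivationMap:
    """Nodal local activation times (ms); +inf marks unreached tissue."""

    myocardium: np.ndarray          # (n_vert,) ms
    tree: np.ndarray                # (n_tree_nodes,) ms
    protocol: str = ""


def edge_speeds(tree: PurkinjeTree, model: ConductionModel) -> np.ndarray:
    """Per-edge conduction velocity (m/s) resolving class, fascicle and scenario."""
    cv = np.full(tree.n_edges, model.hps_cv)
    fas = tree.edge_fascicle
    is_fasc = tree.edge_class == _pk.FASCICLE
    for label, v in model.fascicle_cv.items():
        cv[is_fasc & (fas == label)] = v
    lv_side = ((tree.edge_class == _pk.LEFT_BUNDLE)
               | np.isin(fas, LV_FASCICLES))
    cv[lv_side] *= model.lv_hps_factor
    return cv


def solve_network(tree: PurkinjeTree, model: ConductionModel,
                  sources) -> np.ndarray:
    """Earliest-arrival times on the tree from ``sources`` = [(node, ms), ...]."""
    if len(sources) == 0:
        raise SolverError("network solve needs at least one source")
    src = np.asarray([s[0] for s in sources], dtype=np.int64)
    t0 = np.asarray([s[1] for s in sources], dtype=float)
    if src.min() < 0 or src.max() >= tree.n_nodes:
        raise SolverError("network source on non-existent tree node")
    if np.any(t0 < 0):
        raise SolverError("source times must be >= 0")

    cv = edge_speeds(tree, model)
    keep = tree.conductive & (cv > 0)
    w = tree.edge_length[keep] / cv[keep]
    n = tree.n_nodes
    # virtual node n connects to each source with weight = its onset
    rows = np.concatenate([tree.edge_a[keep], tree.edge_b[keep],
                           np.full(len(src), n)])
    cols = np.concatenate([tree.edge_b[keep], tree.edge_a[keep], src])
    dat = np.concatenate([w, w, t0])
    g = sparse.csr_matrix((dat, (rows, cols)), shape=(n + 1, n + 1))
    d = dijkstra(g, directed=True, indices=n)
    return d[:n]


def _element_metrics(mesh: LabeledMesh, fibers: FiberField,
                     model: ConductionModel):
    f = fibers.vectors
    norms = np.linalg.norm(f, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise SolverError("fiber vectors must be unit length")
    mult = np.ones(mesh.n_elements)
    base = mesh.base_region
    for region, m in model.region_multiplier.items():
        mult[base == region] = m
    mult = mult * mesh.cv_scale()
    active = mult > 0.0

    vf = np.where(active, model.v_fiber * mult, 1.0)
    vt = model.anisotropy_ratio * vf
    a = 1.0 / vf**2
    b = 1.0 / vt**2
    m6 = np.empty((mesh.n_elements, 6))
    m6[:, 0] = b + (a - b) * f[:, 0] * f[:, 0]
    m6[:, 1] = b + (a - b) * f[:, 1] * f[:, 1]
    m6[:, 2] = b + (a - b) * f[:, 2] * f[:, 2]
    m6[:, 3] = (a - b) * f[:, 0] * f[:, 1]
    m6[:, 4] = (a - b) * f[:, 0] * f[:, 2]
    m6[:, 5] = (a - b) * f[:, 1] * f[:, 2]
    return m6, active


def solve_myocardium(mesh: LabeledMesh, fibers: FiberField,
                     model: ConductionModel, sources) -> np.ndarray:
    """Anisotropic Eikonal first-arrival times from ``sources`` = [(node, ms), ...]."""
    if len(sources) == 0:
        raise SolverError("myocardial solve needs at least one source")
    src = np.asarray([s[0] for s in sources], dtype=np.int64)
    t0 = np.asarray([s[1] for s in sources], dtype=float)
    if src.min() < 0 or src.max() >= mesh.n_vertices:
        raise SolverError("myocardial source on non-existent mesh node")
    if np.any(t0 < 0):
        raise SolverError("source times must be >= 0")

    m6, active = _element_metrics(mesh, fibers, model)
    indptr, adj = mesh.node_to_elements()
    for s in src:
        elems = adj[indptr[s]:indptr[s + 1]]
        if len(elems) == 0 or not np.any(active[elems]):
            raise SolverError(
                f"source node {s} lies in a zero-speed (non-conductive) region")
    return fim_solve(mesh.vertices, mesh.tetrahedra.astype(np.int64), m6,
                     active, indptr, adj, src, t0, model.eikonal_tol_ms)


def solve_coupled(mesh: LabeledMesh, fibers: FiberField, tree: PurkinjeTree,
                  model: ConductionModel, protocol) -> ActivationMap:
    """Fixed point of the bidirectionally PMJ-coupled tree/tissue system.

    ``protocol`` needs ``tree_stimuli`` and ``myo_stimuli`` lists of
    (node, onset_ms) and a ``name``. Iteration: network solve from tree
    stimuli plus retrograde PMJ candidates; myocardial solve from direct
    stimuli plus anterograde PMJ candidates; repeat until no activation time
    decreases by more than the coupling tolerance. Each pass can only lower
    times, so the iteration is monotone and terminates.
    """
    tree_stim = list(getattr(protocol, "tree_stimuli", []) or [])
    myo_stim = list(getattr(protocol, "myo_stimuli", []) or [])
    if not tree_stim and not myo_stim:
        raise SolverError("protocol defines no stimuli")

    pmj_tree = tree.pmj_tree_nodes
    pmj_mesh = tree.pmj_mesh_nodes
    antero = tree.pmj_anterograde
    retro = tree.pmj_retrograde

    tree_t = np.full(tree.n_nodes, np.inf)
    myo_t = np.full(mesh.n_vertices, np.inf)
    tol = model.coupling_tol_ms

    for it in range(model.max_coupling_iters):
        sources_t = list(tree_stim)
        if model.retrograde_enabled and len(pmj_tree):
            cand = myo_t[pmj_mesh] + retro
            ok = np.isfinite(cand)
            sources_t += [(int(n), float(t))
                          for n, t in zip(pmj_tree[ok], cand[ok])]
        new_tree = (solve_network(tree, model, sources_t)
                    if sources_t else np.full(tree.n_nodes, np.inf))

        sources_m = list(myo_stim)
        if len(pmj_tree):
            cand = new_tree[pmj_tree] + antero
            ok = np.isfinite(cand)
            sources_m += [(int(n), float(t))
                          for n, t in zip(pmj_mesh[ok], cand[ok])]
        new_myo = (solve_myocardium(mesh, fibers, model, sources_m)
                   if sources_m else np.full(mesh.n_vertices, np.inf))

        both_fin = np.isfinite(myo_t) & np.isfinite(new_myo)
        d_myo = np.max(myo_t[both_fin] - new_myo[both_fin]) if both_fin.any() else 0.0
        newly = np.isinf(myo_t) & np.isfinite(new_myo)
        both_fin_t = np.isfinite(tree_t) & np.isfinite(new_tree)
        d_tree = (np.max(tree_t[both_fin_t] - new_tree[both_fin_t])
                  if both_fin_t.any() else 0.0)
        newly_t = np.isinf(tree_t) & np.isfinite(new_tree)
        tree_t, myo_t = new_tree, np.minimum(myo_t, new_myo)
        if it > 0 and not newly.any() and not newly_t.any() \
                and d_myo <= tol and d_tree <= tol:
            break
    else:
        raise ConvergenceError(
            f"PMJ coupling did not converge in {model.max_coupling_iters} "
            f"iterations (residual myo {d_myo:.3g} ms, tree {d_tree:.3g} ms)")

    return ActivationMap(myocardium=myo_t, tree=tree_t,
                         protocol=getattr(protocol, "name", ""))
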