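"""Stimulus protocols for all pacing modalities and the VVD sweep.

Modalities: intrinsic sinus; His bundle pacing (HBP, distal to a proximal
block); selective LBBP (left bundle only); non-selective LBBP (bundle plus
the septal myocardium within the capture radius); LV septal pacing (LVSP,
myocardium only); LV epicardial pacing at the latest-activated baseline
site; RV apical pacing; and the two-lead combinations BVP (RV + LV epi),
LOT-CRT (LBBAP variant + LV epi) and HOT-CRT (HBP + LV epi).

Two-lead protocols carry a signed ventriculo-ventricular delay (VVD):
negative VVD fires the LBBAP/RV lead first, positive fires the LV epicardial
lead first; onsets are normalized so the earliest stimulus is t = 0. Pacing
overrides intrinsic activation, so paced protocols contain no sinus source.

The VVD sweep uses the min-plus structure of the earliest-arrival problem:
the coupled activation map with both leads equals the element-wise minimum
of the two single-lead coupled maps shifted by their onsets, so one sweep
costs two coupled solves regardless of the grid size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import geometry as G
from . import metrics as M
from .eikonal import ActivationMap, solve_coupled
from .errors import ParameterError, SolverError

MODALITIES = ("SINUS", "HBP", "S_LBBP", "NS_LBBP", "LVSP", "LVEPI", "RVP",
              "BVP", "LOT_CRT_S", "LOT_CRT_NS", "LOT_CRT_LVSP", "HOT_CRT")
TWO_LEAD = ("BVP", "LOT_CRT_S", "LOT_CRT_NS", "LOT_CRT_LVSP", "HOT_CRT")


@dataclass
class StimulusProtocol:
    """Resolved stimuli of one pacing protocol (onsets in ms, earliest = 0)."""

    modality: str
    tree_stimuli: list = field(default_factory=list)   # [(tree node, ms)]
    myo_stimuli: list = field(default_factory=list)    # [(mesh node, ms)]
    vvd: float = 0.0
    capture_radius: float = 2.0

    @property
    def name(self) -> str:
        return f"{self.modality}@vvd={self.vvd:g}"


def locate_lvepi_lead(baseline: ActivationMap, mesh: G.LabeledMesh,
                      basal_cut: float = 0.9) -> int:
    """Latest-activated LV free-wall epicardial node at baseline.

    Valve-masked (basal) and septal territory is excluded; ties break to the
    lowest node index.
    """
    epi = mesh.face_tags == G.EPI
    lv_faces = mesh.boundary_faces[epi][
        mesh.base_region[mesh.face_owner[epi]] == G.LV_MYO]
    nodes = np.unique(lv_faces)
    nodes = nodes[mesh.apicobasal[nodes] <= basal_cut]
    lat = baseline.myocardium[nodes]
    ok = np.isfinite(lat)
    if not ok.any():
        raise SolverError("no eligible LV epicardial node with a finite "
                          "baseline activation time")
    nodes, lat = nodes[ok], lat[ok]
    # argmax returns the first (lowest-index) maximum; nodes are sorted
    return int(nodes[int(np.argmax(lat))])


def resolve_sites(mesh: G.LabeledMesh, tree, baseline: ActivationMap | None = None,
                  capture_radius: float = 2.0, basal_cut: float = 0.9) -> dict:
    """Anatomical pacing targets for all modalities.

    The LV epicardial lead needs a baseline map (latest-activated area); it
    is omitted when ``baseline`` is None.
    """
    sites = {
        "his_root": int(tree.his_root),
        "hbp_node": int(tree.hbp_node),
        "lbbp_node": int(tree.lbbp_node),
    }
    # septal myocardial capture around the LBBP lead tip
    tip = tree.nodes[tree.lbbp_node]
    endo = mesh.surface_nodes("LV_ENDO")
    kd = cKDTree(mesh.vertices[endo])
    idx = kd.query_ball_point(tip, capture_radius)
    if not idx:
        idx = [int(kd.query(tip)[1])]
    sites["lvsp_nodes"] = sorted(int(endo[i]) for i in idx)
    rv_endo = mesh.surface_nodes("RV_ENDO_SEPTAL", "RV_ENDO_FREE")
    sites["rv_apex_node"] = int(rv_endo[int(np.argmin(mesh.vertices[rv_endo, 2]))])
    if baseline is not None:
        sites["lvepi_node"] = locate_lvepi_lead(baseline, mesh, basal_cut)
    return sites


def _lead_groups(modality: str, sites: dict):
    """(group1, group2) stimuli at onset 0; group1 = LBBAP/RV side."""
    need = lambda k: sites.get(k) if sites.get(k) is not None else _missing(modality, k)
    if modality == "SINUS":
        return ([("tree", sites["his_root"])], None)
    if modality == "HBP":
        return ([("tree", need("hbp_node"))], None)
    if modality == "S_LBBP":
        return ([("tree", need("lbbp_node"))], None)
    if modality == "NS_LBBP":
        return ([("tree", need("lbbp_node"))]
                + [("myo", n) for n in need("lvsp_nodes")], None)
    if modality == "LVSP":
        return ([("myo", n) for n in need("lvsp_nodes")], None)
    if modality == "LVEPI":
        return ([("myo", need("lvepi_node"))], None)
    if modality == "RVP":
        return ([("myo", need("rv_apex_node"))], None)
    if modality == "BVP":
        return ([("myo", need("rv_apex_node"))], [("myo", need("lvepi_node"))])
    if modality == "LOT_CRT_S":
        return ([("tree", need("lbbp_node"))], [("myo", need("lvepi_node"))])
    if modality == "LOT_CRT_NS":
        return ([("tree", need("lbbp_node"))]
                + [("myo", n) for n in need("lvsp_nodes")],
                [("myo", need("lvepi_node"))])
    if modality == "LOT_CRT_LVSP":
        return ([("myo", n) for n in need("lvsp_nodes")],
                [("myo", need("lvepi_node"))])
    if modality == "HOT_CRT":
        return ([("tree", need("hbp_node"))], [("myo", need("lvepi_node"))])
    raise ParameterError(f"unknown modality {modality!r}; one of {MODALITIES}")


def _missing(modality, key):
    raise ParameterError(f"modality {modality} needs site {key!r}, "
                         "which is not resolved")


def make_protocol(modality: str, sites: dict, vvd: float = 0.0,
                  capture_radius: float = 2.0) -> StimulusProtocol:
    """Build a stimulus protocol; two-lead modalities honour the VVD sign
    convention (negative = LBBAP/RV first, positive = LV epicardial first)."""
    g1, g2 = _lead_groups(modality, sites)
    if g2 is None:
        onset1, onset2 = 0.0, None
        if vvd:
            raise ParameterError(f"{modality} is single-lead; vvd must be 0")
    elif vvd < 0:
        onset1, onset2 = 0.0, -float(vvd)
    else:
        onset1, onset2 = float(vvd), 0.0
    proto = StimulusProtocol(modality=modality, vvd=float(vvd),
                             capture_radius=capture_radius)
    for kind, node in g1:
        (proto.tree_stimuli if kind == "tree" else proto.myo_stimuli).append(
            (node, onset1))
    if g2 is not None:
        for kind, node in g2:
            (proto.tree_stimuli if kind == "tree" else proto.myo_stimuli
             ).append((node, onset2))
    return proto


def vvd_grid(vvd_min: float = -100.0, vvd_max: float = 100.0,
             step: float = 10.0) -> np.ndarray:
    if step <= 0 or vvd_min > vvd_max:
        raise ParameterError("need step > 0 and vvd_min <= vvd_max")
    n = int(round((vvd_max - vvd_min) / step))
    return vvd_min + step * np.arange(n + 1)


def vvd_sweep(mesh, fibers, tree, model, modality: str, sites: dict,
              vvd_min: float = -100.0, vvd_max: float = 100.0,
              step: float = 10.0, baseline_record: M.MetricsRecord | None = None,
              basal_cut: float = 0.9, scenario: str = "",
              severity: str = "") -> M.SweepResult:
    """Sweep the VVD grid for a two-lead modality.

    Solves one coupled activation map per lead and superposes them per VVD;
    records the synchrony metrics (and responses, when a baseline record is
    given) at every grid point and picks the optimal VVD.
    """
    if modality not in TWO_LEAD:
        raise ParameterError(f"{modality} is not a two-lead modality")
    g1, g2 = _lead_groups(modality, sites)
    u1 = _unit_map(mesh, fibers, tree, model, g1, f"{modality}:lead1")
    u2 = _unit_map(mesh, fibers, tree, model, g2, f"{modality}:lead2")

    records = {}
    for vvd in vvd_grid(vvd_min, vvd_max, step):
        o1, o2 = (0.0, -vvd) if vvd < 0 else (vvd, 0.0)
        lat = np.minimum(u1.myocardium + o1, u2.myocardium + o2)
        rec = M.compute_metrics(lat, mesh, basal_cut)
        if baseline_record is not None:
            rec = M.response(rec, baseline_record)
        records[int(round(vvd))] = rec
    best, flag = M.optimal_vvd(records)
    return M.SweepResult(records=records, optimal_vvd=best, boundary_flag=flag,
                         scenario=scenario, severity=severity,
                         modality=modality)


def _unit_map(mesh, fibers, tree, model, group, name) -> ActivationMap:
    proto = StimulusProtocol(modality=name)
    for kind, node in group:
        (proto.tree_stimuli if kind == "tree" else proto.myo_stimuli).append(
            (node, 0.0))
    return solve_coupled(mesh, fibers, tree, model, proto)


def simulate(mesh, fibers, tree, model, modality: str, sites: dict,
             vvd: float = 0.0, capture_radius: float = 2.0) -> ActivationMap:
    """Solve one protocol end to end (thin convenience wrapper)."""
    proto = make_protocol(modality, sites, vvd, capture_radius)
    return solve_coupled(mesh, fibers, tree, model, proto)
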