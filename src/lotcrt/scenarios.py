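"""Left-ventricular conduction-substrate scenarios.

Three disease mechanisms produce an LBBB-like activation pattern and are
modelled here by modifying the conduction model and the tree:

1. proximal LBBB — the left bundle is cut just distal to the His bifurcation;
2. diffuse LV conduction-system delay — the left-sided His-Purkinje CV
   (left bundle, LV fascicles, LV Purkinje) is scaled down;
3. LV intra-myocardial delay — the LV myocardial CV (LV free wall and the
   LV half of the septum) is scaled down.

Scenario codes combine them: A = block + slow LV HPS, B = block + slow LV
myocardium, C = slow LV HPS alone, D = slow LV myocardium alone. With a
proximal block the mild/severe factors are 60%/40% of healthy CV; without a
block, 60% slowing barely prolongs LV activation, so mild/severe use
40%/20% instead. The RV side is never touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry as G
from . import purkinje as P
from .errors import ParameterError

MILD, SEVERE = "MILD", "SEVERE"
CODES = ("HEALTHY", "LBBB_ONLY", "A", "B", "C", "D")

# (with proximal block?, mild factor, severe factor)
_FACTORS_WITH_BLOCK = {MILD: 0.6, SEVERE: 0.4}
_FACTORS_NO_BLOCK = {MILD: 0.4, SEVERE: 0.2}


@dataclass(frozen=True)
class ScenarioSpec:
    """One conduction-substrate scenario.

    ``hps_factor`` scales the LV His-Purkinje CV, ``myo_factor`` the LV
    myocardial CV (both 1.0 = healthy); ``proximal_block`` cuts the left
    bundle. ``scar`` optionally holds (center, radius_mm, cv_scale,
    purkinje_conductive) for a lateral-wall scar.
    """

    code: str
    severity: str = SEVERE
    hps_factor: float = 1.0
    myo_factor: float = 1.0
    proximal_block: bool = False
    scar: tuple | None = None

    def __post_init__(self):
        if not (0.0 < self.hps_factor <= 1.0 and 0.0 < self.myo_factor <= 1.0):
            raise ParameterError("severity factors must lie in (0, 1]")


def make_scenario(code: str, severity: str = SEVERE) -> ScenarioSpec:
    """Build a scenario spec from its code and severity."""
    code = code.upper()
    if code not in CODES:
        raise ParameterError(f"unknown scenario code {code!r}; one of {CODES}")
    if severity not in (MILD, SEVERE):
        raise ParameterError(f"severity must be MILD or SEVERE, got {severity!r}")
    if code == "HEALTHY":
        return ScenarioSpec(code, severity)
    if code == "LBBB_ONLY":
        return ScenarioSpec(code, severity, proximal_block=True)
    if code in ("A", "B"):
        f = _FACTORS_WITH_BLOCK[severity]
        block = True
    else:
        f = _FACTORS_NO_BLOCK[severity]
        block = False
    if code in ("A", "C"):
        return ScenarioSpec(code, severity, hps_factor=f, proximal_block=block)
    return ScenarioSpec(code, severity, myo_factor=f, proximal_block=block)


def apply_scenario(spec: ScenarioSpec, tree: P.PurkinjeTree, model):
    """Return (tree', model') with the scenario applied; inputs untouched.

    The LV HPS factor scales the left bundle, LV fascicles and LV Purkinje
    (the His trunk and all right-sided segments keep the healthy CV); the
    myocardial factor sets the CV multiplier of LV_MYO and SEPTUM_LV.
    """
    model2 = model.copy()
    model2.lv_hps_factor = spec.hps_factor
    model2.region_multiplier[G.LV_MYO] = spec.myo_factor
    model2.region_multiplier[G.SEPTUM_LV] = spec.myo_factor
    tree2 = P.apply_proximal_lbbb(tree) if spec.proximal_block else tree.copy()
    return tree2, model2


def apply_scar(mesh: G.LabeledMesh, tree: P.PurkinjeTree, center,
               radius_mm: float, cv_scale: float = 0.5,
               purkinje_conductive: bool = True):
    """Insert a spherical scar region; returns (mesh', tree').

    Elements whose centroid lies within ``radius_mm`` of ``center`` are
    relabelled SCAR and their CV scaled by ``cv_scale`` (0 = non-conductive);
    the original wall label is retained for metric masks. Purkinje edges
    overlying the scar are flagged non-conductive unless
    ``purkinje_conductive``.
    """
    center = np.asarray(center, float)
    if radius_mm <= 0:
        raise ParameterError("scar radius must be positive")
    if cv_scale < 0:
        raise ParameterError("scar cv_scale must be >= 0")
    cent = mesh.element_centroid
    inside = np.linalg.norm(cent - center, axis=1) <= radius_mm
    if not np.any(inside):
        raise ParameterError("scar region does not intersect the mesh")

    mesh2 = mesh.copy()
    if mesh2.element_region_pre_scar is None:
        mesh2.element_region_pre_scar = mesh.element_region.copy()
    mesh2.element_region = mesh2.element_region.copy()
    mesh2.element_region[inside] = G.SCAR
    scale = mesh2.cv_scale().copy()
    scale[inside] = cv_scale
    mesh2.element_cv_scale = scale

    tree2 = tree.copy()
    if not purkinje_conductive and tree.n_edges:
        mid = 0.5 * (tree.nodes[tree.edge_a] + tree.nodes[tree.edge_b])
        over = np.linalg.norm(mid - center, axis=1) <= radius_mm
        tree2.conductive[over] = False
    return mesh2, tree2
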