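"""Activation-time synchrony metrics and optimal-VVD selection.

All interval metrics are "shortest time interval taken to activate q% of
the region": the narrowest time window containing q% of the element-volume-
weighted activation mass (element-centroid times). The window may slide, so
up to (100 - q)% of early- or late-activating volume falls outside it; this
is what makes pre-exciting a small, late-activating territory with a large
lead offset beneficial rather than self-penalizing. q = 100 gives the total
activation time (TAT-style span, max - min), q = 95 the AT95 metrics the
device programming is optimized against. The basal band around the valves is
always excluded, and the septum counts toward the ventricle its transmural
half belongs to. Epicardial variants restrict the same computation to the
EPI triangle surface (area-weighted), mirroring what body-surface imaging
can see.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np

from . import geometry as G
from .errors import ParameterError, SolverError


@dataclass
class MetricsRecord:
    """Synchrony metrics (ms) for one activation map.

    ``*_response`` fields are paced minus baseline; negative = improvement.
    """

    tat: float = np.nan
    lvtat: float = np.nan
    bivat95: float = np.nan
    lvat95: float = np.nan
    epi_tat: float = np.nan
    epi_lvtat: float = np.nan
    epi_bivat95: float = np.nan
    epi_lvat95: float = np.nan
    tat_response: float = np.nan
    lvtat_response: float = np.nan
    bivat95_response: float = np.nan
    lvat95_response: float = np.nan
    epi_bivat95_response: float = np.nan
    epi_lvat95_response: float = np.nan
    masks: tuple = ()          # (basal_cut, lv-region codes) used

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name != "masks"}


@dataclass
class SweepResult:
    """Per-VVD metrics of one sweep plus the optimal delay."""

    records: dict                      # vvd (int ms) -> MetricsRecord
    optimal_vvd: float = np.nan
    boundary_flag: bool = False
    scenario: str = ""
    severity: str = ""
    modality: str = ""


def _weighted_shortest_window(values, weights, q):
    """Width of the narrowest interval holding q% of the weight mass."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    total = cum[-1]
    need = (q / 100.0) * total
    # window starting at element i must end at the smallest j with
    # cum[j] - cum[i-1] >= need
    prev = np.concatenate(([0.0], cum[:-1]))
    targets = prev + need - 1e-12 * total
    ends = np.searchsorted(cum, targets)
    ok = ends < len(v)
    if not ok.any():
        return float(v[-1] - v[0])
    widths = v[ends[ok]] - v[ok]
    return float(widths.min())


def activation_interval(lat: np.ndarray, mesh: G.LabeledMesh,
                        region_mask: np.ndarray, q: float = 95.0,
                        exclude_mask: np.ndarray | None = None,
                        basal_cut: float = 0.9) -> float:
    """Volume-weighted q-th percentile activation interval of a region (ms).

    ``lat`` is nodal; element-centroid times are volume-weighted and the
    interval is the narrowest window containing q% of the region's
    activation mass. The valve-exclusion mask
    (apicobasal > ``basal_cut``) is always applied on top of any explicit
    ``exclude_mask``. Unreached (non-finite) elements are dropped with a
    warning.
    """
    if not (0.0 < q <= 100.0):
        raise ParameterError("percentile q must lie in (0, 100]")
    sel = np.asarray(region_mask, bool).copy()
    sel &= ~G.valve_exclusion_mask(mesh, basal_cut)
    if exclude_mask is not None:
        sel &= ~np.asarray(exclude_mask, bool)
    if not np.any(sel):
        raise ParameterError("region mask empty after exclusions")
    clat = lat[mesh.tetrahedra[sel]].mean(axis=1)
    finite = np.isfinite(clat)
    if not finite.any():
        raise SolverError("all activation times in the region are unreached")
    if not finite.all():
        warnings.warn(f"{(~finite).sum()} unreached elements excluded from "
                      "the activation interval", stacklevel=2)
    clat = clat[finite]
    w = mesh.element_volume[sel][finite]
    return _weighted_shortest_window(clat, w, q)


def lv_region_mask(mesh: G.LabeledMesh) -> np.ndarray:
    """LV elements: LV free wall plus the LV half of the septum (scar keeps
    its wall of origin)."""
    return np.isin(mesh.base_region, G.LV_REGIONS)


def biv_region_mask(mesh: G.LabeledMesh) -> np.ndarray:
    return np.ones(mesh.n_elements, bool)


def _epi_interval(lat, mesh, faces, owners, q, basal_cut):
    fc_apico = mesh.apicobasal[faces].mean(axis=1)
    sel = fc_apico <= basal_cut
    faces, owners = faces[sel], owners[sel]
    if len(faces) == 0:
        raise ParameterError("no epicardial faces after valve exclusion")
    flat = lat[faces].mean(axis=1)
    finite = np.isfinite(flat)
    if not finite.any():
        raise SolverError("epicardial surface entirely unreached")
    p = mesh.vertices[faces]
    area = 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
                                axis=1)
    flat, area = flat[finite], area[finite]
    return _weighted_shortest_window(flat, area, q)


def epicardial_metrics(lat: np.ndarray, mesh: G.LabeledMesh,
                       basal_cut: float = 0.9) -> MetricsRecord:
    """Interval metrics restricted to the epicardial surface (area-weighted).

    The LV epicardium is the set of EPI faces owned by LV free-wall elements
    (the septum has no epicardial exposure).
    """
    epi = mesh.face_tags == G.EPI
    if not np.any(epi):
        raise ParameterError("mesh has no EPI faces")
    faces = mesh.boundary_faces[epi]
    owners = mesh.face_owner[epi]
    lv = mesh.base_region[owners] == G.LV_MYO
    rec = MetricsRecord(masks=(basal_cut, G.LV_REGIONS))
    rec.epi_tat = _epi_interval(lat, mesh, faces, owners, 100.0, basal_cut)
    rec.epi_bivat95 = _epi_interval(lat, mesh, faces, owners, 95.0, basal_cut)
    rec.epi_lvtat = _epi_interval(lat, mesh, faces[lv], owners[lv], 100.0,
                                  basal_cut)
    rec.epi_lvat95 = _epi_interval(lat, mesh, faces[lv], owners[lv], 95.0,
                                   basal_cut)
    return rec


def compute_metrics(lat: np.ndarray, mesh: G.LabeledMesh,
                    basal_cut: float = 0.9) -> MetricsRecord:
    """Full volumetric + epicardial metrics record for one nodal LAT array."""
    lv = lv_region_mask(mesh)
    biv = biv_region_mask(mesh)
    rec = epicardial_metrics(lat, mesh, basal_cut)
    rec.tat = activation_interval(lat, mesh, biv, 100.0, basal_cut=basal_cut)
    rec.lvtat = activation_interval(lat, mesh, lv, 100.0, basal_cut=basal_cut)
    rec.bivat95 = activation_interval(lat, mesh, biv, 95.0, basal_cut=basal_cut)
    rec.lvat95 = activation_interval(lat, mesh, lv, 95.0, basal_cut=basal_cut)
    return rec


def response(paced: MetricsRecord, baseline: MetricsRecord) -> MetricsRecord:
    """Paced-minus-baseline responses; the clinical reporting convention
    prints improvements with a minus sign (e.g. a response of -40 ms)."""
    if paced.masks != baseline.masks:
        raise ParameterError("paced and baseline metrics use different masks")
    out = MetricsRecord(**{k: v for k, v in paced.as_dict().items()},
                        masks=paced.masks)
    for name in ("tat", "lvtat", "bivat95", "lvat95", "epi_bivat95",
                 "epi_lvat95"):
        setattr(out, name + "_response",
                getattr(paced, name) - getattr(baseline, name))
    return out


def optimal_vvd(records: dict) -> tuple:
    """(vvd, boundary_flag) minimizing LVAT95 over a sweep.

    Ties prefer the smaller |VVD|, then the negative candidate; the flag is
    set when the optimum sits on a grid endpoint.
    """
    if not records:
        raise ParameterError("empty sweep")
    vvds = sorted(records)
    best = min(vvds, key=lambda v: (records[v].lvat95, abs(v), v))
    return best, bool(best in (vvds[0], vvds[-1]))
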