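"""Geometry: mesh construction, labels, coordinates, fibers, I/O round-trips."""

import dataclasses

import numpy as np
import pytest

from lotcrt import geometry as G
from lotcrt import io as lio
from lotcrt.errors import FormatError, ParameterError


def test_all_region_and_surface_labels_populated(small_mesh):
    regions = set(small_mesh.element_region)
    assert {G.LV_MYO, G.RV_MYO, G.SEPTUM_LV, G.SEPTUM_RV} <= regions
    tags = set(small_mesh.face_tags)
    assert G.EPI in tags and G.LV_ENDO in tags
    assert {G.RV_ENDO_SEPTAL, G.RV_ENDO_FREE, G.BASE} <= tags
    assert small_mesh.element_volume.min() > 0


def test_same_params_and_seed_reproduce_mesh(small_params, small_mesh):
    again = G.build_idealized_biventricular_mesh(small_params)
    assert np.array_equal(again.vertices, small_mesh.vertices)
    assert np.array_equal(again.tetrahedra, small_mesh.tetrahedra)
    assert np.array_equal(again.element_region, small_mesh.element_region)


def test_different_seed_changes_shape(small_params, small_mesh):
    other = G.build_idealized_biventricular_mesh(
        dataclasses.replace(small_params, seed=4))
    assert other.n_vertices != small_mesh.n_vertices or not np.allclose(
        other.vertices[: min(100, other.n_vertices)],
        small_mesh.vertices[: min(100, small_mesh.n_vertices)])


def test_halving_edge_length_scales_element_count(small_params, small_mesh):
    fine = G.build_idealized_biventricular_mesh(
        dataclasses.replace(small_params, edge_length=1.25))
    ratio = fine.n_elements / small_mesh.n_elements
    assert 4.0 <= ratio <= 16.0   # ~8x within a factor of 2


def test_infeasible_wall_thickness_rejected():
    with pytest.raises(ParameterError):
        G.build_idealized_biventricular_mesh(
            G.AnatomyParams(lv_radius=8.0, lv_wall=9.0))


def test_normalized_coordinates_sane(small_mesh):
    m = small_mesh
    assert np.all((m.apicobasal >= 0) & (m.apicobasal <= 1))
    assert np.all((m.transmural >= 0) & (m.transmural <= 1))
    # endocardial surfaces sit at depth ~0, the epicardium at ~1; medians are
    # used because crescent-horn junction nodes are legitimately intermediate
    assert np.median(m.transmural[m.surface_nodes("LV_ENDO")]) < 0.05
    assert np.median(m.transmural[m.surface_nodes("RV_ENDO_FREE")]) < 0.05
    assert np.median(m.transmural[m.surface_nodes("EPI")]) > 0.95


def test_fiber_field_unit_norm_and_helix_rule(small_mesh):
    fib = G.assign_fibers(small_mesh, 60.0, -60.0)
    norms = np.linalg.norm(fib.vectors, axis=1)
    assert np.max(np.abs(norms - 1.0)) < 1e-9
    depth = small_mesh.transmural[small_mesh.tetrahedra].mean(axis=1)
    # near the equator the longitudinal direction is ~z, so |sin(helix)| ~ |f_z|
    meas = np.degrees(np.arcsin(np.clip(np.abs(fib.vectors[:, 2]), 0, 1)))
    expect = np.abs(60.0 - 120.0 * depth)
    equatorial = np.abs(small_mesh.element_centroid[:, 2]) < 6.0
    assert np.median(np.abs(meas - expect)[equatorial]) < 3.0
    # the linear rule crosses zero at midwall
    mid = equatorial & (np.abs(depth - 0.5) < 0.05)
    assert np.median(meas[mid]) < 8.0


def test_fiber_helix_boundary_angles_on_uniform_depth():
    # a slab has transmural depth 0 everywhere, so the rule boundary is exact
    slab = G.build_slab_mesh(8.0, 4.0, 4.0, 2.0)
    shifted = slab.copy()
    shifted.vertices = shifted.vertices + np.array([30.0, 0.0, 0.0])
    fib = G.assign_fibers(shifted, 60.0, -60.0)
    angles = np.degrees(np.arcsin(np.clip(fib.vectors[:, 2], -1, 1)))
    assert np.all(np.abs(angles - 60.0) < 2.0)
    shifted.transmural = np.ones_like(shifted.transmural)
    fib_epi = G.assign_fibers(shifted, 60.0, -60.0)
    angles = np.degrees(np.arcsin(np.clip(fib_epi.vectors[:, 2], -1, 1)))
    assert np.all(np.abs(angles + 60.0) < 2.0)


def test_septum_split_conserves_volume_and_respects_midsurface(small_mesh):
    m = small_mesh
    sept = np.isin(m.element_region, (G.SEPTUM_LV, G.SEPTUM_RV))
    resplit = G.split_septum(m)
    sept2 = np.isin(resplit.element_region, (G.SEPTUM_LV, G.SEPTUM_RV))
    assert np.array_equal(sept, sept2)
    assert (m.element_volume[sept].sum()
            == pytest.approx(resplit.element_volume[sept2].sum()))
    depth = resplit.transmural[resplit.tetrahedra].mean(axis=1)
    lv_half = resplit.element_region == G.SEPTUM_LV
    rv_half = resplit.element_region == G.SEPTUM_RV
    assert np.all(depth[lv_half] <= 0.5)       # includes the exact-tie case
    assert np.all(depth[rv_half] > 0.5)
    assert lv_half.sum() > 0 and rv_half.sum() > 0


def test_valve_exclusion_mask_bounds(small_mesh):
    mask = G.valve_exclusion_mask(small_mesh, 0.9)
    assert 0 < mask.sum() < small_mesh.n_elements
    apico = small_mesh.apicobasal[small_mesh.tetrahedra].mean(axis=1)
    assert not mask[int(np.argmin(apico))]     # apical element kept
    assert mask[int(np.argmax(apico))]         # most basal element dropped


def test_epicardial_surface_extraction(small_mesh):
    faces, node_map, coords = G.extract_epicardial_surface(small_mesh)
    assert len(np.unique(node_map)) == len(node_map)
    assert np.allclose(coords, small_mesh.vertices[node_map])
    # every returned face is a boundary face tagged EPI
    tagged = {tuple(sorted(f))
              for f in small_mesh.boundary_faces[small_mesh.face_tags == G.EPI]}
    for f in node_map[faces]:
        assert tuple(sorted(f)) in tagged
    lv_endo = {tuple(sorted(f))
               for f in small_mesh.boundary_faces[small_mesh.face_tags == G.LV_ENDO]}
    assert not any(tuple(sorted(f)) in lv_endo for f in node_map[faces])


def test_vtu_round_trip(tmp_path, small_mesh):
    fib = G.assign_fibers(small_mesh)
    path = tmp_path / "mesh.vtu"
    lio.write_vtu(small_mesh, path, fibers=fib)
    mesh2, fib2 = lio.load_external_mesh(path)
    assert np.array_equal(mesh2.vertices, small_mesh.vertices)
    assert np.array_equal(mesh2.element_region, small_mesh.element_region)
    assert np.array_equal(mesh2.face_tags, small_mesh.face_tags)
    assert np.array_equal(mesh2.apicobasal, small_mesh.apicobasal)
    assert np.allclose(fib2.vectors, fib.vectors)


def test_carp_round_trip(tmp_path, small_mesh):
    fib = G.assign_fibers(small_mesh)
    base = tmp_path / "heart"
    lio.write_carp(small_mesh, fib, base)
    mesh2, fib2 = lio.read_carp(base)
    assert np.array_equal(mesh2.vertices, small_mesh.vertices)
    assert np.array_equal(mesh2.element_region, small_mesh.element_region)
    assert np.allclose(fib2.vectors, fib.vectors)


def test_missing_fiber_component_named(tmp_path, small_mesh):
    path = tmp_path / "nofib.vtu"
    lio.write_vtu(small_mesh, path, fibers=None)
    with pytest.raises(FormatError, match="fiber"):
        lio.load_external_mesh(path)


def test_hexahedral_input_rejected(tmp_path, small_mesh):
    fib = G.assign_fibers(small_mesh)
    path = tmp_path / "hex.vtu"
    lio.write_vtu(small_mesh, path, fibers=fib)
    text = path.read_text()
    # flip one cell type code from tetra (10) to hexahedron (12)
    import re
    def break_types(match):
        body = match.group(2).split()
        body[0] = "12"
        return match.group(1) + " ".join(body) + match.group(3)
    text = re.sub(r'(Name="types"[^>]*>)([^<]+)(</DataArray>)',
                  break_types, text)
    path.write_text(text)
    with pytest.raises(FormatError, match="hexahedron"):
        lio.load_external_mesh(path)


def test_unit_coercion(tmp_path, small_mesh):
    fib = G.assign_fibers(small_mesh)
    path = tmp_path / "mesh.vtu"
    lio.write_vtu(small_mesh, path, fibers=fib)
    mesh_cm, _ = lio.load_external_mesh(path, units="cm")
    assert np.allclose(mesh_cm.vertices, 10.0 * small_mesh.vertices)


def test_slab_mesh_volume_exact():
    slab = G.build_slab_mesh(10.0, 4.0, 2.0, 1.0)
    assert slab.element_volume.sum() == pytest.approx(80.0)
    assert slab.element_volume.min() > 0
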