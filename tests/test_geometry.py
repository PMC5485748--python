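"""Cell shapes, layouts and the labeled structured mesher."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mealf import (
    CellGeometry,
    ConfigurationError,
    InvalidGeometryError,
    MeshingError,
    MeshResolution,
    SimulationDomain,
    build_mea_layout,
    four_electrode_layout,
    generate_mesh,
    make_cell_shape,
    two_electrode_layout,
)

RES_COARSE = MeshResolution(h_fine=6.0, h_coarse=60.0)


class TestCellShape:
    def test_full_sphere_limit(self):
        # at y0 = r0 the cap degenerates exactly to the free sphere
        cell = make_cell_shape(10.0, 10.0, adherent=True)
        assert cell.shape == "spherical_cap"
        assert cell.r_cap == pytest.approx(10.0, abs=1e-12)
        assert cell.h == pytest.approx(20.0, abs=1e-12)

    def test_cap_radius_and_height(self):
        cell = make_cell_shape(10.0, 5.0, adherent=True)
        assert cell.h == pytest.approx(15.0)
        assert cell.r_cap == pytest.approx(10.925925925925926, rel=1e-12)

    def test_cap_volume_equals_sphere(self):
        cell = make_cell_shape(10.0, 5.0, adherent=True)
        assert cell.cap_volume == pytest.approx(4188.790204786391, rel=1e-12)
        assert cell.cap_volume == pytest.approx(cell.volume, rel=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(r0=st.floats(1.0, 30.0), frac=st.floats(1e-3, 1.0))
    def test_volume_conservation_property(self, r0, frac):
        # |V_cap - V_sphere| / V_sphere < 1e-9 for all y0 in (0, r0]
        cell = make_cell_shape(r0, frac * r0, adherent=True)
        assert abs(cell.cap_volume - cell.volume) / cell.volume < 1e-9

    def test_invalid_and_degenerate(self):
        with pytest.raises(InvalidGeometryError):
            make_cell_shape(10.0, 0.0, adherent=True)
        with pytest.raises(InvalidGeometryError):
            make_cell_shape(-1.0, 5.0, adherent=False)
        with pytest.warns(UserWarning, match="detached"):
            cell = make_cell_shape(10.0, 15.0, adherent=True)
        assert cell.shape == "sphere"

    def test_gap_excluded_from_radius(self):
        # the 500 nm gap lifts the cap but does not enter Eq.-5 geometry
        a = make_cell_shape(10.0, 5.0, adherent=True, gap=0.5)
        b = make_cell_shape(10.0, 5.0, adherent=True, gap=2.0)
        assert a.r_cap == b.r_cap and a.h == b.h
        assert b.bounds()[0][1] == pytest.approx(2.0)

    def test_contains_sphere_and_cap(self):
        cap = make_cell_shape(10.0, 5.0, adherent=True)
        pts = np.array([
            [0.0, 5.0, 0.0],       # inside
            [0.0, 0.1, 0.0],       # below the gap plane -> outside
            [0.0, 15.4, 0.0],      # just under the top (gap + h = 15.5)
            [0.0, 16.0, 0.0],      # above the top
            [10.5, 1.0, 0.0],      # outside the footprint
        ])
        assert list(cap.contains(pts)) == [True, False, True, False, False]


class TestLayout:
    def test_default_two_electrode(self):
        lay = build_mea_layout("two_electrode")
        assert len(lay.electrodes) == 2
        assert sorted(e.center[0] for e in lay.electrodes) == [-50.0, 50.0]
        assert all(e.diameter == 30.0 for e in lay.electrodes)
        assert not lay.is_four_electrode

    def test_default_four_electrode(self):
        lay = build_mea_layout({"preset": "four_electrode"})
        xs = sorted(e.center[0] for e in lay.electrodes)
        assert xs == [-150.0, -50.0, 50.0, 150.0]
        assert all(e.center[1] == 0.0 for e in lay.electrodes)
        assert lay.is_four_electrode

    @pytest.mark.parametrize("bad", [
        {"electrodes": []},
        {"electrodes": [
            {"center": [0, 0], "role": "excitation"},
            {"center": [10, 0], "role": "counter"},  # overlapping 30 µm discs
        ]},
        {"electrodes": [
            {"center": [-50, 0], "role": "excitation"},
            {"center": [50, 0], "role": "excitation"},  # duplicate role
        ]},
    ])
    def test_invalid_layouts(self, bad):
        with pytest.raises(ConfigurationError):
            build_mea_layout(bad)


class TestMesh:
    def test_cell_free_mesh_has_no_cytoplasm(self):
        mesh = generate_mesh(two_electrode_layout(), None, resolution=RES_COARSE)
        assert (mesh.region == 1).sum() == 0
        assert mesh.membrane_faces_med.shape[0] == 0
        assert set(mesh.electrode_faces) == {"E2", "E3"}

    def test_refinement_monotone_and_deterministic(self):
        lay = two_electrode_layout()
        m1 = generate_mesh(lay, None, resolution=RES_COARSE)
        m2 = generate_mesh(lay, None, resolution=RES_COARSE.refined(1))
        assert m2.n_elements > m1.n_elements
        m1b = generate_mesh(lay, None, resolution=RES_COARSE)
        assert m1.n_elements == m1b.n_elements
        assert np.array_equal(m1.nodes, m1b.nodes)
        assert np.array_equal(m1.tets, m1b.tets)

    def test_cell_mesh_topology(self):
        # adherent cell over the counter electrode: closed membrane surface,
        # non-empty cytoplasm
        cell = make_cell_shape(10.0, 5.0, adherent=True, x0=50.0)
        mesh = generate_mesh(two_electrode_layout(), cell,
                             resolution=MeshResolution(h_fine=3.0))
        assert (mesh.region == 1).sum() > 0
        assert mesh.membrane_faces_med.shape[0] > 0
        assert mesh.membrane_is_closed()
        # duplicated membrane nodes coincide geometrically
        assert np.allclose(mesh.nodes[mesh.membrane_faces_med],
                           mesh.nodes[mesh.membrane_faces_cyt])
        # cytoplasm volume approximates the cell volume
        vol = mesh.element_volumes()[mesh.region == 1].sum()
        assert vol == pytest.approx(cell.volume / mesh.symmetry_factor, rel=0.2)

    def test_mirror_symmetry(self):
        # reflecting the layout about x = 0 mirrors the mesh vertex set
        lay = build_mea_layout({"electrodes": [
            {"id": "A", "center": [50, 0], "role": "excitation"},
            {"id": "B", "center": [-10, 0], "role": "counter"},
        ]})
        mir = build_mea_layout({"electrodes": [
            {"id": "A", "center": [-50, 0], "role": "excitation"},
            {"id": "B", "center": [10, 0], "role": "counter"},
        ]})
        m1 = generate_mesh(lay, None, resolution=RES_COARSE)
        m2 = generate_mesh(mir, None, resolution=RES_COARSE)
        assert m1.n_nodes == m2.n_nodes
        v1 = np.sort(np.round(m1.nodes[:, 0], 9))
        v2 = np.sort(np.round(-m2.nodes[:, 0], 9))
        assert np.allclose(v1, v2, atol=1e-7)

    def test_cell_collisions_and_domain(self):
        lay = two_electrode_layout()
        below = CellGeometry(r0=10.0, x0=0.0, y0=5.0, z0=0.0, shape="sphere")
        with pytest.raises(MeshingError, match="substrate"):
            generate_mesh(lay, below, resolution=RES_COARSE)
        outside = CellGeometry(r0=10.0, x0=500.0, y0=20.0, z0=0.0, shape="sphere")
        with pytest.raises(MeshingError, match="outside"):
            generate_mesh(lay, outside, resolution=RES_COARSE)
        off_plane = CellGeometry(r0=10.0, x0=0.0, y0=20.0, z0=30.0, shape="sphere")
        with pytest.raises(MeshingError, match="symmetry"):
            generate_mesh(lay, off_plane, resolution=RES_COARSE)

    def test_full_domain_option(self):
        dom = SimulationDomain(symmetry="none")
        cell = CellGeometry(r0=10.0, x0=0.0, y0=20.0, z0=30.0, shape="sphere")
        mesh = generate_mesh(two_electrode_layout(), cell, dom,
                             MeshResolution(h_fine=5.0))
        assert mesh.symmetry_factor == 1.0
        assert (mesh.region == 1).sum() > 0
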