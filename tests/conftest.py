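"""Shared fixtures: coarse but physically faithful models, solved once.

The session fixtures use meshes a step coarser than the library defaults so
the whole suite stays fast; the physics checks they feed are ratio/percent
quantities that the convergence tests show are stable at this resolution.
"""

from __future__ import annotations

import numpy as np
import pytest

from mealf import (
    DriveSpec,
    FemModel,
    MeshResolution,
    compute_sensitivity,
    four_electrode_layout,
    generate_mesh,
    sensitivity_scan,
    solve_drive,
    two_electrode_layout,
)

# test-scale resolutions (coarser than library defaults; ratios stable)
RES_2E = MeshResolution(h_fine=4.0)
RES_4E = MeshResolution(h_fine=4.0, refine_x_windows=((-16.0, 216.0),))
SCAN_XS = np.arange(0.0, 105.0, 5.0)
SCAN_XS_4E = np.arange(0.0, 205.0, 5.0)
LEADFIELD_F = 100e3


@pytest.fixture(scope="session")
def two_elec_solution():
    layout = two_electrode_layout()
    mesh = generate_mesh(layout, None, resolution=RES_2E)
    model = FemModel(mesh)
    system = model.assemble(LEADFIELD_F)
    sol = solve_drive(system, DriveSpec("E2", "E3"))
    return layout, model, system, sol


@pytest.fixture(scope="session")
def two_elec_field(two_elec_solution):
    _, _, _, sol = two_elec_solution
    return compute_sensitivity(sol, sol)


@pytest.fixture(scope="session")
def two_elec_profile(two_elec_field):
    pos = np.array([(x, y) for y in (5.0, 10.0, 15.0) for x in SCAN_XS])
    return sensitivity_scan(two_elec_field, pos)


@pytest.fixture(scope="session")
def four_elec_solutions():
    layout = four_electrode_layout()
    mesh = generate_mesh(layout, None, resolution=RES_4E)
    model = FemModel(mesh)
    system = model.assemble(LEADFIELD_F)
    sol_i = solve_drive(system, DriveSpec("E1", "E4"))
    sol_e = solve_drive(system, DriveSpec("E2", "E3"))
    return layout, model, system, sol_i, sol_e


@pytest.fixture(scope="session")
def four_elec_field(four_elec_solutions):
    _, _, _, sol_i, sol_e = four_elec_solutions
    return compute_sensitivity(sol_i, sol_e)


@pytest.fixture(scope="session")
def four_elec_profile(four_elec_field):
    pos = np.array([(x, y) for y in (5.0, 15.0) for x in SCAN_XS_4E])
    return sensitivity_scan(four_elec_field, pos)


SWEEP_F = 100e3
SWEEP_POS_2E = [(40.0, 5.0), (45.0, 5.0), (50.0, 5.0), (55.0, 5.0), (60.0, 5.0),
                (70.0, 5.0), (80.0, 5.0), (50.0, 10.0), (50.0, 15.0)]
SWEEP_POS_4E = [(0.0, 5.0), (20.0, 5.0), (35.0, 5.0), (40.0, 5.0), (50.0, 5.0),
                (60.0, 5.0), (65.0, 5.0), (70.0, 5.0), (100.0, 5.0),
                (135.0, 5.0), (150.0, 5.0), (165.0, 5.0),
                (35.0, 15.0), (50.0, 15.0), (65.0, 15.0)]


@pytest.fixture(scope="session")
def two_elec_sweep():
    from mealf import position_sweep

    return position_sweep(two_electrode_layout(), SWEEP_POS_2E,
                          frequency=SWEEP_F, resolution=RES_2E)


@pytest.fixture(scope="session")
def four_elec_sweep():
    from mealf import position_sweep

    return position_sweep(four_electrode_layout(), SWEEP_POS_4E,
                          frequency=SWEEP_F, resolution=RES_4E)


@pytest.fixture(scope="session")
def spectrum_baselines():
    from mealf import simulate_four_electrode, simulate_two_electrode

    res = MeshResolution(h_fine=5.0)
    two = simulate_two_electrode(two_electrode_layout(), None, resolution=res)
    four = simulate_four_electrode(four_electrode_layout(), None, resolution=res)
    return two, four


@pytest.fixture(scope="session")
def spreading_resistance_levels():
    """Ideal-disc spreading resistance at two refinement levels (ohms)."""
    from mealf import (DriveSpec, InterfaceSet, MaterialProps,
                       SimulationDomain, build_mea_layout, solve_drive)

    sigma, a = 1.57, 15.0
    materials = MaterialProps(sigma_medium=sigma, epsr_medium=1.0)
    layout = build_mea_layout({"electrodes": [
        {"id": "D", "center": [0.0, 0.0], "diameter": 2 * a, "role": "excitation"},
        {"id": "far", "center": [700.0, 0.0], "diameter": 2 * a, "role": "counter"},
    ]})
    domain = SimulationDomain(x_extent=(-800.0, 800.0), y_extent=(0.0, 800.0),
                              z_extent=(-800.0, 800.0), outer_bc="ground")
    vals = {}
    for h in (3.0, 2.0):
        res = MeshResolution(h_fine=h, h_coarse=80.0, y_fine_top=20.0,
                             z_fine_halfwidth=20.0, extra_y_planes=())
        mesh = generate_mesh(layout, None, domain, res)
        model = FemModel(mesh, materials, InterfaceSet.ideal())
        sol = solve_drive(model.assemble(1.0), DriveSpec("D", "__outer__"))
        vals[h] = abs(sol.impedance)
    return vals, 1.0 / (4.0 * sigma * a * 1e-6)
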