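"""End-to-end two- and four-electrode impedance spectrum simulation.

Bipolar (two-electrode) measurements drive current through the same pair
used to sense voltage, so both electrode interface films enter the
measured Z = (U_exc - U_counter)/I_T.  Tetrapolar (four-electrode)
measurements drive the outer pair and sense the floating inner pair
behind their films with an ideal (infinite-impedance) amplifier:
Z = (U_rec+ - U_rec-)/I_T, which cancels the interface impedance and
yields a flat cell-free baseline.

Spectra against a cell-free baseline are reported as the normalized
magnitude change (|Z| - |Z0|)/|Z0|; position sweeps re-mesh the cell at
each location on an identical background grid so baseline discretization
error cancels in the difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MealfError
from .fem_core import DriveSpec, FemModel, InterfaceSet, solve_drive
from .geometry import (
    CellGeometry,
    MEALayout,
    MeshResolution,
    SimulationDomain,
    generate_mesh,
    make_cell_shape,
)
from .interface_models import MaterialProps

__all__ = [
    "FREQUENCIES_18",
    "ImpedanceSpectrum",
    "NormalizedSpectrum",
    "PositionSweepResult",
    "simulate_two_electrode",
    "simulate_four_electrode",
    "normalize_impedance",
    "position_sweep",
]

log = logging.getLogger(__name__)

#: the standard 18-frequency sweep, Hz
FREQUENCIES_18: tuple[float, ...] = (
    10.0, 20.0, 30.0, 40.0, 50.0, 80.0, 100.0, 200.0, 500.0,
    1e3, 2e3, 5e3, 1e4, 2e4, 5e4, 1e5, 5e5, 1e6,
)


@dataclass
class ImpedanceSpectrum:
    """Complex impedance over a frequency sweep for one configuration."""

    frequencies: np.ndarray          # (F,) Hz, strictly increasing
    z: np.ndarray                    # (F,) complex, Ω
    descriptor: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.z = np.asarray(self.z, dtype=complex)
        if self.frequencies.ndim != 1 or self.frequencies.size != self.z.size:
            raise ValueError("one impedance per frequency required")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.z)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frequency_hz": self.frequencies,
            "z_real_ohm": self.z.real,
            "z_imag_ohm": self.z.imag,
        })


@dataclass
class NormalizedSpectrum:
    """Signed normalized magnitude change (|Z| - |Z0|)/|Z0| vs frequency."""

    frequencies: np.ndarray
    z_normal: np.ndarray             # (F,) signed, dimensionless
    delta_z: np.ndarray              # (F,) complex (Z - Z0)/|Z0| for loci
    reference: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frequency_hz": self.frequencies,
            "z_normal": self.z_normal,
            "delta_re": self.delta_z.real,
            "delta_im": self.delta_z.imag,
        })


@dataclass
class PositionSweepResult:
    """Normalized impedance deviation vs cell position at a fixed frequency."""

    frequency: float
    positions: np.ndarray            # (P, 2) of (x0, y0), µm
    z_normal: np.ndarray             # (P,) signed (|Z|-|Z0|)/|Z0|
    z: np.ndarray                    # (P,) complex impedance with cell
    z_baseline: complex
    failures: list = field(default_factory=list)
    n_nodes: int = 0                 # baseline mesh size

    def value_at(self, x0: float, y0: float) -> float:
        hit = np.flatnonzero(
            (np.abs(self.positions[:, 0] - x0) < 1e-9)
            & (np.abs(self.positions[:, 1] - y0) < 1e-9)
        )
        if hit.size == 0:
            raise KeyError(f"no sweep point at ({x0}, {y0})")
        return float(self.z_normal[hit[0]])

    def percent_of_max(self, x0: float, y0: float,
                       max_subset_y: float | None = None) -> float:
        """|Z_normal| at a position as percent of the sweep maximum
        (optionally the maximum over one height only)."""
        mask = np.ones(self.positions.shape[0], dtype=bool)
        if max_subset_y is not None:
            mask = np.abs(self.positions[:, 1] - max_subset_y) < 1e-9
        peak = np.nanmax(np.abs(self.z_normal[mask]))
        return 100.0 * abs(self.value_at(x0, y0)) / peak

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x0_um": self.positions[:, 0],
            "y0_um": self.positions[:, 1],
            "z_normal": self.z_normal,
        })


def _measure(layout: MEALayout, sol) -> complex:
    if layout.is_four_electrode:
        return sol.transfer_impedance(
            layout.by_role("recording_pos").id, layout.by_role("recording_neg").id)
    return sol.impedance


def _simulate(layout: MEALayout, cell: CellGeometry | None,
              materials: MaterialProps | None, interfaces: InterfaceSet | None,
              frequencies, domain, resolution, seed: int) -> ImpedanceSpectrum:
    frequencies = np.asarray(
        FREQUENCIES_18 if frequencies is None else frequencies, dtype=float)
    mesh = generate_mesh(layout, cell, domain, resolution, seed=seed)
    model = FemModel(mesh, materials, interfaces)
    drive = DriveSpec(layout.by_role("excitation").id, layout.by_role("counter").id)
    z = np.empty(frequencies.size, dtype=complex)
    for i, f in enumerate(frequencies):
        sol = solve_drive(model.assemble(f), drive)
        z[i] = _measure(layout, sol)
        log.info("f=%.3g Hz |Z|=%.4g ohm (residual %.1e)", f, abs(z[i]), sol.residual)
    descriptor = {
        "mode": "four_electrode" if layout.is_four_electrode else "two_electrode",
        "cell": None if cell is None else {
            "r0": cell.r0, "x0": cell.x0, "y0": cell.y0, "z0": cell.z0,
            "shape": cell.shape,
        },
        "n_nodes": mesh.n_nodes,
    }
    return ImpedanceSpectrum(frequencies, z, descriptor)


def simulate_two_electrode(
    layout: MEALayout,
    cell: CellGeometry | None,
    materials: MaterialProps | None = None,
    interfaces: InterfaceSet | None = None,
    frequencies=None,
    domain: SimulationDomain | None = None,
    resolution: MeshResolution | None = None,
    seed: int = 0,
) -> ImpedanceSpectrum:
    """Bipolar impedance spectrum Z(f) = (U_exc - U_counter)/I_T."""
    if layout.is_four_electrode:
        raise MealfError("layout has recording electrodes; "
                         "use simulate_four_electrode")
    return _simulate(layout, cell, materials, interfaces, frequencies,
                     domain, resolution, seed)


def simulate_four_electrode(
    layout: MEALayout,
    cell: CellGeometry | None,
    materials: MaterialProps | None = None,
    interfaces: InterfaceSet | None = None,
    frequencies=None,
    domain: SimulationDomain | None = None,
    resolution: MeshResolution | None = None,
    seed: int = 0,
) -> ImpedanceSpectrum:
    """Tetrapolar transfer-impedance spectrum Z(f) = (U_rec+ - U_rec-)/I_T."""
    if not layout.is_four_electrode:
        raise MealfError("layout lacks recording electrodes; "
                         "use simulate_two_electrode")
    return _simulate(layout, cell, materials, interfaces, frequencies,
                     domain, resolution, seed)


def normalize_impedance(spectrum: ImpedanceSpectrum,
                        baseline: ImpedanceSpectrum) -> NormalizedSpectrum:
    """Pointwise (|Z| - |Z0|)/|Z0| against the cell-free baseline."""
    if (spectrum.frequencies.size != baseline.frequencies.size
            or not np.allclose(spectrum.frequencies, baseline.frequencies)):
        raise ValueError("spectrum and baseline frequency grids differ")
    z0 = baseline.magnitude
    if np.any(z0 == 0):
        raise ValueError("baseline impedance magnitude is zero at some frequency")
    return NormalizedSpectrum(
        frequencies=spectrum.frequencies,
        z_normal=(spectrum.magnitude - z0) / z0,
        delta_z=(spectrum.z - baseline.z) / z0,
        reference=dict(baseline.descriptor),
    )


def position_sweep(
    layout: MEALayout,
    positions,
    frequency: float = 100e3,
    r0: float = 10.0,
    *,
    adherent_below: float | None = None,
    materials: MaterialProps | None = None,
    interfaces: InterfaceSet | None = None,
    domain: SimulationDomain | None = None,
    resolution: MeshResolution | None = None,
    seed: int = 0,
) -> PositionSweepResult:
    """|Z_normal| at one frequency for a cell re-meshed at each position.

    The cell takes the shape an adhering cell would have at each height
    (volume-conserving cap for y0 <= ``adherent_below``, default r0; free
    sphere above).  The background grid is identical for the baseline and
    every position: the refinement window in x is widened to span all
    scanned positions before meshing, so baseline discretization error
    cancels in the normalized difference.  Per-position failures are
    recorded and the sweep continues.
    """
    positions = np.asarray(positions, dtype=float)
    if adherent_below is None:
        adherent_below = r0
    resolution = resolution or MeshResolution()
    pad = r0 + 6.0
    window = (positions[:, 0].min() - pad, positions[:, 0].max() + pad)
    resolution = MeshResolution(
        **{**resolution.__dict__,
           "refine_x_windows": tuple(resolution.refine_x_windows) + (window,)})

    base_mesh = generate_mesh(layout, None, domain, resolution, seed=seed)
    model = FemModel(base_mesh, materials, interfaces)
    drive = DriveSpec(layout.by_role("excitation").id, layout.by_role("counter").id)
    z0 = _measure(layout, solve_drive(model.assemble(frequency), drive))

    z = np.full(positions.shape[0], np.nan + 0j, dtype=complex)
    zn = np.full(positions.shape[0], np.nan)
    failures: list[tuple[float, float, str]] = []
    for i, (x0, y0) in enumerate(positions):
        try:
            cell = make_cell_shape(r0, y0, adherent=(0 < y0 <= adherent_below), x0=x0)
            mesh = generate_mesh(layout, cell, domain, resolution, seed=seed)
            m = FemModel(mesh, materials, interfaces)
            zi = _measure(layout, solve_drive(m.assemble(frequency), drive))
            z[i] = zi
            zn[i] = (abs(zi) - abs(z0)) / abs(z0)
            log.info("sweep (%g, %g): z_normal=%.4f", x0, y0, zn[i])
        except MealfError as exc:
            failures.append((float(x0), float(y0), str(exc)))
            log.warning("sweep point (%g, %g) failed: %s", x0, y0, exc)
    return PositionSweepResult(
        frequency=frequency, positions=positions, z_normal=zn, z=z,
        z_baseline=z0, failures=failures, n_nodes=base_mesh.n_nodes,
    )
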