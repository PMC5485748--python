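"""Deterministic fixture generation: every test input is built in-process.

Kinds:
  synthetic_electrode_spectrum — CPE+RC+R_B spectra at 26 log-spaced
      frequencies, 10 Hz – 1 MHz (the electrode characterization
      protocol), optionally with multiplicative complex noise; used by
      the circuit-fit tests.
  toy_mesh — a very coarse two-electrode mesh that assembles and solves
      in well under a second, for solver unit tests.
  reference_configs — YAML configs reproducing the default two- and
      four-electrode simulation setups.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .config import RunConfig, LayoutConfig, ResolutionConfig
from .geometry import MeshResolution, generate_mesh, two_electrode_layout
from .interface_models import ElectrodeInterfaceParams
from .io import write_msh, write_table

__all__ = ["generate_fixtures", "synthetic_electrode_spectrum", "toy_mesh",
           "FIT_FREQUENCIES_26"]

#: 26 frequencies distributed logarithmically between 10 Hz and 1 MHz
FIT_FREQUENCIES_26 = tuple(np.logspace(1, 6, 26))


def synthetic_electrode_spectrum(
    params: ElectrodeInterfaceParams | None = None,
    noise: float = 0.0,
    seed: int = 0,
    frequencies=FIT_FREQUENCIES_26,
):
    """(f, Z) pairs of the full measured-circuit model Z_el + R_B.

    ``noise`` is the std of multiplicative complex Gaussian noise
    (0.01 = 1%).
    """
    from .interface_models import electrode_interface_impedance

    params = params or ElectrodeInterfaceParams()
    f = np.asarray(frequencies, dtype=float)
    z = electrode_interface_impedance(f, params) + params.r_b
    if noise > 0:
        rng = np.random.default_rng(seed)
        z = z * (1.0 + noise * (rng.standard_normal(f.size)
                                + 1j * rng.standard_normal(f.size)))
    return f, z


def toy_mesh(seed: int = 0):
    """Tiny two-electrode mesh (coarse resolution, small bath)."""
    from .geometry import SimulationDomain

    return generate_mesh(
        two_electrode_layout(),
        None,
        SimulationDomain(x_extent=(-200., 200.), y_extent=(0., 150.),
                         z_extent=(-100., 100.)),
        MeshResolution(h_fine=10.0, h_coarse=50.0, z_fine_halfwidth=25.0),
        seed=seed,
    )


def generate_fixtures(kind: str, seed: int, out_dir: str | Path) -> list[Path]:
    """Write deterministic fixture files; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "synthetic_electrode_spectrum":
        import pandas as pd

        for noise, name in ((0.0, "clean"), (0.01, "noisy")):
            f, z = synthetic_electrode_spectrum(noise=noise, seed=seed)
            frame = pd.DataFrame({
                "frequency_hz": f, "z_real_ohm": z.real, "z_imag_ohm": z.imag,
            })
            written.append(write_table(
                out / f"electrode_spectrum_{name}.csv", frame,
                {"seed": seed, "noise": noise, "synthetic": True}))
    elif kind == "toy_mesh":
        written.append(write_msh(out / "toy_mesh.msh", toy_mesh(seed)))
    elif kind == "reference_configs":
        for preset in ("two_electrode", "four_electrode"):
            cfg = RunConfig(layout=LayoutConfig(preset=preset), seed=seed)
            p = out / f"{preset}_default.yaml"
            p.write_text(cfg.to_yaml())
            written.append(p)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written
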