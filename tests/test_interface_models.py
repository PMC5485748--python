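"""Electrode-interface and membrane film models, and the circuit fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mealf import (
    ElectrodeInterfaceParams,
    MaterialProps,
    MembraneParams,
    electrode_interface_impedance,
    fit_equivalent_circuit,
    membrane_surface_impedance,
    surface_impedance_electrode,
)
from mealf.fixtures import FIT_FREQUENCIES_26, synthetic_electrode_spectrum


class TestElectrodeInterface:
    def test_value_at_1khz(self):
        # frozen from an independent complex-arithmetic evaluation of the
        # CPE + parallel-RC circuit at 1 kHz with the default parameters
        z = electrode_interface_impedance(1e3, ElectrodeInterfaceParams())
        assert z.real == pytest.approx(115922.7748324857, rel=1e-12)
        assert z.imag == pytest.approx(-218286.05657209235, rel=1e-12)

    def test_frequency_limits(self):
        p = ElectrodeInterfaceParams()
        assert abs(electrode_interface_impedance(1e12, p)) < 1.0
        # CPE divergence toward DC: |Z| grows without bound as f -> 0+
        assert abs(electrode_interface_impedance(1e-9, p)) > 1e12
        assert (abs(electrode_interface_impedance(1e-3, p))
                > abs(electrode_interface_impedance(1.0, p)))
        with pytest.raises(ValueError):
            electrode_interface_impedance(0.0, p)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(logf=st.floats(0.0, 7.0),
           cpe_p=st.floats(0.1, 0.9),
           logr=st.floats(3.0, 8.0))
    def test_capacitive_sign(self, logf, cpe_p, logr):
        # Im(Z_el) < 0 for every positive frequency and positive parameters
        p = ElectrodeInterfaceParams(cpe_p=cpe_p, r=10.0 ** logr)
        assert electrode_interface_impedance(10.0 ** logf, p).imag < 0

    def test_magnitude_monotone_over_band(self):
        f = np.logspace(1, 6, 200)
        z = electrode_interface_impedance(f, ElectrodeInterfaceParams())
        assert np.all(np.diff(np.abs(z)) < 0)

    def test_convention_switch(self):
        p = ElectrodeInterfaceParams().with_convention("literal")
        assert p.cpe_t == pytest.approx(2.819e8)
        assert ElectrodeInterfaceParams().with_convention("fig1").cpe_t == \
            pytest.approx(2.819e-8)

    def test_surface_impedance_scaling(self):
        # z_s is the scale-free equivalent of the x10 enlarged-electrode
        # model: linear in area and in the roughness scale factor
        f, area = 1e3, np.pi * 15.0 ** 2
        p1 = ElectrodeInterfaceParams(area_scale=1.0)
        p10 = ElectrodeInterfaceParams(area_scale=10.0)
        z1 = surface_impedance_electrode(f, p1, area)
        z10 = surface_impedance_electrode(f, p10, area)
        assert z10 == pytest.approx(10.0 * z1)
        # uniformly covering the disc with z_s recovers the lumped value:
        # (1/z_s) * A integrates to 1 / (Z_el * area_scale)
        zel = electrode_interface_impedance(f, p1)
        assert (1.0 / z1) * (area * 1e-12) == pytest.approx(1.0 / zel)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ElectrodeInterfaceParams(cpe_p=1.2)
        with pytest.raises(ValueError):
            ElectrodeInterfaceParams(r=-1.0)
        with pytest.raises(ValueError):
            MaterialProps(sigma_medium=0.0)


class TestMembrane:
    def test_dc_limit_and_corner(self):
        p = MembraneParams()  # 1 mS/cm², 1 µF/cm²
        assert membrane_surface_impedance(0.0, p) == pytest.approx(1000.0)
        f_c = 1e-3 / (2 * np.pi * 1e-6)  # g_m / (2 pi c_m) ≈ 159.15 Hz
        z = membrane_surface_impedance(f_c, p)
        assert abs(z) == pytest.approx(1000.0 / np.sqrt(2.0), rel=1e-12)
        assert np.angle(z, deg=True) == pytest.approx(-45.0, abs=1e-9)

    def test_high_frequency_shorts(self):
        assert abs(membrane_surface_impedance(1e9, MembraneParams())) < 1e-2

    def test_divergence_and_validation(self):
        with pytest.raises(ValueError):
            membrane_surface_impedance(0.0, MembraneParams(g_m=0.0))
        with pytest.raises(ValueError):
            MembraneParams(c_m=0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(logf=st.floats(-1.0, 8.0), g=st.floats(0.1, 50.0), c=st.floats(0.1, 10.0))
    def test_parallel_rc_identity(self, logf, g, c):
        # the film equals the parallel-RC closed form at every frequency
        f = 10.0 ** logf
        p = MembraneParams(g_m=g, c_m=c)
        expected = 1.0 / (g * 1e-3 + 1j * 2 * np.pi * f * c * 1e-6)
        assert membrane_surface_impedance(f, p) == pytest.approx(expected, rel=1e-12)


class TestCircuitFit:
    def test_noiseless_recovery(self):
        f, z = synthetic_electrode_spectrum(noise=0.0)
        result = fit_equivalent_circuit(f, z)
        ref = ElectrodeInterfaceParams()
        for name in ("cpe_t", "cpe_p", "r", "c", "r_b"):
            got, want = getattr(result.params, name), getattr(ref, name)
            assert got == pytest.approx(want, rel=1e-3), name

    def test_noisy_recovery(self):
        # 1% multiplicative complex noise, 26 log-spaced frequencies;
        # key parameters recovered within a few percent (established by
        # Monte-Carlo simulation of this generator)
        f, z = synthetic_electrode_spectrum(noise=0.01, seed=7)
        result = fit_equivalent_circuit(f, z)
        ref = ElectrodeInterfaceParams()
        assert result.params.cpe_p == pytest.approx(ref.cpe_p, rel=0.02)
        assert result.params.cpe_t == pytest.approx(ref.cpe_t, rel=0.10)
        assert result.params.c == pytest.approx(ref.c, rel=0.10)
        assert result.params.r_b == pytest.approx(ref.r_b, rel=0.05)
        # the charge-transfer resistance is weakly identified at 1% noise:
        # its RC corner (~1.3 Hz) lies below the measured band
        assert result.params.r == pytest.approx(ref.r, rel=0.5)

    def test_pure_resistor_degenerates(self):
        f = np.asarray(FIT_FREQUENCIES_26)
        z = np.full(f.size, 5000.0 + 0.0j)
        result = fit_equivalent_circuit(f, z)
        p = result.params
        model = (p.r_b + p.r / (1 + 2j * np.pi * f * p.r * p.c)
                 + 1.0 / (p.cpe_t * (2j * np.pi * f) ** p.cpe_p))
        # the full model reproduces the flat spectrum; CPE and RC branches
        # contribute negligibly at every frequency
        assert np.allclose(np.abs(model), 5000.0, rtol=1e-3)
        assert np.all(np.abs(model - p.r_b) < 0.01 * 5000.0)

    def test_preconditions(self):
        with pytest.raises(ValueError, match="6 frequencies"):
            fit_equivalent_circuit(np.array([10.0, 1e6]), np.ones(2, complex))
        f = np.linspace(100.0, 200.0, 10)
        with pytest.raises(ValueError, match="decades"):
            fit_equivalent_circuit(f, np.ones(10, complex))
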