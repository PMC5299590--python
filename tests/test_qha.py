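"""Thermal pressure, quasi-harmonic states and free-energy curves."""

import numpy as np
import pytest

from polyphonon.fixtures import explicit_volume_minimum
from polyphonon.phonons import ThermoState
from polyphonon.qha import (DegenerateCurvesError, expansion_coefficient,
                            free_energy_curve, qha_state, thermal_pressure,
                            transition_temperature)


class TestThermalPressure:
    def test_zero_at_zero_temperature_by_default(self, fcc, fcc_min):
        # zero-point expansion is considered built into the force field
        assert thermal_pressure(fcc_min, fcc.ff, 0.0) == pytest.approx(0.0,
                                                                       abs=1e-12)

    def test_zpe_pressure_positive_on_fixture(self, fcc, fcc_min):
        p = thermal_pressure(fcc_min, fcc.ff, 0.0, include_zpe=True)
        assert p > 0

    def test_matches_dense_volume_fit(self, fcc, fcc_min):
        from polyphonon.constants import KJMOL_ANG3_TO_GPA
        from polyphonon.phonons import sample_spectrum, vib_free_energy

        T = 300.0
        p_fd = thermal_pressure(fcc_min, fcc.ff, T, grid=(3, 3, 3))
        scales = np.linspace(0.99, 1.01, 5)
        f = []
        for s in scales:
            th = vib_free_energy(
                sample_spectrum(fcc_min.scaled(s), fcc.ff, grid=(3, 3, 3)), T
            )
            f.append(th.f_vib - th.zpe)
        coef = np.polyfit(scales * fcc_min.volume, f, 2)
        slope = 2 * coef[0] * fcc_min.volume + coef[1]
        assert p_fd == pytest.approx(-slope * KJMOL_ANG3_TO_GPA, rel=0.02)

    def test_bad_step_rejected(self, fcc, fcc_min):
        with pytest.raises(ValueError):
            thermal_pressure(fcc_min, fcc.ff, 300.0, dV_frac=0.1)


class TestQHAState:
    def test_zero_kelvin_state_is_static_minimum(self, fcc, fcc_min):
        from polyphonon.energy import lattice_energy
        from polyphonon.phonons import sample_spectrum, vib_free_energy

        st = qha_state(fcc_min, fcc.ff, 0.0, grid=(3, 3, 3))
        assert st.expanded.volume == pytest.approx(fcc_min.volume, abs=1e-8)
        e_latt = lattice_energy(fcc_min, fcc.ff).e_inter
        zpe = vib_free_energy(
            sample_spectrum(fcc_min, fcc.ff, grid=(3, 3, 3)), 0.0
        ).zpe
        assert st.a_qha == pytest.approx(e_latt + zpe, abs=1e-8)

    @pytest.mark.parametrize("T", [100.0, 300.0])
    def test_matches_explicit_volume_minimisation(self, fcc, fcc_min, T):
        st = qha_state(fcc_min, fcc.ff, T, grid=(3, 3, 3))
        oracle = explicit_volume_minimum(fcc_min, fcc.ff, T, grid=(3, 3, 3))
        assert st.expanded.volume == pytest.approx(oracle["volume"], rel=0.003)
        assert st.a_qha == pytest.approx(oracle["a_min"], abs=0.05)

    def test_qha_below_harmonic(self, fcc, fcc_min):
        from polyphonon.energy import lattice_energy
        from polyphonon.phonons import sample_spectrum, vib_free_energy

        T = 300.0
        st = qha_state(fcc_min, fcc.ff, T, grid=(3, 3, 3))
        e_latt = lattice_energy(fcc_min, fcc.ff).e_inter
        a_ha = e_latt + vib_free_energy(
            sample_spectrum(fcc_min, fcc.ff, grid=(3, 3, 3)), T
        ).f_vib
        assert st.a_qha <= a_ha + 1e-6

    def test_entropy_increases_with_temperature(self, fcc, fcc_min):
        s100 = qha_state(fcc_min, fcc.ff, 100.0, grid=(2, 2, 2)).entropy
        s300 = qha_state(fcc_min, fcc.ff, 300.0, grid=(2, 2, 2)).entropy
        assert s300 > s100


class TestExpansionCoefficient:
    def test_arithmetic(self):
        assert expansion_coefficient(100.0, 105.0, 350.0) == pytest.approx(
            1.4286e-4, rel=1e-4
        )

    def test_zero_expansion(self):
        assert expansion_coefficient(50.0, 50.0, 100.0) == 0.0

    def test_micro_kelvin_convention(self):
        alpha = expansion_coefficient(100.0, 105.0, 350.0)
        assert alpha * 1e6 == pytest.approx(142.86, abs=0.01)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            expansion_coefficient(-1.0, 105.0, 350.0)
        with pytest.raises(ValueError):
            expansion_coefficient(100.0, 105.0, 0.0)

    def test_positive_on_fixture(self, fcc, fcc_min):
        st = qha_state(fcc_min, fcc.ff, 300.0, grid=(2, 2, 2))
        alpha = expansion_coefficient(fcc_min.volume, st.expanded.volume, 300.0)
        assert alpha > 0


def _node(T, A, S):
    return ThermoState(T=T, zpe=0.0, f_vib=A, entropy=S, cv=0.0, e_latt=0.0)


class TestFreeEnergyCurve:
    def test_constant_curve(self):
        curve = free_energy_curve([_node(0, 5.0, 0.0), _node(100, 5.0, 0.0)])
        assert curve(50.0) == pytest.approx(5.0)

    def test_cubic_reproduces_quadratic(self):
        b = 1e-4
        nodes = [_node(T, -b * T**2, 2 * b * T) for T in (0, 100, 200, 300)]
        curve = free_energy_curve(nodes)
        ts = np.linspace(0, 300, 61)
        np.testing.assert_allclose(curve(ts), -b * ts**2, atol=1e-12)

    def test_slope_at_node_is_minus_entropy(self):
        nodes = [_node(0, 1.0, 0.0), _node(100, 0.5, 0.012),
                 _node(200, -0.9, 0.015)]
        curve = free_energy_curve(nodes)
        np.testing.assert_allclose(curve.entropy([0.0, 100.0, 200.0]),
                                   [0.0, 0.012, 0.015], atol=1e-10)

    def test_extrapolation_rejected(self):
        curve = free_energy_curve([_node(0, 1.0, 0.0), _node(100, 0.0, 0.01)])
        with pytest.raises(ValueError):
            curve(150.0)

    def test_nodes_must_increase(self):
        with pytest.raises(ValueError):
            free_energy_curve([_node(100, 1.0, 0.0), _node(100, 0.0, 0.0)])


class TestTransitionTemperature:
    def _linear(self, a0, slope, t_hi=500.0):
        return free_energy_curve(
            [_node(0, a0, slope), _node(t_hi, a0 - slope * t_hi, slope)]
        )

    def test_constructed_crossing_at_350(self):
        # dA(T) = 1 - T/350
        ca = self._linear(1.0, 1.0 / 350.0)
        cb = self._linear(0.0, 0.0)
        roots = transition_temperature(ca, cb)
        assert len(roots) == 1
        assert roots[0] == pytest.approx(350.0, abs=0.1)

    def test_parallel_curves_never_cross(self):
        ca = self._linear(1.0, 0.01)
        cb = self._linear(0.0, 0.01)
        assert transition_temperature(ca, cb) == []

    def test_identical_curves_flagged(self):
        ca = self._linear(1.0, 0.01)
        cb = self._linear(1.0, 0.01)
        with pytest.raises(DegenerateCurvesError):
            transition_temperature(ca, cb)
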