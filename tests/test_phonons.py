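"""Dynamical matrices, spectra, DOS smoothing and harmonic thermodynamics."""

import math

import numpy as np
import pytest

from polyphonon.constants import HC_KJMOL_CM, KB_KJMOL
from polyphonon.phonons import (ForceConstants, PhononSpectrum, dos_kde,
                                sample_spectrum, vib_free_energy)


class TestDynamicalMatrix:
    def test_chain_dispersion_matches_analytic(self, chain):
        fc = ForceConstants(chain.crystal, chain.ff)
        disp = chain.oracle["dispersion_cm"]
        for k in (0.05, 0.125, 0.25, 0.375, 0.5):
            longitudinal = fc.frequencies([k, 0, 0])[-1]
            assert longitudinal == pytest.approx(disp(k), rel=1e-3)

    def test_acoustic_sum_rule_at_gamma(self, chain, fcc, fcc_min,
                                        diatomic_alpha, diatomic_beta):
        cases = [(chain.crystal, chain.ff), (fcc_min, fcc.ff),
                 (diatomic_alpha[1], diatomic_alpha[0].ff),
                 (diatomic_beta[1], diatomic_beta[0].ff)]
        for crystal, ff in cases:
            f = ForceConstants(crystal, ff).frequencies([0.0, 0.0, 0.0])
            acoustic = np.sort(np.abs(f))[:3]
            assert acoustic.max() < 0.1

    def test_time_reversal_symmetry(self, fcc, fcc_min):
        fc = ForceConstants(fcc_min, fcc.ff)
        for k in ([0.13, 0.21, -0.34], [0.5, 0.25, 0.0]):
            np.testing.assert_allclose(
                fc.frequencies(k), fc.frequencies([-x for x in k]), atol=1e-8
            )

    def test_hermitian(self, diatomic_alpha):
        fx, crystal = diatomic_alpha
        D = ForceConstants(crystal, fx.ff).dynamical_matrix([0.1, 0.2, 0.3])
        np.testing.assert_allclose(D, D.conj().T, atol=1e-10)

    def test_linear_molecule_has_five_dof(self, diatomic_alpha):
        fx, crystal = diatomic_alpha
        fc = ForceConstants(crystal, fx.ff)
        assert fc.dof == [5, 5]
        assert fc.total_dof == 10


class TestSampleSpectrum:
    def test_chain_debye_velocity(self, chain):
        spec = sample_spectrum(chain.crystal, chain.ff,
                               grid=chain.oracle["grid"])
        # acoustic probes along the transverse axes see no dispersion, so
        # compare the longitudinal probe slope instead of the 3-D average
        fc = ForceConstants(chain.crystal, chain.ff)
        recip = 2 * math.pi * np.linalg.inv(chain.crystal.lattice_vectors).T
        k = 0.02
        v_long = fc.frequencies([k, 0, 0])[-1] / (k * np.linalg.norm(recip[0]))
        assert v_long == pytest.approx(
            chain.oracle["debye_velocity_cm_ang"], rel=0.02
        )

    def test_gamma_only_grid(self, fcc, fcc_min):
        spec = sample_spectrum(fcc_min, fcc.ff, grid=(1, 1, 1))
        assert len(spec.kpoints) == 1
        assert spec.mode_count == pytest.approx(0.0)  # monatomic: all acoustic
        assert spec.n_debye_modes == pytest.approx(3.0)

    def test_grid_convergence_of_free_energy(self, fcc, fcc_min):
        f = {}
        for n in (3, 6):
            spec = sample_spectrum(fcc_min, fcc.ff, grid=(n, n, n))
            f[n] = vib_free_energy(spec, 300.0).f_vib
        assert abs(f[6] - f[3]) < 0.1

    def test_instability_raises(self, fcc, fcc_min):
        from polyphonon.phonons import InstabilityError

        stretched = fcc_min.scaled(1.5**3)
        with pytest.raises(InstabilityError):
            sample_spectrum(stretched, fcc.ff, grid=(2, 2, 2))


class TestKDE:
    def _single_mode_spectrum(self, freq=100.0, n_mol=1):
        return PhononSpectrum(
            kpoints=np.zeros((1, 3)), weights=np.ones(1),
            frequencies=[np.array([freq])],
            mode_freqs=np.array([freq]), mode_weights=np.ones(1),
            debye_velocity=0.0, omega_d=0.0, n_debye_modes=0.0,
            n_molecules=n_mol,
        )

    def test_single_kernel_normalisation(self):
        spec = self._single_mode_spectrum()
        grid = dos_kde(spec, 5.0)
        omega, g = grid[:, 0], grid[:, 1]
        assert omega[np.argmax(g)] == pytest.approx(100.0, abs=0.5)
        assert np.trapezoid(g, omega) == pytest.approx(1.0, abs=1e-6)

    def test_two_modes_integral_two(self):
        spec = self._single_mode_spectrum()
        spec.mode_freqs = np.array([80.0, 120.0])
        spec.mode_weights = np.ones(2)
        grid = dos_kde(spec, 3.0)
        assert np.trapezoid(grid[:, 1], grid[:, 0]) == pytest.approx(2.0,
                                                                     abs=1e-6)

    def test_bandwidth_must_be_positive(self):
        with pytest.raises(ValueError):
            dos_kde(self._single_mode_spectrum(), 0.0)

    def test_kde_free_energy_converges_to_discrete(self, fcc, fcc_min):
        spec = sample_spectrum(fcc_min, fcc.ff, grid=(3, 3, 3))
        ref = vib_free_energy(spec, 300.0).f_vib
        devs = []
        for bw in (3.0, 0.5):
            spec.dos_grid = dos_kde(spec, bw)
            devs.append(abs(vib_free_energy(spec, 300.0, use_kde=True).f_vib
                            - ref))
        assert devs[1] < devs[0]
        assert devs[1] < 0.01


class TestThermo:
    def test_zero_temperature_is_zpe(self, fcc, fcc_min):
        spec = sample_spectrum(fcc_min, fcc.ff, grid=(3, 3, 3))
        th = vib_free_energy(spec, 0.0)
        assert th.f_vib == pytest.approx(th.zpe, abs=1e-12)
        assert th.entropy == 0.0

    def test_single_mode_closed_form(self):
        # one mode with hw/kT = 1: F/hw = 0.5 + ln(1 - 1/e)
        freq = 100.0
        T = HC_KJMOL_CM * freq / KB_KJMOL  # makes x = 1
        spec = TestKDE()._single_mode_spectrum(freq)
        th = vib_free_energy(spec, T)
        hw = HC_KJMOL_CM * freq
        assert th.f_vib / hw == pytest.approx(0.5 + math.log(1 - math.exp(-1)),
                                              rel=1e-10)
        assert th.f_vib / hw == pytest.approx(0.04131, abs=5e-5)

    def test_entropy_matches_minus_dF_dT(self, fcc, fcc_min):
        spec = sample_spectrum(fcc_min, fcc.ff, grid=(3, 3, 3))
        for T in (100.0, 300.0):
            dT = 0.1
            fp = vib_free_energy(spec, T + dT).f_vib
            fm = vib_free_energy(spec, T - dT).f_vib
            S = vib_free_energy(spec, T).entropy
            assert S == pytest.approx(-(fp - fm) / (2 * dT), abs=1e-6)

    def test_debye_t3_law(self, fcc, fcc_min):
        spec = sample_spectrum(fcc_min, fcc.ff, grid=(3, 3, 3))
        x_d = HC_KJMOL_CM * spec.omega_d / KB_KJMOL  # K at x_D = 1
        T = x_d / 60.0  # deep quantum regime for the Debye term
        cv1 = vib_free_energy(spec, T).cv
        cv2 = vib_free_energy(spec, 2 * T).cv
        assert 7.6 <= cv2 / cv1 <= 8.0

    def test_classical_limit_equipartition(self):
        spec = TestKDE()._single_mode_spectrum(freq=10.0)
        T = HC_KJMOL_CM * 10.0 / KB_KJMOL / 0.05  # x = 0.05
        th = vib_free_energy(spec, T)
        assert th.cv == pytest.approx(KB_KJMOL, rel=0.01)

    def test_negative_temperature_rejected(self, fcc, fcc_min):
        spec = sample_spectrum(fcc_min, fcc.ff, grid=(2, 2, 2))
        with pytest.raises(ValueError):
            vib_free_energy(spec, -1.0)

    def test_mean_frequency_softens_on_expansion(self, fcc, fcc_min):
        s0 = sample_spectrum(fcc_min, fcc.ff, grid=(3, 3, 3))
        s1 = sample_spectrum(fcc_min.scaled(1.03), fcc.ff, grid=(3, 3, 3))
        assert s1.mode_freqs.mean() < s0.mode_freqs.mean()
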