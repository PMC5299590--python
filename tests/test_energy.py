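"""Pair energies, lattice sums and Ewald electrostatics.

The Madelung oracles are direct summations (Evjen charge-weighted cubes),
independent of the Ewald code path.
"""

import math

import numpy as np
import pytest

from polyphonon.constants import COULOMB_KJMOL_ANG
from polyphonon.energy import ewald_energy, lattice_energy, pair_energy
from polyphonon.forcefield import ForceField, PairParams
from polyphonon.structures import Atom, Crystal


def rock_salt(spacing=1.0):
    pos = {(0, 0, 0): 1, (.5, .5, 0): 1, (.5, 0, .5): 1, (0, .5, .5): 1,
           (.5, 0, 0): -1, (0, .5, 0): -1, (0, 0, .5): -1, (.5, .5, .5): -1}
    atoms = [Atom("Na" if q > 0 else "Cl", 23.0, np.array(f), float(q))
             for f, q in pos.items()]
    return Crystal(np.eye(3) * 2 * spacing, atoms)


def cscl(spacing=1.0):
    a = 2 * spacing / math.sqrt(3)
    atoms = [Atom("Cs", 132.9, [0, 0, 0], 1.0),
             Atom("Cl", 35.45, [.5, .5, .5], -1.0)]
    return Crystal(np.eye(3) * a, atoms)


def evjen_madelung(structure: str, n_cells: int = 8) -> float:
    """Direct-summation Madelung constant with Evjen boundary weights."""
    total = 0.0
    if structure == "nacl":
        rng = range(-n_cells, n_cells + 1)
        for i in rng:
            for j in rng:
                for k in rng:
                    if i == j == k == 0:
                        continue
                    w = 1.0
                    for t in (i, j, k):
                        if abs(t) == n_cells:
                            w *= 0.5
                    q = (-1.0) ** (i + j + k)
                    total += w * q / math.sqrt(i * i + j * j + k * k)
        return -total
    raise ValueError(structure)


class TestPairEnergy:
    def test_exp6_hand_value(self):
        p = PairParams(1000.0, 3.0, 100.0)
        expect = 1000.0 * math.exp(-12.0) - 100.0 / 4096.0
        assert pair_energy(p, 0.0, 0.0, 4.0) == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(-0.01827, abs=5e-5)

    def test_coulomb_constant(self):
        p = PairParams(0.0, 1.0, 0.0)
        assert pair_energy(p, 1.0, 1.0, 1.0) == pytest.approx(1389.35, abs=0.01)

    def test_null_interaction(self):
        p = PairParams(0.0, 1.0, 0.0)
        for r in (0.5, 1.0, 7.3):
            assert pair_energy(p, 0.0, 0.0, r) == 0.0

    def test_zero_distance_is_error(self):
        with pytest.raises(ValueError):
            pair_energy(PairParams(1.0, 1.0, 1.0), 0.0, 0.0, 0.0)


class TestEwald:
    def test_nacl_madelung_vs_direct_sum(self):
        c = rock_salt()
        e = ewald_energy(c, accuracy=1e-8)
        mad = -e / 4 / COULOMB_KJMOL_ANG  # 4 ion pairs, spacing 1 Å
        assert mad == pytest.approx(1.747565, abs=1e-5)
        assert mad == pytest.approx(evjen_madelung("nacl"), abs=1e-4)

    def test_cscl_madelung(self):
        e = ewald_energy(cscl(), accuracy=1e-8)
        assert -e / COULOMB_KJMOL_ANG == pytest.approx(1.762675, abs=1e-5)

    def test_independent_of_splitting_parameter(self):
        c = rock_salt()
        e1 = ewald_energy(c, accuracy=1e-8, alpha=1.0)
        e2 = ewald_energy(c, accuracy=1e-8, alpha=2.0)
        assert e2 == pytest.approx(e1, abs=1e-5)

    def test_zero_charges_give_zero(self):
        c = rock_salt()
        assert ewald_energy(c, charges=np.zeros(8)) == 0.0

    def test_net_charge_rejected(self):
        c = rock_salt()
        with pytest.raises(ValueError):
            ewald_energy(c, charges=np.ones(8))


class TestLatticeEnergy:
    def test_isolated_molecule_noninteracting(self):
        lat = np.eye(3) * 100.0
        atoms = [Atom("C", 12.0, [0.5, 0.5, 0.5], 0.1, "C1"),
                 Atom("O", 16.0, [0.511, 0.5, 0.5], -0.1, "O1")]
        c = Crystal(lat, atoms, [[0, 1]])
        p = PairParams(1e5, 3.6, 2000.0)
        ff = ForceField({("C1", "C1"): p, ("O1", "O1"): p, ("C1", "O1"): p},
                        com_cutoff=20.0)
        e = lattice_energy(c, ff)
        assert e.e_rep_disp == pytest.approx(0.0, abs=1e-10)
        assert abs(e.e_elec) < 1e-4  # Ewald tolerance for an isolated dipole

    def test_translation_invariance(self, fcc, fcc_min):
        e0 = lattice_energy(fcc_min, fcc.ff).e_inter
        shifted = fcc_min.replace_geometry(
            fcc_min.lattice_vectors, fcc_min.cart_coords + [0.37, -1.2, 0.55]
        )
        assert lattice_energy(shifted, fcc.ff).e_inter == pytest.approx(
            e0, abs=1e-8
        )

    def test_rotation_invariance(self, fcc, fcc_min):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec([0.3, -0.2, 0.9]).as_matrix()
        rot = fcc_min.replace_geometry(
            fcc_min.lattice_vectors @ R.T, fcc_min.cart_coords @ R.T
        )
        if np.linalg.det(rot.lattice_vectors) < 0:
            pytest.skip("rotation flipped handedness")
        e0 = lattice_energy(fcc_min, fcc.ff).e_inter
        assert lattice_energy(rot, fcc.ff).e_inter == pytest.approx(e0, abs=1e-8)

    def test_breakdown_sums(self, diatomic_alpha):
        fx, crystal = diatomic_alpha
        e = lattice_energy(crystal, fx.ff)
        assert e.e_inter == pytest.approx(e.e_rep_disp + e.e_elec, abs=1e-10)

    def test_pv_term(self, fcc, fcc_min):
        from polyphonon.constants import GPA_TO_KJMOL_ANG3

        e = lattice_energy(fcc_min, fcc.ff, pressure=1.0)
        assert e.pv_term == pytest.approx(
            GPA_TO_KJMOL_ANG3 * fcc_min.volume, rel=1e-12
        )

    def test_overlap_raises_geometry_error(self):
        from polyphonon.energy import GeometryError

        lat = np.eye(3) * 5.0
        atoms = [Atom("C", 12.0, [0.0, 0.0, 0.0], 0.0, "C1"),
                 Atom("C", 12.0, [0.005, 0.0, 0.0], 0.0, "C1")]
        c = Crystal(lat, atoms, [[0], [1]])
        ff = ForceField({("C1", "C1"): PairParams(1e5, 3.6, 2000.0)},
                        com_cutoff=10.0)
        with pytest.raises(GeometryError):
            lattice_energy(c, ff)


def test_combining_rules_logged(caplog):
    p1 = PairParams(100.0, 3.0, 10.0)
    p2 = PairParams(400.0, 5.0, 40.0)
    ff = ForceField({("A", "A"): p1, ("B", "B"): p2})
    import logging

    with caplog.at_level(logging.WARNING):
        cross = ff.get_pair("A", "B")
    assert cross.A == pytest.approx(200.0)
    assert cross.B == pytest.approx(4.0)
    assert cross.C == pytest.approx(20.0)
    assert "combining rules" in caplog.text


def test_forcefield_file_round_trip(tmp_path):
    from polyphonon.forcefield import read_forcefield, write_forcefield

    p = tmp_path / "ff.txt"
    p.write_text("""# toy force field
[types]
C1 C 12.011 0.15
O1 O 15.999 -0.15
[pairs]
C1 C1 1.0e5 3.6 2000.0
C1 O1 1.1e5 3.6 2100.0
O1 O1 1.2e5 3.6 2200.0
""")
    ff = read_forcefield(p)
    assert ff.charges["O1"] == -0.15
    assert ff.get_pair("O1", "C1").A == pytest.approx(1.1e5)
    p2 = tmp_path / "ff2.txt"
    write_forcefield(ff, p2)
    ff2 = read_forcefield(p2)
    assert ff2.pair_params == ff.pair_params
    assert ff2.charges == ff.charges
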