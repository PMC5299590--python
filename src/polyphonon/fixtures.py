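"""Deterministic toy crystals and synthetic datasets with built-in oracles.

Every generator returns a :class:`Fixture` bundling a crystal, a force field
and an ``oracle`` mapping of independently computable reference quantities
(analytic dispersion relations, explicit energy-volume grids, distribution
parameters).  Force constants are chosen so lattice-mode frequencies fall in
the 10-200 cm^-1 range typical of organic molecular crystals, which keeps the
toy thermodynamics in a realistic regime.  No fixture reads external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energy import lattice_energy
from .forcefield import ForceField, PairParams
from .phonons import sample_spectrum, vib_free_energy
from .polymorphs import PolymorphPair
from .structures import Atom, Crystal

__all__ = [
    "Fixture",
    "chain_1d",
    "exp6_fcc",
    "rigid_diatomic_crystal",
    "synthetic_pair_ensemble",
    "explicit_volume_minimum",
]


@dataclass
class Fixture:
    """A test crystal, its force field and named reference quantities."""

    name: str
    crystal: Crystal
    ff: ForceField
    oracle: dict = field(default_factory=dict)


def _tension_exp6(kappa: float, a: float, Ba: float = 10.0,
                  gamma: float = 0.9) -> PairParams:
    """exp-6 parameters with phi''(a) = kappa and the bond under tension.

    gamma < 1 sets the ratio of repulsive to dispersive force at r = a, so
    phi'(a) = (1 - gamma) 6C/a^7 > 0 (transverse branches stay real).
    """
    B = Ba / a
    C = kappa * a**8 / (6.0 * gamma * Ba - 42.0)
    A = gamma * 6.0 * C / (B * a**7 * math.exp(-Ba))
    return PairParams(A, B, C)


def chain_1d(kappa: float = 40.0, m: float = 14.0, a: float = 4.0,
             n: int = 8) -> Fixture:
    """Monatomic chain with nearest-neighbour coupling kappa (kJ/mol/Å²).

    The chain runs along x inside a 3-D cell with wide transverse spacing;
    the COM cutoff of 1.5a restricts interactions to nearest neighbours, so
    the longitudinal dispersion is exactly
    omega(k) = 2 sqrt(kappa/m) |sin(k a / 2)|.  ``n`` is the number of cells
    to sample along the chain (grid (n, 1, 1)).
    """
    if min(kappa, m, a) <= 0:
        raise ValueError("kappa, m and a must be positive")
    if n < 2:
        raise ValueError("need at least 2 cells along the chain")
    p = _tension_exp6(kappa, a)
    lat = np.diag([a, 3.0 * a, 3.0 * a])
    crystal = Crystal(lat, [Atom("C", m, [0.0, 0.0, 0.0], 0.0, "X")])
    ff = ForceField({("X", "X"): p}, com_cutoff=1.5 * a, ewald_accuracy=1e-8)
    from .constants import FREQ_CM_PER_SQRT

    def dispersion(k_reduced):
        return (2.0 * math.sqrt(kappa / m) * FREQ_CM_PER_SQRT
                * np.abs(np.sin(math.pi * np.asarray(k_reduced))))

    return Fixture(
        name="chain_1d",
        crystal=crystal,
        ff=ff,
        oracle={
            "kappa": kappa,
            "mass": m,
            "spacing": a,
            "grid": (n, 1, 1),
            "dispersion_cm": dispersion,
            "debye_velocity_cm_ang": a * math.sqrt(kappa / m) * FREQ_CM_PER_SQRT,
        },
    )


def exp6_fcc(a_param: float = 1.5894e6, b_param: float = 3.0,
             c_param: float = 8.0e4, mass: float = 83.798,
             r_nn: float = 4.0) -> Fixture:
    """Monatomic fcc exp-6 crystal near its static minimum.

    The defaults put the isolated-pair minimum at 4.0 Å with a well depth of
    about 10 kJ/mol, binding the lattice strongly enough that it stays well
    inside its spinodal under the thermal pressures reached by 400 K, while
    the krypton-like mass keeps the phonons in the molecular lattice-mode
    range (roughly 50-130 cm^-1).  The primitive (rhombohedral) cell holds
    one atom.  The COM cutoff sits mid-gap between the third and fourth
    neighbour shells, so no shell crosses it over the volume range explored
    by thermal expansion and the truncated energy surface stays smooth in V.
    """
    if a_param <= 0 or c_param <= 0:
        raise ValueError("need A > 0 and C > 0 for a bound exp-6 minimum")
    ac = r_nn * math.sqrt(2.0)
    lat = 0.5 * ac * np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
    crystal = Crystal(lat, [Atom("Kr", mass, [0.0, 0.0, 0.0], 0.0, "KR")])
    ff = ForceField(
        {("KR", "KR"): PairParams(a_param, b_param, c_param)},
        com_cutoff=7.45, ewald_accuracy=1e-8,
    )
    return Fixture(
        name="exp6_fcc",
        crystal=crystal,
        ff=ff,
        oracle={"r_nn": r_nn, "mass": mass},
    )


# Relaxed geometries of the two rigid-diatomic packings, frozen from a
# stability search over candidate layered/herringbone arrangements at the
# default parameters.  Both are genuine minima: all phonons real on a dense
# k-scan and positive-definite elastic tensors.  "alpha" descends from an
# ac-layered antiparallel start, "beta" from a body-centred antiparallel one;
# they relax to distinct triclinic packings 0.8 kJ/mol apart.
_DIATOMIC_PACKINGS: dict[str, dict] = {
    "alpha": {
        "lattice": [[4.226424, 0.0, 0.0],
                    [-1.427122, 3.166649, 0.0],
                    [1.318548, 0.594155, 5.750373]],
        "coms": [(0.036560, 0.010660, 0.998206),
                 (0.994656, 0.489703, 0.503442)],
        "axes": [(0.894658, 0.403297, -0.192197),
                 (-0.894658, -0.403296, 0.192197)],
    },
    "beta": {
        "lattice": [[4.242522, 0.0, 0.0],
                    [0.0, 3.461291, 0.0],
                    [-1.469164, 0.0, 5.255918]],
        "coms": [(0.030366, 0.999970, 0.994636),
                 (0.500990, 0.499970, 0.506946)],
        "axes": [(0.910698, 0.0, -0.413073),
                 (-0.910698, 0.0, 0.413073)],
    },
}


def rigid_diatomic_crystal(bond: float = 1.1, q: float = 0.15,
                           packing: str = "alpha") -> Fixture:
    """A rigid heteronuclear diatomic (CO-like) crystal in one of two packings.

    Packings "alpha" and "beta" are two distinct antiparallel layered
    arrangements (two molecules per cell) of the same rigid molecule; they
    form a synthetic polymorph pair about 0.8 kJ/mol apart in lattice energy.
    Charges are +-q on the two atoms (neutral cell); each molecule
    contributes 3 translational and 2 librational modes (a linear rigid body
    has no axial rotation).
    """
    if packing not in _DIATOMIC_PACKINGS:
        raise ValueError(f"unknown packing {packing!r}; "
                         f"choose from {sorted(_DIATOMIC_PACKINGS)}")
    if bond <= 0:
        raise ValueError("bond length must be positive")
    pk = _DIATOMIC_PACKINGS[packing]
    lat = np.array(pk["lattice"], dtype=float)
    inv = np.linalg.inv(lat)
    axes = pk["axes"]
    atoms: list[Atom] = []
    units: list[list[int]] = []
    for i, (f, ax) in enumerate(zip(pk["coms"], axes)):
        com = np.asarray(f, dtype=float) @ lat
        ax = np.asarray(ax, dtype=float)
        ax = ax / np.linalg.norm(ax)
        atoms.append(Atom("C", 12.011, (com - 0.5 * bond * ax) @ inv, q, "C1"))
        atoms.append(Atom("O", 15.999, (com + 0.5 * bond * ax) @ inv, -q, "O1"))
        units.append([2 * i, 2 * i + 1])
    crystal = Crystal(lat, atoms, units)

    B, C = 3.6, 6000.0
    r0 = 3.6
    A = 6.0 * C * math.exp(B * r0) / (B * r0**7)
    pp = PairParams(A, B, C)
    ff = ForceField(
        {("C1", "C1"): pp, ("O1", "O1"): pp, ("C1", "O1"): pp},
        charges={"C1": q, "O1": -q},
        masses={"C1": 12.011, "O1": 15.999},
        elements={"C1": "C", "O1": "O"},
        com_cutoff=15.0,
        ewald_accuracy=1e-9,
    )
    return Fixture(
        name=f"rigid_diatomic_{packing}",
        crystal=crystal,
        ff=ff,
        oracle={"bond": bond, "charge": q, "packing": packing},
    )


def synthetic_pair_ensemble(n: int, sigma_dd: float = 0.42,
                            seed: int = 0) -> list[PolymorphPair]:
    """Synthetic polymorph-pair energy differences (kJ/mol per molecule).

    Emulates the statistical structure of a large polymorph survey: static
    lattice-energy differences ~ N(0, 2.0), zero-point differences
    ~ N(0, 0.5), harmonic thermal-vibration differences at melting
    ~ N(0, 1.0), and a thermal-expansion (QHA - HA) contribution
    ~ N(0, sigma_dd).  Melting points ~ N(410, 35) K.  Deterministic for a
    given seed.
    """
    if n < 1:
        raise ValueError("need n >= 1 pairs")
    rng = np.random.default_rng(seed)
    d_elatt = rng.normal(0.0, 2.0, n)
    d_zpe = rng.normal(0.0, 0.5, n)
    d_harm = rng.normal(0.0, 1.0, n)
    d_qha = rng.normal(0.0, sigma_dd, n) if sigma_dd > 0 else np.zeros(n)
    t_m = np.clip(rng.normal(410.0, 35.0, n), 250.0, 600.0)
    pairs = []
    for i in range(n):
        d_a0 = d_elatt[i] + d_zpe[i]
        pair = PolymorphPair(
            id_a=f"P{i:04d}a", id_b=f"P{i:04d}b",
            d_elatt=float(d_elatt[i]),
            d_a0=float(d_a0),
            d_a_tm=float(d_a0 + d_harm[i] + d_qha[i]),
            t_m=float(t_m[i]),
        )
        pairs.append(pair.classify())
    return pairs


def explicit_volume_minimum(
    crystal: Crystal,
    ff: ForceField,
    T: float,
    v_lo: float = 0.98,
    v_hi: float = 1.08,
    n_points: int = 15,
    grid: tuple[int, int, int] = (3, 3, 3),
    include_zpe: bool = False,
) -> dict:
    """Independent QHA oracle: minimise E_latt(V) + F_vib(V, T) on a V grid.

    Scales the reference crystal isotropically over ``n_points`` volumes,
    evaluates the static energy and the harmonic vibrational free energy at
    each, and refines the discrete minimum with a local quadratic fit.
    Returns the refined volume and free energy per molecule.
    """
    scales = np.linspace(v_lo, v_hi, n_points)
    V = crystal.volume
    a_obj = np.empty(n_points)   # objective: E + thermal part of F_vib
    a_full = np.empty(n_points)  # E + full F_vib (reported free energy)
    for i, s in enumerate(scales):
        c = crystal.scaled(s)
        e = lattice_energy(c, ff).e_inter
        th = vib_free_energy(sample_spectrum(c, ff, grid=grid), T)
        f = th.f_vib if include_zpe else th.f_vib - th.zpe
        a_obj[i] = e + f
        a_full[i] = e + th.f_vib
    i0 = int(np.argmin(a_obj))
    i0 = min(max(i0, 1), n_points - 2)
    x = scales[i0 - 1:i0 + 2] * V
    coef = np.polyfit(x, a_obj[i0 - 1:i0 + 2], 2)
    v_min = -coef[1] / (2.0 * coef[0])
    a_min = float(np.polyval(np.polyfit(x, a_full[i0 - 1:i0 + 2], 2), v_min))
    return {
        "volume": float(v_min),
        "a_min": a_min,
        "volumes": scales * V,
        "free_energies": a_full,
        "objective": a_obj,
    }
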