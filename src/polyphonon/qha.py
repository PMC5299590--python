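"""Thermal-pressure quasi-harmonic approximation.

The thermal pressure P_th(T) = -dF_vib/dV is evaluated by central finite
difference of the vibrational free energy over isotropically scaled cells
(rigid-unit geometry fixed, COMs scaled affinely).  A static optimisation at
the external pressure -P_th then yields the thermally expanded structure, on
which the phonon spectrum is recomputed to give

    A_QHA(T) = E_latt(T) + F_vib(T).

The empirical exp-6 force field is fitted to low-temperature crystal
structures, so zero-point expansion is considered built in: by default the
zero-point part of F_vib is excluded from the thermal pressure (P_th(0) = 0
and the T = 0 QHA structure is the static minimum, A_QHA(0) = E_latt + ZPE).
Pass ``include_zpe=True`` to drive expansion with the full F_vib.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicHermiteSpline
from scipy.optimize import brentq

from .constants import KJMOL_ANG3_TO_GPA
from .energy import lattice_energy
from .forcefield import ForceField
from .optimizer import optimize
from .phonons import ThermoState, sample_spectrum, vib_free_energy
from .structures import Crystal

__all__ = [
    "QHAResult",
    "FreeEnergyCurve",
    "DegenerateCurvesError",
    "thermal_pressure",
    "qha_state",
    "expansion_coefficient",
    "free_energy_curve",
    "transition_temperature",
]


class DegenerateCurvesError(ValueError):
    """Two free-energy curves are identical: no meaningful crossing."""


@dataclass
class QHAResult:
    """Quasi-harmonic state at one temperature (energies kJ/mol per molecule)."""

    T: float
    p_thermal: float        # GPa
    expanded: Crystal
    e_latt_T: float
    f_vib_T: float
    entropy: float          # kJ/mol/K
    zpe: float
    alpha_v: float | None = None  # 1/K vs the 0 K reference, if attached

    @property
    def a_qha(self) -> float:
        return self.e_latt_T + self.f_vib_T


def _fvib_per_cell(crystal: Crystal, ff: ForceField, T: float,
                   grid, include_zpe: bool) -> float:
    spec = sample_spectrum(crystal, ff, grid=grid)
    th = vib_free_energy(spec, T)
    f = th.f_vib if include_zpe else th.f_vib - th.zpe
    return f * crystal.n_molecules


def thermal_pressure(
    crystal: Crystal,
    ff: ForceField,
    T: float,
    dV_frac: float = 0.005,
    grid: tuple[int, int, int] = (3, 3, 3),
    include_zpe: bool = False,
) -> float:
    """P_th(T) = -dF_vib/dV in GPa, by central difference over +-dV_frac.

    Positive when the modes soften on expansion (the usual case).  Raises if
    the scaled structures are dynamically unstable.
    """
    if not 0.0 < dV_frac <= 0.02:
        raise ValueError("dV_frac must be in (0, 0.02]")
    V = crystal.volume
    fp = _fvib_per_cell(crystal.scaled(1.0 + dV_frac), ff, T, grid, include_zpe)
    fm = _fvib_per_cell(crystal.scaled(1.0 - dV_frac), ff, T, grid, include_zpe)
    dfdv = (fp - fm) / (2.0 * V * dV_frac)
    return -dfdv * KJMOL_ANG3_TO_GPA


def qha_state(
    crystal: Crystal,
    ff: ForceField,
    T: float,
    grid: tuple[int, int, int] = (3, 3, 3),
    dV_frac: float = 0.005,
    include_zpe: bool = False,
    opt_tol: float = 1e-4,
) -> QHAResult:
    """One quasi-harmonic state: expand at -P_th(T), re-evaluate phonons.

    ``crystal`` must be the optimised 0 K reference minimum; the thermal
    pressure is taken at that fixed reference (single pass).
    """
    p_th = thermal_pressure(crystal, ff, T, dV_frac=dV_frac, grid=grid,
                            include_zpe=include_zpe)
    if abs(p_th) > 0.0:
        res = optimize(crystal, ff, pressure=-p_th, tol=opt_tol)
        expanded = res.crystal
    else:
        expanded = crystal
    spec = sample_spectrum(expanded, ff, grid=grid)
    e_latt = lattice_energy(expanded, ff).e_inter
    th = vib_free_energy(spec, T, e_latt=e_latt)
    return QHAResult(
        T=T, p_thermal=p_th, expanded=expanded,
        e_latt_T=e_latt, f_vib_T=th.f_vib, entropy=th.entropy, zpe=th.zpe,
    )


def expansion_coefficient(v0: float, vT: float, dT: float) -> float:
    """Volumetric expansion coefficient alpha_V = (vT - v0)/(v0 dT), in 1/K."""
    if v0 <= 0 or dT <= 0:
        raise ValueError("v0 and dT must be positive")
    return (vT - v0) / (v0 * dT)


@dataclass
class FreeEnergyCurve:
    """Piecewise-cubic Hermite A(T) with exact node slopes dA/dT = -S."""

    temperatures: np.ndarray
    free_energies: np.ndarray
    entropies: np.ndarray
    _spline: CubicHermiteSpline

    def __call__(self, T):
        T = np.asarray(T, dtype=float)
        if np.any(T < self.temperatures[0] - 1e-9) or np.any(
            T > self.temperatures[-1] + 1e-9
        ):
            raise ValueError("temperature outside the interpolation range")
        return self._spline(T)

    def entropy(self, T):
        return -self._spline.derivative()(np.asarray(T, dtype=float))

    @property
    def t_range(self) -> tuple[float, float]:
        return float(self.temperatures[0]), float(self.temperatures[-1])


def free_energy_curve(states: list) -> FreeEnergyCurve:
    """Hermite interpolant through (T, A, S) nodes of QHA or harmonic states.

    Accepts :class:`QHAResult` or :class:`~polyphonon.phonons.ThermoState`
    nodes; slopes are the analytic -S, so the interpolant's derivative at
    every node equals minus the computed entropy exactly.
    """
    if len(states) < 2:
        raise ValueError("need at least two temperature nodes")
    T = np.array([s.T for s in states], dtype=float)
    if np.any(np.diff(T) <= 0):
        raise ValueError("temperatures must be strictly increasing")
    A = np.array(
        [s.a_qha if isinstance(s, QHAResult) else s.a_ha for s in states]
    )
    S = np.array([s.entropy for s in states])
    spline = CubicHermiteSpline(T, A, -S)
    return FreeEnergyCurve(T, A, S, spline)


def transition_temperature(
    curve_a: FreeEnergyCurve,
    curve_b: FreeEnergyCurve,
    tol: float = 1e-12,
) -> list[float]:
    """Temperatures where the two free-energy curves cross, sorted.

    Returns an empty list when dA never changes sign over the overlapping
    range; raises :class:`DegenerateCurvesError` for identical curves.
    """
    lo = max(curve_a.t_range[0], curve_b.t_range[0])
    hi = min(curve_a.t_range[1], curve_b.t_range[1])
    if hi <= lo:
        raise ValueError("curves have no overlapping temperature range")
    ts = np.linspace(lo, hi, 2001)
    d = curve_a(ts) - curve_b(ts)
    if np.all(np.abs(d) < tol):
        raise DegenerateCurvesError("free-energy curves are identical")
    roots = []
    sign = np.sign(d)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        roots.append(brentq(lambda t: curve_a(t) - curve_b(t), ts[i], ts[i + 1]))
    for t in ts[np.abs(d) < tol]:  # tangential touches on the mesh
        if not any(abs(t - r) < 1e-6 * max(1.0, hi) for r in roots):
            roots.append(float(t))
    return sorted(roots)
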