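"""Rigid-body + unit-cell lattice-energy minimisation at external pressure.

Minimises the enthalpy E_latt + P.V over the 6 independent entries of a
triangular lattice matrix (which pins the global orientation) plus, per rigid
unit, a centre-of-mass translation and a rotation.  The first unit's
translation is held fixed to remove uniform drift.  Rotations are
parametrised as rotation vectors composed onto the starting orientation;
rotation axes with zero inertia (single atoms, the axis of a linear molecule)
are excluded.  Gradients are central finite differences; updates are
quasi-Newton (BFGS).

A structure that collapses or explodes under the applied pressure (volume
change beyond 50%, or a COM displacement beyond 3 Å) raises
:class:`DrasticChangeError`, mirroring the exclusion of structures that are
unstable at their thermal pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .constants import GPA_TO_KJMOL_ANG3
from .energy import lattice_energy
from .forcefield import ForceField
from .structures import Crystal

__all__ = ["OptimizationResult", "StabilityReport", "DrasticChangeError",
           "optimize", "check_stability"]

FD_STEP = 1e-4  # Å / rad / cell entry


class DrasticChangeError(RuntimeError):
    """The optimiser left the basin of the starting structure."""


@dataclass
class OptimizationResult:
    crystal: Crystal
    enthalpy: float          # kJ/mol per molecule, E_latt + P V
    gradient_norm: float     # max |dH/dq|, kJ/mol per unit coordinate
    n_iterations: int
    converged: bool


@dataclass
class StabilityReport:
    """Diagnostics of mechanical and dynamical stability at a stationary point."""

    gamma_frequencies: np.ndarray   # cm^-1
    min_optic_frequency: float      # cm^-1, beyond the 3 acoustic zeros
    elastic_positive_definite: bool
    stable: bool


class _RigidBodyProblem:
    """Parametrisation of (cell, COM translations, orientations)."""

    def __init__(self, crystal: Crystal, ff: ForceField, pressure: float,
                 relax_cell: bool, pair_list=None):
        self.ff = ff
        self.pressure = pressure
        self.relax_cell = relax_cell
        # canonicalise to a lower-triangular lattice (rigid rotation of the
        # whole crystal; energies are rotation invariant)
        G = crystal.lattice_vectors @ crystal.lattice_vectors.T
        L = np.linalg.cholesky(G)
        R = np.linalg.inv(crystal.lattice_vectors) @ L  # rotation matrix
        cart = crystal.cart_coords @ R
        crystal = crystal.replace_geometry(L, cart)

        self.template = crystal
        self.lat0 = L
        M = crystal.n_molecules
        self.offsets = []          # atom offsets from COM, rigid, Cartesian
        self.com_frac = np.empty((M, 3))
        self.rot_axes = []         # list of (3, n_rot) free rotation axes
        inv = np.linalg.inv(L)
        for u in range(M):
            unit = crystal.rigid_unit(u)
            pos = crystal.unit_positions(u)
            self.offsets.append(pos - unit.com)
            self.com_frac[u] = unit.com @ inv
            evals, evecs = np.linalg.eigh(unit.inertia_tensor)
            free = evals > 1e-8 * max(evals.max(), 1.0)
            self.rot_axes.append(evecs[:, free])
        self.n_units = M

        self.tri = [(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]
        n = (6 if relax_cell else 0) + 3 * (M - 1) + sum(
            a.shape[1] for a in self.rot_axes
        )
        self.n_params = n
        # frozen molecule-pair image list: keeps the surface smooth while
        # coordinates move (the sharp COM cutoff is re-applied afterwards);
        # derivative drivers (elastic tensors) pass one shared list so their
        # finite differences see a single consistent truncation
        from .energy import FrozenPairList

        self.pairs = pair_list or FrozenPairList(self.template, ff)
        self.vol0 = self.template.volume

    def initial(self) -> np.ndarray:
        x = np.zeros(self.n_params)
        if self.relax_cell:
            x[:6] = [self.lat0[i, j] for i, j in self.tri]
        return x

    def build(self, x: np.ndarray) -> Crystal:
        pos = 0
        if self.relax_cell:
            L = np.zeros((3, 3))
            for v, (i, j) in zip(x[:6], self.tri):
                L[i, j] = v
            pos = 6
        else:
            L = self.lat0
        M = self.n_units
        trans = np.zeros((M, 3))
        trans[1:] = x[pos:pos + 3 * (M - 1)].reshape(M - 1, 3)
        pos += 3 * (M - 1)
        cart = np.empty((len(self.template.atoms), 3))
        for u in range(M):
            axes = self.rot_axes[u]
            nr = axes.shape[1]
            rotvec = axes @ x[pos:pos + nr] if nr else np.zeros(3)
            pos += nr
            Rm = Rotation.from_rotvec(rotvec).as_matrix()
            com = self.com_frac[u] @ L + trans[u]
            cart[self.template.rigid_units[u]] = com + self.offsets[u] @ Rm.T
        return self.template.replace_geometry(L, cart)

    def enthalpy(self, x: np.ndarray) -> float:
        """Per-cell enthalpy E_latt + P V (kJ/mol).

        Degenerate trial geometries (collapsed cells, overlapping molecules)
        get a large finite penalty so the line search backs off instead of
        crashing.
        """
        from .energy import GeometryError, ewald_energy

        try:
            c = self.build(x)
            if not 0.2 < c.volume / self.vol0 < 4.0:
                return 1e8  # runaway cell: stop before image lists explode
            e = self.pairs.exp6_energy(c)
            e += ewald_energy(c, accuracy=self.ff.ewald_accuracy)
        except (ValueError, GeometryError):
            return 1e8
        return e + self.pressure * GPA_TO_KJMOL_ANG3 * c.volume

    def gradient(self, x: np.ndarray) -> np.ndarray:
        g = np.empty_like(x)
        for i in range(len(x)):
            xp, xm = x.copy(), x.copy()
            xp[i] += FD_STEP
            xm[i] -= FD_STEP
            g[i] = (self.enthalpy(xp) - self.enthalpy(xm)) / (2 * FD_STEP)
        return g


def optimize(
    crystal: Crystal,
    ff: ForceField,
    pressure: float = 0.0,
    tol: float = 1e-4,
    max_iter: int = 300,
    relax_cell: bool = True,
    pair_list=None,
) -> OptimizationResult:
    """Minimise E_latt + P.V over rigid-body and (optionally) cell coordinates.

    ``pressure`` in GPa (negative values expand: the thermal-pressure route).
    Non-convergence within ``max_iter`` is flagged on the result, not raised.
    """
    prob = _RigidBodyProblem(crystal, ff, pressure, relax_cell, pair_list)
    x0 = prob.initial()
    if prob.n_params == 0:  # e.g. one single-atom unit with the cell clamped
        e = lattice_energy(crystal, ff, pressure=pressure)
        return OptimizationResult(crystal, e.enthalpy, 0.0, 0, True)
    g0 = prob.gradient(x0)
    if np.abs(g0).max() < tol:
        start = prob.build(x0)
        e = lattice_energy(start, ff, pressure=pressure)
        return OptimizationResult(start, e.enthalpy, float(np.abs(g0).max()),
                                  0, True)
    res = minimize(
        prob.enthalpy, x0, jac=prob.gradient, method="BFGS",
        options={"gtol": tol, "maxiter": max_iter, "norm": np.inf},
    )
    final = prob.build(res.x)

    v0, v1 = crystal.volume, final.volume
    if abs(v1 - v0) / v0 > 0.5:
        raise DrasticChangeError(
            f"volume changed by {100 * (v1 - v0) / v0:.0f}% under "
            f"P = {pressure} GPa"
        )
    disp = np.abs(res.x[6 if relax_cell else 0:][: 3 * (prob.n_units - 1)])
    if disp.size and disp.max() > 3.0:
        raise DrasticChangeError("rigid-unit COM moved by more than 3 Å")

    gnorm = float(np.abs(prob.gradient(res.x)).max())
    return OptimizationResult(
        crystal=final,
        enthalpy=lattice_energy(final, ff, pressure=pressure).enthalpy,
        gradient_norm=gnorm,
        n_iterations=int(res.nit),
        converged=bool(gnorm < 10 * tol),
    )


def check_stability(crystal: Crystal, ff: ForceField) -> StabilityReport:
    """Dynamical (Gamma phonons) and mechanical (elastic tensor) diagnostics.

    Near-zero frequencies (|w| < 0.1 cm^-1) beyond the three acoustic zeros —
    e.g. free rotations of an isolated molecule — count as neutral, not
    unstable.
    """
    from .elastic import elastic_tensor
    from .phonons import ZERO_FREQ_CM, ForceConstants

    fc = ForceConstants(crystal, ff)
    f = fc.frequencies([0.0, 0.0, 0.0])
    order = np.argsort(np.abs(f))
    optic = np.sort(f[order[3:]])
    min_optic = float(optic[0]) if optic.size else math.inf
    try:
        et = elastic_tensor(crystal, ff)
        elastic_pd = et.positive_definite
    except Exception:
        elastic_pd = False
    stable = bool(min_optic > -ZERO_FREQ_CM and elastic_pd)
    return StabilityReport(
        gamma_frequencies=f,
        min_optic_frequency=min_optic,
        elastic_positive_definite=elastic_pd,
        stable=stable,
    )
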