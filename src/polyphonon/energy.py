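"""Intermolecular lattice energy: exp-6 atom-atom sums plus Ewald electrostatics.

The repulsion--dispersion part is summed over whole-molecule pairs whose
centre-of-mass distance is below the force field's cutoff, enumerating all
periodic images.  Charge--charge electrostatics are summed by Ewald over all
atoms (no cutoff).  Energies are reported per molecule in kJ/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erfc

from .constants import COULOMB_KJMOL_ANG, GPA_TO_KJMOL_ANG3
from .forcefield import ForceField, PairParams
from .structures import Crystal

__all__ = [
    "EnergyBreakdown",
    "GeometryError",
    "pair_energy",
    "lattice_energy",
    "ewald_energy",
]

MIN_CONTACT = 0.1  # Å; closer non-bonded contacts indicate a broken geometry


class GeometryError(RuntimeError):
    """Raised for overlapping molecules or otherwise unusable geometry."""


@dataclass
class EnergyBreakdown:
    """Lattice-energy components, kJ/mol per molecule."""

    e_rep_disp: float
    e_elec: float
    pv_term: float = 0.0

    @property
    def e_inter(self) -> float:
        return self.e_rep_disp + self.e_elec

    @property
    def enthalpy(self) -> float:
        return self.e_inter + self.pv_term


def pair_energy(params: PairParams, q_i: float, q_k: float, R: float) -> float:
    """Single atom-atom interaction A e^{-BR} - C/R^6 + k_C q_i q_k / R."""
    if R <= 0:
        raise ValueError("interatomic distance must be positive")
    return (
        params.A * math.exp(-params.B * R)
        - params.C / R**6
        + COULOMB_KJMOL_ANG * q_i * q_k / R
    )


# -- image enumeration ------------------------------------------------------


def lattice_images(lattice: np.ndarray, rmax: float) -> np.ndarray:
    """Integer lattice translations n with |n.L| possibly <= rmax.

    Bounds use the perpendicular cell heights, so the set is a (safe)
    superset of the sphere of radius ``rmax``.
    """
    recip = np.linalg.inv(lattice)
    # perpendicular height along cell direction i is 1 / |column i of inv(L)|
    heights = 1.0 / np.linalg.norm(recip.T, axis=1)
    nmax = np.ceil(rmax / heights).astype(int)
    rng = [np.arange(-n, n + 1) for n in nmax]
    grid = np.stack(np.meshgrid(*rng, indexing="ij"), axis=-1).reshape(-1, 3)
    keep = np.linalg.norm(grid @ lattice, axis=1) <= rmax + 1e-9
    return grid[keep]


class _UnitGeometry:
    """Per-rigid-unit geometry and pair-parameter tables for fast sums."""

    def __init__(self, crystal: Crystal, ff: ForceField):
        self.crystal = crystal
        self.ff = ff
        M = crystal.n_molecules
        self.positions = [crystal.unit_positions(u) for u in range(M)]
        masses = crystal.masses
        self.coms = np.array(
            [
                masses[idx] @ self.positions[u] / masses[idx].sum()
                for u, idx in enumerate(crystal.rigid_units)
            ]
        )
        self.types = [
            [crystal.atoms[i].ff_type for i in idx] for idx in crystal.rigid_units
        ]
        self.charges = [crystal.charges[idx] for idx in crystal.rigid_units]
        self._params: dict[tuple[int, int], tuple[np.ndarray, ...]] = {}
        self.max_radius = max(
            (np.linalg.norm(p - c, axis=1).max() if len(p) else 0.0)
            for p, c in zip(self.positions, self.coms)
        )

    def pair_tables(self, a: int, b: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(A, B, C, qq) arrays of shape (na, nb) for unit pair (a, b)."""
        key = (a, b)
        if key not in self._params:
            ta, tb = self.types[a], self.types[b]
            A = np.empty((len(ta), len(tb)))
            B = np.empty_like(A)
            C = np.empty_like(A)
            for i, t1 in enumerate(ta):
                for j, t2 in enumerate(tb):
                    p = self.ff.get_pair(t1, t2)
                    A[i, j], B[i, j], C[i, j] = p.A, p.B, p.C
            qq = np.outer(self.charges[a], self.charges[b])
            self._params[key] = (A, B, C, qq)
        return self._params[key]

    def image_sets(self, cutoff: float) -> list[tuple[int, int, np.ndarray, np.ndarray]]:
        """All interacting (a, b, n_images, T_cart) with COM distance < cutoff.

        Ordered pairs with a <= b; for a == b the set excludes T = 0 and
        contains both T and -T (callers halve the self-pair sums).
        """
        lat = self.crystal.lattice_vectors
        # pad by the in-cell COM spread: |T| can exceed the cutoff by the
        # distance between the two COMs inside the reference cell
        spread = 0.0
        if len(self.coms) > 1:
            d = self.coms[:, None, :] - self.coms[None, :, :]
            spread = float(np.linalg.norm(d, axis=-1).max())
        cand = lattice_images(lat, cutoff + spread + 1e-6)
        Tcart_all = cand @ lat
        out = []
        M = self.crystal.n_molecules
        for a in range(M):
            for b in range(a, M):
                d = self.coms[b] + Tcart_all - self.coms[a]
                mask = np.linalg.norm(d, axis=1) < cutoff
                if a == b:
                    mask &= np.abs(cand).sum(axis=1) > 0
                if mask.any():
                    out.append((a, b, cand[mask], Tcart_all[mask]))
        return out


class FrozenPairList:
    """Molecule-pair image list frozen at a reference geometry.

    The sharp COM cutoff makes the lattice energy discontinuous (by the tail
    dispersion of whole-molecule pairs) whenever a pair crosses the cutoff.
    Inside an optimisation those jumps poison finite-difference gradients and
    line searches, so the pair list is built once from the starting geometry,
    padded by ``pad`` Å, and held fixed while coordinates move.  Energies of
    converged structures should be re-evaluated with :func:`lattice_energy`.
    """

    def __init__(self, crystal: Crystal, ff: ForceField, pad: float = 0.0):
        geom = _UnitGeometry(crystal, ff)
        self.ff = ff
        self.sets = geom.image_sets(ff.com_cutoff + pad)
        self.tables = {(a, b): geom.pair_tables(a, b) for a, b, _, _ in self.sets}
        self.ref_com_frac = geom.coms @ np.linalg.inv(crystal.lattice_vectors)

    def _anchored_positions(self, crystal: Crystal) -> list[np.ndarray]:
        """Unit positions shifted to the lattice image nearest the reference.

        Stored fractional coordinates wrap into [0, 1), which would make the
        energy over a fixed image list jump by whole shells whenever a COM
        crosses a cell face; re-anchoring to the reference image keeps the
        surface continuous while coordinates move.
        """
        geom = _UnitGeometry(crystal, self.ff)
        inv = np.linalg.inv(crystal.lattice_vectors)
        out = []
        for u, pos in enumerate(geom.positions):
            shift = np.round(geom.coms[u] @ inv - self.ref_com_frac[u])
            out.append(pos - shift @ crystal.lattice_vectors)
        return out

    def exp6_energy(self, crystal: Crystal) -> float:
        """exp-6 energy per cell over the frozen pair list, current geometry."""
        positions = self._anchored_positions(crystal)
        total = 0.0
        lat = crystal.lattice_vectors
        for a, b, n, _ in self.sets:
            A, B, C, _ = self.tables[(a, b)]
            T = n @ lat
            d = positions[a][None, :, None, :] - (
                positions[b][None, None, :, :] + T[:, None, None, :]
            )
            r = np.linalg.norm(d, axis=-1)
            if r.min() < MIN_CONTACT:
                raise GeometryError(
                    f"atoms of units {a} and {b} overlap (R = {r.min():.3f} Å)"
                )
            e = (A * np.exp(-B * r) - C / r**6).sum()
            total += 0.5 * e if a == b else e
        return total


def _expsix_sum(geom: _UnitGeometry, cutoff: float) -> float:
    """Total exp-6 energy per cell (kJ/mol), COM-cutoff whole-molecule sums."""
    total = 0.0
    for a, b, _, T in geom.image_sets(cutoff):
        A, B, C, _ = geom.pair_tables(a, b)
        d = geom.positions[a][None, :, None, :] - (
            geom.positions[b][None, None, :, :] + T[:, None, None, :]
        )
        r = np.linalg.norm(d, axis=-1)
        if r.min() < MIN_CONTACT:
            raise GeometryError(
                f"atoms of units {a} and {b} overlap (R = {r.min():.3f} Å)"
            )
        e = (A * np.exp(-B * r) - C / r**6).sum()
        total += 0.5 * e if a == b else e
    return total


def ewald_energy(
    crystal: Crystal,
    charges: np.ndarray | None = None,
    accuracy: float = 1e-7,
    alpha: float | None = None,
) -> float:
    """Point-charge electrostatic energy per cell (kJ/mol) by Ewald summation.

    The result is independent of the splitting parameter ``alpha`` within
    ``accuracy``; tinfoil (conducting) boundary conditions are used.
    """
    q = np.asarray(charges if charges is not None else crystal.charges, float)
    if abs(q.sum()) > 1e-8:
        raise ValueError(f"cell is not charge neutral (net {q.sum():.3e} e)")
    if not np.any(q):
        return 0.0
    lat = crystal.lattice_vectors
    V = crystal.volume
    pos = crystal.cart_coords
    n = len(q)

    if alpha is None:
        # balance real and reciprocal work for a homogeneous system
        alpha = (n * math.pi**3 / V**2) ** (1.0 / 6.0)
        alpha = max(alpha, 2.0 / V ** (1.0 / 3.0))
    tol = math.sqrt(-math.log(accuracy))
    r_cut = tol / alpha
    k_cut = 2.0 * alpha * tol

    # real space; image list padded by the cell diameter so every atom pair
    # within r_cut is reachable
    e_real = 0.0
    diam = np.linalg.norm(lat, axis=1).sum()
    images = lattice_images(lat, r_cut + diam)
    T = images @ lat
    for i in range(n):
        d = pos[None, :, :] + T[:, None, :] - pos[i]
        r = np.linalg.norm(d, axis=-1)
        mask = (r > 1e-12) & (r < r_cut)
        qq = q[i] * np.broadcast_to(q, r.shape)
        e_real += 0.5 * (qq[mask] * erfc(alpha * r[mask]) / r[mask]).sum()

    # reciprocal space
    recip = 2.0 * math.pi * np.linalg.inv(lat).T  # rows are b1, b2, b3
    hmax = np.ceil(k_cut / np.linalg.norm(recip, axis=1) * 1.5).astype(int) + 1
    rng = [np.arange(-h, h + 1) for h in hmax]
    hkl = np.stack(np.meshgrid(*rng, indexing="ij"), axis=-1).reshape(-1, 3)
    hkl = hkl[np.abs(hkl).sum(axis=1) > 0]
    kvec = hkl @ recip
    k2 = (kvec**2).sum(axis=1)
    keep = k2 <= k_cut**2
    kvec, k2 = kvec[keep], k2[keep]
    phase = kvec @ pos.T  # (nk, natoms)
    s_re = np.cos(phase) @ q
    s_im = np.sin(phase) @ q
    e_recip = (2.0 * math.pi / V) * (
        np.exp(-k2 / (4.0 * alpha**2)) / k2 * (s_re**2 + s_im**2)
    ).sum()

    e_self = -alpha / math.sqrt(math.pi) * (q**2).sum()
    return COULOMB_KJMOL_ANG * (e_real + e_recip + e_self)


def intramolecular_coulomb(crystal: Crystal) -> float:
    """Direct-sum Coulomb energy within each rigid unit, per cell (kJ/mol).

    The Ewald sum runs over all charge pairs; the intermolecular energy must
    exclude the (rigid, constant) within-molecule interactions.
    """
    total = 0.0
    for u, idx in enumerate(crystal.rigid_units):
        if len(idx) < 2:
            continue
        pos = crystal.unit_positions(u)
        q = crystal.charges[idx]
        d = pos[:, None, :] - pos[None, :, :]
        r = np.linalg.norm(d, axis=-1)
        iu = np.triu_indices(len(idx), k=1)
        total += COULOMB_KJMOL_ANG * (np.outer(q, q)[iu] / r[iu]).sum()
    return total


def lattice_energy(
    crystal: Crystal, ff: ForceField, pressure: float = 0.0
) -> EnergyBreakdown:
    """Intermolecular lattice energy (kJ/mol per molecule) at a given pressure.

    exp-6 terms are summed over whole-molecule pairs with COM separation below
    ``ff.com_cutoff``; electrostatics by Ewald over the atomic point charges,
    minus the intramolecular Coulomb terms (interactions are between
    molecules only).  ``pressure`` (GPa) only enters the PV term of the
    reported enthalpy.
    """
    geom = _UnitGeometry(crystal, ff)
    M = crystal.n_molecules
    e_rd = _expsix_sum(geom, ff.com_cutoff) / M
    e_el = (ewald_energy(crystal, accuracy=ff.ewald_accuracy)
            - intramolecular_coulomb(crystal)) / M
    pv = pressure * GPA_TO_KJMOL_ANG3 * crystal.volume / M
    return EnergyBreakdown(e_rep_disp=e_rd, e_elec=e_el, pv_term=pv)
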