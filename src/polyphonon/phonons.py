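"""Rigid-body lattice dynamics: dynamical matrices, spectra and thermodynamics.

Each rigid unit contributes translational coordinates (mass-weighted by the
molecular mass) and rotational coordinates about its principal inertia axes
(weighted by the corresponding moments).  Axes with zero moment (the axis of a
linear molecule, or all axes of a single atom) carry no dynamics and are
projected out, so a unit has 3 + rank(inertia) coordinates: 6 for a
non-linear molecule, 5 for a linear one, 3 for an atom.

Force constants are assembled analytically from first and second derivatives
of the atom-atom pair potential (exp-6 plus real-space Coulomb), summed over
whole-molecule pairs within the force field's centre-of-mass cutoff.  For
neutral rigid units the electrostatic force constants decay at least as fast
as dipole-dipole curvature (R^-5), so the real-space molecule-pair sum is
absolutely convergent and the translational acoustic sum rule holds exactly
by construction.

Acoustic dispersion near the zone centre is handled by a Debye model fitted
to the acoustic branch slopes at small-|k| probe points; optic (and sampled
acoustic) modes enter the thermodynamic sums directly, or smoothed by a
Gaussian kernel density estimate of the density of states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import FREQ_CM_PER_SQRT, HC_KJMOL_CM, KB_KJMOL
from .energy import _UnitGeometry
from .forcefield import ForceField
from .structures import Crystal

__all__ = [
    "ForceConstants",
    "PhononSpectrum",
    "ThermoState",
    "InstabilityError",
    "dynamical_matrix",
    "frequencies_at",
    "sample_spectrum",
    "dos_kde",
    "vib_free_energy",
]

#: frequencies with |w| below this (cm^-1) are treated as numerical zeros
ZERO_FREQ_CM = 0.1

#: relative inertia-moment threshold below which a rotation axis is dropped
INERTIA_TOL = 1e-8


class InstabilityError(RuntimeError):
    """Raised when a structure has imaginary phonon frequencies."""


def _pair_derivs(A, B, C, qq, r, coulomb_k):
    """phi'(r) and phi''(r) of A e^{-Br} - C/r^6 + k qq / r, elementwise."""
    ex = A * np.exp(-B * r)
    phi1 = -B * ex + 6.0 * C / r**7 - coulomb_k * qq / r**2
    phi2 = B**2 * ex - 42.0 * C / r**8 + 2.0 * coulomb_k * qq / r**3
    return phi1, phi2


def _skew(v: np.ndarray) -> np.ndarray:
    out = np.zeros(v.shape[:-1] + (3, 3))
    out[..., 0, 1], out[..., 0, 2] = -v[..., 2], v[..., 1]
    out[..., 1, 0], out[..., 1, 2] = v[..., 2], -v[..., 0]
    out[..., 2, 0], out[..., 2, 1] = -v[..., 1], v[..., 0]
    return out


class ForceConstants:
    """Real-space rigid-body force constants of a crystal.

    Built once per geometry; dynamical matrices at arbitrary wavevectors are
    then assembled by Fourier summation of the stored 6x6 blocks.
    """

    def __init__(self, crystal: Crystal, ff: ForceField):
        from .constants import COULOMB_KJMOL_ANG

        self.crystal = crystal
        self.ff = ff
        geom = _UnitGeometry(crystal, ff)
        M = crystal.n_molecules
        self.n_units = M

        # per-unit mass-weighted coordinate bases
        self.masses = np.empty(M)
        self.bases: list[np.ndarray] = []     # (6, dof), includes 1/sqrt(weight)
        jacobians: list[np.ndarray] = []      # (na, 3, 6) d x_atom / d (t, theta)
        for u in range(M):
            unit = crystal.rigid_unit(u)
            self.masses[u] = unit.mass
            d = geom.positions[u] - geom.coms[u]
            J = np.zeros((len(d), 3, 6))
            J[:, :, :3] = np.eye(3)
            J[:, :, 3:] = -_skew(d)
            jacobians.append(J)
            evals, evecs = np.linalg.eigh(unit.inertia_tensor)
            scale = max(evals.max(), 1.0)
            cols = [np.concatenate((np.eye(3)[i] / math.sqrt(unit.mass),
                                    np.zeros(3))) for i in range(3)]
            for lam, vec in zip(evals, evecs.T):
                if lam > INERTIA_TOL * scale:
                    cols.append(np.concatenate((np.zeros(3), vec / math.sqrt(lam))))
            self.bases.append(np.array(cols).T)
        self.dof = [b.shape[1] for b in self.bases]
        self.total_dof = int(sum(self.dof))

        # accumulate 6x6 blocks
        self.blocks: list[tuple[int, int, np.ndarray, np.ndarray]] = []
        self_blocks = [np.zeros((6, 6)) for _ in range(M)]
        for a, b, n_int, T in geom.image_sets(ff.com_cutoff):
            # ordered enumeration: for a < b also process the mirrored (b, a)
            ordered = [(a, b, n_int, T)]
            if a != b:
                ordered.append((b, a, -n_int, -T))
            for ua, ub, nn, TT in ordered:
                A, B, C, qq = geom.pair_tables(ua, ub)
                xa = geom.positions[ua]
                xb = geom.positions[ub]
                dvec = xa[None, :, None, :] - (xb[None, None, :, :] + TT[:, None, None, :])
                r = np.linalg.norm(dvec, axis=-1)
                u = dvec / r[..., None]
                phi1, phi2 = _pair_derivs(A, B, C, qq, r, COULOMB_KJMOL_ANG)
                uu = u[..., :, None] * u[..., None, :]
                H = phi2[..., None, None] * uu + (phi1 / r)[..., None, None] * (
                    np.eye(3) - uu
                )
                Ja, Jb = jacobians[ua], jacobians[ub]
                cross = -np.einsum("aip,tabij,bjq->tpq", Ja, H, Jb, optimize=True)
                onsite = np.einsum("aip,tabij,ajq->pq", Ja, H, Ja, optimize=True)
                # curvature of atom positions under rotation, times the force
                g = phi1[..., None] * u                      # dphi/dx_a
                gsum = g.sum(axis=(0, 2))                    # (na, 3)
                da = xa - geom.coms[ua]
                gd = np.einsum("ai,ai->", gsum, da)
                K = 0.5 * (np.einsum("ai,aj->ij", gsum, da)
                           + np.einsum("ai,aj->ij", da, gsum)) - gd * np.eye(3)
                onsite[3:, 3:] += K
                self_blocks[ua] += onsite
                self.blocks.append((ua, ub, nn.astype(float), cross))
        self.self_blocks = self_blocks

    def dynamical_matrix(self, k_frac) -> np.ndarray:
        """Mass-weighted Hermitian dynamical matrix at fractional wavevector k."""
        k = np.asarray(k_frac, dtype=float)
        M = self.n_units
        D6 = np.zeros((M, M, 6, 6), dtype=complex)
        for u in range(M):
            D6[u, u] += self.self_blocks[u]
        for ua, ub, n, block in self.blocks:
            phase = np.exp(2j * math.pi * (n @ k))
            D6[ua, ub] += np.einsum("t,tpq->pq", phase, block)
        offs = np.concatenate(([0], np.cumsum(self.dof)))
        D = np.zeros((self.total_dof, self.total_dof), dtype=complex)
        for a in range(M):
            for b in range(M):
                Qa, Qb = self.bases[a], self.bases[b]
                D[offs[a]:offs[a + 1], offs[b]:offs[b + 1]] = Qa.T @ D6[a, b] @ Qb
        return 0.5 * (D + D.conj().T)

    def frequencies(self, k_frac) -> np.ndarray:
        """Phonon frequencies at k in cm^-1 (negative = imaginary), sorted."""
        lam = np.linalg.eigvalsh(self.dynamical_matrix(k_frac))
        return np.sort(np.sign(lam) * FREQ_CM_PER_SQRT * np.sqrt(np.abs(lam)))


def dynamical_matrix(crystal: Crystal, ff: ForceField, k_frac) -> np.ndarray:
    """Rigid-body dynamical matrix at fractional wavevector ``k_frac``."""
    return ForceConstants(crystal, ff).dynamical_matrix(k_frac)


def frequencies_at(crystal: Crystal, ff: ForceField, k_frac) -> np.ndarray:
    return ForceConstants(crystal, ff).frequencies(k_frac)


# -- spectra ----------------------------------------------------------------


@dataclass
class PhononSpectrum:
    """k-sampled frequencies plus the Debye acoustic parameters.

    ``mode_freqs``/``mode_weights`` hold every sampled mode except the three
    zone-centre acoustic zeros, which the Debye term represents:
    ``n_debye_modes`` (= 3/N_k) modes per primitive cell below ``omega_d``.
    """

    kpoints: np.ndarray
    weights: np.ndarray
    frequencies: list[np.ndarray]
    mode_freqs: np.ndarray
    mode_weights: np.ndarray
    debye_velocity: float      # cm^-1 Å (omega = v |k|, k in rad/Å)
    omega_d: float             # cm^-1
    n_debye_modes: float
    n_molecules: int
    kde_bandwidth: float = 3.0
    dos_grid: np.ndarray | None = None

    @property
    def mode_count(self) -> float:
        """Modes per primitive cell carried by the discrete part."""
        return float(self.mode_weights.sum())


def _gamma_split(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a Gamma-point frequency list into (acoustic zeros, optic)."""
    order = np.argsort(np.abs(freqs))
    return freqs[order[:3]], freqs[order[3:]]


def sample_spectrum(
    crystal: Crystal,
    ff: ForceField,
    grid: tuple[int, int, int] = (4, 4, 4),
    kde_bandwidth: float = 3.0,
    allow_imaginary: bool = False,
    probe_k: float = 0.02,
) -> PhononSpectrum:
    """Sample phonons on a uniform Gamma-centred grid and fit the Debye model.

    Raises :class:`InstabilityError` on imaginary frequencies unless
    ``allow_imaginary`` (diagnostics only; imaginary modes are reported as
    negative numbers).
    """
    fc = ForceConstants(crystal, ff)
    n1, n2, n3 = grid
    nk = n1 * n2 * n3
    kpts, freqs, w = [], [], 1.0 / nk
    mode_f, mode_w = [], []
    for i in range(n1):
        for j in range(n2):
            for l in range(n3):
                k = np.array([i / n1, j / n2, l / n3])
                k -= np.round(k)
                f = fc.frequencies(k)
                kpts.append(k)
                freqs.append(f)
                if np.allclose(k, 0.0):
                    acoustic, optic = _gamma_split(f)
                    if np.abs(acoustic).max() > ZERO_FREQ_CM:
                        raise InstabilityError(
                            "acoustic sum rule violated at Gamma: "
                            f"|w| up to {np.abs(acoustic).max():.3f} cm^-1"
                        )
                    kept = optic
                else:
                    kept = f
                if kept.size and kept.min() < ZERO_FREQ_CM and not allow_imaginary:
                    raise InstabilityError(
                        f"imaginary/soft mode {kept.min():.3f} cm^-1 at k={k}"
                    )
                mode_f.append(kept)
                mode_w.append(np.full(kept.shape, w))

    # Debye fit on small-|k| probes along the reciprocal axes and the diagonal
    recip = 2.0 * math.pi * np.linalg.inv(crystal.lattice_vectors).T
    vels = []
    for d in (np.array([1.0, 0, 0]), np.array([0, 1.0, 0]),
              np.array([0, 0, 1.0]), np.array([1.0, 1.0, 1.0])):
        q = probe_k * d / np.linalg.norm(d)
        knorm = np.linalg.norm(q @ recip)
        f = fc.frequencies(q)
        acoustic = np.sort(f)[:3] if fc.total_dof > 3 else np.sort(f)
        acoustic = acoustic[:3]
        if np.any(acoustic < 0) and not allow_imaginary:
            raise InstabilityError("imaginary acoustic branch near Gamma")
        vels.append(np.maximum(acoustic, 1e-10) / knorm)
    vels = np.concatenate(vels)
    v_debye = float(np.mean(vels**-3.0) ** (-1.0 / 3.0))
    n_debye = 3.0 / nk
    k_d = (6.0 * math.pi**2 / (crystal.volume * nk)) ** (1.0 / 3.0)
    omega_d = v_debye * k_d

    spec = PhononSpectrum(
        kpoints=np.array(kpts),
        weights=np.full(nk, w),
        frequencies=freqs,
        mode_freqs=np.concatenate(mode_f),
        mode_weights=np.concatenate(mode_w),
        debye_velocity=v_debye,
        omega_d=omega_d,
        n_debye_modes=n_debye,
        n_molecules=crystal.n_molecules,
        kde_bandwidth=kde_bandwidth,
    )
    if spec.mode_freqs.size:
        spec.dos_grid = dos_kde(spec, kde_bandwidth)
    return spec


def dos_kde(spectrum: PhononSpectrum, bandwidth: float) -> np.ndarray:
    """Gaussian-KDE density of states of the discrete (non-Debye) modes.

    Returns an (n, 2) array of (omega [cm^-1], g [modes per cm^-1 per cell]),
    normalised so the integral equals the discrete mode count.
    """
    if bandwidth <= 0:
        raise ValueError("KDE bandwidth must be positive")
    f = spectrum.mode_freqs
    if f.size == 0:
        raise ValueError("no modes to smooth")
    w = spectrum.mode_weights
    lo = max(f.min() - 5 * bandwidth, 1e-4)
    hi = f.max() + 5 * bandwidth
    omega = np.linspace(lo, hi, 2048)
    g = np.zeros_like(omega)
    norm = 1.0 / (bandwidth * math.sqrt(2 * math.pi))
    for fi, wi in zip(f, w):
        g += wi * norm * np.exp(-0.5 * ((omega - fi) / bandwidth) ** 2)
    integral = np.trapezoid(g, omega)
    g *= spectrum.mode_count / integral
    return np.column_stack((omega, g))


# -- harmonic thermodynamics ------------------------------------------------


@dataclass
class ThermoState:
    """Vibrational thermodynamics per molecule at one temperature (kJ/mol)."""

    T: float
    zpe: float
    f_vib: float
    entropy: float  # kJ/mol/K
    cv: float       # kJ/mol/K
    e_latt: float | None = None

    @property
    def a_ha(self) -> float:
        """Harmonic free energy E_latt + F_vib (requires e_latt)."""
        if self.e_latt is None:
            raise ValueError("e_latt not attached to this ThermoState")
        return self.e_latt + self.f_vib


def _mode_thermo(omega_cm: np.ndarray, T: float):
    """Per-mode (F, S, Cv, ZPE) of harmonic oscillators at wavenumber omega."""
    e = HC_KJMOL_CM * omega_cm
    zpe = 0.5 * e
    if T <= 0:
        zero = np.zeros_like(e)
        return zpe, zero, zero, zpe
    x = np.minimum(e / (KB_KJMOL * T), 700.0)
    emx = np.exp(-x)
    log1m = np.log1p(-emx)
    F = zpe + KB_KJMOL * T * log1m
    occ = x * emx / (1.0 - emx)          # x / (e^x - 1), overflow-safe
    S = KB_KJMOL * (occ - log1m)
    Cv = KB_KJMOL * x**2 * emx / (1.0 - emx) ** 2
    return F, S, Cv, zpe


def _debye_thermo(spectrum: PhononSpectrum, T: float, n_quad: int = 96):
    """(F, S, Cv, ZPE) of the Debye acoustic term, per primitive cell."""
    n = spectrum.n_debye_modes
    wd = spectrum.omega_d
    if wd <= 0 or n <= 0:
        return 0.0, 0.0, 0.0, 0.0
    x, wq = np.polynomial.legendre.leggauss(n_quad)
    omega = 0.5 * wd * (x + 1.0)
    dw = 0.5 * wd * wq
    g = 3.0 * n * omega**2 / wd**3
    F, S, Cv, zpe = _mode_thermo(omega, T)
    return (g * F) @ dw, (g * S) @ dw, (g * Cv) @ dw, (g * zpe) @ dw


def vib_free_energy(
    spectrum: PhononSpectrum,
    T: float,
    e_latt: float | None = None,
    use_kde: bool = False,
) -> ThermoState:
    """Harmonic vibrational free energy, entropy, Cv and ZPE per molecule.

    The discrete sampled modes are summed directly (default) or integrated
    against the KDE density of states (``use_kde``); the Debye acoustic term
    is integrated in closed quadrature either way.  Entropy is evaluated from
    the analytic per-mode formula, not by differencing.
    """
    if T < 0:
        raise ValueError("temperature must be non-negative")
    if use_kde:
        omega, g = spectrum.dos_grid[:, 0], spectrum.dos_grid[:, 1]
        F, S, Cv, zpe = _mode_thermo(omega, T)
        tot = [np.trapezoid(g * x, omega) for x in (F, S, Cv, zpe)]
    else:
        F, S, Cv, zpe = _mode_thermo(spectrum.mode_freqs, T)
        w = spectrum.mode_weights
        tot = [float(w @ x) for x in (F, S, Cv, zpe)]
    dF, dS, dCv, dZ = _debye_thermo(spectrum, T)
    M = spectrum.n_molecules
    return ThermoState(
        T=T,
        zpe=(tot[3] + dZ) / M,
        f_vib=(tot[0] + dF) / M,
        entropy=(tot[1] + dS) / M,
        cv=(tot[2] + dCv) / M,
        e_latt=e_latt,
    )
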