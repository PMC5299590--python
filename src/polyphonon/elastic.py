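"""Elastic tensors by finite strain and Voigt/Reuss/Hill aggregate moduli.

The 6x6 elastic-constant matrix (Voigt notation, GPa) is built from central
finite differences of the energy density with respect to the six engineering
strains; shear rows use the engineering convention (gamma = 2 eps), so the
applied deformation for Voigt component i >= 4 puts gamma/2 in each of the two
symmetric off-diagonal slots.  Rigid-body internal coordinates can be
re-relaxed at every strained cell (relaxed-ion, default) or clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KJMOL_ANG3_TO_GPA
from .forcefield import ForceField
from .structures import Crystal

__all__ = ["ElasticTensor", "AggregateModuli", "elastic_tensor", "hill_moduli",
           "softening_profile"]

_VOIGT = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]


@dataclass
class ElasticTensor:
    c: np.ndarray           # 6x6, GPa
    relaxed_internal: bool

    @property
    def positive_definite(self) -> bool:
        return bool(np.all(np.linalg.eigvalsh(0.5 * (self.c + self.c.T)) > 0))


@dataclass
class AggregateModuli:
    k_voigt: float
    k_reuss: float
    k_hill: float
    g_voigt: float
    g_reuss: float
    g_hill: float


def _strain_matrix(voigt: np.ndarray) -> np.ndarray:
    e = np.empty((3, 3))
    for i, (a, b) in enumerate(_VOIGT):
        v = voigt[i] if i < 3 else 0.5 * voigt[i]
        e[a, b] = e[b, a] = v
    return e


def _apply_strain(crystal: Crystal, voigt: np.ndarray) -> Crystal:
    """Deform the cell by (1 + eps); COMs move affinely, molecules stay rigid."""
    F = np.eye(3) + _strain_matrix(voigt)
    lat = crystal.lattice_vectors @ F.T
    cart = np.empty((len(crystal.atoms), 3))
    m = crystal.masses
    for u, idx in enumerate(crystal.rigid_units):
        pos = crystal.unit_positions(u)
        com = m[idx] @ pos / m[idx].sum()
        cart[idx] = com @ F.T + (pos - com)
    return crystal.replace_geometry(lat, cart)


def elastic_tensor(
    crystal: Crystal,
    ff: ForceField,
    strain: float = 0.002,
    relax_internal: bool = True,
    relax_tol: float = 1e-5,
) -> ElasticTensor:
    """Second-derivative elastic constants at an optimised structure.

    ``relax_internal`` re-relaxes rigid-body coordinates (cell held fixed) at
    every strained geometry; relaxation failure raises, naming the strain
    component responsible.
    """
    from .energy import FrozenPairList, ewald_energy
    from .optimizer import optimize

    V0 = crystal.volume
    # one pair list for every strained evaluation: a sharp-cutoff list
    # rebuilt per strain would jump between evaluations and wreck the
    # second differences
    frozen = FrozenPairList(crystal, ff)

    def energy(voigt) -> float:
        s = _apply_strain(crystal, np.asarray(voigt, float))
        if relax_internal:
            try:
                res = optimize(s, ff, pressure=0.0, tol=relax_tol,
                               relax_cell=False, pair_list=frozen)
            except Exception as exc:
                raise RuntimeError(
                    f"internal relaxation failed at strain {voigt}: {exc}"
                ) from exc
            s = res.crystal
        return frozen.exp6_energy(s) + ewald_energy(s, accuracy=ff.ewald_accuracy)

    h = strain
    e0 = energy(np.zeros(6))
    c = np.empty((6, 6))
    for i in range(6):
        ei = np.zeros(6)
        ei[i] = h
        ep, em = energy(ei), energy(-ei)
        c[i, i] = (ep - 2 * e0 + em) / h**2
        for j in range(i + 1, 6):
            ej = np.zeros(6)
            ej[j] = h
            epp = energy(ei + ej)
            emm = energy(-ei - ej)
            epm = energy(ei - ej)
            emp = energy(ej - ei)
            c[i, j] = c[j, i] = (epp + emm - epm - emp) / (4 * h**2)
    c *= KJMOL_ANG3_TO_GPA / V0
    c = 0.5 * (c + c.T)
    return ElasticTensor(c=c, relaxed_internal=relax_internal)


def hill_moduli(tensor: ElasticTensor | np.ndarray) -> AggregateModuli:
    """Voigt (upper), Reuss (lower) and Hill (mean) polycrystal moduli."""
    c = tensor.c if isinstance(tensor, ElasticTensor) else np.asarray(tensor)
    if not np.allclose(c, c.T, atol=1e-6):
        raise ValueError("elastic matrix must be symmetric")
    k_v = (c[0, 0] + c[1, 1] + c[2, 2] + 2 * (c[0, 1] + c[0, 2] + c[1, 2])) / 9.0
    g_v = (
        c[0, 0] + c[1, 1] + c[2, 2] - c[0, 1] - c[0, 2] - c[1, 2]
        + 3 * (c[3, 3] + c[4, 4] + c[5, 5])
    ) / 15.0
    try:
        s = np.linalg.inv(c)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular elastic matrix: Reuss bound undefined") from exc
    k_r = 1.0 / (s[0, 0] + s[1, 1] + s[2, 2] + 2 * (s[0, 1] + s[0, 2] + s[1, 2]))
    g_r = 15.0 / (
        4 * (s[0, 0] + s[1, 1] + s[2, 2]) - 4 * (s[0, 1] + s[0, 2] + s[1, 2])
        + 3 * (s[3, 3] + s[4, 4] + s[5, 5])
    )
    return AggregateModuli(
        k_voigt=k_v, k_reuss=k_r, k_hill=0.5 * (k_v + k_r),
        g_voigt=g_v, g_reuss=g_r, g_hill=0.5 * (g_v + g_r),
    )


def softening_profile(
    reference: Crystal,
    expanded: list[tuple[float, Crystal]],
    ff: ForceField,
    strain: float = 0.002,
) -> list[dict]:
    """Hill moduli on thermally expanded structures and their softening.

    ``expanded`` is a list of (T, crystal); the percentage decrease of K and G
    is reported against the reference (0 K) structure.  A structure whose
    tensor cannot be evaluated yields an error entry; the profile continues.
    """
    ref = hill_moduli(elastic_tensor(reference, ff, strain=strain))
    out = [{"T": 0.0, "moduli": ref, "k_decrease_pct": 0.0,
            "g_decrease_pct": 0.0}]
    for T, crys in expanded:
        try:
            agg = hill_moduli(elastic_tensor(crys, ff, strain=strain))
        except Exception as exc:  # per-T failure must not kill the profile
            out.append({"T": T, "error": str(exc)})
            continue
        out.append({
            "T": T,
            "moduli": agg,
            "k_decrease_pct": (ref.k_hill - agg.k_hill) / ref.k_hill * 100.0,
            "g_decrease_pct": (ref.g_hill - agg.g_hill) / ref.g_hill * 100.0,
        })
    return out
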