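"""Force-field container and plain-text parameter file parser.

The intermolecular model is Buckingham (exp-6) repulsion--dispersion between
atom types plus atomic point-charge electrostatics:

    V(R) = A exp(-B R) - C / R^6 + k_C q_i q_k / R

Parameter files are whitespace-separated text with three sections::

    [types]
    # label  element  mass  charge
    C1  C  12.011  -0.10
    [pairs]
    # type1 type2  A[kJ/mol]  B[1/Å]  C[kJ/mol Å^6]
    C1  C1  180000.0  3.60  2400.0
    [settings]          # optional
    com_cutoff 20.0     # whole-molecule COM cutoff, Å
    ewald_accuracy 1e-7
    epsilon_r 5.0

Missing cross terms fall back to combining rules (geometric mean for A and C,
arithmetic mean for B); the fallback is logged, never silent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

from .structures import Crystal

logger = logging.getLogger(__name__)

__all__ = ["PairParams", "ForceField", "read_forcefield", "write_forcefield"]


@dataclass(frozen=True)
class PairParams:
    """exp-6 parameters for one unordered type pair."""

    A: float  # kJ/mol
    B: float  # 1/Å
    C: float  # kJ/mol Å^6

    def __post_init__(self):
        if self.B <= 0:
            raise ValueError("exp-6 B must be positive")
        if self.A < 0 or self.C < 0:
            raise ValueError("exp-6 A and C must be non-negative")


@dataclass
class ForceField:
    """Pair parameters, per-type charges and summation settings.

    ``com_cutoff`` is the whole-molecule centre-of-mass cutoff (Å) for the
    repulsion--dispersion sum; electrostatics are summed by Ewald and have no
    cutoff.  ``epsilon_r`` is carried as metadata only (it documents the
    dielectric environment the charges were derived in; it never scales any
    energy here).
    """

    pair_params: dict[tuple[str, str], PairParams]
    charges: dict[str, float] = field(default_factory=dict)
    masses: dict[str, float] = field(default_factory=dict)
    elements: dict[str, str] = field(default_factory=dict)
    com_cutoff: float = 20.0
    ewald_accuracy: float = 1e-7
    epsilon_r: float = 5.0

    def __post_init__(self):
        self.pair_params = {
            tuple(sorted(k)): v for k, v in self.pair_params.items()
        }

    def get_pair(self, t1: str, t2: str) -> PairParams:
        """Parameters for (t1, t2); combining-rule fallback is logged."""
        key = tuple(sorted((t1, t2)))
        p = self.pair_params.get(key)
        if p is not None:
            return p
        p1 = self.pair_params.get((t1, t1))
        p2 = self.pair_params.get((t2, t2))
        if p1 is None or p2 is None:
            raise KeyError(f"no pair parameters resolvable for ({t1}, {t2})")
        p = PairParams(
            math.sqrt(p1.A * p2.A), 0.5 * (p1.B + p2.B), math.sqrt(p1.C * p2.C)
        )
        logger.warning(
            "pair (%s, %s) not in force field; using combining rules", t1, t2
        )
        self.pair_params[key] = p
        return p

    def charge_of(self, ff_type: str) -> float:
        return self.charges.get(ff_type, 0.0)

    def assign_charges(self, crystal: Crystal) -> Crystal:
        """Return a copy of ``crystal`` with charges filled in from the types."""
        atoms = [replace(a, charge=self.charges.get(a.ff_type, a.charge))
                 for a in crystal.atoms]
        return Crystal(crystal.lattice_vectors.copy(), atoms,
                       [list(u) for u in crystal.rigid_units])

    def validate(self, crystal: Crystal) -> None:
        """Check that every ff_type in the crystal is resolvable."""
        for a in crystal.atoms:
            if (a.ff_type, a.ff_type) not in self.pair_params:
                ok = any(a.ff_type in k for k in self.pair_params)
                if not ok:
                    raise KeyError(f"ff_type {a.ff_type!r} unknown to force field")


def read_forcefield(path, **kwargs) -> ForceField:
    """Parse the documented plain-text force-field format."""
    section = None
    types: dict[str, tuple[str, float, float]] = {}
    pairs: dict[tuple[str, str], PairParams] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[]").lower()
            if section not in ("types", "pairs", "settings"):
                raise ValueError(f"{path}:{ln}: unknown section [{section}]")
            continue
        tok = line.split()
        if section == "settings":
            if len(tok) != 2 or tok[0] not in ("com_cutoff", "ewald_accuracy",
                                               "epsilon_r"):
                raise ValueError(f"{path}:{ln}: expected 'key value' with a "
                                 "known settings key")
            kwargs.setdefault(tok[0], float(tok[1]))
        elif section == "types":
            if len(tok) != 4:
                raise ValueError(f"{path}:{ln}: expected 'label element mass charge'")
            types[tok[0]] = (tok[1], float(tok[2]), float(tok[3]))
        elif section == "pairs":
            if len(tok) != 5:
                raise ValueError(f"{path}:{ln}: expected 'type1 type2 A B C'")
            pairs[(tok[0], tok[1])] = PairParams(*map(float, tok[2:]))
        else:
            raise ValueError(f"{path}:{ln}: data before any section header")
    return ForceField(
        pair_params=pairs,
        charges={t: q for t, (_, _, q) in types.items()},
        masses={t: m for t, (_, m, _) in types.items()},
        elements={t: el for t, (el, _, _) in types.items()},
        **kwargs,
    )


def write_forcefield(ff: ForceField, path) -> None:
    lines = ["[types]", "# label element mass charge"]
    for t, q in ff.charges.items():
        el = ff.elements.get(t, t)
        m = ff.masses.get(t, 0.0)
        lines.append(f"{t} {el} {m:.6f} {q:.6f}")
    lines += ["[pairs]", "# type1 type2 A B C"]
    for (t1, t2), p in sorted(ff.pair_params.items()):
        lines.append(f"{t1} {t2} {p.A:.8g} {p.B:.8g} {p.C:.8g}")
    lines += ["[settings]",
              f"com_cutoff {ff.com_cutoff:.8g}",
              f"ewald_accuracy {ff.ewald_accuracy:.8g}",
              f"epsilon_r {ff.epsilon_r:.8g}"]
    Path(path).write_text("\n".join(lines) + "\n")
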