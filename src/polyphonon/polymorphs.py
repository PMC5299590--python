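"""Pairwise polymorph comparison, classification and error statistics.

A polymorph pair is compared through three energy differences (B minus A, per
molecule): the static lattice energy, the quasi-harmonic free energy at 0 K
(which includes zero-point energy) and at the melting point.  A pair whose
free-energy difference changes sign between 0 K and T_m is re-ranked — the
model predicts an enantiotropic relationship; otherwise the prediction is
monotropic, with the curves classified as diverging or converging according
to whether |dA| grows or shrinks with temperature.

Packing polymorphs are screened with a conformer RMSD filter: molecules whose
optimally superposed heavy-atom coordinates differ by more than 0.25 Å are
treated as conformational rather than packing polymorphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .forcefield import ForceField
from .qha import qha_state
from .structures import Crystal

__all__ = [
    "PolymorphPair",
    "PairClassification",
    "ErrorStats",
    "RMSD_FILTER_ANGSTROM",
    "conformer_rmsd",
    "classify_pair",
    "error_stats",
    "survey",
    "compare_pair",
    "load_expansion_benchmark",
]

#: conformer-difference threshold (Å) above which a pair is not a packing pair
RMSD_FILTER_ANGSTROM = 0.25


def conformer_rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    elements: list[str] | None = None,
    ignore_h: bool = True,
) -> float:
    """Minimum RMSD (Å) between two conformers over rigid superposition.

    Atom correspondence is by position in the arrays.  With ``ignore_h`` and
    an ``elements`` list, hydrogens are excluded before superposition.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must be matched (n, 3)")
    if ignore_h and elements is not None:
        keep = np.array([e.upper() != "H" for e in elements])
        a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError("need at least 3 (heavy) atoms for superposition")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(a, b)
    return float(rssd / np.sqrt(len(a)))


@dataclass
class PairClassification:
    relationship: str   # 'enantiotropic-predicted' | 'monotropic-predicted' | 'degenerate'
    curve_shape: str    # 'diverging' | 'converging' | 'degenerate'
    reranked: bool


def classify_pair(d_a0: float, d_a_tm: float, tol: float = 0.01) -> PairClassification:
    """Classify a pair from dA(0) and dA(T_m) (kJ/mol, same sign convention).

    Sign change with both magnitudes above ``tol`` means the stability order
    re-ranks between 0 K and melting: a predicted enantiotropic pair.  Values
    within ``tol`` of zero are reported as degenerate, never silently forced
    into a class.
    """
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    if abs(d_a0) <= tol or abs(d_a_tm) <= tol:
        return PairClassification("degenerate", "degenerate", False)
    if np.sign(d_a0) != np.sign(d_a_tm):
        return PairClassification("enantiotropic-predicted", "converging", True)
    shape = "diverging" if abs(d_a_tm) > abs(d_a0) else "converging"
    return PairClassification("monotropic-predicted", shape, False)


@dataclass
class PolymorphPair:
    """Energy differences (B - A, kJ/mol per molecule) and classification."""

    id_a: str
    id_b: str
    d_elatt: float
    d_a0: float
    d_a_tm: float
    t_m: float
    relationship: str = ""
    curve_shape: str = ""
    reranked: bool = False

    def classify(self, tol: float = 0.01) -> "PolymorphPair":
        c = classify_pair(self.d_a0, self.d_a_tm, tol=tol)
        self.relationship = c.relationship
        self.curve_shape = c.curve_shape
        self.reranked = c.reranked
        return self


@dataclass
class ErrorStats:
    """Mean absolute and mean signed percentage errors of (calc, exp) pairs."""

    mape: float
    mean_signed: float
    n: int


def error_stats(pairs) -> ErrorStats:
    """MA%E and mean signed error (%) of calculated vs experimental values."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 1:
        raise ValueError("expected a non-empty list of (calc, exp) pairs")
    calc, exp = arr[:, 0], arr[:, 1]
    zero = np.nonzero(exp == 0)[0]
    if zero.size:
        raise ValueError(f"experimental value is zero in row(s) {zero.tolist()}")
    rel = (calc - exp) / exp * 100.0
    return ErrorStats(
        mape=float(np.mean(np.abs(rel))),
        mean_signed=float(np.mean(rel)),
        n=len(arr),
    )


def survey(pairs: list[PolymorphPair], tol: float = 0.01) -> dict:
    """Summary of a set of polymorph pairs.

    Reports the fractions of re-ranked and diverging pairs and distribution
    summaries of the energy differences, including the QHA thermal-expansion
    contribution proxy dA(T_m) - dA(0).
    """
    if not pairs:
        raise ValueError("need at least one pair")
    for p in pairs:
        if not p.relationship:
            p.classify(tol=tol)
    n = len(pairs)
    frac_reranked = sum(p.reranked for p in pairs) / n
    frac_diverging = sum(p.curve_shape == "diverging" for p in pairs) / n
    frac_degenerate = sum(p.relationship == "degenerate" for p in pairs) / n

    def summary(vals):
        v = np.asarray(vals, dtype=float)
        return {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
            "q25": float(np.quantile(v, 0.25)),
            "median": float(np.quantile(v, 0.5)),
            "q75": float(np.quantile(v, 0.75)),
        }

    return {
        "n_pairs": n,
        "frac_reranked": frac_reranked,
        "frac_diverging": frac_diverging,
        "frac_degenerate": frac_degenerate,
        "d_elatt": summary([p.d_elatt for p in pairs]),
        "d_a0": summary([p.d_a0 for p in pairs]),
        "d_a_tm": summary([p.d_a_tm for p in pairs]),
        "vib_contribution": summary([p.d_a_tm - p.d_a0 for p in pairs]),
    }


def compare_pair(
    crystal_a: Crystal,
    crystal_b: Crystal,
    ff: ForceField,
    t_m: float,
    id_a: str = "A",
    id_b: str = "B",
    grid: tuple[int, int, int] = (3, 3, 3),
    tol: float = 0.01,
) -> PolymorphPair:
    """End-to-end pairwise comparison of two optimised polymorph structures.

    Both crystals must already be 0 K lattice-energy minima of ``ff``.
    Differences are B minus A, per molecule.
    """
    states = {}
    for label, crys in (("a", crystal_a), ("b", crystal_b)):
        s0 = qha_state(crys, ff, 0.0, grid=grid)
        st = qha_state(crys, ff, t_m, grid=grid)
        states[label] = (s0, st)
    (a0, at), (b0, bt) = states["a"], states["b"]
    pair = PolymorphPair(
        id_a=id_a, id_b=id_b,
        d_elatt=b0.e_latt_T - a0.e_latt_T,
        d_a0=b0.a_qha - a0.a_qha,
        d_a_tm=bt.a_qha - at.a_qha,
        t_m=t_m,
    )
    return pair.classify(tol=tol)


def load_expansion_benchmark() -> pd.DataFrame:
    """Benchmark table of calculated vs experimental volumetric expansion
    coefficients (10^-6 1/K) for eight well-characterised molecular crystals."""
    with resources.files("polyphonon.data").joinpath(
        "thermal_expansion_benchmark.csv"
    ).open() as fh:
        return pd.read_csv(fh, comment="#")
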