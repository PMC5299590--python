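"""Melting-point estimators.

Two estimators are provided: the Gold–Ogle rule T_m = 0.5839 T_b, and a
regression of melting temperature on the intermolecular lattice energy after
a variance-stabilising square-root (Anscombe) transform,

    T_m = beta0 + beta1 * sqrt(-E_inter),

fitted by ordinary least squares (the model is linear in the transformed
predictor).  The mean of a fragment-based estimate and the regression value
is the combined prediction; the fragment estimate itself is user-supplied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["MeltingModel", "gold_ogle", "fit_melting_model", "combined_estimate"]

GOLD_OGLE_COEFF = 0.5839


def gold_ogle(t_boil: float) -> float:
    """Melting point from the boiling point via T_m = 0.5839 T_b."""
    if t_boil <= 0:
        raise ValueError("boiling point must be positive")
    return GOLD_OGLE_COEFF * t_boil


@dataclass
class MeltingModel:
    """T_m = beta0 + beta1 sqrt(-E_inter); E_inter in kJ/mol (negative)."""

    beta0: float          # K
    beta1: float          # K (kJ/mol)^(-1/2)
    residual_sd: float    # K
    n_fit: int
    se_beta0: float = float("nan")
    se_beta1: float = float("nan")

    def predict(self, e_inter) -> np.ndarray | float:
        e = np.asarray(e_inter, dtype=float)
        if np.any(e >= 0):
            raise ValueError("model evaluable only for cohesive (negative) E_inter")
        out = self.beta0 + self.beta1 * np.sqrt(-e)
        return float(out) if out.ndim == 0 else out


def fit_melting_model(e_inter, t_m) -> MeltingModel:
    """OLS fit of T_m on sqrt(-E_inter).

    Residual standard deviation is sqrt(SSR / (n - 2)).
    """
    e = np.asarray(e_inter, dtype=float)
    t = np.asarray(t_m, dtype=float)
    if e.shape != t.shape or e.ndim != 1:
        raise ValueError("e_inter and t_m must be equal-length 1-D sequences")
    if len(e) < 3:
        raise ValueError("need at least 3 points to fit the melting model")
    if np.any(e >= 0):
        raise ValueError("all intermolecular energies must be negative")
    x = np.sqrt(-e)
    if np.ptp(x) < 1e-12:
        raise np.linalg.LinAlgError("constant predictor: rank-deficient fit")
    res = stats.linregress(x, t)
    resid = t - (res.intercept + res.slope * x)
    ssr = float(resid @ resid)
    n = len(e)
    sd = math.sqrt(ssr / (n - 2))
    se_b0 = res.intercept_stderr
    se_b1 = res.stderr
    return MeltingModel(
        beta0=float(res.intercept), beta1=float(res.slope),
        residual_sd=sd, n_fit=n, se_beta0=float(se_b0), se_beta1=float(se_b1),
    )


def combined_estimate(fragment_tm: float | None, model_tm: float | None) -> float:
    """Mean of the fragment-based and regression estimates.

    If one is missing the other is returned with a warning; both missing is
    an error.
    """
    vals = [v for v in (fragment_tm, model_tm) if v is not None]
    if not vals:
        raise ValueError("no melting-point estimate available")
    if any(v <= 0 for v in vals):
        raise ValueError("melting-point estimates must be positive")
    if len(vals) == 1:
        warnings.warn("only one melting-point estimator available; using it",
                      stacklevel=2)
        return float(vals[0])
    return 0.5 * (vals[0] + vals[1])
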