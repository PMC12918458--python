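"""Zellner-Siow (JZS) Bayes factors for linear-regression comparison.

BF10 against the intercept-only model is a one-dimensional integral over
the mixing parameter g of

    (1 + g)^((n - p - 1)/2) * (1 + g * (1 - R^2))^(-(n - 1)/2)

against the inverse-gamma(1/2, n * r_scale^2 / 2) prior density.  The
integral is evaluated deterministically on the log scale after mapping g to
the unit interval; no Monte Carlo is involved.

Omitted-predictor BF_01 values compare the reduced model (one predictor
dropped) against the full model, so low values mark the dropped predictor
as important.  Evidence categories use closed boundaries at 3 and 1/3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special

__all__ = [
    "DEFAULT_R_SCALE",
    "BFResult",
    "jzs_bf10",
    "bf01_omitted",
    "classify_evidence",
    "evidence_table",
    "CATEGORY_FAVORS_OMISSION",
    "CATEGORY_FAVORS_INCLUSION",
    "CATEGORY_INCONCLUSIVE",
]

#: Default prior scale on standardized effects ("medium", sqrt(2)/4).
DEFAULT_R_SCALE = float(np.sqrt(2.0) / 4.0)

CATEGORY_FAVORS_OMISSION = "favors-omission"      # BF_01 >= 3
CATEGORY_FAVORS_INCLUSION = "favors-inclusion"    # BF_01 <= 1/3
CATEGORY_INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class BFResult:
    predictors: tuple[str, ...]
    bf10: float
    log_bf10: float
    quad_error: float
    n: int
    p: int
    r_scale: float


def _log_integrand(g: np.ndarray, r2: float, n: int, p: int,
                   r_scale: float) -> np.ndarray:
    """Log of likelihood-ratio term times the inverse-gamma(1/2, b) prior."""
    b = n * r_scale * r_scale / 2.0
    g = np.asarray(g, dtype=float)
    out = np.full(g.shape, -np.inf)
    pos = g > 0
    gp = g[pos]
    ll = (0.5 * (n - p - 1) * np.log1p(gp)
          - 0.5 * (n - 1) * np.log1p(gp * (1.0 - r2)))
    log_prior = (0.5 * np.log(b) - special.gammaln(0.5)
                 - 1.5 * np.log(gp) - b / gp)
    out[pos] = ll + log_prior
    return out


def jzs_bf10(r2: float, n: int, p: int,
             r_scale: float = DEFAULT_R_SCALE,
             predictors: tuple[str, ...] = ()) -> BFResult:
    """JZS Bayes factor of a p-predictor model against the intercept-only model.

    Computed from the coefficient of determination alone, which is
    sufficient under the standardized formulation.
    """
    if not (0.0 <= r2 < 1.0):
        raise ValueError(f"R^2 must lie in [0, 1), got {r2}")
    if p < 1:
        raise ValueError("need at least one predictor")
    if n <= p + 1:
        raise ValueError(f"n = {n} too small for p = {p}")
    if r_scale <= 0:
        raise ValueError("r_scale must be positive")

    # map g = u / (1 - u) onto u in (0, 1); dg = du / (1 - u)^2
    def log_f(u) -> np.ndarray:
        u = np.atleast_1d(np.asarray(u, dtype=float))
        g = u / (1.0 - u)
        return _log_integrand(g, r2, n, p, r_scale) - 2.0 * np.log1p(-u)

    # locate the mode on a coarse grid to stabilize the exponential
    u_grid = np.linspace(1e-9, 1.0 - 1e-9, 4001)
    log_vals = log_f(u_grid)
    shift = float(np.max(log_vals))

    val, err = integrate.quad(lambda u: float(np.exp(log_f(u)[0] - shift)),
                              0.0, 1.0, limit=400, epsabs=1e-12, epsrel=1e-10)
    log_bf = shift + np.log(val)
    with np.errstate(over="ignore"):
        bf10 = float(np.exp(log_bf))
        quad_err = float(err * np.exp(shift))
    return BFResult(predictors=predictors, bf10=bf10,
                    log_bf10=float(log_bf), quad_error=quad_err,
                    n=n, p=p, r_scale=r_scale)


def bf01_omitted(r2_full: float, r2_reduced: float, n: int, p_full: int,
                 r_scale: float = DEFAULT_R_SCALE) -> float:
    """BF_01 of the reduced (one predictor omitted) model vs the full model.

    Defined as BF10(reduced) / BF10(full); values below 1/3 mark the omitted
    predictor as clearly important.  A reduced R^2 slightly above the full
    R^2 (rounding noise) is tolerated, not rejected.
    """
    if p_full < 2:
        raise ValueError("full model needs >= 2 predictors")
    for r2 in (r2_full, r2_reduced):
        if not (0.0 <= r2 < 1.0):
            raise ValueError(f"R^2 must lie in [0, 1), got {r2}")
    log_reduced = jzs_bf10(r2_reduced, n, p_full - 1, r_scale).log_bf10
    log_full = jzs_bf10(r2_full, n, p_full, r_scale).log_bf10
    # clamp so extreme evidence never under/overflows to 0 or inf
    return float(np.exp(np.clip(log_reduced - log_full, -690.0, 690.0)))


def classify_evidence(bf01: float) -> str:
    """Three-way category with closed boundaries at 3 and 1/3."""
    if not np.isfinite(bf01) or bf01 <= 0:
        raise ValueError(f"BF_01 must be a positive number, got {bf01}")
    if bf01 >= 3.0:
        return CATEGORY_FAVORS_OMISSION
    if bf01 <= 1.0 / 3.0:
        return CATEGORY_FAVORS_INCLUSION
    return CATEGORY_INCONCLUSIVE


def evidence_table(bf01_frame: pd.DataFrame) -> pd.DataFrame:
    """Classify a table of BF_01 values cell-wise, preserving its layout."""
    return bf01_frame.map(classify_evidence)
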