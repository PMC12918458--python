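"""Trait-by-method CFA fit by diagonally weighted least squares.

Fits a simple-structure factor model (each ordinal item loading on exactly
one trait-by-method factor, factor variances fixed at 1, all factor
correlations free unless constrained) to a polychoric correlation matrix by
minimizing the diagonally weighted least-squares discrepancy over the lower
triangle.  Also provides fit indices, AVE, the Fornell-Larcker check, HTMT
ratios, and nested model comparison for equality-constrained factor
correlations.

The reported test statistic is the naive T = (N - 1) * F_min; mean- or
mean-and-variance-scaled robust statistics are deliberately not computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .corr import CorrelationMatrix

__all__ = [
    "CFAModelSpec",
    "CFAFit",
    "FitIndices",
    "ValidityTable",
    "model_implied_corr",
    "fit_dwls",
    "fit_baseline",
    "fit_indices",
    "compute_ave",
    "fornell_larcker",
    "htmt",
    "compare_nested",
]


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass
class CFAModelSpec:
    """Item-to-factor assignment with optional fixed factor correlations.

    ``fixed_corr`` maps unordered factor-label pairs to a fixed value, e.g.
    ``{("SD3_mach", "DD_mach"): 1.0}`` for the constrained-overlap test.
    """

    factors: list[str]
    assignment: dict[str, str]           # item label -> factor label
    fixed_corr: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.factors)
        for item, f in self.assignment.items():
            if f not in known:
                raise ValueError(f"item {item!r} assigned to unknown factor {f!r}")
        for (a, b), v in self.fixed_corr.items():
            if a not in known or b not in known:
                raise ValueError(f"fixed correlation names unknown factor: {(a, b)}")
            if abs(v) > 1:
                raise ValueError(f"fixed correlation {v} outside [-1, 1]")

    @property
    def items(self) -> list[str]:
        return list(self.assignment)

    @property
    def n_items(self) -> int:
        return len(self.assignment)

    def factor_index(self) -> np.ndarray:
        pos = {f: i for i, f in enumerate(self.factors)}
        return np.array([pos[self.assignment[it]] for it in self.items])

    def free_corr_pairs(self) -> list[tuple[int, int]]:
        pos = {f: i for i, f in enumerate(self.factors)}
        fixed = {tuple(sorted((pos[a], pos[b]))) for a, b in self.fixed_corr}
        nf = len(self.factors)
        return [(a, b) for a in range(nf) for b in range(a + 1, nf)
                if (a, b) not in fixed]

    @property
    def n_free(self) -> int:
        return self.n_items + len(self.free_corr_pairs())

    @property
    def df(self) -> int:
        p = self.n_items
        return p * (p - 1) // 2 - self.n_free

    def fixed_phi(self) -> np.ndarray:
        """Factor-correlation template: fixed entries filled, others NaN."""
        pos = {f: i for i, f in enumerate(self.factors)}
        nf = len(self.factors)
        phi = np.full((nf, nf), np.nan)
        np.fill_diagonal(phi, 1.0)
        for (a, b), v in self.fixed_corr.items():
            i, j = pos[a], pos[b]
            phi[i, j] = phi[j, i] = v
        return phi


@dataclass
class CFAFit:
    spec: CFAModelSpec
    loadings: np.ndarray           # per item, order = spec.items
    factor_corr: np.ndarray        # over spec.factors
    f_min: float
    chi_square: float
    df: int
    n: int
    converged: bool
    srmr: float | None = None
    n_restarts_used: int = 0

    def loading_of(self, item: str) -> float:
        return float(self.loadings[self.spec.items.index(item)])

    def phi_of(self, fa: str, fb: str) -> float:
        i, j = self.spec.factors.index(fa), self.spec.factors.index(fb)
        return float(self.factor_corr[i, j])


@dataclass(frozen=True)
class FitIndices:
    cfi: float
    tli: float
    rmsea: float
    srmr: float


@dataclass
class ValidityTable:
    """Per-factor and per-pair convergent/discriminant validity evidence."""

    factors: list[str]
    ave: dict[str, float]
    ordinal_alpha: dict[str, float]
    factor_corr: np.ndarray
    fornell_larcker_pass: dict[str, bool]
    fl_pairs: dict[tuple[str, str], bool]
    htmt: dict[tuple[str, str], float]
    htmt_pass: dict[tuple[str, str], bool]
    htmt_threshold: float = 0.85


# ---------------------------------------------------------------------------
# model-implied structure
# ---------------------------------------------------------------------------

def model_implied_corr(loadings: np.ndarray, phi: np.ndarray,
                       spec: CFAModelSpec) -> CorrelationMatrix:
    """Implied item correlations r_ij = lambda_i * Phi_ab * lambda_j."""
    lam = np.asarray(loadings, dtype=float)
    if np.any(np.abs(lam) >= 1):
        raise ValueError("standardized loadings must satisfy |lambda| < 1")
    f = spec.factor_index()
    sigma = np.outer(lam, lam) * np.asarray(phi)[np.ix_(f, f)]
    np.fill_diagonal(sigma, 1.0)
    return CorrelationMatrix(spec.items, sigma, kind="implied")


# ---------------------------------------------------------------------------
# DWLS fit
# ---------------------------------------------------------------------------

def _unpack(theta: np.ndarray, spec: CFAModelSpec,
            free_pairs: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    p = spec.n_items
    lam = theta[:p]
    phi = spec.fixed_phi()
    phi[np.isnan(phi)] = 0.0
    for k, (a, b) in enumerate(free_pairs):
        phi[a, b] = phi[b, a] = theta[p + k]
    return lam, phi


def fit_dwls(poly: CorrelationMatrix, spec: CFAModelSpec, n: int,
             weights: np.ndarray | None = None, seed: int = 0,
             max_restarts: int = 3) -> CFAFit:
    """Minimize the DWLS discrepancy over the lower-triangle correlations.

    ``weights`` is a symmetric matrix of asymptotic variances of the
    polychoric estimates (diagonal ignored); ``None`` falls back to unit
    weights (unweighted least squares).  The start is deterministic
    (loadings .5, correlations .3) with up to ``max_restarts`` seeded
    jittered restarts on failure.
    """
    s = poly.submatrix(spec.items)
    p = spec.n_items
    iu = np.triu_indices(p, 1)
    s_vec = s[iu]
    if weights is None:
        w_vec = np.ones_like(s_vec)
    else:
        # estimator variances scale like 1/n; rescale to per-observation
        # asymptotic variances so T = (N - 1) * F_min is on the chi2 scale
        w_vec = np.asarray(weights)[iu].astype(float) * n
        bad = ~np.isfinite(w_vec) | (w_vec <= 0)
        if np.all(bad):
            w_vec = np.ones_like(s_vec)
        elif np.any(bad):
            w_vec = np.where(bad, np.nanmedian(w_vec[~bad]), w_vec)
    w_inv = 1.0 / w_vec

    f_idx = spec.factor_index()
    free_pairs = spec.free_corr_pairs()
    n_par = p + len(free_pairs)

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        lam, phi = _unpack(theta, spec, free_pairs)
        phi_items = phi[np.ix_(f_idx, f_idx)]
        sigma = np.outer(lam, lam) * phi_items
        resid = s_vec - sigma[iu]
        f_val = float(np.sum(w_inv * resid * resid))
        # gradient via the symmetric weighted-residual matrix M
        m = np.zeros((p, p))
        m[iu] = w_inv * resid
        m = m + m.T
        g_lam = -2.0 * np.sum(m * phi_items * lam[None, :], axis=1)
        g_phi = np.empty(len(free_pairs))
        outer = np.outer(lam, lam) * m
        for k, (a, b) in enumerate(free_pairs):
            g_phi[k] = -2.0 * np.sum(outer[np.ix_(f_idx == a, f_idx == b)])
        return f_val, np.concatenate([g_lam, g_phi])

    bounds = [(-0.999, 0.999)] * n_par
    x0 = np.concatenate([np.full(p, 0.5), np.full(len(free_pairs), 0.3)])
    rng = np.random.default_rng(seed)
    best = None
    restarts_used = 0
    for attempt in range(max_restarts + 1):
        start = x0 if attempt == 0 else np.clip(
            x0 + rng.normal(scale=0.15, size=n_par), -0.9, 0.9)
        res = optimize.minimize(objective, start, jac=True, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": 2000, "ftol": 1e-14,
                                         "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
            restarts_used = attempt
        if res.success:
            break

    lam, phi = _unpack(best.x, spec, free_pairs)
    f_min = float(best.fun)
    sigma = np.outer(lam, lam) * phi[np.ix_(f_idx, f_idx)]
    resid = s_vec - sigma[iu]
    srmr = float(np.sqrt(np.mean(resid ** 2)))
    return CFAFit(spec=spec, loadings=lam, factor_corr=phi, f_min=f_min,
                  chi_square=(n - 1) * f_min, df=spec.df, n=n,
                  converged=bool(best.success), srmr=srmr,
                  n_restarts_used=restarts_used)


def fit_baseline(poly: CorrelationMatrix, items: list[str], n: int,
                 weights: np.ndarray | None = None) -> CFAFit:
    """Independence baseline: implied item correlations all zero."""
    s = poly.submatrix(items)
    p = len(items)
    iu = np.triu_indices(p, 1)
    s_vec = s[iu]
    if weights is None:
        w_inv = np.ones_like(s_vec)
    else:
        w_vec = np.asarray(weights)[iu].astype(float) * n
        bad = ~np.isfinite(w_vec) | (w_vec <= 0)
        w_vec = np.where(bad, np.nanmedian(np.where(bad, np.nan, w_vec)), w_vec)
        w_inv = 1.0 / w_vec
    f_min = float(np.sum(w_inv * s_vec ** 2))
    spec = CFAModelSpec(factors=["__null__"],
                        assignment={it: "__null__" for it in items})
    return CFAFit(spec=spec, loadings=np.zeros(p), factor_corr=np.eye(1),
                  f_min=f_min, chi_square=(n - 1) * f_min,
                  df=p * (p - 1) // 2, n=n, converged=True,
                  srmr=float(np.sqrt(np.mean(s_vec ** 2))))


# ---------------------------------------------------------------------------
# fit indices and validity statistics
# ---------------------------------------------------------------------------

def fit_indices(fit: CFAFit, baseline: CFAFit, n: int | None = None) -> FitIndices:
    """CFI / TLI / RMSEA / SRMR from the naive chi-square statistics."""
    n = n or fit.n
    t_m, df_m = fit.chi_square, fit.df
    t_b, df_b = baseline.chi_square, baseline.df
    num = max(t_m - df_m, 0.0)
    cfi = 1.0 - num / max(t_b - df_b, t_m - df_m, 1e-300)
    if df_m == 0 or df_b == 0:
        tli = float("nan")
        rmsea = float("nan")
    else:
        ratio_b = t_b / df_b
        tli = (ratio_b - t_m / df_m) / (ratio_b - 1.0)
        rmsea = float(np.sqrt(max(t_m - df_m, 0.0) / (df_m * (n - 1))))
    return FitIndices(cfi=float(cfi), tli=float(tli), rmsea=rmsea,
                      srmr=float(fit.srmr))


def compute_ave(loadings) -> float:
    """Average variance extracted: mean squared standardized loading."""
    lam = np.asarray(loadings, dtype=float)
    if lam.size == 0:
        raise ValueError("AVE requires at least one loading")
    return float(np.mean(lam ** 2))


def fornell_larcker(ave: dict[str, float], phi: np.ndarray,
                    factors: list[str]
                    ) -> tuple[dict[str, bool], dict[tuple[str, str], bool]]:
    """Discriminant validity: sqrt(AVE) must strictly exceed every |phi|.

    Ties fail (strict inequality).  Returns per-factor verdicts and the
    per-pair diagnostics they aggregate.
    """
    per_pair: dict[tuple[str, str], bool] = {}
    per_factor: dict[str, bool] = {}
    for i, fa in enumerate(factors):
        ok = True
        for j, fb in enumerate(factors):
            if i == j:
                continue
            passed = np.sqrt(ave[fa]) > abs(phi[i, j])
            per_pair[(fa, fb)] = bool(passed)
            ok = ok and passed
        per_factor[fa] = bool(ok)
    return per_factor, per_pair


def htmt(item_corr: CorrelationMatrix, assignment: dict[str, str],
         factor_pair: tuple[str, str],
         denominator_rule: str = "arithmetic") -> float:
    """Between-set over within-set mean item correlations for a factor pair.

    ``denominator_rule`` is ``"arithmetic"`` (mean of the two within-set
    mean correlations) or ``"geometric"`` (their geometric mean).  Returns
    NaN when the denominator is not positive.
    """
    if denominator_rule not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown denominator rule {denominator_rule!r}")
    fa, fb = factor_pair
    items_a = [it for it, f in assignment.items() if f == fa]
    items_b = [it for it, f in assignment.items() if f == fb]
    if len(items_a) < 2 or len(items_b) < 2:
        raise ValueError("HTMT needs >= 2 items per factor")

    between = float(np.mean(item_corr.between(items_a, items_b)))

    def within_mean(items: list[str]) -> float:
        sub = item_corr.submatrix(items)
        k = sub.shape[0]
        return float(np.mean(sub[np.triu_indices(k, 1)]))

    wa, wb = within_mean(items_a), within_mean(items_b)
    if denominator_rule == "arithmetic":
        denom = 0.5 * (wa + wb)
    else:
        prod = wa * wb
        denom = float(np.sqrt(prod)) if prod > 0 else -1.0
    if denom <= 0:
        return float("nan")
    return between / denom


def validity_table(fit: CFAFit, item_corr: CorrelationMatrix,
                   alpha_fn, trait_pairs: list[tuple[str, str]],
                   denominator_rule: str = "arithmetic",
                   htmt_threshold: float = 0.85) -> ValidityTable:
    """Assemble AVE, ordinal alpha, Fornell-Larcker, and HTMT in one table.

    ``alpha_fn`` maps a factor label to its (ordinal) alpha; ``trait_pairs``
    lists the factor pairs (typically same trait, different method) to score
    with HTMT.
    """
    spec = fit.spec
    ave = {}
    alphas = {}
    lam = fit.loadings
    f_idx = spec.factor_index()
    for i, f in enumerate(spec.factors):
        ave[f] = compute_ave(lam[f_idx == i])
        alphas[f] = alpha_fn(f)
    per_factor, per_pair = fornell_larcker(ave, fit.factor_corr, spec.factors)
    ratios = {}
    verdicts = {}
    for pair in trait_pairs:
        r = htmt(item_corr, spec.assignment, pair, denominator_rule)
        ratios[pair] = r
        verdicts[pair] = bool(r < htmt_threshold) if np.isfinite(r) else False
    return ValidityTable(factors=list(spec.factors), ave=ave,
                         ordinal_alpha=alphas, factor_corr=fit.factor_corr,
                         fornell_larcker_pass=per_factor, fl_pairs=per_pair,
                         htmt=ratios, htmt_pass=verdicts,
                         htmt_threshold=htmt_threshold)


# ---------------------------------------------------------------------------
# nested comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NestedComparison:
    delta_chi2: float
    delta_df: int
    p_value: float
    anomaly: bool  # constrained model fit better than free (non-monotone)


def compare_nested(fit_free: CFAFit, fit_constrained: CFAFit) -> NestedComparison:
    """Chi-square difference test for a constrained vs free factor model."""
    ddf = fit_constrained.df - fit_free.df
    if ddf <= 0:
        raise ValueError("constrained model must have more df than free model")
    d = fit_constrained.chi_square - fit_free.chi_square
    anomaly = d < 0
    d_stat = max(d, 0.0)
    p = float(stats.chi2.sf(d_stat, ddf)) if d_stat > 0 else 1.0
    return NestedComparison(delta_chi2=float(d), delta_df=int(ddf),
                            p_value=p, anomaly=bool(anomaly))
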