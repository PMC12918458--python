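"""Descriptive statistics, reliability, and correlation machinery.

Provides the numeric substrate used by every later analysis stage:
moment-based descriptives with the +/-2 skew/kurtosis screen, standardized
(Cronbach) alpha from a correlation matrix, Pearson and polychoric
correlation estimation, Fisher's z transform, and standardized OLS
regression computed directly from correlation input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Descriptives",
    "CorrelationMatrix",
    "RegressionResult",
    "PolychoricResult",
    "describe",
    "cronbach_alpha",
    "pearson_matrix",
    "polychoric_corr",
    "polychoric_matrix",
    "fisher_z",
    "fisher_z_inv",
    "standardized_ols",
    "smooth_to_psd",
]

#: |skewness| and |kurtosis| beyond this are flagged out of range.
MOMENT_SCREEN = 2.0

#: Polychoric estimates are clipped to +/- this bound.
RHO_CLIP = 0.999


# ---------------------------------------------------------------------------
# dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Descriptives:
    """Sample moments for one variable plus the +/-2 screening flag."""

    n_valid: int
    mean: float
    sd: float
    skewness: float
    kurtosis: float
    in_range: bool
    undefined_moments: bool = False


@dataclass
class CorrelationMatrix:
    """Labeled symmetric correlation matrix with provenance metadata."""

    labels: list[str]
    values: np.ndarray
    kind: str = "pearson"  # "pearson" | "polychoric"
    n: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {k} labels"
            )
        self.validate()

    def validate(self, atol: float = 1e-8) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=atol):
            raise ValueError("correlation matrix diagonal is not 1")
        finite = np.isfinite(v)
        if np.any(np.abs(v[finite]) > 1 + atol):
            raise ValueError("correlation entries outside [-1, 1]")

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def submatrix(self, labels: list[str]) -> np.ndarray:
        idx = [self.index(l) for l in labels]
        return self.values[np.ix_(idx, idx)]

    def between(self, rows: list[str], cols: list[str]) -> np.ndarray:
        ri = [self.index(l) for l in rows]
        ci = [self.index(l) for l in cols]
        return self.values[np.ix_(ri, ci)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, kind: str = "pearson",
                   n: int | None = None) -> "CorrelationMatrix":
        return cls(list(frame.columns), frame.to_numpy(dtype=float), kind=kind, n=n)


@dataclass(frozen=True)
class RegressionResult:
    """Standardized regression of one criterion on a predictor set."""

    criterion: str
    predictors: tuple[str, ...]
    betas: tuple[float, ...]
    r_squared: float
    p_values: tuple[float, ...]
    n: int


@dataclass(frozen=True)
class PolychoricResult:
    """Two-step polychoric estimate with the threshold vectors used."""

    rho: float
    tau_x: tuple[float, ...]
    tau_y: tuple[float, ...]
    var_rho: float | None = None
    converged: bool = True


# ---------------------------------------------------------------------------
# descriptives and reliability
# ---------------------------------------------------------------------------

def describe(values, kurtosis_excess: bool = True) -> Descriptives:
    """Moment-based descriptives with the adjusted (sample-corrected) g1/g2.

    A constant vector yields sd = 0 and an ``undefined_moments`` flag rather
    than an exception.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("describe requires at least 3 finite values")
    n = x.size
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return Descriptives(n, mean, 0.0, np.nan, np.nan,
                            in_range=False, undefined_moments=True)
    skew = float(stats.skew(x, bias=False))
    kurt = float(stats.kurtosis(x, fisher=kurtosis_excess, bias=False))
    in_range = abs(skew) <= MOMENT_SCREEN and abs(kurt) <= MOMENT_SCREEN
    return Descriptives(n, mean, sd, skew, kurt, in_range=in_range)


def cronbach_alpha(corr: CorrelationMatrix, items: list[str] | None = None) -> float:
    """Standardized alpha k*rbar / (1 + (k-1)*rbar) from a correlation matrix.

    Applied to a polychoric matrix this is ordinal alpha.  Returns ``nan``
    when rbar <= -1/(k-1) (alpha undefined).
    """
    labels = items if items is not None else corr.labels
    if len(labels) < 2:
        raise ValueError("alpha requires at least 2 items")
    sub = corr.submatrix(list(labels))
    k = sub.shape[0]
    off = sub[np.triu_indices(k, 1)]
    rbar = float(np.mean(off))
    denom = 1.0 + (k - 1) * rbar
    if denom <= 0:
        return float("nan")
    return k * rbar / denom


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------

def pearson_matrix(data: pd.DataFrame, policy: str = "listwise") -> CorrelationMatrix:
    """Product-moment correlation matrix of numeric columns.

    ``policy`` is ``"listwise"`` (drop any row with a missing value) or
    ``"pairwise"``.  Zero-variance columns get NaN correlations.
    """
    if policy not in ("listwise", "pairwise"):
        raise ValueError(f"unknown missing-data policy {policy!r}")
    if policy == "listwise":
        data = data.dropna()
        if len(data) < 3:
            raise ValueError("fewer than 3 complete rows after listwise deletion")
        values = data.corr(min_periods=3).to_numpy()
        n = len(data)
    else:
        values = data.corr(min_periods=3).to_numpy()
        n = int(data.notna().all(axis=1).sum())
    np.fill_diagonal(values, 1.0)
    return CorrelationMatrix(list(data.columns), values, kind="pearson", n=n)


# ---------------------------------------------------------------------------
# polychoric
# ---------------------------------------------------------------------------

def _bvn_cdf(h: np.ndarray, k: np.ndarray, rho: float) -> np.ndarray:
    """Standard bivariate normal CDF P(X<=h, Y<=k), vectorized.

    Drezner & Wesolowsky Gauss-Legendre scheme; relative accuracy ~1e-14.
    Infinite bounds are handled exactly via the univariate marginal.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    out = np.empty(h.shape, dtype=float)

    hf = np.where(np.isfinite(h), h, 0.0)
    kf = np.where(np.isfinite(k), k, 0.0)
    # interior: both bounds finite
    interior = np.isfinite(h) & np.isfinite(k)
    out[interior] = _bvn_cdf_finite(hf[interior], kf[interior], rho)
    # edges collapse to univariate marginals
    out[h == np.inf] = stats.norm.cdf(k[h == np.inf])
    out[k == np.inf] = np.where(
        np.isfinite(h[k == np.inf]), stats.norm.cdf(h[k == np.inf]), out[k == np.inf]
    )
    out[(h == np.inf) & (k == np.inf)] = 1.0
    out[(h == -np.inf) | (k == -np.inf)] = 0.0
    return out


# 24-point Gauss-Legendre nodes/weights on [0, 1]
_GL_X, _GL_W = np.polynomial.legendre.leggauss(24)
_GL_X = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W


def _bvn_cdf_finite(h: np.ndarray, k: np.ndarray, rho: float) -> np.ndarray:
    if abs(rho) < 1e-14:
        return stats.norm.cdf(h) * stats.norm.cdf(k)
    rho = float(np.clip(rho, -RHO_CLIP, RHO_CLIP))
    # Phi2(h,k;rho) = Phi(h)Phi(k)
    #   + 1/(2*pi) * int_0^arcsin(rho) exp(-(h^2 - 2*h*k*sin(u) + k^2)
    #                                       / (2*cos^2(u))) du
    # (tetrachoric identity with t = sin(u); no endpoint singularity)
    a = np.arcsin(rho)
    u = a * _GL_X
    hh = h[:, None]
    kk = k[:, None]
    sin_u = np.sin(u)[None, :]
    cos2_u = np.cos(u)[None, :] ** 2
    integrand = np.exp(-(hh * hh - 2.0 * sin_u * hh * kk + kk * kk) / (2.0 * cos2_u))
    integral = a * (integrand @ _GL_W)
    return stats.norm.cdf(h) * stats.norm.cdf(k) + integral / (2.0 * np.pi)


def _thresholds(counts: np.ndarray) -> np.ndarray:
    """Inverse-normal thresholds from marginal category counts."""
    cum = np.cumsum(counts) / counts.sum()
    return stats.norm.ppf(cum[:-1])


def _cell_probs(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    tx = np.concatenate(([-np.inf], tau_x, [np.inf]))
    ty = np.concatenate(([-np.inf], tau_y, [np.inf]))
    grid = _bvn_cdf(tx[:, None], ty[None, :], rho)
    return np.diff(np.diff(grid, axis=0), axis=1)


def polychoric_corr(x, y, name_x: str = "x", name_y: str = "y",
                    with_variance: bool = False) -> PolychoricResult:
    """Two-step polychoric correlation of two ordinal vectors.

    Thresholds come from the inverse-normal cumulative marginals; rho then
    maximizes the bivariate-normal likelihood of the contingency table over
    (-1, 1) and is clipped to +/-0.999.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    mask = np.isfinite(x.astype(float)) & np.isfinite(y.astype(float))
    x, y = x[mask], y[mask]
    cats_x, xi = np.unique(x, return_inverse=True)
    cats_y, yi = np.unique(y, return_inverse=True)
    if cats_x.size < 2:
        raise ValueError(f"variable {name_x!r} has a single observed category")
    if cats_y.size < 2:
        raise ValueError(f"variable {name_y!r} has a single observed category")
    table = np.zeros((cats_x.size, cats_y.size))
    np.add.at(table, (xi, yi), 1.0)
    tau_x = _thresholds(table.sum(axis=1))
    tau_y = _thresholds(table.sum(axis=0))

    def nll(rho: float) -> float:
        probs = np.clip(_cell_probs(tau_x, tau_y, rho), 1e-300, None)
        return -float(np.sum(table * np.log(probs)))

    res = optimize.minimize_scalar(nll, bounds=(-RHO_CLIP, RHO_CLIP),
                                   method="bounded",
                                   options={"xatol": 1e-7})
    rho = float(np.clip(res.x, -RHO_CLIP, RHO_CLIP))
    var_rho = None
    if with_variance:
        var_rho = _rho_variance(nll, rho)
    return PolychoricResult(rho, tuple(tau_x), tuple(tau_y),
                            var_rho=var_rho, converged=bool(res.success))


def _rho_variance(nll, rho: float, eps: float = 1e-4) -> float:
    """Asymptotic variance 1/I(rho) from the profile likelihood curvature."""
    r = float(np.clip(rho, -RHO_CLIP + 2 * eps, RHO_CLIP - 2 * eps))
    d2 = (nll(r + eps) - 2.0 * nll(r) + nll(r - eps)) / (eps * eps)
    if not np.isfinite(d2) or d2 <= 0:
        return np.nan
    return 1.0 / d2


def polychoric_matrix(data: pd.DataFrame, smooth: bool = True,
                      with_variance: bool = False
                      ) -> tuple[CorrelationMatrix, np.ndarray | None]:
    """Pairwise polychoric matrix of ordinal columns, smoothed to PSD.

    Returns the matrix and, when requested, the symmetric matrix of
    asymptotic rho variances (diagonal NaN) used as DWLS weights.
    """
    cols = list(data.columns)
    k = len(cols)
    values = np.eye(k)
    variances = np.full((k, k), np.nan) if with_variance else None
    for i in range(k):
        for j in range(i + 1, k):
            res = polychoric_corr(data[cols[i]], data[cols[j]],
                                  name_x=cols[i], name_y=cols[j],
                                  with_variance=with_variance)
            values[i, j] = values[j, i] = res.rho
            if with_variance:
                variances[i, j] = variances[j, i] = res.var_rho
    if smooth:
        values = smooth_to_psd(values)
    mat = CorrelationMatrix(cols, values, kind="polychoric", n=len(data.dropna()))
    return mat, variances


def smooth_to_psd(values: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Nearest-PSD smoothing: clip negative eigenvalues, rescale to unit diag."""
    w, v = np.linalg.eigh((values + values.T) / 2.0)
    if w.min() >= eps:
        return values
    w = np.clip(w, max(eps, 1e-10), None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


# ---------------------------------------------------------------------------
# Fisher z and standardized OLS
# ---------------------------------------------------------------------------

def fisher_z(r):
    """Fisher's variance-stabilizing transform z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def fisher_z_inv(z):
    z = np.asarray(z, dtype=float)
    out = np.tanh(z)
    return float(out) if out.ndim == 0 else out


def standardized_ols(corr: CorrelationMatrix, criterion: str,
                     predictors: list[str], n: int | None = None) -> RegressionResult:
    """Standardized regression from correlation input.

    beta = Rxx^-1 r_xy and R^2 = r_xy' beta; p-values from t statistics with
    n - p - 1 degrees of freedom.
    """
    if n is None:
        n = corr.n
    if n is None:
        raise ValueError("sample size n required for inference")
    p = len(predictors)
    if n <= p + 1:
        raise ValueError(f"n = {n} too small for {p} predictors")
    rxx = corr.submatrix(list(predictors))
    rxy = corr.between(list(predictors), [criterion])[:, 0]
    cond = np.linalg.cond(rxx)
    if cond > 1e10:
        raise ValueError(
            f"singular predictor block for {criterion!r}: {predictors} "
            f"(condition number {cond:.2e})"
        )
    betas = np.linalg.solve(rxx, rxy)
    r2 = float(rxy @ betas)
    r2 = min(max(r2, 0.0), 1.0)
    df = n - p - 1
    rxx_inv_diag = np.diag(np.linalg.inv(rxx))
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt((1.0 - r2) / df * rxx_inv_diag)
        tvals = betas / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    return RegressionResult(criterion, tuple(predictors), tuple(betas),
                            r2, tuple(pvals), n)
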