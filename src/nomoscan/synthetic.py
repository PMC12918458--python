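"""Seeded synthetic-data generator with a latent trait-by-method structure.

Produces ordinal Likert item tables plus continuous criterion scores from a
fully specified latent model: multivariate-normal factor scores with a
trait-by-method correlation structure, single-loading items discretized at
fixed thresholds, and criteria built as weighted combinations of trait
scores.  Ground truth is exported so recovery tests can compare estimates
against the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MethodSpec",
    "CriterionSpec",
    "MTMMModelSpec",
    "GroundTruth",
    "build_model_spec",
    "default_config",
    "divergent_config",
    "simulate_latent_scores",
    "discretize_to_likert",
    "simulate_criterion_scores",
    "simulate_dataset",
]


@dataclass(frozen=True)
class MethodSpec:
    """One measurement method: items per trait and response categories."""

    label: str
    items_per_trait: int
    n_categories: int

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError(f"method {self.label!r}: need K >= 2 categories")
        if self.items_per_trait < 1:
            raise ValueError(f"method {self.label!r}: need >= 1 item per trait")


@dataclass(frozen=True)
class CriterionSpec:
    """A criterion variable generated from trait scores.

    ``trait_weights`` holds one weight per trait; ``method_weights``, when
    given, overrides it with a per-method weight vector so the two methods'
    criterion profiles can be made to diverge.
    """

    name: str
    set_name: str
    trait_weights: tuple[float, ...]
    resid_sd: float
    method_weights: dict[str, tuple[float, ...]] | None = None

    def __post_init__(self) -> None:
        if self.resid_sd < 0:
            raise ValueError(f"criterion {self.name!r}: negative residual s.d.")


@dataclass
class MTMMModelSpec:
    """Complete generating model for a trait-by-method ordinal inventory."""

    traits: list[str]
    methods: list[MethodSpec]
    loadings: np.ndarray            # one per item, order = item_labels
    factor_corr: np.ndarray         # over factors, order = factor_labels
    thresholds: list[np.ndarray]    # one strictly increasing vector per item
    criteria: list[CriterionSpec] = field(default_factory=list)

    # ----- derived layout -------------------------------------------------
    @property
    def factor_labels(self) -> list[str]:
        return [f"{m.label}_{t}" for m in self.methods for t in self.traits]

    @property
    def n_factors(self) -> int:
        return len(self.traits) * len(self.methods)

    @property
    def item_labels(self) -> list[str]:
        labels = []
        for m in self.methods:
            for t in self.traits:
                labels += [f"{m.label}_{t}_i{k + 1}"
                           for k in range(m.items_per_trait)]
        return labels

    @property
    def item_factor_index(self) -> np.ndarray:
        """Factor index of each item (simple structure: one factor each)."""
        idx = []
        f = 0
        for m in self.methods:
            for _t in self.traits:
                idx += [f] * m.items_per_trait
                f += 1
        return np.array(idx)

    @property
    def n_items(self) -> int:
        return sum(m.items_per_trait * len(self.traits) for m in self.methods)

    def item_categories(self) -> np.ndarray:
        cats = []
        for m in self.methods:
            cats += [m.n_categories] * (m.items_per_trait * len(self.traits))
        return np.array(cats)

    # ----- validation -----------------------------------------------------
    def validate(self) -> None:
        k = self.n_items
        if self.loadings.shape != (k,):
            raise ValueError(f"expected {k} loadings, got {self.loadings.shape}")
        if np.any(self.loadings < 0) or np.any(self.loadings >= 1):
            raise ValueError("loadings must lie in [0, 1)")
        phi = self.factor_corr
        nf = self.n_factors
        if phi.shape != (nf, nf):
            raise ValueError(f"factor_corr must be {nf}x{nf}")
        if not np.allclose(phi, phi.T):
            raise ValueError("factor_corr must be symmetric")
        if not np.allclose(np.diag(phi), 1.0):
            raise ValueError("factor_corr must have unit diagonal")
        off = phi[~np.eye(nf, dtype=bool)]
        if np.any(np.abs(off) > 1.0):
            bad = off[np.abs(off) > 1.0][0]
            raise ValueError(f"factor correlation {bad} outside [-1, 1]")
        eigmin = float(np.linalg.eigvalsh(phi).min())
        if eigmin <= 0:
            raise ValueError(
                f"factor_corr is not positive definite "
                f"(smallest eigenvalue {eigmin:.6g})"
            )
        if len(self.thresholds) != k:
            raise ValueError(f"expected {k} threshold vectors")
        cats = self.item_categories()
        for label, tau, kc in zip(self.item_labels, self.thresholds, cats):
            tau = np.asarray(tau, float)
            if tau.shape != (kc - 1,):
                raise ValueError(
                    f"item {label!r}: expected {kc - 1} thresholds, got {tau.shape}"
                )
            if np.any(np.diff(tau) <= 0):
                raise ValueError(f"item {label!r}: thresholds not strictly increasing")
        for c in self.criteria:
            if len(c.trait_weights) != len(self.traits):
                raise ValueError(
                    f"criterion {c.name!r}: expected {len(self.traits)} weights"
                )
            if c.method_weights is not None:
                for m in self.methods:
                    if m.label not in c.method_weights:
                        raise ValueError(
                            f"criterion {c.name!r}: missing weights for "
                            f"method {m.label!r}"
                        )

    def implied_item_corr(self) -> np.ndarray:
        """Model-implied item correlations lambda_i * Phi_ab * lambda_j."""
        f = self.item_factor_index
        lam = self.loadings
        sigma = np.outer(lam, lam) * self.factor_corr[np.ix_(f, f)]
        np.fill_diagonal(sigma, 1.0)
        return sigma


@dataclass(frozen=True)
class GroundTruth:
    """Latent scores plus the generating spec and seed, for recovery tests."""

    latent_scores: pd.DataFrame
    spec: MTMMModelSpec
    seed: int


# ---------------------------------------------------------------------------
# default preset configuration
# ---------------------------------------------------------------------------

#: Cross-method same-trait factor correlations of the default preset.
DEFAULT_CONVERGENT_CORR = (0.927, 0.718, 0.876)

_DEFAULT_CRITERIA = [
    # (name, set, w_mach, w_nar, w_psych)
    ("BEES", "psychopathy_empathy", -0.20, 0.00, -0.30),
    ("IRI_F", "psychopathy_empathy", 0.10, 0.00, -0.20),
    ("IRI_EC", "psychopathy_empathy", -0.15, 0.05, -0.30),
    ("IRI_PT", "psychopathy_empathy", -0.10, 0.03, -0.17),
    ("IRI_PD", "psychopathy_empathy", 0.13, -0.18, -0.15),
    ("LSRP_PP", "psychopathy_empathy", 0.35, 0.10, 0.35),
    ("LSRP_SP", "psychopathy_empathy", 0.20, -0.18, 0.25),
    ("BFQ_E", "ffm", -0.03, 0.42, 0.08),
    ("BFQ_A", "ffm", -0.24, 0.06, -0.28),
    ("BFQ_C", "ffm", -0.09, 0.24, -0.17),
    ("BFQ_EmSt", "ffm", -0.07, 0.05, -0.09),
    ("BFQ_O", "ffm", -0.04, 0.16, -0.07),
    ("SHS", "mental_health", -0.08, 0.22, 0.03),
    ("BPNS_Aut", "mental_health", -0.20, 0.19, 0.10),
    ("BPNS_Com", "mental_health", -0.16, 0.34, -0.08),
    ("BPNS_Rel", "mental_health", -0.21, 0.28, -0.10),
    ("STICSA", "mental_health", 0.11, -0.11, 0.06),
    ("TDI", "mental_health", 0.10, -0.20, 0.08),
    ("DvC_Pros", "disinhibition", -0.11, 0.25, -0.22),
    ("DvC_Distr", "disinhibition", 0.19, -0.22, 0.17),
    ("DvC_Manip", "disinhibition", 0.42, 0.11, 0.30),
    ("DvC_Order", "disinhibition", -0.06, 0.04, -0.19),
    ("DvC_Risk", "disinhibition", -0.04, 0.10, 0.30),
    ("MC", "desirability", -0.25, -0.10, -0.20),
]


def default_config() -> dict:
    """Default generator settings: 3 traits x 2 methods, 27 + 12 items."""
    return {
        "traits": ["mach", "nar", "psych"],
        "methods": [
            {"label": "SD3", "items_per_trait": 9, "n_categories": 5},
            {"label": "DD", "items_per_trait": 4, "n_categories": 7},
        ],
        "convergent_corr": list(DEFAULT_CONVERGENT_CORR),
        "within_method_corr": {"SD3": 0.55, "DD": 0.50},
        "cross_method_heterotrait_corr": 0.45,
        "loading_range": {"SD3": (0.50, 0.78), "DD": (0.68, 0.85)},
        "threshold_skew": 0.25,
        "criteria": [
            {"name": n, "set": s, "weights": [wm, wn, wp]}
            for (n, s, wm, wn, wp) in _DEFAULT_CRITERIA
        ],
    }


def divergent_config() -> dict:
    """Generator settings whose two methods measure visibly different things.

    Convergent correlations are lowered and the second method's criterion
    weights are permuted across traits, so the consistency benchmarks should
    flag every criterion set.
    """
    config = default_config()
    config["convergent_corr"] = [0.45, 0.30, 0.40]
    for c in config["criteria"]:
        w = c["weights"]
        c["method_weights"] = {"SD3": list(w), "DD": [w[1], w[2], w[0]]}
    return config


def _build_factor_corr(traits, methods, config) -> np.ndarray:
    nt, nm = len(traits), len(methods)
    nf = nt * nm
    conv = list(config.get("convergent_corr", [0.8] * nt))
    if len(conv) != nt:
        raise ValueError("convergent_corr must have one entry per trait")
    within = config.get("within_method_corr", {})
    hetero = float(config.get("cross_method_heterotrait_corr", 0.4))
    phi = np.eye(nf)
    for a in range(nf):
        for b in range(a + 1, nf):
            ma, ta = divmod(a, nt)
            mb, tb = divmod(b, nt)
            if ma == mb:
                r = float(within.get(methods[ma].label, 0.5))
            elif ta == tb:
                r = float(conv[ta])
            else:
                r = hetero
            phi[a, b] = phi[b, a] = r
    return phi


def _skewed_thresholds(n_categories: int, skew: float) -> np.ndarray:
    """Quantile cut-points for geometrically tilted category probabilities.

    ``skew`` = 0 gives equal-probability categories; positive values tilt
    mass toward low categories (positively skewed responses).
    """
    w = np.exp(-skew * np.arange(n_categories))
    probs = w / w.sum()
    return stats.norm.ppf(np.cumsum(probs)[:-1])


def build_model_spec(config: dict | None = None) -> MTMMModelSpec:
    """Build and validate a generating model from generator settings.

    Unspecified settings fall back to :func:`default_config` (3 traits x
    2 methods, 27 five-point + 12 seven-point items, convergent
    correlations .927/.718/.876).
    """
    merged = default_config()
    if config:
        merged.update(config)
    traits = list(merged["traits"])
    methods = [MethodSpec(m["label"], m["items_per_trait"], m["n_categories"])
               for m in merged["methods"]]
    if not traits or not methods:
        raise ValueError("need at least one trait and one method")

    phi = (np.asarray(merged["factor_corr"], dtype=float)
           if "factor_corr" in merged
           else _build_factor_corr(traits, methods, merged))

    loadings = []
    for m in methods:
        lo, hi = merged["loading_range"].get(m.label, (0.5, 0.8))
        per_trait = np.linspace(lo, hi, m.items_per_trait)
        loadings += list(per_trait) * len(traits)
    loadings = np.asarray(loadings)
    if "loadings" in merged:
        loadings = np.asarray(merged["loadings"], dtype=float)

    skew = float(merged.get("threshold_skew", 0.0))
    thresholds = []
    for m in methods:
        tau = _skewed_thresholds(m.n_categories, skew)
        thresholds += [tau.copy()
                       for _ in range(m.items_per_trait * len(traits))]
    if "thresholds" in merged:
        thresholds = [np.asarray(t, dtype=float) for t in merged["thresholds"]]

    criteria = []
    for c in merged.get("criteria", []):
        w = tuple(float(x) for x in c["weights"])
        mw = None
        if "method_weights" in c:
            mw = {k: tuple(float(x) for x in v)
                  for k, v in c["method_weights"].items()}
        resid = c.get("resid_sd")
        if resid is None:
            # keep total variance near 1 under the default factor structure
            resid = float(np.sqrt(max(1.0 - np.sum(np.square(w)), 0.25)))
        criteria.append(CriterionSpec(c["name"], c.get("set", "misc"),
                                      w, float(resid), method_weights=mw))

    spec = MTMMModelSpec(traits, methods, loadings, phi, thresholds, criteria)
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# simulation operations
# ---------------------------------------------------------------------------

def simulate_latent_scores(spec: MTMMModelSpec, n: int, seed: int) -> pd.DataFrame:
    """Multivariate-normal factor scores with covariance Phi."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    scores = rng.multivariate_normal(np.zeros(spec.n_factors), spec.factor_corr,
                                     size=n, method="cholesky")
    return pd.DataFrame(scores, columns=spec.factor_labels)


def discretize_to_likert(values, thresholds) -> np.ndarray:
    """Map continuous item values to categories 1..K at fixed cut-points.

    Category c is assigned iff the value lies in (tau_{c-1}, tau_c] with
    tau_0 = -inf and tau_K = +inf.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] != len(thresholds):
        raise ValueError("one threshold vector required per item column")
    out = np.empty(values.shape, dtype=int)
    for j, tau in enumerate(thresholds):
        tau = np.asarray(tau, dtype=float)
        if tau.size and np.any(np.diff(tau) <= 0):
            raise ValueError(f"item column {j}: thresholds not strictly increasing")
        out[:, j] = np.searchsorted(tau, values[:, j], side="left") + 1
    return out


def simulate_criterion_scores(trait_scores: pd.DataFrame, weights,
                              resid_sd: float, seed: int) -> np.ndarray:
    """Weighted trait combination plus independent normal residual."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (trait_scores.shape[1],):
        raise ValueError(
            f"expected {trait_scores.shape[1]} weights, got {weights.shape}"
        )
    if resid_sd < 0:
        raise ValueError("residual s.d. must be nonnegative")
    rng = np.random.default_rng(seed)
    y = trait_scores.to_numpy() @ weights
    return y + resid_sd * rng.standard_normal(len(trait_scores))


def simulate_dataset(spec: MTMMModelSpec, n: int, seed: int
                     ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Full generation pass: items, criterion table, and ground truth.

    Sub-streams for latent scores, item residuals and each criterion are
    spawned deterministically from the one global seed.
    """
    spec.validate()
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(2 + len(spec.criteria))

    latent = simulate_latent_scores(spec, n, seeds[0])
    rng_items = np.random.default_rng(seeds[1])
    f = spec.item_factor_index
    lam = spec.loadings
    item_values = (latent.to_numpy()[:, f] * lam
                   + np.sqrt(1.0 - lam ** 2) * rng_items.standard_normal((n, spec.n_items)))
    items = pd.DataFrame(discretize_to_likert(item_values, spec.thresholds),
                         columns=spec.item_labels)

    nt = len(spec.traits)
    crit = {}
    for c, sub in zip(spec.criteria, seeds[2:]):
        if c.method_weights is not None:
            w = np.concatenate([np.asarray(c.method_weights[m.label], float)
                                for m in spec.methods])
        else:
            # split trait weight evenly across the methods' factors
            w = np.tile(np.asarray(c.trait_weights, float) / len(spec.methods),
                        len(spec.methods))
        crit[c.name] = simulate_criterion_scores(latent, w, c.resid_sd, sub)
    criteria = pd.DataFrame(crit, index=items.index)

    truth = GroundTruth(latent_scores=latent, spec=spec, seed=seed)
    return items, criteria, truth
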