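"""Nomological/prediction-consistency statistics and benchmark report.

Compares two methods' trait-criterion correlation profiles and regression
summaries: mean absolute correlation differences (Fisher-z or raw scale),
difference of mean R-squared values, double-entry profile intraclass
correlations, pairwise Fisher z-tests, and agreement percentages between
Bayes-factor evidence categories.  Results are screened against fixed
cutoffs (delta_r_bar <= .10, delta_R2_bar <= .05, ICC >= .80, z-test
p >= .05, agreement >= 80%), all closed inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .corr import fisher_z, fisher_z_inv

__all__ = [
    "CUTOFFS",
    "CorrelationProfile",
    "ConsistencyReport",
    "delta_r_bar",
    "delta_R2_bar",
    "profile_icc",
    "compare_correlation_pair",
    "agreement_percentage",
    "evaluate_benchmarks",
]

CUTOFFS = {
    "delta_r_bar": 0.10,      # pass iff <=
    "delta_R2_bar": 0.05,     # pass iff <=
    "icc": 0.80,              # pass iff >=
    "z_test_p": 0.05,         # pass iff every p >=
    "agreement_pct": 80.0,    # pass iff >=
}


@dataclass(frozen=True)
class CorrelationProfile:
    """Trait-criterion correlations of one trait measured by one method."""

    trait: str
    method: str
    criteria: tuple[str, ...]
    r: tuple[float, ...]
    n: int

    def __post_init__(self) -> None:
        if len(self.criteria) != len(self.r):
            raise ValueError("criteria and r must have equal length")
        if any(abs(v) >= 1 for v in self.r):
            raise ValueError("profile correlations must satisfy |r| < 1")


def _check_matched(a: CorrelationProfile, b: CorrelationProfile) -> None:
    if a.criteria != b.criteria:
        raise ValueError(
            f"criterion mismatch between profiles: {a.criteria} vs {b.criteria}"
        )


def delta_r_bar(profile_a: CorrelationProfile, profile_b: CorrelationProfile,
                scale_rule: str = "fisher") -> float:
    """Mean absolute difference between two correlation profiles.

    ``"fisher"`` averages |z_a - z_b| on the Fisher-z scale and
    back-transforms with tanh; ``"raw"`` averages |r_a - r_b| directly.
    """
    _check_matched(profile_a, profile_b)
    ra = np.asarray(profile_a.r)
    rb = np.asarray(profile_b.r)
    if scale_rule == "fisher":
        return float(fisher_z_inv(np.mean(np.abs(fisher_z(ra) - fisher_z(rb)))))
    if scale_rule == "raw":
        return float(np.mean(np.abs(ra - rb)))
    raise ValueError(f"unknown scale rule {scale_rule!r}")


def delta_R2_bar(r2_list_a, r2_list_b) -> float:
    """Absolute difference of the two per-method mean R-squared values.

    Difference of means — not the mean of per-criterion differences.
    """
    a = np.asarray(r2_list_a, dtype=float)
    b = np.asarray(r2_list_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("R^2 lists must be non-empty")
    if a.size != b.size:
        raise ValueError("R^2 lists must have equal length")
    return float(abs(a.mean() - b.mean()))


def profile_icc(profile_a: CorrelationProfile, profile_b: CorrelationProfile,
                method_rule: str = "double-entry-z") -> float:
    """Profile-similarity intraclass correlation of two correlation profiles.

    ``"double-entry-z"`` (default): Pearson correlation of the double-entered
    vectors [(a, b)] + [(b, a)] computed on Fisher-z transformed values;
    ``"double-entry-raw"`` skips the z transform.  Returns NaN when the
    double-entered vectors have zero variance.
    """
    _check_matched(profile_a, profile_b)
    if len(profile_a.criteria) < 2:
        raise ValueError("profile ICC needs >= 2 matched criteria")
    ra = np.asarray(profile_a.r)
    rb = np.asarray(profile_b.r)
    if method_rule == "double-entry-z":
        ra, rb = fisher_z(ra), fisher_z(rb)
    elif method_rule != "double-entry-raw":
        raise ValueError(f"unknown ICC rule {method_rule!r}")
    x = np.concatenate([ra, rb])
    y = np.concatenate([rb, ra])
    if np.std(x) < 1e-12 or np.std(y) < 1e-12:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def compare_correlation_pair(r_a: float, n_a: int, r_b: float, n_b: int
                             ) -> tuple[float, float]:
    """Independent-samples Fisher z-test for two correlations."""
    if n_a <= 3 or n_b <= 3:
        raise ValueError("both sample sizes must exceed 3")
    z = (fisher_z(r_a) - fisher_z(r_b)) / np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def agreement_percentage(categories_a, categories_b) -> float:
    """Percent of cells whose evidence categories agree across methods."""
    a = list(categories_a)
    b = list(categories_b)
    if len(a) != len(b):
        raise ValueError(f"category sequences differ in length: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("category sequences must be non-empty")
    matches = sum(x == y for x, y in zip(a, b))
    return 100.0 * matches / len(a)


# ---------------------------------------------------------------------------
# benchmark report
# ---------------------------------------------------------------------------

@dataclass
class MetricVerdict:
    value: float | None
    cutoff: float
    direction: str  # "<=" or ">="
    passed: bool | None  # None = not evaluable

    @staticmethod
    def of(value: float | None, cutoff: float, direction: str) -> "MetricVerdict":
        if value is None or not np.isfinite(value):
            return MetricVerdict(value, cutoff, direction, None)
        ok = value <= cutoff if direction == "<=" else value >= cutoff
        return MetricVerdict(float(value), cutoff, direction, bool(ok))


@dataclass
class ConsistencyReport:
    """Benchmark verdicts for one criterion set."""

    set_name: str
    delta_r_bar: dict[str, MetricVerdict] = field(default_factory=dict)
    delta_R2_bar: MetricVerdict | None = None
    icc: dict[str, MetricVerdict] = field(default_factory=dict)
    z_tests: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    z_test_all_ns: MetricVerdict | None = None
    agreement_pct: MetricVerdict | None = None

    @property
    def overall_pass(self) -> bool | None:
        verdicts = []
        verdicts += [v.passed for v in self.delta_r_bar.values()]
        verdicts += [v.passed for v in self.icc.values()]
        for v in (self.delta_R2_bar, self.z_test_all_ns, self.agreement_pct):
            if v is not None:
                verdicts.append(v.passed)
        if any(v is None for v in verdicts) or not verdicts:
            return None
        return all(verdicts)


def evaluate_benchmarks(set_name: str,
                        profiles_a: dict[str, CorrelationProfile] | None = None,
                        profiles_b: dict[str, CorrelationProfile] | None = None,
                        r2_a=None, r2_b=None,
                        categories_a=None, categories_b=None,
                        scale_rule: str = "fisher",
                        icc_rule: str = "double-entry-z") -> ConsistencyReport:
    """Compute every available consistency metric for one criterion set.

    ``profiles_a``/``profiles_b`` map trait labels to matched correlation
    profiles for the two methods.  Components whose inputs are missing are
    marked not-evaluable, never silently passed.
    """
    report = ConsistencyReport(set_name=set_name)

    if profiles_a and profiles_b:
        # delta_r_bar over the pooled profile of all traits in the set
        all_ps = []
        for trait in profiles_a:
            pa, pb = profiles_a[trait], profiles_b[trait]
            report.delta_r_bar[trait] = MetricVerdict.of(
                delta_r_bar(pa, pb, scale_rule), CUTOFFS["delta_r_bar"], "<=")
            icc_val = (profile_icc(pa, pb, icc_rule)
                       if len(pa.criteria) >= 2 else None)
            report.icc[trait] = MetricVerdict.of(icc_val, CUTOFFS["icc"], ">=")
            for crit, ra, rb in zip(pa.criteria, pa.r, pb.r):
                z, p = compare_correlation_pair(ra, pa.n, rb, pb.n)
                report.z_tests[(trait, crit)] = (z, p)
                all_ps.append(p)
        min_p = min(all_ps) if all_ps else None
        report.z_test_all_ns = MetricVerdict.of(min_p, CUTOFFS["z_test_p"], ">=")
    else:
        report.z_test_all_ns = MetricVerdict.of(None, CUTOFFS["z_test_p"], ">=")

    if r2_a is not None and r2_b is not None:
        report.delta_R2_bar = MetricVerdict.of(
            delta_R2_bar(r2_a, r2_b), CUTOFFS["delta_R2_bar"], "<=")
    else:
        report.delta_R2_bar = MetricVerdict.of(None, CUTOFFS["delta_R2_bar"], "<=")

    if categories_a is not None and categories_b is not None:
        report.agreement_pct = MetricVerdict.of(
            agreement_percentage(categories_a, categories_b),
            CUTOFFS["agreement_pct"], ">=")
    else:
        report.agreement_pct = MetricVerdict.of(None, CUTOFFS["agreement_pct"], ">=")

    return report
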