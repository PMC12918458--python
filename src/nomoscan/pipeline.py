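"""Dataset loading, full-analysis orchestration, and report serialization.

Two execution modes are supported: raw-data mode runs the complete chain
(descriptives -> correlations -> CFA/validity -> regressions -> Bayes
factors -> consistency benchmarks) on a person-by-variable table plus a
codebook; fixture mode starts from the bundled transcriptions of the
published regression-summary and Bayes-factor tables and reproduces the
derived consistency statistics exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayesfactor as bf
from . import consistency as nc
from . import corr, mtmm
from .synthetic import MTMMModelSpec

__all__ = [
    "ItemDef",
    "CriterionDef",
    "Codebook",
    "AnalysisConfig",
    "LikertDataset",
    "load_dataset",
    "write_dataset",
    "codebook_from_spec",
    "load_table1_fixture",
    "load_table3_fixture",
    "fixture_consistency",
    "run_full_analysis",
    "write_report",
]

log = logging.getLogger("nomoscan")

#: Value substituted for censored "<0.001" Bayes-factor cells.
BF_CENSOR_VALUE = 0.0005


# ---------------------------------------------------------------------------
# codebook
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ItemDef:
    column: str
    scale: str
    trait: str
    method: str
    min: int
    max: int
    reverse: bool = False


@dataclass(frozen=True)
class CriterionDef:
    name: str
    columns: tuple[str, ...]
    set_name: str
    scoring: str = "mean"


@dataclass
class Codebook:
    items: list[ItemDef]
    criteria: list[CriterionDef]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for it in self.items:
            if it.column in seen:
                raise ValueError(
                    f"item column {it.column!r} assigned to both "
                    f"{seen[it.column]!r} and {it.scale!r}"
                )
            seen[it.column] = it.scale
            if it.min >= it.max:
                raise ValueError(f"item {it.column!r}: empty response range")

    @property
    def methods(self) -> list[str]:
        out = []
        for it in self.items:
            if it.method not in out:
                out.append(it.method)
        return out

    @property
    def traits(self) -> list[str]:
        out = []
        for it in self.items:
            if it.trait not in out:
                out.append(it.trait)
        return out

    @property
    def sets(self) -> list[str]:
        out = []
        for c in self.criteria:
            if c.set_name not in out:
                out.append(c.set_name)
        return out

    def items_of(self, method: str, trait: str) -> list[str]:
        return [it.column for it in self.items
                if it.method == method and it.trait == trait]

    def to_dict(self) -> dict:
        return {
            "items": [dataclasses.asdict(it) for it in self.items],
            "criteria": [
                {"name": c.name, "columns": list(c.columns),
                 "set": c.set_name, "scoring": c.scoring}
                for c in self.criteria
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Codebook":
        items = [ItemDef(column=i["column"], scale=i["scale"], trait=i["trait"],
                         method=i["method"], min=int(i["min"]), max=int(i["max"]),
                         reverse=bool(i.get("reverse", False)))
                 for i in d.get("items", [])]
        crits = [CriterionDef(name=c["name"],
                              columns=tuple(c.get("columns") or [c["column"]]),
                              set_name=c.get("set", "misc"),
                              scoring=c.get("scoring", "mean"))
                 for c in d.get("criteria", [])]
        return cls(items, crits)

    @classmethod
    def from_yaml(cls, path) -> "Codebook":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def codebook_from_spec(spec: MTMMModelSpec) -> Codebook:
    """Codebook describing a synthetic dataset generated from ``spec``."""
    items = []
    i = 0
    for m in spec.methods:
        for t in spec.traits:
            for _k in range(m.items_per_trait):
                items.append(ItemDef(column=spec.item_labels[i],
                                     scale=f"{m.label}_{t}", trait=t,
                                     method=m.label, min=1, max=m.n_categories))
                i += 1
    crits = [CriterionDef(name=c.name, columns=(c.name,), set_name=c.set_name,
                          scoring="column")
             for c in spec.criteria]
    return Codebook(items, crits)


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

@dataclass
class LikertDataset:
    items: pd.DataFrame       # integer categories, reverse-coding applied
    criteria: pd.DataFrame    # continuous criterion scores
    codebook: Codebook
    n_out_of_range: int = 0

    @property
    def n(self) -> int:
        return len(self.items)


def load_dataset(data_path, codebook) -> LikertDataset:
    """Read a person-by-variable CSV against a codebook.

    Items are coerced to integers within their declared range (out-of-range
    cells become missing, with a logged count) and reverse-coded where
    flagged.  Criterion scores are computed per the scoring rule.
    """
    if not isinstance(codebook, Codebook):
        codebook = Codebook.from_yaml(codebook)
    data = pd.read_csv(data_path)
    missing_cols = [it.column for it in codebook.items
                    if it.column not in data.columns]
    missing_cols += [c for cr in codebook.criteria for c in cr.columns
                     if c not in data.columns]
    if missing_cols:
        raise ValueError(f"codebook references missing columns: {missing_cols}")

    out_of_range = 0
    item_cols = {}
    for it in codebook.items:
        col = pd.to_numeric(data[it.column], errors="raise").astype(float)
        bad = col.notna() & ((col < it.min) | (col > it.max) | (col % 1 != 0))
        out_of_range += int(bad.sum())
        col[bad] = np.nan
        if it.reverse:
            col = it.min + it.max - col
        item_cols[it.column] = col
    items = pd.DataFrame(item_cols)
    if out_of_range:
        log.info("load_dataset: %d out-of-range item cells set missing",
                 out_of_range)

    crit_cols = {}
    for cr in codebook.criteria:
        block = data[list(cr.columns)].apply(pd.to_numeric, errors="raise")
        if cr.scoring in ("column", "mean"):
            crit_cols[cr.name] = block.mean(axis=1)
        elif cr.scoring == "sum":
            crit_cols[cr.name] = block.sum(axis=1)
        else:
            raise ValueError(f"unknown scoring rule {cr.scoring!r}")
    criteria = pd.DataFrame(crit_cols)
    return LikertDataset(items, criteria, codebook, n_out_of_range=out_of_range)


def write_dataset(outdir, items: pd.DataFrame, criteria: pd.DataFrame,
                  codebook: Codebook, truth: dict | None = None) -> dict:
    """Write data.csv + codebook.yaml (+ ground_truth.json); return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = pd.concat([items, criteria], axis=1)
    data_path = outdir / "data.csv"
    data.to_csv(data_path, index=False)
    cb_path = outdir / "codebook.yaml"
    codebook.to_yaml(cb_path)
    paths = {"data": str(data_path), "codebook": str(cb_path)}
    if truth is not None:
        gt_path = outdir / "ground_truth.json"
        with open(gt_path, "w") as fh:
            json.dump(_jsonify(truth), fh, indent=1, sort_keys=True)
        paths["ground_truth"] = str(gt_path)
    return paths


# ---------------------------------------------------------------------------
# analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    seed: int = 0
    missing_policy: str = "listwise"          # listwise | pairwise
    delta_r_scale_rule: str = "fisher"        # fisher | raw
    icc_rule: str = "double-entry-z"          # double-entry-z | double-entry-raw
    htmt_denominator_rule: str = "arithmetic"  # arithmetic | geometric
    bf_r_scale: float = bf.DEFAULT_R_SCALE
    output_precision: int = 3
    include_cfa: bool = True
    dwls_weights: str = "asymptotic"          # asymptotic | unit

    _ENUMS = {
        "missing_policy": ("listwise", "pairwise"),
        "delta_r_scale_rule": ("fisher", "raw"),
        "icc_rule": ("double-entry-z", "double-entry-raw"),
        "htmt_denominator_rule": ("arithmetic", "geometric"),
        "dwls_weights": ("asymptotic", "unit"),
    }

    def __post_init__(self) -> None:
        for name, allowed in self._ENUMS.items():
            if getattr(self, name) not in allowed:
                raise ValueError(
                    f"{name} must be one of {allowed}, got {getattr(self, name)!r}"
                )

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "seed", "missing_policy", "delta_r_scale_rule", "icc_rule",
            "htmt_denominator_rule", "bf_r_scale", "output_precision",
            "include_cfa", "dwls_weights")}


# ---------------------------------------------------------------------------
# fixture mode
# ---------------------------------------------------------------------------

def _fixture_path(name: str):
    return resources.files("nomoscan") / "fixtures" / name


def load_table1_fixture() -> pd.DataFrame:
    """Bundled regression summaries: per-criterion betas and R^2 per method."""
    with resources.as_file(_fixture_path("table1_regressions.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_table3_fixture() -> pd.DataFrame:
    """Bundled omitted-predictor BF_01 table; censored cells become 0.0005."""
    with resources.as_file(_fixture_path("table3_bf01.tsv")) as p:
        frame = pd.read_csv(p, sep="\t")
    value_cols = [c for c in frame.columns if c not in ("set", "criterion")]
    for c in value_cols:
        frame[c] = frame[c].map(
            lambda v: BF_CENSOR_VALUE if str(v).strip() == "<0.001" else float(v))
    return frame


_TRAITS = ("mach", "nar", "psych")


def fixture_consistency() -> dict:
    """Derived consistency statistics from the bundled fixture tables.

    Returns, per criterion set, the difference of mean R^2 values and the
    cross-method Bayes-factor evidence agreement percentage, plus the full
    classification tables.
    """
    t1 = load_table1_fixture()
    t3 = load_table3_fixture()
    out: dict[str, dict] = {}
    for set_name in t1["set"].unique():
        block1 = t1[t1["set"] == set_name]
        d_r2 = nc.delta_R2_bar(block1["sd3_r2"], block1["dd_r2"])

        block3 = t3[t3["set"] == set_name]
        cats_sd3, cats_dd = [], []
        cells = []
        for _, row in block3.iterrows():
            for trait in _TRAITS:
                ca = bf.classify_evidence(row[f"sd3_{trait}"])
                cb = bf.classify_evidence(row[f"dd_{trait}"])
                cats_sd3.append(ca)
                cats_dd.append(cb)
                cells.append({"criterion": row["criterion"], "trait": trait,
                              "sd3": ca, "dd": cb, "match": ca == cb})
        pct = nc.agreement_percentage(cats_sd3, cats_dd)
        out[set_name] = {
            "delta_R2_bar": d_r2,
            "agreement_pct": pct,
            "n_cells": len(cells),
            "cells": cells,
        }
    return out


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

def _scale_scores(dataset: LikertDataset) -> pd.DataFrame:
    """Per-person trait scores: mean item response per trait-method scale."""
    cb = dataset.codebook
    cols = {}
    for m in cb.methods:
        for t in cb.traits:
            items = cb.items_of(m, t)
            if items:
                cols[f"{m}_{t}"] = dataset.items[items].mean(axis=1)
    return pd.DataFrame(cols)


def run_full_analysis(dataset: LikertDataset,
                      config: AnalysisConfig | None = None) -> dict:
    """Run every analysis stage on a loaded dataset; returns the bundle.

    Stage order: descriptives -> correlations -> CFA/validity ->
    regressions -> Bayes factors -> consistency benchmarks.  Any stage
    failure aborts with the stage name; completed stages stay in the bundle.
    """
    config = config or AnalysisConfig()
    cb = dataset.codebook
    if len(cb.methods) < 2:
        raise ValueError("analysis requires >= 2 methods sharing the traits")
    bundle: dict = {"config": config.to_dict(), "stages_completed": []}
    stage = "descriptives"
    try:
        scores = _scale_scores(dataset)
        bundle["descriptives"] = {
            col: dataclasses.asdict(corr.describe(scores[col]))
            for col in scores.columns
        }
        bundle["stages_completed"].append(stage)

        stage = "correlations"
        joint = pd.concat([scores, dataset.criteria], axis=1)
        pearson = corr.pearson_matrix(joint, policy=config.missing_policy)
        bundle["n_effective"] = pearson.n
        bundle["stages_completed"].append(stage)

        stage = "cfa_validity"
        if config.include_cfa:
            bundle["cfa"] = _cfa_stage(dataset, config)
            bundle["stages_completed"].append(stage)

        stage = "regressions"
        regressions = _regression_stage(cb, pearson)
        bundle["regressions"] = regressions
        bundle["stages_completed"].append(stage)

        stage = "bayes_factors"
        bundle["bf01"] = _bf_stage(cb, pearson, regressions, config)
        bundle["stages_completed"].append(stage)

        stage = "consistency"
        bundle["consistency"] = _consistency_stage(cb, pearson, regressions,
                                                   bundle["bf01"], config)
        bundle["stages_completed"].append(stage)
    except Exception as exc:
        raise RuntimeError(
            f"analysis stage {stage!r} failed: {exc}; "
            f"completed stages: {bundle['stages_completed']}"
        ) from exc
    return bundle


def _cfa_stage(dataset: LikertDataset, config: AnalysisConfig) -> dict:
    cb = dataset.codebook
    item_cols = [it.column for it in cb.items]
    items = dataset.items[item_cols].dropna()
    poly, variances = corr.polychoric_matrix(
        items, with_variance=(config.dwls_weights == "asymptotic"))
    factors = [f"{m}_{t}" for m in cb.methods for t in cb.traits]
    assignment = {it.column: f"{it.method}_{it.trait}" for it in cb.items}
    spec = mtmm.CFAModelSpec(factors=factors, assignment=assignment)
    n = len(items)
    fit = mtmm.fit_dwls(poly, spec, n, weights=variances, seed=config.seed)
    base = mtmm.fit_baseline(poly, item_cols, n, weights=variances)
    indices = mtmm.fit_indices(fit, base)

    def alpha_fn(factor: str) -> float:
        f_items = [it for it, f in assignment.items() if f == factor]
        return corr.cronbach_alpha(poly, f_items)

    trait_pairs = []
    methods = cb.methods
    for t in cb.traits:
        for i in range(len(methods)):
            for j in range(i + 1, len(methods)):
                trait_pairs.append((f"{methods[i]}_{t}", f"{methods[j]}_{t}"))
    validity = mtmm.validity_table(fit, poly, alpha_fn, trait_pairs,
                                   denominator_rule=config.htmt_denominator_rule)

    nested = {}
    for pair in trait_pairs:
        cspec = mtmm.CFAModelSpec(factors=factors, assignment=assignment,
                                  fixed_corr={pair: 1.0})
        cfit = mtmm.fit_dwls(poly, cspec, n, weights=variances,
                             seed=config.seed)
        cmp_ = mtmm.compare_nested(fit, cfit)
        nested["|".join(pair)] = dataclasses.asdict(cmp_)

    return {
        "n": n,
        "df": fit.df,
        "chi_square": fit.chi_square,
        "converged": fit.converged,
        "loadings": dict(zip(spec.items, fit.loadings.tolist())),
        "factor_corr": {"labels": factors,
                        "values": fit.factor_corr.tolist()},
        "fit_indices": dataclasses.asdict(indices),
        "ave": validity.ave,
        "ordinal_alpha": validity.ordinal_alpha,
        "fornell_larcker_pass": validity.fornell_larcker_pass,
        "htmt": {"|".join(k): v for k, v in validity.htmt.items()},
        "htmt_pass": {"|".join(k): v for k, v in validity.htmt_pass.items()},
        "nested_comparisons": nested,
    }


def _regression_stage(cb: Codebook, pearson: corr.CorrelationMatrix) -> dict:
    out: dict = {}
    for m in cb.methods:
        predictors = [f"{m}_{t}" for t in cb.traits]
        for cr in cb.criteria:
            res = corr.standardized_ols(pearson, cr.name, predictors)
            out[(m, cr.name)] = res
    return out


def _bf_stage(cb: Codebook, pearson: corr.CorrelationMatrix,
              regressions: dict, config: AnalysisConfig) -> dict:
    """Omitted-predictor BF_01 per (method, criterion, omitted trait)."""
    out: dict = {}
    for m in cb.methods:
        predictors = [f"{m}_{t}" for t in cb.traits]
        for cr in cb.criteria:
            full = regressions[(m, cr.name)]
            for t in cb.traits:
                omit = f"{m}_{t}"
                reduced_preds = [p for p in predictors if p != omit]
                reduced = corr.standardized_ols(pearson, cr.name, reduced_preds)
                bf01 = bf.bf01_omitted(full.r_squared, reduced.r_squared,
                                       full.n, len(predictors),
                                       r_scale=config.bf_r_scale)
                out[(m, cr.name, t)] = {
                    "bf01": bf01,
                    "category": bf.classify_evidence(bf01),
                    "r2_full": full.r_squared,
                    "r2_reduced": reduced.r_squared,
                }
    return out


def _consistency_stage(cb: Codebook, pearson: corr.CorrelationMatrix,
                       regressions: dict, bf01: dict,
                       config: AnalysisConfig) -> dict:
    methods = cb.methods
    m_a, m_b = methods[0], methods[1]
    n = pearson.n
    out: dict = {}
    for set_name in cb.sets:
        crits = [c.name for c in cb.criteria if c.set_name == set_name]
        profiles_a, profiles_b = {}, {}
        for t in cb.traits:
            ra = [float(pearson.values[pearson.index(f"{m_a}_{t}"),
                                       pearson.index(c)]) for c in crits]
            rb = [float(pearson.values[pearson.index(f"{m_b}_{t}"),
                                       pearson.index(c)]) for c in crits]
            profiles_a[t] = nc.CorrelationProfile(t, m_a, tuple(crits),
                                                  tuple(ra), n)
            profiles_b[t] = nc.CorrelationProfile(t, m_b, tuple(crits),
                                                  tuple(rb), n)
        r2_a = [regressions[(m_a, c)].r_squared for c in crits]
        r2_b = [regressions[(m_b, c)].r_squared for c in crits]
        cats_a = [bf01[(m_a, c, t)]["category"] for c in crits for t in cb.traits]
        cats_b = [bf01[(m_b, c, t)]["category"] for c in crits for t in cb.traits]
        report = nc.evaluate_benchmarks(
            set_name, profiles_a, profiles_b, r2_a, r2_b, cats_a, cats_b,
            scale_rule=config.delta_r_scale_rule, icc_rule=config.icc_rule)
        out[set_name] = report
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k) if not isinstance(k, str) else k: _jsonify(v)
                for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_report(bundle: dict, outdir, precision: int = 3) -> dict:
    """Write report.json (full precision) plus rounded human-readable TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    json_path = outdir / "report.json"
    payload = _jsonify(bundle)
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths = {"json": str(json_path)}

    cons = bundle.get("consistency")
    if cons:
        rows = []
        for set_name, rep in cons.items():
            if isinstance(rep, nc.ConsistencyReport):
                row = {"set": set_name}
                for t, v in rep.delta_r_bar.items():
                    if v.value is not None:
                        row[f"delta_r_bar_{t}"] = round(v.value, precision)
                if rep.delta_R2_bar and rep.delta_R2_bar.value is not None:
                    row["delta_R2_bar"] = round(rep.delta_R2_bar.value, precision)
                for t, v in rep.icc.items():
                    if v.value is not None:
                        row[f"icc_{t}"] = round(v.value, precision)
                if rep.agreement_pct and rep.agreement_pct.value is not None:
                    row["agreement_pct"] = round(rep.agreement_pct.value, 2)
                row["overall_pass"] = rep.overall_pass
                rows.append(row)
            else:  # fixture-mode plain dict
                rows.append({"set": set_name,
                             **{k: round(v, precision) if isinstance(v, float) else v
                                for k, v in rep.items() if k != "cells"}})
        tsv_path = outdir / "consistency_report.tsv"
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
        paths["consistency_tsv"] = str(tsv_path)
    return paths
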