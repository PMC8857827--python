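"""End-to-end orchestration: classify -> nutrition -> diagnostics -> report.

The pipeline consumes a per-pregnancy cohort CSV (columns matching
:class:`~growthdx.customized.PregnancyRecord`), classifies fetal size under
each configured growth standard, computes neonatal nutrition status under
BMI and PI references, and runs the diagnostic comparison battery per
stratum (all / term 37-42 / preterm < 37 weeks, by GA at birth).

Two entry layers exist: the functions here (importable, DataFrame in/out)
and the thin click CLI in :mod:`growthdx.cli`.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import diagnostics as dx
from .customized import (
    DEFAULT_COEFFICIENTS,
    DEFAULT_PROPORTIONALITY,
    CustomizedCoefficients,
    CustomizedStandard,
    PregnancyRecord,
    Sex,
    SizeClass,
    proportionality_fraction,
)
from .errors import CohortValidationError, EmptyAnalysisError, GrowthDxError
from .nutrition import (
    IndexKind,
    NutritionReference,
    default_bmi_reference,
    default_pi_reference,
    neonatal_bmi,
    ponderal_index,
)
from .population import GrowthStandard, TableStandard, load_demo_table

logger = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "maternal_age",
    "maternal_height",
    "pregestational_weight",
    "sex",
    "ga_scan",
    "efw",
    "ga_birth",
    "birthweight",
    "birth_length",
]

STRATA = {
    "all": lambda ga: ga <= 42.0,
    "term": lambda ga: (ga >= 37.0) & (ga <= 42.0),
    "preterm": lambda ga: ga < 37.0,
}

METRIC_ORDER = [
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "lr_pos",
    "lr_neg",
    "youden",
    "dor",
    "rr",
]


def read_cohort(path: str | Path, strict: bool = True) -> tuple[pd.DataFrame, list]:
    """Strictly parse a cohort CSV; returns (valid rows, [(row, message), ...]).

    Every row is validated through :class:`PregnancyRecord`; with
    ``strict=True`` any invalid row raises :class:`CohortValidationError`
    listing row numbers, otherwise invalid rows are returned as rejects.
    """
    raw = pd.read_csv(path, comment="#")
    missing = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortValidationError([(0, f"missing required columns: {missing}")])
    rejects: list[tuple[int, str]] = []
    keep: list[int] = []
    sexes: list[str] = []
    for idx, row in raw.iterrows():
        try:
            record = PregnancyRecord(
                **{
                    col: (None if pd.isna(row[col]) else row[col])
                    for col in COHORT_COLUMNS
                }
            )
            sexes.append("male" if record.sex is Sex.MALE else "female")
            keep.append(idx)
        except GrowthDxError as err:
            rejects.append((int(idx) + 2, str(err)))  # +2: header + 1-based
        except (TypeError, ValueError) as err:
            rejects.append((int(idx) + 2, str(err)))
    if rejects and strict:
        raise CohortValidationError(rejects)
    frame = raw.loc[keep, COHORT_COLUMNS].reset_index(drop=True)
    frame["sex"] = sexes
    return frame, rejects


def default_standards() -> dict[str, GrowthStandard]:
    return {
        "customized": CustomizedStandard(),
        "population": TableStandard(load_demo_table()),
    }


def term_optimal_weights(
    frame: pd.DataFrame, coef: CustomizedCoefficients = DEFAULT_COEFFICIENTS
) -> np.ndarray:
    """Vectorised term-optimal-weight model over a cohort frame."""
    sex_male = (frame["sex"] == "male").to_numpy(dtype=float)
    return (
        coef.intercept
        + frame["maternal_age"].to_numpy(dtype=float) * coef.age_coef
        + frame["pregestational_weight"].to_numpy(dtype=float) * coef.weight_coef
        + frame["maternal_height"].to_numpy(dtype=float) * coef.height_coef
        + sex_male * coef.sex_coef
    )


def _standard_centiles(
    standard: GrowthStandard, frame: pd.DataFrame, weights: np.ndarray, gas: np.ndarray
) -> np.ndarray:
    """Centiles for a whole cohort under one standard (vectorised fast paths)."""
    if isinstance(standard, CustomizedStandard):
        tow = term_optimal_weights(frame, standard.coef)
        return standard.centile_of_cohort(weights, gas, tow)
    if isinstance(standard, TableStandard):
        centiles = np.empty(len(frame), dtype=float)
        sex_labels = frame["sex"].to_numpy()
        for sex in ("male", "female"):
            mask = sex_labels == sex
            if mask.any():
                centiles[mask] = np.asarray(
                    standard.centile_of(weights[mask], gas[mask], sex=sex)
                )
        return centiles
    return np.array(
        [
            standard.centile_of(w, g, sex=s)
            for w, g, s in zip(weights, gas, frame["sex"])
        ],
        dtype=float,
    )


def _size_labels(centiles: np.ndarray) -> np.ndarray:
    return np.where(
        centiles < 10.0,
        SizeClass.SGA.value,
        np.where(centiles > 90.0, SizeClass.LGA.value, SizeClass.AGA.value),
    )


def nutrition_centiles_vec(
    values: np.ndarray,
    sex_labels: np.ndarray,
    ga_birth: np.ndarray,
    reference: NutritionReference,
) -> np.ndarray:
    """Vectorised centile lookup; NaN marks out-of-coverage records."""
    weeks = np.floor(np.asarray(ga_birth, dtype=float)).astype(int)
    lookup = {
        (row.sex, int(row.ga_weeks)): (row.mean, row.sd)
        for row in reference.frame.itertuples()
    }
    mean = np.full(len(values), np.nan)
    sd = np.full(len(values), np.nan)
    for i, (sex, week) in enumerate(zip(sex_labels, weeks)):
        params = lookup.get((sex, int(week)))
        if params is not None:
            mean[i], sd[i] = params
    with np.errstate(invalid="ignore"):
        return ndtr((np.asarray(values, dtype=float) - mean) / sd) * 100.0


def _nutrition_labels(centiles: np.ndarray) -> np.ndarray:
    return np.select(
        [
            ~np.isfinite(centiles),
            centiles < 10.0,
            centiles > 90.0,
        ],
        [dx.OUT_OF_COVERAGE, "undernourished", "overnourished"],
        default="normal",
    )


def classify_cohort(
    frame: pd.DataFrame,
    standards: dict[str, GrowthStandard] | None = None,
    mode: str = "scan",
    bmi_reference: NutritionReference | None = None,
    pi_reference: NutritionReference | None = None,
) -> pd.DataFrame:
    """Per-record size class under each standard plus nutrition status.

    ``mode='scan'`` classifies the EFW at scan GA (prenatal suspicion, the
    default test); ``mode='birth'`` classifies birthweight at birth GA.
    """
    if mode not in {"scan", "birth"}:
        raise GrowthDxError(f"unknown classification mode {mode!r}")
    standards = standards or default_standards()
    bmi_reference = bmi_reference or default_bmi_reference()
    pi_reference = pi_reference or default_pi_reference()

    out = frame.copy().reset_index(drop=True)
    if mode == "scan":
        weights = out["efw"].to_numpy(dtype=float)
        gas = out["ga_scan"].to_numpy(dtype=float)
    else:
        weights = out["birthweight"].to_numpy(dtype=float)
        gas = out["ga_birth"].to_numpy(dtype=float)

    for name, standard in standards.items():
        centiles = _standard_centiles(standard, out, weights, gas)
        out[f"centile_{name}"] = centiles
        out[f"size_{name}"] = _size_labels(centiles)

    sex_labels = out["sex"].to_numpy()
    ga_birth = out["ga_birth"].to_numpy(dtype=float)
    out["bmi_value"] = neonatal_bmi(
        out["birthweight"].to_numpy(dtype=float), out["birth_length"].to_numpy(dtype=float)
    )
    out["pi_value"] = ponderal_index(
        out["birthweight"].to_numpy(dtype=float), out["birth_length"].to_numpy(dtype=float)
    )
    out["bmi_centile"] = nutrition_centiles_vec(
        out["bmi_value"].to_numpy(), sex_labels, ga_birth, bmi_reference
    )
    out["pi_centile"] = nutrition_centiles_vec(
        out["pi_value"].to_numpy(), sex_labels, ga_birth, pi_reference
    )
    out["bmi_status"] = _nutrition_labels(out["bmi_centile"].to_numpy())
    out["pi_status"] = _nutrition_labels(out["pi_centile"].to_numpy())
    n_out = int((out["bmi_status"] == dx.OUT_OF_COVERAGE).sum())
    if n_out:
        logger.warning("%d record(s) outside nutrition reference coverage", n_out)
    return out


@dataclasses.dataclass
class RunConfig:
    """Configuration for a full analysis run."""

    input_path: str | Path | None = None
    output_dir: str | Path = "growthdx_out"
    standards: tuple[str, ...] = ("customized", "population")
    indices: tuple[str, ...] = ("BMI", "PI")
    strata: tuple[str, ...] = ("all", "term", "preterm")
    mode: str = "scan"
    seed: int = 0
    youden_ci: str = "bootstrap"
    continuity: bool = False
    population_table: str | Path | None = None

    def __post_init__(self) -> None:
        if not self.standards or not self.indices:
            raise GrowthDxError("at least one standard and one nutrition index required")
        unknown = set(self.strata) - set(STRATA)
        if unknown:
            raise GrowthDxError(f"unknown strata: {sorted(unknown)}")


def _group_metrics(
    sub: pd.DataFrame, standard: str, index: str, seed: int, youden_ci: str, continuity: bool
) -> tuple[list[dict], dx.ContingencyTable | None, dx.RiskRatioResult | None]:
    status_col = f"{index.lower()}_status"
    pairs = sub[[f"size_{standard}", status_col]].rename(
        columns={f"size_{standard}": "size_class", status_col: "nutrition"}
    )
    try:
        table = dx.build_table(pairs)
    except EmptyAnalysisError:
        return [], None, None
    summary = dx.diagnostic_summary(
        table, youden_ci=youden_ci, seed=seed, continuity=continuity
    )
    try:
        rr = dx.relative_risk(table, continuity=continuity)
        rr_metric = dx.MetricEstimate(rr.rr, rr.ci_low, rr.ci_high)
    except (dx.DomainError, EmptyAnalysisError):
        rr = None
        rr_metric = dx.MetricEstimate(math.nan, math.nan, math.nan, defined=False, note="zero events")
    rows = []
    metric_map = summary.metrics()
    metric_map["rr"] = rr_metric
    exclusions = (
        table.excluded_lga + table.excluded_overnourished + table.excluded_out_of_coverage
    )
    for metric in METRIC_ORDER:
        est = metric_map[metric]
        rows.append(
            {
                "standard": standard,
                "index": index,
                "metric": metric,
                "estimate": est.estimate,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "defined": est.defined,
                "n_eligible": table.n_eligible,
                "exclusions": exclusions,
                "note": est.note,
            }
        )
    return rows, table, rr


def analyze_classifications(classified: pd.DataFrame, config: RunConfig) -> dict:
    """Diagnostics over a classified cohort; pure function of its inputs.

    Returns a dict with tidy ``metrics``, ``comparisons``, ``tallies`` and
    ``forest`` DataFrames plus the exclusion audit.
    """
    results_metrics: list[dict] = []
    comparisons: list[dict] = []
    tallies: list[dict] = []
    forest: list[dict] = []
    audit: list[dict] = []

    ga_birth = classified["ga_birth"].to_numpy(dtype=float)
    n_postterm = int((ga_birth > 42.0).sum())
    if n_postterm:
        logger.warning("%d post-term (>42 wk) record(s) excluded from all strata", n_postterm)

    for stratum in config.strata:
        mask = STRATA[stratum](ga_birth)
        sub = classified.loc[mask]
        audit.append(
            {
                "stratum": stratum,
                "n_records": int(mask.sum()),
                "n_postterm_excluded": n_postterm if stratum == "all" else 0,
            }
        )
        if sub.empty:
            logger.warning("stratum %s is empty; reported and skipped", stratum)
            continue

        # classification tallies per standard
        for standard in config.standards:
            counts = sub[f"size_{standard}"].value_counts()
            tallies.append(
                {
                    "stratum": stratum,
                    "standard": standard,
                    "n": int(len(sub)),
                    "SGA": int(counts.get("SGA", 0)),
                    "AGA": int(counts.get("AGA", 0)),
                    "LGA": int(counts.get("LGA", 0)),
                }
            )

        for index in config.indices:
            per_standard: dict[str, tuple] = {}
            for standard in config.standards:
                rows, table, rr = _group_metrics(
                    sub, standard, index, config.seed, config.youden_ci, config.continuity
                )
                for row in rows:
                    row["stratum"] = stratum
                results_metrics.extend(rows)
                per_standard[standard] = (table, rr)
                if table is not None:
                    summary_dor = dx.diagnostic_summary(
                        table, youden_ci="delta", continuity=config.continuity
                    ).dor
                    forest.append(
                        {
                            "stratum": stratum,
                            "standard": standard,
                            "index": index,
                            "dor": summary_dor.estimate,
                            "ci_low": summary_dor.ci_low,
                            "ci_high": summary_dor.ci_high,
                        }
                    )

            # paired method comparisons for the first two standards
            if len(config.standards) >= 2:
                s1, s2 = config.standards[0], config.standards[1]
                comparisons.extend(
                    _method_comparisons(sub, s1, s2, index, stratum, per_standard)
                )

    return {
        "metrics": pd.DataFrame(results_metrics),
        "comparisons": pd.DataFrame(comparisons),
        "tallies": pd.DataFrame(tallies),
        "forest": pd.DataFrame(forest),
        "audit": pd.DataFrame(audit),
    }


def _method_comparisons(
    sub: pd.DataFrame,
    s1: str,
    s2: str,
    index: str,
    stratum: str,
    per_standard: dict,
) -> list[dict]:
    status_col = f"{index.lower()}_status"
    rows: list[dict] = []

    rr1 = per_standard.get(s1, (None, None))[1]
    rr2 = per_standard.get(s2, (None, None))[1]
    if rr1 is not None and rr2 is not None:
        comp = dx.compare_rr(rr1, rr2)
        rows.append(
            {
                "stratum": stratum,
                "index": index,
                "comparison": "rr_ratio",
                "estimate": comp.ratio,
                "ci_low": comp.ci_low,
                "ci_high": comp.ci_high,
                "p_value": comp.p_value,
            }
        )

    eligible = (
        sub[status_col].isin(["undernourished", "normal"])
        & (sub[f"size_{s1}"] != "LGA")
        & (sub[f"size_{s2}"] != "LGA")
    )
    pos = sub.loc[eligible & (sub[status_col] == "undernourished")]
    neg = sub.loc[eligible & (sub[status_col] == "normal")]
    for name, subset, positive_is_sga in (
        ("mcnemar_sensitivity", pos, True),
        ("mcnemar_specificity", neg, False),
    ):
        if subset.empty:
            continue
        m1 = (subset[f"size_{s1}"] == "SGA").to_numpy()
        m2 = (subset[f"size_{s2}"] == "SGA").to_numpy()
        if not positive_is_sga:
            m1, m2 = ~m1, ~m2
        result = dx.mcnemar_test(m1, m2)
        rows.append(
            {
                "stratum": stratum,
                "index": index,
                "comparison": name,
                "estimate": result.statistic,
                "ci_low": math.nan,
                "ci_high": math.nan,
                "p_value": result.p_value,
            }
        )

    # SGA frequency difference, chi-square as commonly (if imperfectly) applied
    n = len(sub)
    k1 = int((sub[f"size_{s1}"] == "SGA").sum())
    k2 = int((sub[f"size_{s2}"] == "SGA").sum())
    if n:
        prop = dx.compare_proportions(k1, n, k2, n)
        rows.append(
            {
                "stratum": stratum,
                "index": index,
                "comparison": "sga_frequency_chi2",
                "estimate": prop.chi2,
                "ci_low": math.nan,
                "ci_high": math.nan,
                "p_value": prop.p_value,
            }
        )

    # risk ratio for records called SGA by BOTH methods vs AGA by both
    both = sub.loc[
        sub[status_col].isin(["undernourished", "normal"])
        & (
            ((sub[f"size_{s1}"] == "SGA") & (sub[f"size_{s2}"] == "SGA"))
            | ((sub[f"size_{s1}"] == "AGA") & (sub[f"size_{s2}"] == "AGA"))
        )
    ]
    if not both.empty:
        exposed = both[f"size_{s1}"] == "SGA"
        diseased = both[status_col] == "undernourished"
        table_counts = dict(
            tp=int((exposed & diseased).sum()),
            fp=int((exposed & ~diseased).sum()),
            fn=int((~exposed & diseased).sum()),
            tn=int((~exposed & ~diseased).sum()),
        )
        try:
            rr_both = dx.relative_risk(
                dx.ContingencyTable(**table_counts, exposure_label="SGA-by-both"),
                continuity=True,
            )
            rows.append(
                {
                    "stratum": stratum,
                    "index": index,
                    "comparison": "rr_sga_by_both",
                    "estimate": rr_both.rr,
                    "ci_low": rr_both.ci_low,
                    "ci_high": rr_both.ci_high,
                    "p_value": math.nan,
                }
            )
        except (EmptyAnalysisError, dx.DomainError):
            pass
    return rows


def render_report(results: dict, config: RunConfig) -> str:
    """Human-readable Markdown report mirroring the metric-grid layout."""
    lines = ["# Growth-standard diagnostic comparison", ""]
    lines.append(f"Mode: {config.mode} classification; seed {config.seed}.")
    lines.append("")
    tallies = results["tallies"]
    if not tallies.empty:
        lines.append("## Size classification tallies")
        lines.append(tallies.to_string(index=False))
        lines.append("")
    metrics = results["metrics"]
    for index in config.indices:
        lines.append(f"## Malnutrition = neonatal {index} < 10th centile")
        for stratum in config.strata:
            block = metrics[(metrics["index"] == index) & (metrics["stratum"] == stratum)]
            if block.empty:
                continue
            lines.append(f"### Stratum: {stratum}")
            pivot = block.pivot(index="metric", columns="standard", values="estimate")
            pivot = pivot.reindex(METRIC_ORDER)
            lines.append(pivot.round(4).to_string())
            lines.append("")
    comparisons = results["comparisons"]
    if not comparisons.empty:
        lines.append("## Method comparisons")
        lines.append(comparisons.round(4).to_string(index=False))
        lines.append("")
    notes = metrics.loc[metrics["note"] != "", ["stratum", "standard", "index", "metric", "note"]]
    if not notes.empty:
        lines.append("## Footnotes")
        lines.append(notes.drop_duplicates().to_string(index=False))
        lines.append("")
    return "\n".join(lines)


def run_analysis(config: RunConfig, cohort: pd.DataFrame | None = None) -> dict:
    """Full pipeline: read -> classify -> analyze -> persist report bundle."""
    if cohort is None:
        if config.input_path is None:
            raise GrowthDxError("run_analysis needs an input path or an in-memory cohort")
        cohort, rejects = read_cohort(config.input_path, strict=False)
        if rejects:
            logger.warning("%d row(s) rejected during parsing", len(rejects))
    else:
        rejects = []
        cohort = cohort[COHORT_COLUMNS].copy()

    standards = default_standards()
    if config.population_table is not None:
        from .population import ReferenceCurveTable

        standards["population"] = TableStandard(
            ReferenceCurveTable.from_csv(config.population_table)
        )
    standards = {name: standards[name] for name in config.standards}

    classified = classify_cohort(cohort, standards, mode=config.mode)
    results = analyze_classifications(classified, config)
    results["classified"] = classified
    results["rejects"] = rejects

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    classified.to_csv(outdir / "classifications.csv", index=False)
    results["metrics"].to_csv(outdir / "metrics.csv", index=False)
    results["comparisons"].to_csv(outdir / "comparisons.csv", index=False)
    results["tallies"].to_csv(outdir / "tallies.csv", index=False)
    results["forest"].to_csv(outdir / "forest.csv", index=False)
    if rejects:
        pd.DataFrame(rejects, columns=["row", "message"]).to_csv(
            outdir / "rejects.csv", index=False
        )
    report = render_report(results, config)
    (outdir / "report.md").write_text(report)
    results["report"] = report
    return results
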