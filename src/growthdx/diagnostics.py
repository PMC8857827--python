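"""Diagnostic-accuracy battery for comparing two growth standards.

Builds exposure/outcome 2x2 tables (SGA vs undernutrition, with LGA,
overnourished and out-of-coverage records excluded and audited), then
computes sensitivity, specificity, predictive values, likelihood ratios,
diagnostic odds ratio and the Youden index with 95% confidence intervals,
relative risks with Katz log intervals, a log-scale z comparison of two
relative risks, the McNemar paired test and a chi-square comparison of
proportions.

Confidence-interval conventions:

* proportions (sens/spec/PPV/NPV): Clopper-Pearson exact;
* ratio metrics (LR+/-, DOR, RR): log-normal with the standard variance
  formulas;
* Youden index: seeded multinomial bootstrap by default, delta method by
  option.

Continuity corrections (adding 0.5 to every cell) are opt-in and recorded
in the result, never applied silently.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .customized import SizeClass
from .errors import DomainError, EmptyAnalysisError
from .nutrition import NutritionLabel, NutritionStatus

logger = logging.getLogger(__name__)

Z975 = stats.norm.ppf(0.975)

#: sentinel outcome label for records the nutrition reference cannot cover
OUT_OF_COVERAGE = "out_of_coverage"


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """2x2 exposure (SGA vs AGA) by outcome (undernourished vs normal) counts.

    Exclusion counters keep the audit trail so that
    ``tp+fp+fn+tn + exclusions == cohort size``.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    exposure_label: str = "SGA"
    outcome_label: str = "undernourished"
    excluded_lga: int = 0
    excluded_overnourished: int = 0
    excluded_out_of_coverage: int = 0

    def __post_init__(self) -> None:
        counts = (self.tp, self.fp, self.fn, self.tn)
        if any(c < 0 for c in counts):
            raise DomainError("contingency counts must be non-negative")
        if sum(counts) < 1:
            raise EmptyAnalysisError("contingency table has no eligible records")

    @property
    def n_eligible(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_total(self) -> int:
        return (
            self.n_eligible
            + self.excluded_lga
            + self.excluded_overnourished
            + self.excluded_out_of_coverage
        )

    def swapped(self) -> "ContingencyTable":
        """Swap both exposure and outcome labels (tp<->tn, fp<->fn).

        Maps sens<->spec, ppv<->npv and lr+ <-> 1/lr-; the DOR is invariant
        under this relabelling.
        """
        return dataclasses.replace(
            self,
            tp=self.tn,
            fp=self.fn,
            fn=self.fp,
            tn=self.tp,
            exposure_label=f"not-{self.exposure_label}",
            outcome_label=f"not-{self.outcome_label}",
        )

    def with_continuity(self) -> tuple[float, float, float, float]:
        return self.tp + 0.5, self.fp + 0.5, self.fn + 0.5, self.tn + 0.5


@dataclasses.dataclass(frozen=True)
class MetricEstimate:
    """Point estimate with a 95% CI; ``defined`` is False when a margin is zero."""

    estimate: float
    ci_low: float
    ci_high: float
    defined: bool = True
    note: str = ""

    def as_tuple(self) -> tuple[float, float, float]:
        return self.estimate, self.ci_low, self.ci_high


@dataclasses.dataclass(frozen=True)
class DiagnosticSummary:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    lr_pos: MetricEstimate
    lr_neg: MetricEstimate
    dor: MetricEstimate
    youden: MetricEstimate
    table: ContingencyTable

    def metrics(self) -> dict[str, MetricEstimate]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "lr_pos": self.lr_pos,
            "lr_neg": self.lr_neg,
            "dor": self.dor,
            "youden": self.youden,
        }


@dataclasses.dataclass(frozen=True)
class RiskRatioResult:
    rr: float
    ci_low: float
    ci_high: float
    log_se: float
    continuity_corrected: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.rr <= self.ci_high):
            raise DomainError("risk-ratio CI must bracket the point estimate")


def _size_value(item) -> str:
    return item.value if isinstance(item, SizeClass) else str(item)


def _nutrition_value(item) -> str:
    if isinstance(item, NutritionStatus):
        return item.value.value
    if isinstance(item, NutritionLabel):
        return item.value
    if item is None:
        return OUT_OF_COVERAGE
    return str(item)


def build_table(
    cohort_classifications: Iterable[tuple] | pd.DataFrame,
    exposure_label: str = "SGA",
    outcome_label: str = "undernourished",
) -> ContingencyTable:
    """Count the 2x2 table from per-record (size class, nutrition status) pairs.

    Accepts an iterable of pairs or a DataFrame with ``size_class`` and
    ``nutrition`` columns.  LGA records leave the exposure margin;
    overnourished and out-of-coverage records leave the outcome margin; all
    exclusions are counted so totals are conserved.
    """
    if isinstance(cohort_classifications, pd.DataFrame):
        pairs = zip(
            cohort_classifications["size_class"], cohort_classifications["nutrition"]
        )
    else:
        pairs = iter(cohort_classifications)

    tp = fp = fn = tn = lga = over = out = 0
    for size_item, nutrition_item in pairs:
        size = _size_value(size_item)
        nutrition = _nutrition_value(nutrition_item)
        if size == SizeClass.LGA.value:
            lga += 1
            continue
        if nutrition == OUT_OF_COVERAGE:
            out += 1
            continue
        if nutrition == NutritionLabel.OVERNOURISHED.value:
            over += 1
            continue
        exposed = size == SizeClass.SGA.value
        diseased = nutrition == NutritionLabel.UNDERNOURISHED.value
        if exposed and diseased:
            tp += 1
        elif exposed:
            fp += 1
        elif diseased:
            fn += 1
        else:
            tn += 1
    if tp + fp + fn + tn == 0:
        raise EmptyAnalysisError("no eligible (SGA/AGA x under/normal) records")
    return ContingencyTable(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        exposure_label=exposure_label,
        outcome_label=outcome_label,
        excluded_lga=lga,
        excluded_overnourished=over,
        excluded_out_of_coverage=out,
    )


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval."""
    if n == 0:
        return 0.0, 1.0
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def _proportion(k: int, n: int, note: str = "") -> MetricEstimate:
    if n == 0:
        return MetricEstimate(math.nan, math.nan, math.nan, defined=False, note="zero margin")
    low, high = clopper_pearson(k, n)
    return MetricEstimate(k / n, low, high, note=note)


def _log_ratio_ci(estimate: float, log_se: float) -> tuple[float, float]:
    return (
        float(estimate * math.exp(-Z975 * log_se)),
        float(estimate * math.exp(Z975 * log_se)),
    )


def _youden_bootstrap(
    table: ContingencyTable, n_boot: int, seed: int
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    n = table.n_eligible
    probs = np.array([table.tp, table.fp, table.fn, table.tn], dtype=float) / n
    draws = rng.multinomial(n, probs, size=n_boot).astype(float)
    tp, fp, fn, tn = draws.T
    with np.errstate(invalid="ignore", divide="ignore"):
        youden = tp / (tp + fn) + tn / (tn + fp) - 1.0
    youden = youden[np.isfinite(youden)]
    if youden.size == 0:
        return math.nan, math.nan
    return float(np.quantile(youden, 0.025)), float(np.quantile(youden, 0.975))


def diagnostic_summary(
    table: ContingencyTable,
    youden_ci: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
    continuity: bool = False,
) -> DiagnosticSummary:
    """Full accuracy summary with 95% CIs.

    ``continuity=True`` adds 0.5 to every cell for the *ratio* metrics only
    (LR+/-, DOR) when a zero cell would otherwise make them undefined; the
    correction is recorded in the metric note.
    """
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    sens = _proportion(tp, tp + fn)
    spec = _proportion(tn, tn + fp)
    ppv = _proportion(tp, tp + fp)
    npv = _proportion(tn, tn + fn)

    zero_cell = min(tp, fp, fn, tn) == 0
    if zero_cell and continuity:
        a, b, c, d = table.with_continuity()
        note = "continuity correction +0.5 applied"
        logger.warning("diagnostic_summary: %s", note)
    else:
        a, b, c, d = float(tp), float(fp), float(fn), float(tn)
        note = ""

    def ratio_metric(value_fn, se_fn) -> MetricEstimate:
        try:
            value = value_fn()
            se = se_fn()
        except ZeroDivisionError:
            return MetricEstimate(math.nan, math.nan, math.nan, defined=False, note="zero cell")
        if not math.isfinite(value) or value <= 0 or not math.isfinite(se):
            return MetricEstimate(value, math.nan, math.nan, defined=False, note="zero cell")
        low, high = _log_ratio_ci(value, se)
        return MetricEstimate(value, low, high, note=note)

    lr_pos = ratio_metric(
        lambda: (a / (a + c)) / (b / (b + d)),
        lambda: math.sqrt(1 / a - 1 / (a + c) + 1 / b - 1 / (b + d)),
    )
    lr_neg = ratio_metric(
        lambda: (c / (a + c)) / (d / (b + d)),
        lambda: math.sqrt(1 / c - 1 / (a + c) + 1 / d - 1 / (b + d)),
    )
    dor = ratio_metric(
        lambda: (a * d) / (b * c),
        lambda: math.sqrt(1 / a + 1 / b + 1 / c + 1 / d),
    )

    youden_point = (
        sens.estimate + spec.estimate - 1.0 if sens.defined and spec.defined else math.nan
    )
    if not math.isfinite(youden_point):
        youden = MetricEstimate(math.nan, math.nan, math.nan, defined=False, note="zero margin")
    elif youden_ci == "bootstrap":
        low, high = _youden_bootstrap(table, n_boot=n_boot, seed=seed)
        youden = MetricEstimate(youden_point, low, high, note="bootstrap CI")
    elif youden_ci == "delta":
        var = sens.estimate * (1 - sens.estimate) / (tp + fn) + spec.estimate * (
            1 - spec.estimate
        ) / (tn + fp)
        half = Z975 * math.sqrt(var)
        youden = MetricEstimate(
            youden_point, youden_point - half, youden_point + half, note="delta-method CI"
        )
    else:
        raise DomainError(f"unknown youden_ci method {youden_ci!r}")

    return DiagnosticSummary(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        dor=dor,
        youden=youden,
        table=table,
    )


def operating_point_metrics(sensitivity: float, specificity: float) -> dict[str, float]:
    """LR+, LR-, DOR and Youden index from a (sensitivity, specificity) pair.

    Inputs are proportions in (0, 1).  Useful for metric-identity checks on
    published operating points where the underlying counts are unavailable.
    """
    if not (0.0 < sensitivity < 1.0 and 0.0 < specificity < 1.0):
        raise DomainError("sensitivity and specificity must lie strictly inside (0, 1)")
    lr_pos = sensitivity / (1.0 - specificity)
    lr_neg = (1.0 - sensitivity) / specificity
    return {
        "lr_pos": lr_pos,
        "lr_neg": lr_neg,
        "dor": lr_pos / lr_neg,
        "youden": sensitivity + specificity - 1.0,
    }


def relative_risk(table: ContingencyTable, continuity: bool = False) -> RiskRatioResult:
    """Risk ratio of the outcome in exposed (SGA) vs non-exposed (AGA), Katz log CI."""
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    if tp + fp == 0 or fn + tn == 0:
        raise EmptyAnalysisError("relative_risk requires both exposure groups non-empty")
    corrected = False
    if tp == 0 or fn == 0:
        if not continuity:
            raise DomainError(
                "zero events in an exposure group; pass continuity=True to apply +0.5"
            )
        tp, fp, fn, tn = (x + 0.5 for x in (tp, fp, fn, tn))
        corrected = True
        logger.warning("relative_risk: continuity correction +0.5 applied")
    risk_exposed = tp / (tp + fp)
    risk_unexposed = fn / (fn + tn)
    rr = risk_exposed / risk_unexposed
    log_se = math.sqrt(1 / tp - 1 / (tp + fp) + 1 / fn - 1 / (fn + tn))
    low, high = _log_ratio_ci(rr, log_se)
    return RiskRatioResult(rr=rr, ci_low=low, ci_high=high, log_se=log_se, continuity_corrected=corrected)


@dataclasses.dataclass(frozen=True)
class RiskRatioComparison:
    ratio: float
    ci_low: float
    ci_high: float
    p_value: float


def compare_rr(rr1: RiskRatioResult, rr2: RiskRatioResult) -> RiskRatioComparison:
    """Compare two risk ratios on the log scale (ratio of RRs, z test)."""
    for rr in (rr1, rr2):
        if not (math.isfinite(rr.rr) and rr.rr > 0 and math.isfinite(rr.log_se)):
            raise DomainError("compare_rr requires finite, positive risk ratios with log SEs")
    log_diff = math.log(rr1.rr) - math.log(rr2.rr)
    se_diff = math.sqrt(rr1.log_se**2 + rr2.log_se**2)
    ratio = math.exp(log_diff)
    if se_diff == 0:
        p = 1.0 if log_diff == 0 else 0.0
        return RiskRatioComparison(ratio, ratio, ratio, p)
    z = log_diff / se_diff
    p = float(2.0 * (1.0 - ndtr(abs(z))))
    low, high = _log_ratio_ci(ratio, se_diff)
    return RiskRatioComparison(ratio, low, high, p)


@dataclasses.dataclass(frozen=True)
class McNemarResult:
    statistic: float
    p_value: float
    b: int
    c: int
    method: str


EXACT_DISCORDANT_LIMIT = 25


def mcnemar_from_discordant(b: int, c: int) -> McNemarResult:
    """McNemar test from discordant-pair counts.

    Exact binomial when b + c < 25, chi-square with continuity correction
    otherwise; zero discordant pairs give p = 1 with a warning.
    """
    if b < 0 or c < 0:
        raise DomainError("discordant counts must be non-negative")
    n_disc = b + c
    if n_disc == 0:
        warnings.warn("McNemar test with zero discordant pairs; p = 1", stacklevel=2)
        return McNemarResult(statistic=0.0, p_value=1.0, b=b, c=c, method="degenerate")
    if n_disc < EXACT_DISCORDANT_LIMIT:
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n_disc, 0.5)))
        return McNemarResult(statistic=float(min(b, c)), p_value=p, b=b, c=c, method="exact")
    statistic = (abs(b - c) - 1.0) ** 2 / n_disc
    p = float(stats.chi2.sf(statistic, df=1))
    return McNemarResult(statistic=statistic, p_value=p, b=b, c=c, method="chi2-cc")


def mcnemar_test(
    method1_positive: Sequence[bool], method2_positive: Sequence[bool]
) -> McNemarResult:
    """Paired McNemar test on two methods' positive calls for the same subjects.

    Callers restrict the pairs to the relevant subset first (outcome-positive
    records when comparing sensitivities, outcome-negative for specificities).
    """
    m1 = np.asarray(method1_positive, dtype=bool)
    m2 = np.asarray(method2_positive, dtype=bool)
    if m1.shape != m2.shape:
        raise DomainError("paired classifications must have equal length")
    b = int(np.sum(m1 & ~m2))
    c = int(np.sum(~m1 & m2))
    return mcnemar_from_discordant(b, c)


@dataclasses.dataclass(frozen=True)
class ProportionComparison:
    chi2: float
    p_value: float
    method: str


def compare_proportions(
    k1: int, n1: int, k2: int, n2: int, paired_discordant: tuple[int, int] | None = None
) -> ProportionComparison:
    """Pearson chi-square for k1/n1 vs k2/n2 treated as independent samples.

    This mirrors the common (if imperfect) practice of chi-squaring two
    classification rates measured on the same cohort; pass
    ``paired_discordant=(b, c)`` to use the statistically preferable McNemar
    alternative instead.  Falls back to Fisher's exact test with a warning
    when an expected cell drops below 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise DomainError("sample sizes must be positive")
    if paired_discordant is not None:
        result = mcnemar_from_discordant(*paired_discordant)
        return ProportionComparison(chi2=result.statistic, p_value=result.p_value, method="mcnemar")
    observed = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / observed.sum()
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    if expected.min() < 1.0:
        warnings.warn("expected cell < 1; using Fisher exact p-value", stacklevel=2)
        p = float(stats.fisher_exact(observed.astype(int))[1])
        return ProportionComparison(chi2=chi2, p_value=p, method="fisher-exact")
    p = float(stats.chi2.sf(chi2, df=1))
    return ProportionComparison(chi2=chi2, p_value=p, method="pearson-chi2")
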