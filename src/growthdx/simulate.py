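"""Synthetic hypertensive-pregnancy cohorts.

Generates cohorts with the statistical structure the analysis assumes:
maternal covariates drawn from the target marginals, fetal weight generated
from the customized expected-weight curve with a fixed coefficient of
variation (optionally mean-shifted to mimic placental growth restriction),
and a neonatal nutrition latent coupled to the fetal-weight latent through a
Gaussian copula.  Birth length is solved so that the neonatal BMI attains
the drawn nutrition centile under the packaged BMI reference.

All randomness flows from ``SimulationConfig.seed`` through a single
``numpy`` Generator; replicate ``r`` of a Monte-Carlo run uses ``seed + r``.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import truncnorm

from .customized import DEFAULT_COEFFICIENTS, proportionality_fraction
from .errors import DomainError, EmptyAnalysisError
from .nutrition import NutritionReference, default_bmi_reference
from .pipeline import classify_cohort, term_optimal_weights
from .population import GrowthStandard

logger = logging.getLogger(__name__)

# physical plausibility window for solved birth lengths (cm)
LENGTH_MIN, LENGTH_MAX = 25.0, 65.0
MAX_RESAMPLE_ROUNDS = 100


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Marginal and coupling parameters of a simulated HDP cohort.

    Default maternal marginals follow the target cohort profile: age
    32.6 +/- 5.3 y, height 162.02 +/- 6.16 cm, pregestational BMI
    29.93 +/- 6.52 kg/m^2 (weight derived from BMI and height), 49.2% male,
    GA at birth 37.7 +/- 2.2 weeks truncated to [32, 42].  ``hdp_shift`` is
    a mean shift (in CV units) of the fetal-weight latent; ``rho`` couples
    the fetal-weight and nutrition latents.
    """

    n: int = 226
    seed: int = 0
    maternal_age_mean: float = 32.6
    maternal_age_sd: float = 5.3
    maternal_height_mean: float = 162.02
    maternal_height_sd: float = 6.16
    bmi_mean: float = 29.93
    bmi_sd: float = 6.52
    p_male: float = 0.492
    ga_birth_mean: float = 37.7
    ga_birth_sd: float = 2.2
    ga_birth_low: float = 32.0
    ga_birth_high: float = 42.0
    growth_cv: float = 0.12
    rho: float = 0.6
    hdp_shift: float = 0.0
    scan_lag_max: float = 2.0
    efw_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError("cohort size must be >= 1")
        for name in (
            "maternal_age_sd",
            "maternal_height_sd",
            "bmi_sd",
            "ga_birth_sd",
            "growth_cv",
        ):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0")
        if not -1.0 <= self.rho <= 1.0:
            raise DomainError("rho must lie in [-1, 1]")
        if not 0.0 <= self.p_male <= 1.0:
            raise DomainError("p_male must lie in [0, 1]")


def _truncated_positive_normal(rng, mean, sd, size):
    """Plain normal resampled until strictly positive (tail mass is tiny)."""
    draw = rng.normal(mean, sd, size)
    for _ in range(MAX_RESAMPLE_ROUNDS):
        bad = draw <= 0
        if not bad.any():
            return draw
        draw[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise DomainError("could not draw strictly positive covariates")


def simulate_cohort(
    config: SimulationConfig = SimulationConfig(),
    bmi_reference: NutritionReference | None = None,
) -> pd.DataFrame:
    """One synthetic cohort as a DataFrame in the pipeline's CSV schema.

    Adds latent-truth columns ``true_weight_centile`` (realised size centile
    under the generating customized standard, shift included) and
    ``true_nutrition_centile``, plus ``n_length_resampled`` in ``attrs``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    reference = bmi_reference or default_bmi_reference()

    age = _truncated_positive_normal(rng, config.maternal_age_mean, config.maternal_age_sd, n)
    height = _truncated_positive_normal(
        rng, config.maternal_height_mean, config.maternal_height_sd, n
    )
    bmi = _truncated_positive_normal(rng, config.bmi_mean, config.bmi_sd, n)
    weight = bmi * (height / 100.0) ** 2  # derived, keeps covariates coherent
    sex = np.where(rng.random(n) < config.p_male, "male", "female")

    a = (config.ga_birth_low - config.ga_birth_mean) / config.ga_birth_sd
    b = (config.ga_birth_high - config.ga_birth_mean) / config.ga_birth_sd
    ga_birth = truncnorm.rvs(
        a, b, loc=config.ga_birth_mean, scale=config.ga_birth_sd, size=n, random_state=rng
    )

    z_weight = rng.standard_normal(n)
    z_nutrition = config.rho * z_weight + math.sqrt(1.0 - config.rho**2) * rng.standard_normal(n)

    frame = pd.DataFrame(
        {
            "maternal_age": age,
            "maternal_height": height,
            "pregestational_weight": weight,
            "sex": sex,
        }
    )
    tow = term_optimal_weights(frame, DEFAULT_COEFFICIENTS)
    shifted = z_weight + config.hdp_shift
    ideal_birth = tow * proportionality_fraction(ga_birth) / 100.0
    birthweight = ideal_birth * (1.0 + config.growth_cv * shifted)
    # non-positive weights require |z| > 1/cv ~ 8.3; resample those draws
    for _ in range(MAX_RESAMPLE_ROUNDS):
        bad = birthweight <= 0
        if not bad.any():
            break
        z_weight[bad] = rng.standard_normal(int(bad.sum()))
        shifted = z_weight + config.hdp_shift
        birthweight = ideal_birth * (1.0 + config.growth_cv * shifted)

    ga_scan = ga_birth - rng.uniform(0.0, config.scan_lag_max, n)
    efw = (
        tow
        * proportionality_fraction(ga_scan)
        / 100.0
        * (1.0 + config.growth_cv * shifted)
        * np.exp(rng.normal(0.0, config.efw_noise_sd, n))
    )

    # solve birth length so BMI attains the nutrition latent's centile
    weeks = np.floor(ga_birth).astype(int)
    lookup = {
        (row.sex, int(row.ga_weeks)): (row.mean, row.sd)
        for row in reference.frame.itertuples()
    }
    lo, hi = reference.coverage()
    clamped_weeks = np.clip(weeks, lo, hi)  # nearest row when GA range was widened
    ref_mean = np.empty(n)
    ref_sd = np.empty(n)
    for i in range(n):
        ref_mean[i], ref_sd[i] = lookup[(sex[i], int(clamped_weeks[i]))]

    n_resampled = 0
    length = np.full(n, np.nan)
    for _ in range(MAX_RESAMPLE_ROUNDS):
        target_bmi = ref_mean + ref_sd * z_nutrition
        with np.errstate(invalid="ignore", divide="ignore"):
            candidate = np.sqrt((birthweight / 1000.0) / target_bmi) * 100.0
        feasible = (
            (target_bmi > 0) & (candidate >= LENGTH_MIN) & (candidate <= LENGTH_MAX)
        )
        length = np.where(feasible, candidate, np.nan)
        bad = ~feasible
        if not bad.any():
            break
        n_resampled += int(bad.sum())
        z_nutrition[bad] = config.rho * z_weight[bad] + math.sqrt(
            1.0 - config.rho**2
        ) * rng.standard_normal(int(bad.sum()))
    if np.isnan(length).any():
        raise DomainError("could not solve a physical birth length for some records")
    if n_resampled:
        logger.info("resampled nutrition latent for %d infeasible length draw(s)", n_resampled)

    frame["ga_scan"] = ga_scan
    frame["efw"] = efw
    frame["ga_birth"] = ga_birth
    frame["birthweight"] = birthweight
    frame["birth_length"] = length
    frame["true_weight_centile"] = ndtr(shifted) * 100.0
    frame["true_nutrition_centile"] = ndtr(z_nutrition) * 100.0
    frame.attrs["n_length_resampled"] = n_resampled
    frame.attrs["config"] = dataclasses.asdict(config)
    return frame


def recover_operating_characteristics(
    config: SimulationConfig,
    n_reps: int,
    standards: dict[str, GrowthStandard] | None = None,
    mode: str = "scan",
    index: str = "BMI",
) -> pd.DataFrame:
    """Monte-Carlo operating characteristics of each standard.

    Runs the full classify-and-tabulate pipeline on ``n_reps`` independent
    cohorts (replicate ``r`` seeded with ``seed + r``) and returns one row
    per replicate x standard with sensitivity, specificity and DOR.
    Degenerate replicates (empty 2x2 margin) are recorded with NaN metrics.
    """
    from . import diagnostics as dxmod
    from .pipeline import default_standards

    if n_reps < 1:
        raise DomainError("n_reps must be >= 1")
    standards = standards or default_standards()
    status_col = f"{index.lower()}_status"
    rows = []
    for rep in range(n_reps):
        rep_config = dataclasses.replace(config, seed=config.seed + rep)
        cohort = simulate_cohort(rep_config)
        classified = classify_cohort(cohort, standards, mode=mode)
        for name in standards:
            pairs = classified[[f"size_{name}", status_col]].rename(
                columns={f"size_{name}": "size_class", status_col: "nutrition"}
            )
            row = {"rep": rep, "standard": name}
            try:
                table = dxmod.build_table(pairs)
                sens_n = table.tp + table.fn
                spec_n = table.tn + table.fp
                row["sensitivity"] = table.tp / sens_n if sens_n else math.nan
                row["specificity"] = table.tn / spec_n if spec_n else math.nan
                row["dor"] = (
                    (table.tp * table.tn) / (table.fp * table.fn)
                    if min(table.tp, table.fp, table.fn, table.tn) > 0
                    else math.nan
                )
                row["degenerate"] = False
            except EmptyAnalysisError:
                row.update(sensitivity=math.nan, specificity=math.nan, dor=math.nan)
                row["degenerate"] = True
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_operating_characteristics(per_rep: pd.DataFrame) -> pd.DataFrame:
    """Monte-Carlo means and standard errors per standard."""
    summaries = []
    for name, group in per_rep.groupby("standard"):
        entry = {"standard": name, "n_reps": len(group), "n_degenerate": int(group["degenerate"].sum())}
        for metric in ("sensitivity", "specificity", "dor"):
            values = group[metric].dropna()
            entry[f"{metric}_mean"] = float(values.mean()) if len(values) else math.nan
            entry[f"{metric}_se"] = (
                float(values.std(ddof=1) / math.sqrt(len(values))) if len(values) > 1 else math.nan
            )
        summaries.append(entry)
    return pd.DataFrame(summaries)
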