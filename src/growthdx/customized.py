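"""Customized fetal growth standard.

A per-pregnancy expected-weight curve: a linear model of maternal
anthropometrics and fetal sex predicts the optimal weight at 40 weeks
("term optimal weight"), a cubic proportionality polynomial in gestational
age scales that weight across gestation, and a fixed coefficient of
variation converts the observed/expected weight ratio into a z-score and
centile.  Size classes (SGA / AGA / LGA) follow the conventional 10th and
90th centile cut-offs.

All numeric operations accept scalars or NumPy arrays; classification of
arrays returns an object array of :class:`SizeClass`.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Mapping

import numpy as np
from scipy.special import ndtr

from .errors import DomainError, GARangeError, MissingFieldError
from .population import GrowthStandard

GA_MIN = 20.0
GA_MAX = 44.0
SGA_THRESHOLD = 10.0
LGA_THRESHOLD = 90.0


class Sex(enum.IntEnum):
    """Fetal/newborn sex; male is coded 1 and female 0 in the weight model."""

    FEMALE = 0
    MALE = 1

    @classmethod
    def parse(cls, value) -> "Sex":
        """Coerce common encodings (0/1, 'M'/'F', 'male'/'female')."""
        if isinstance(value, Sex):
            return value
        if isinstance(value, str):
            key = value.strip().lower()
            if key in {"m", "male", "1"}:
                return cls.MALE
            if key in {"f", "female", "0"}:
                return cls.FEMALE
            raise DomainError(f"unrecognised sex encoding: {value!r}")
        if value in (0, 1):
            return cls(int(value))
        raise DomainError(f"unrecognised sex encoding: {value!r}")


class SizeClass(str, enum.Enum):
    """Mutually exclusive, exhaustive size-for-gestational-age classes."""

    SGA = "SGA"
    AGA = "AGA"
    LGA = "LGA"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclasses.dataclass(frozen=True)
class CustomizedCoefficients:
    """Linear term-optimal-weight model plus the weight coefficient of variation.

    Defaults are the published model: grams at 40 weeks as
    ``intercept + age*age_coef + weight*weight_coef + height*height_coef +
    sex*sex_coef`` with age in years, pregestational weight in kg, height in
    cm and sex coded male=1 / female=0.
    """

    intercept: float = 1407.501
    age_coef: float = 4.087
    weight_coef: float = 6.506
    height_coef: float = 8.716
    sex_coef: float = 150.375
    cv: float = 0.12

    def __post_init__(self) -> None:
        if not self.cv > 0:
            raise DomainError(f"coefficient of variation must be > 0, got {self.cv}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "CustomizedCoefficients":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise DomainError(f"unknown coefficient keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


@dataclasses.dataclass(frozen=True)
class ProportionalityCoefficients:
    """Cubic polynomial in GA (weeks) giving percent of the 40-week weight.

    The polynomial is used raw: its value at 40 weeks is ~100.3%, not
    renormalised to exactly 100, matching the published worked example
    (66.21% at 34 weeks).
    """

    c0: float = 299.1
    c1: float = -31.85
    c2: float = 1.094
    c3: float = -0.01055

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ProportionalityCoefficients":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise DomainError(f"unknown coefficient keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


DEFAULT_COEFFICIENTS = CustomizedCoefficients()
DEFAULT_PROPORTIONALITY = ProportionalityCoefficients()


@dataclasses.dataclass(frozen=True)
class PregnancyRecord:
    """One pregnancy: maternal covariates, prenatal scan and birth outcome.

    All fields are optional so partially observed records can be represented;
    each operation checks for the fields it needs and raises
    :class:`~growthdx.errors.MissingFieldError` rather than imputing.
    """

    maternal_age: float | None = None  # years
    maternal_height: float | None = None  # cm
    pregestational_weight: float | None = None  # kg
    sex: Sex | None = None
    ga_scan: float | None = None  # decimal weeks
    efw: float | None = None  # grams
    ga_birth: float | None = None  # decimal weeks
    birthweight: float | None = None  # grams
    birth_length: float | None = None  # cm

    def __post_init__(self) -> None:
        if self.sex is not None:
            object.__setattr__(self, "sex", Sex.parse(self.sex))
        for name in (
            "maternal_age",
            "maternal_height",
            "pregestational_weight",
            "efw",
            "birthweight",
            "birth_length",
        ):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise DomainError(f"{name} must be strictly positive, got {value}")
        for name in ("ga_scan", "ga_birth"):
            value = getattr(self, name)
            if value is not None and not (GA_MIN <= value <= GA_MAX):
                raise GARangeError(
                    f"{name}={value} outside supported range [{GA_MIN}, {GA_MAX}] weeks"
                )


def term_optimal_weight(
    record: PregnancyRecord,
    coef: CustomizedCoefficients = DEFAULT_COEFFICIENTS,
) -> float:
    """Model-predicted optimal birthweight (g) at 40 weeks for this pregnancy."""
    missing = [
        name
        for name in ("maternal_age", "pregestational_weight", "maternal_height", "sex")
        if getattr(record, name) is None
    ]
    if missing:
        raise MissingFieldError(f"term_optimal_weight requires fields: {missing}")
    return float(
        coef.intercept
        + record.maternal_age * coef.age_coef
        + record.pregestational_weight * coef.weight_coef
        + record.maternal_height * coef.height_coef
        + int(record.sex) * coef.sex_coef
    )


def proportionality_fraction(
    ga, coef: ProportionalityCoefficients = DEFAULT_PROPORTIONALITY
):
    """Percent of the 40-week weight expected at gestational age ``ga`` (weeks).

    Raw cubic polynomial on the percent scale; not renormalised at term.
    """
    ga_arr = np.asarray(ga, dtype=float)
    if np.any((ga_arr < GA_MIN) | (ga_arr > GA_MAX)) or not np.all(np.isfinite(ga_arr)):
        raise GARangeError(f"gestational age outside [{GA_MIN}, {GA_MAX}] weeks")
    value = coef.c0 + ga_arr * (coef.c1 + ga_arr * (coef.c2 + ga_arr * coef.c3))
    return float(value) if np.isscalar(ga) else value


def expected_weight(
    record: PregnancyRecord,
    ga,
    coef: CustomizedCoefficients = DEFAULT_COEFFICIENTS,
    prop: ProportionalityCoefficients = DEFAULT_PROPORTIONALITY,
):
    """Customized expected (ideal) weight in grams at gestational age ``ga``."""
    return term_optimal_weight(record, coef) * proportionality_fraction(ga, prop) / 100.0


def weight_zscore(observed, ideal, cv: float = DEFAULT_COEFFICIENTS.cv):
    """z = (observed/ideal - 1) / cv."""
    ideal_arr = np.asarray(ideal, dtype=float)
    if np.any(ideal_arr <= 0):
        raise DomainError("ideal weight must be strictly positive")
    if not cv > 0:
        raise DomainError("cv must be strictly positive")
    z = (np.asarray(observed, dtype=float) / ideal_arr - 1.0) / cv
    return float(z) if np.isscalar(observed) and np.isscalar(ideal) else z


def centile_from_z(z):
    """Cumulative standard-normal probability below ``z``, times 100."""
    z_arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z_arr)):
        raise DomainError("z-score must be finite")
    centile = ndtr(z_arr) * 100.0
    return float(centile) if np.isscalar(z) else centile


def classify_size(centile):
    """SGA below the 10th centile, LGA above the 90th, AGA otherwise.

    Exact 10th/90th centile ties are AGA ("between 10 to 90th" read as
    inclusive).
    """
    arr = np.asarray(centile, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any((arr <= 0) | (arr >= 100)):
        raise DomainError("centile must lie strictly inside (0, 100)")
    out = np.where(
        arr < SGA_THRESHOLD, SizeClass.SGA, np.where(arr > LGA_THRESHOLD, SizeClass.LGA, SizeClass.AGA)
    )
    if np.isscalar(centile):
        return SizeClass(out.item())
    return out


# Widely published four-parameter log10 regression for estimated fetal
# weight from biometry (cm inputs, gram output).  Kept as config data, not
# code: any {term: coefficient} mapping with product terms joined by '*'
# may be supplied instead.
HADLOCK_DEFAULT: Mapping[str, float] = {
    "intercept": 1.3596,
    "hc": 0.0064,
    "ac": 0.0424,
    "fl": 0.174,
    "bpd*ac": 0.00061,
    "ac*fl": -0.00386,
}


def hadlock_efw(
    bpd: float | None = None,
    hc: float | None = None,
    ac: float | None = None,
    fl: float | None = None,
    coefficients: Mapping[str, float] = HADLOCK_DEFAULT,
) -> float:
    """Estimated fetal weight (g) from biometry via a log10 regression table.

    ``coefficients`` maps term names ('intercept', variable names, or
    '*'-joined products of biometric variables, in cm) to regression
    coefficients; the result is ``10**sum(term values)`` grams.  This is a
    convenience utility only — the pipeline accepts EFW directly.
    """
    values = {"bpd": bpd, "hc": hc, "ac": ac, "fl": fl}
    log10_weight = 0.0
    for term, coefficient in coefficients.items():
        if term == "intercept":
            log10_weight += coefficient
            continue
        product = coefficient
        for var in term.split("*"):
            if var not in values:
                raise DomainError(f"unknown biometry variable in term {term!r}")
            if values[var] is None:
                if coefficient == 0:
                    product = 0.0
                    break
                raise MissingFieldError(f"hadlock_efw: biometry {var!r} required by term {term!r}")
            product *= values[var]
        log10_weight += product
    return float(10.0 ** log10_weight)


class CustomizedStandard(GrowthStandard):
    """Growth-standard interface backed by the customized per-pregnancy model."""

    name = "customized"

    def __init__(
        self,
        coef: CustomizedCoefficients = DEFAULT_COEFFICIENTS,
        prop: ProportionalityCoefficients = DEFAULT_PROPORTIONALITY,
    ) -> None:
        self.coef = coef
        self.prop = prop

    def centile_of(self, weight, ga, sex=None, record: PregnancyRecord | None = None):
        if record is None:
            raise MissingFieldError("customized standard requires the pregnancy record")
        ideal = expected_weight(record, ga, self.coef, self.prop)
        return centile_from_z(weight_zscore(weight, ideal, self.coef.cv))

    def centile_of_cohort(self, weights, gas, term_weights):
        """Vectorised centiles given precomputed term optimal weights."""
        ideal = np.asarray(term_weights, dtype=float) * proportionality_fraction(
            np.asarray(gas, dtype=float), self.prop
        ) / 100.0
        return centile_from_z(weight_zscore(np.asarray(weights, dtype=float), ideal, self.coef.cv))
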