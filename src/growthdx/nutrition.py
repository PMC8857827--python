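"""Neonatal nutrition indices and their sex x GA references.

Computes neonatal BMI (kg/m^2) and Rohrer's ponderal index
(g x 100 / cm^3), looks the value up in a sex x completed-week reference
table of means and SDs, and classifies nutritional status at the 10th/90th
centile cut-offs.  Overnourished newborns (> 90th centile) carry an
exclusion flag because they are removed from the diagnostic analysis.

The packaged reference tables cover 32-42 completed weeks; gestational age
is floored to completed weeks for lookup (obstetric convention).  Records
outside coverage raise :class:`OutOfCoverageError` so callers can flag and
count them rather than silently dropping them.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .errors import DomainError, OutOfCoverageError

UNDER_THRESHOLD = 10.0
OVER_THRESHOLD = 90.0


class IndexKind(str, enum.Enum):
    BMI = "BMI"
    PI = "PI"


class NutritionLabel(str, enum.Enum):
    UNDERNOURISHED = "undernourished"
    NORMAL = "normal"
    OVERNOURISHED = "overnourished"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclasses.dataclass(frozen=True)
class NutritionStatus:
    """Classified nutritional status with the centile that produced it."""

    value: NutritionLabel
    centile: float

    @property
    def exclude_from_diagnostics(self) -> bool:
        """Overnourished newborns are excluded from the 2x2 analysis."""
        return self.value is NutritionLabel.OVERNOURISHED


@dataclasses.dataclass(frozen=True)
class NutritionReference:
    """Sex x completed-week table of index means and SDs."""

    index_kind: IndexKind
    frame: pd.DataFrame  # columns: sex, ga_weeks (int), mean, sd

    def __post_init__(self) -> None:
        frame = self.frame
        for column in ("sex", "ga_weeks", "mean", "sd"):
            if column not in frame.columns:
                raise DomainError(f"nutrition reference missing column {column!r}")
        if not (frame["mean"] > 0).all() or not (frame["sd"] > 0).all():
            raise DomainError("nutrition reference means and SDs must be strictly positive")
        object.__setattr__(
            self, "frame", frame.sort_values(["sex", "ga_weeks"]).reset_index(drop=True)
        )

    def coverage(self) -> tuple[int, int]:
        return int(self.frame["ga_weeks"].min()), int(self.frame["ga_weeks"].max())

    def params(self, sex, ga_weeks: int) -> tuple[float, float]:
        sex_label = _sex_label(sex)
        row = self.frame[
            (self.frame["sex"] == sex_label) & (self.frame["ga_weeks"] == int(ga_weeks))
        ]
        if row.empty:
            lo, hi = self.coverage()
            raise OutOfCoverageError(
                f"{self.index_kind.value} reference has no row for sex={sex_label}, "
                f"ga={ga_weeks} completed weeks (coverage {lo}-{hi})"
            )
        return float(row["mean"].iloc[0]), float(row["sd"].iloc[0])

    @classmethod
    def from_csv(cls, path: str | Path, index_kind: IndexKind | None = None):
        frame = pd.read_csv(path, comment="#")
        if index_kind is None:
            kinds = frame["index_kind"].unique()
            if len(kinds) != 1:
                raise DomainError("index_kind must be unique in a reference file")
            index_kind = IndexKind(kinds[0])
        frame = frame[frame["index_kind"] == index_kind.value] if "index_kind" in frame else frame
        return cls(index_kind=index_kind, frame=frame[["sex", "ga_weeks", "mean", "sd"]])


def _packaged(name: str) -> Path:
    return resources.files("growthdx.data").joinpath(name)


def default_bmi_reference() -> NutritionReference:
    with resources.as_file(_packaged("neonatal_bmi_reference.csv")) as path:
        return NutritionReference.from_csv(path, IndexKind.BMI)


def default_pi_reference() -> NutritionReference:
    with resources.as_file(_packaged("neonatal_pi_reference.csv")) as path:
        return NutritionReference.from_csv(path, IndexKind.PI)


def default_reference(kind: IndexKind) -> NutritionReference:
    return default_bmi_reference() if kind is IndexKind.BMI else default_pi_reference()


def neonatal_bmi(weight, length):
    """BMI in kg/m^2 from birthweight (g) and birth length (cm)."""
    w = np.asarray(weight, dtype=float)
    l = np.asarray(length, dtype=float)
    if np.any(w <= 0) or np.any(l <= 0):
        raise DomainError("weight and length must be strictly positive")
    bmi = (w / 1000.0) / (l / 100.0) ** 2
    return float(bmi) if np.isscalar(weight) and np.isscalar(length) else bmi


def ponderal_index(weight, length):
    """Rohrer's ponderal index: weight (g) x 100 / length (cm)^3."""
    w = np.asarray(weight, dtype=float)
    l = np.asarray(length, dtype=float)
    if np.any(w <= 0) or np.any(l <= 0):
        raise DomainError("weight and length must be strictly positive")
    pi = w * 100.0 / l**3
    return float(pi) if np.isscalar(weight) and np.isscalar(length) else pi


def completed_weeks(ga) -> int:
    """Floor decimal weeks to completed weeks."""
    return int(math.floor(ga))


def nutrition_centile(value, sex, ga, reference: NutritionReference):
    """Centile of an index value against the matching (sex, completed-week) row."""
    mean, sd = reference.params(sex, completed_weeks(ga))
    return float(ndtr((float(value) - mean) / sd) * 100.0)


def classify_nutrition(centile) -> NutritionStatus:
    """Under the 10th centile: undernourished; over the 90th: overnourished
    (flagged for exclusion); ties at exactly 10/90 are normal."""
    c = float(centile)
    if not np.isfinite(c) or not (0.0 < c < 100.0):
        raise DomainError("centile must lie strictly inside (0, 100)")
    if c < UNDER_THRESHOLD:
        label = NutritionLabel.UNDERNOURISHED
    elif c > OVER_THRESHOLD:
        label = NutritionLabel.OVERNOURISHED
    else:
        label = NutritionLabel.NORMAL
    return NutritionStatus(value=label, centile=c)


def _sex_label(sex) -> str:
    if isinstance(sex, str) and sex.lower() in {"male", "female"}:
        return sex.lower()
    from .customized import Sex

    return "male" if Sex.parse(sex) is Sex.MALE else "female"
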