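"""Table-based population growth standard.

A population reference is a sex x gestational-age grid of weight-centile
parameters (normal location and scale in grams, optionally a skewness
parameter).  Lookups interpolate linearly inside the grid and never
extrapolate.  The packaged demonstration table is SYNTHETIC — it is shaped
like a published newborn/fetal standard so the full pipeline runs without
any download, but it is not the INTERGROWTH-21st parameterisation; a genuine
published table can be dropped in through the same CSV schema.
"""

from __future__ import annotations

import abc
import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import skewnorm

from .errors import DomainError, OutOfCoverageError

_REQUIRED_COLUMNS = ("sex", "ga_weeks", "location_g", "scale_g")
_MIN_COVERAGE = (24.0, 42.0)


class GrowthStandard(abc.ABC):
    """Contract shared by every growth standard.

    Both concrete standards map (weight, GA, sex, record) to a centile so the
    diagnostics stage is standard-agnostic.
    """

    name: str = "standard"

    @abc.abstractmethod
    def centile_of(self, weight, ga, sex=None, record=None):
        """Percentile of ``weight`` (g) at ``ga`` (weeks) under this standard."""

    def classify(self, weight, ga, sex=None, record=None):
        from .customized import classify_size

        return classify_size(self.centile_of(weight, ga, sex=sex, record=record))


@dataclasses.dataclass(frozen=True)
class ReferenceCurveTable:
    """Sex x GA grid of weight centile parameters.

    ``frame`` columns: sex ('male'/'female'), ga_weeks, location_g, scale_g
    and optionally skew.  Metadata (name, citation) travel with the table so
    synthetic demonstration data cannot masquerade as a published standard.
    """

    frame: pd.DataFrame
    name: str = "unnamed reference"
    citation: str = ""
    grid_spacing: float = 1.0

    def __post_init__(self) -> None:
        frame = self.frame
        missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise DomainError(f"reference table missing columns: {missing}")
        if not (frame["location_g"] > 0).all() or not (frame["scale_g"] > 0).all():
            raise DomainError("reference table requires location > 0 and scale > 0 in every row")
        bad_sex = set(frame["sex"].unique()) - {"male", "female"}
        if bad_sex:
            raise DomainError(f"reference table sex column must be male/female, got {bad_sex}")
        for sex in ("male", "female"):
            ga = frame.loc[frame["sex"] == sex, "ga_weeks"]
            if ga.empty or ga.min() > _MIN_COVERAGE[0] or ga.max() < _MIN_COVERAGE[1]:
                raise DomainError(
                    f"reference table must cover [{_MIN_COVERAGE[0]}, {_MIN_COVERAGE[1]}] "
                    f"weeks for sex={sex}"
                )
        object.__setattr__(
            self,
            "frame",
            frame.sort_values(["sex", "ga_weeks"]).reset_index(drop=True),
        )

    @property
    def has_skew(self) -> bool:
        return "skew" in self.frame.columns and (self.frame["skew"] != 0).any()

    def coverage(self, sex: str) -> tuple[float, float]:
        ga = self.frame.loc[self.frame["sex"] == sex, "ga_weeks"]
        return float(ga.min()), float(ga.max())

    @classmethod
    def from_csv(cls, path: str | Path, name: str | None = None, citation: str | None = None):
        """Load a reference table, reading '# key: value' header comments as metadata."""
        path = Path(path)
        meta: dict[str, str] = {}
        with open(path) as handle:
            for line in handle:
                if not line.startswith("#"):
                    break
                if ":" in line:
                    key, _, value = line.lstrip("# ").partition(":")
                    meta[key.strip().lower()] = value.strip()
        frame = pd.read_csv(path, comment="#")
        return cls(
            frame=frame,
            name=name or meta.get("name", path.stem),
            citation=citation or meta.get("citation", ""),
        )

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as handle:
            handle.write(f"# name: {self.name}\n# citation: {self.citation}\n")
            self.frame.to_csv(handle, index=False)


def load_demo_table() -> ReferenceCurveTable:
    """The packaged synthetic demonstration table (NOT a published standard)."""
    with resources.as_file(
        resources.files("growthdx.data").joinpath("demo_population_standard.csv")
    ) as path:
        return ReferenceCurveTable.from_csv(path)


def lookup_params(table: ReferenceCurveTable, sex, ga):
    """(location, scale) at ``ga`` for ``sex`` by linear interpolation.

    Raises :class:`OutOfCoverageError` outside the grid; never extrapolates.
    Accepts scalar or array ``ga`` (single sex per call).
    """
    sex_label = _sex_label(sex)
    rows = table.frame[table.frame["sex"] == sex_label]
    grid = rows["ga_weeks"].to_numpy(dtype=float)
    ga_arr = np.asarray(ga, dtype=float)
    if np.any((ga_arr < grid.min()) | (ga_arr > grid.max())):
        raise OutOfCoverageError(
            f"ga outside {table.name} coverage [{grid.min()}, {grid.max()}] for sex={sex_label}"
        )
    location = np.interp(ga_arr, grid, rows["location_g"].to_numpy(dtype=float))
    scale = np.interp(ga_arr, grid, rows["scale_g"].to_numpy(dtype=float))
    if np.isscalar(ga):
        return float(location), float(scale)
    return location, scale


def table_centile(weight, ga, sex, table: ReferenceCurveTable):
    """Percentile of ``weight`` under the table standard.

    Two-parameter rows use the normal CDF of (weight - location)/scale; if a
    nonzero ``skew`` column is present the row is read as a skew-normal
    (shape=skew, loc=location, scale=scale) — the documented three-parameter
    extension.
    """
    location, scale = lookup_params(table, sex, ga)
    w = np.asarray(weight, dtype=float)
    if table.has_skew:
        sex_label = _sex_label(sex)
        rows = table.frame[table.frame["sex"] == sex_label]
        grid = rows["ga_weeks"].to_numpy(dtype=float)
        skew = np.interp(np.asarray(ga, dtype=float), grid, rows["skew"].to_numpy(dtype=float))
        centile = skewnorm.cdf(w, skew, loc=location, scale=scale) * 100.0
    else:
        centile = ndtr((w - location) / np.asarray(scale)) * 100.0
    if np.isscalar(weight) and np.isscalar(ga):
        return float(centile)
    return centile


def _sex_label(sex) -> str:
    if isinstance(sex, str) and sex.lower() in {"male", "female"}:
        return sex.lower()
    from .customized import Sex

    return "male" if Sex.parse(sex) is Sex.MALE else "female"


class TableStandard(GrowthStandard):
    """Growth-standard interface backed by a :class:`ReferenceCurveTable`."""

    def __init__(self, table: ReferenceCurveTable) -> None:
        self.table = table
        self.name = table.name

    def centile_of(self, weight, ga, sex=None, record=None):
        if sex is None:
            if record is None or record.sex is None:
                raise DomainError("table standard requires sex (directly or via record)")
            sex = record.sex
        return table_centile(weight, ga, sex, self.table)


def build_demo_table(
    term_location_male: float = 3280.0,
    term_location_female: float = 3160.0,
    relative_scale: float = 0.135,
    ga_grid=None,
) -> ReferenceCurveTable:
    """Construct the synthetic demonstration table.

    Locations follow a smooth gestational trajectory (the same cubic
    proportionality shape used by the customized model, anchored at a fixed
    term weight per sex) and scales are a constant fraction of location.
    Deliberately lighter at term than a typical customized optimum so the
    two standards diverge, as population and customized references do.
    """
    from .customized import proportionality_fraction

    if ga_grid is None:
        ga_grid = np.arange(24, 44)
    rows = []
    for sex, term in (("male", term_location_male), ("female", term_location_female)):
        fraction = proportionality_fraction(np.asarray(ga_grid, dtype=float)) / 100.0
        for ga, frac in zip(ga_grid, fraction):
            location = term * frac
            rows.append(
                {
                    "sex": sex,
                    "ga_weeks": float(ga),
                    "location_g": round(location, 1),
                    "scale_g": round(relative_scale * location, 1),
                }
            )
    return ReferenceCurveTable(
        frame=pd.DataFrame(rows),
        name="synthetic-demo-population-standard",
        citation="synthetic demonstration table generated by growthdx; not a published standard",
    )
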