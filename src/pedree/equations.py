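"""Registry and evaluator for the 10 REE prediction equations.

Each equation predicts resting energy expenditure from sex, age, weight and
height as a piecewise-linear form

    eREE = intercept + c_w * W + c_h * H + c_a * A

with one coefficient set per (sex, age bracket).  Brackets are half-open
[lo, hi) in years; the lowest bracket starts at 0 and the topmost extends to
infinity, so every equation is total: it scores any subject regardless of
the age range it was developed for (a 5-year-old is scored by the 10-16 y
Molnar equation without complaint, by design).

Coefficients live in a versioned package data file (``data/ree_equations.csv``)
rather than in code; each row is one coefficient set in its source's native
units.  Height units (cm vs m) and output units (kcal/day vs MJ/day) are
declared per row and normalised by the evaluator; MJ/day converts at
239.006 kcal/MJ (thermochemical calorie, 4.184 kJ/kcal).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import ConfigurationError, Sex, Subject, ValidationError, parse_sex

KCAL_PER_MJ = 239.006

#: canonical reporting order of the equation battery
EQUATION_ORDER: tuple[str, ...] = (
    "harris_benedict",
    "who_wt",
    "schofield_wt",
    "schofield_wt_ht",
    "henry",
    "iom_nw",
    "iom_ow_ob",
    "molnar",
    "muller",
    "mifflin",
)

_DATA_FILE = "ree_equations.csv"


@dataclass(frozen=True)
class CoefficientSet:
    """One linear coefficient row: applies to one sex over [age_lo, age_hi)."""

    sex: Sex
    age_lo: float
    age_hi: float
    intercept: float
    coef_weight: float
    coef_height: float
    coef_age: float

    def __post_init__(self):
        if not self.age_lo < self.age_hi:
            raise ConfigurationError(f"bracket lo {self.age_lo} must be < hi {self.age_hi}")
        for name in ("intercept", "coef_weight", "coef_height", "coef_age"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"non-finite coefficient {name}")

    def matches(self, sex: Sex, age_years: float) -> bool:
        return sex is self.sex and self.age_lo <= age_years < self.age_hi


@dataclass(frozen=True)
class EquationSpec:
    """One prediction equation: metadata plus its coefficient sets."""

    id: str
    display_name: str
    height_unit: str        # "cm" or "m"
    output_unit: str        # "kcal_d" or "mj_d"
    terms: tuple[CoefficientSet, ...]

    def __post_init__(self):
        if self.height_unit not in ("cm", "m"):
            raise ConfigurationError(f"{self.id}: bad height_unit {self.height_unit!r}")
        if self.output_unit not in ("kcal_d", "mj_d"):
            raise ConfigurationError(f"{self.id}: bad output_unit {self.output_unit!r}")
        for sex in Sex:
            brackets = sorted(
                (t.age_lo, t.age_hi) for t in self.terms if t.sex is sex
            )
            if not brackets:
                raise ConfigurationError(f"{self.id}: no coefficient sets for {sex.value}")
            if brackets[0][0] != 0 or not math.isinf(brackets[-1][1]):
                raise ConfigurationError(f"{self.id}/{sex.value}: brackets must span [0, inf)")
            for (lo1, hi1), (lo2, _) in zip(brackets, brackets[1:]):
                if hi1 != lo2:
                    raise ConfigurationError(
                        f"{self.id}/{sex.value}: brackets must tile without gap or overlap"
                    )

    def coefficients_for(self, sex: Sex, age_years: float) -> CoefficientSet:
        for t in self.terms:
            if t.matches(sex, age_years):
                return t
        raise ConfigurationError(f"{self.id}: no bracket for {sex.value} age {age_years}")


def _data_path() -> Path:
    return Path(str(resources.files("pedree").joinpath("data", _DATA_FILE)))


def coefficient_file_sha256() -> str:
    """Checksum of the shipped coefficient file, for provenance pinning."""
    return hashlib.sha256(_data_path().read_bytes()).hexdigest()


@lru_cache(maxsize=1)
def registry() -> Mapping[str, EquationSpec]:
    """All 10 equation specs, keyed by id, in canonical order.

    Each spec self-validates (bracket tiling, finite coefficients) at
    construction; a malformed data file raises ConfigurationError.
    """
    frame = pd.read_csv(_data_path())
    specs: dict[str, EquationSpec] = {}
    for eq_id, grp in frame.groupby("equation_id", sort=False):
        units = grp[["height_unit", "output_unit", "display_name"]].drop_duplicates()
        if len(units) != 1:
            raise ConfigurationError(f"{eq_id}: inconsistent units/display name across rows")
        terms = tuple(
            CoefficientSet(
                sex=parse_sex(r.sex),
                age_lo=float(r.age_lo),
                age_hi=float(r.age_hi),
                intercept=float(r.intercept),
                coef_weight=float(r.coef_weight),
                coef_height=float(r.coef_height),
                coef_age=float(r.coef_age),
            )
            for r in grp.itertuples()
        )
        specs[str(eq_id)] = EquationSpec(
            id=str(eq_id),
            display_name=str(units.iloc[0]["display_name"]),
            height_unit=str(units.iloc[0]["height_unit"]),
            output_unit=str(units.iloc[0]["output_unit"]),
            terms=terms,
        )
    ordered = {eq_id: specs[eq_id] for eq_id in EQUATION_ORDER if eq_id in specs}
    extra = set(specs) - set(ordered)
    if extra:
        raise ConfigurationError(f"unknown equation ids in data file: {sorted(extra)}")
    if len(ordered) != len(EQUATION_ORDER):
        raise ConfigurationError("coefficient file does not define all 10 equations")
    return ordered


def get_equation(eq_id: str) -> EquationSpec:
    try:
        return registry()[eq_id]
    except KeyError:
        raise ValidationError(f"unknown equation id {eq_id!r}") from None


def evaluate(spec: EquationSpec, subject: Subject) -> float:
    """Estimated REE, kcal/day, for one subject under one equation.

    Applied irrespective of the subject's age relative to the equation's
    development range.
    """
    for name in ("sex", "age_years", "weight_kg", "height_cm"):
        if getattr(subject, name) is None:
            raise ValidationError(f"subject {subject.id!r}: missing {name}")
    c = spec.coefficients_for(subject.sex, subject.age_years)
    height = subject.height_cm if spec.height_unit == "cm" else subject.height_cm / 100.0
    value = (
        c.intercept
        + c.coef_weight * subject.weight_kg
        + c.coef_height * height
        + c.coef_age * subject.age_years
    )
    if spec.output_unit == "mj_d":
        value *= KCAL_PER_MJ
    return value


def evaluate_all(
    subjects: Sequence[Subject],
    specs: Iterable[EquationSpec] | None = None,
) -> pd.DataFrame:
    """Dense table of eREE (kcal/day): rows = subject ids, columns = equation
    ids in canonical order."""
    if not subjects:
        raise ValidationError("no subjects to evaluate")
    specs = list(specs) if specs is not None else list(registry().values())
    if not specs:
        raise ValidationError("no equations to evaluate")
    data = {}
    for spec in specs:
        try:
            data[spec.id] = [evaluate(spec, s) for s in subjects]
        except ValidationError as exc:
            raise ValidationError(f"equation {spec.id}: {exc}") from exc
    return pd.DataFrame(data, index=pd.Index([s.id for s in subjects], name="id"))
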