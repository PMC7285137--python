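"""Domain types, cohort I/O, eligibility filtering, and stratification.

The unit conventions used throughout the package are fixed here: weight in
kg, height in cm, age in years, energy expenditure in kcal/day, gas exchange
in L/min.  Individual prediction equations that were published in other units
(height in m, output in MJ/day) declare those units in their coefficient
records and the evaluator converts; nothing outside the equation registry
ever handles a non-canonical unit.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("pedree")


# --------------------------------------------------------------------------
# errors
# --------------------------------------------------------------------------

class PedreeError(Exception):
    """Base class for all package errors."""


class SchemaError(PedreeError):
    """An input table is missing required columns or is malformed."""


class ValidationError(PedreeError):
    """A value violates a domain constraint (non-positive weight, NaN z ...)."""


class DomainError(ValidationError):
    """A numeric argument is outside the mathematical domain of an operation."""


class StateError(PedreeError):
    """An operation was called before its required derived fields exist."""


class ConfigurationError(PedreeError):
    """A configuration object or coefficient record is internally inconsistent."""


class OutOfReferenceError(PedreeError):
    """An age falls outside the growth-reference table (no extrapolation)."""


class QCFailureError(PedreeError):
    """A calorimetry recording failed a quality-control rule."""

    def __init__(self, reason: str, message: str = ""):
        self.reason = reason
        super().__init__(message or reason)


class StageError(PedreeError):
    """A pipeline stage was reached with prerequisites unmet."""


# --------------------------------------------------------------------------
# enums and core types
# --------------------------------------------------------------------------

class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


#: accepted spellings for the cohort CSV sex column
_SEX_ALIASES: Mapping[str, Sex] = {
    "f": Sex.FEMALE, "female": Sex.FEMALE, "girl": Sex.FEMALE, "0": Sex.FEMALE,
    "m": Sex.MALE, "male": Sex.MALE, "boy": Sex.MALE, "1": Sex.MALE,
}


def parse_sex(value) -> Sex:
    """Map common encodings (F/M, female/male, 0/1) onto the Sex enum."""
    if isinstance(value, Sex):
        return value
    key = str(value).strip().lower()
    try:
        return _SEX_ALIASES[key]
    except KeyError:
        raise ValidationError(f"unrecognised sex encoding: {value!r}") from None


class WeightStatus(str, enum.Enum):
    UNDERWEIGHT = "underweight"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESITY = "obesity"


@dataclass(frozen=True, order=True)
class Stratum:
    """One cell of the sex x obesity cross-classification.

    ``obesity=False`` pools underweight, normal weight and overweight, i.e.
    "without obesity" in the reporting labels.
    """

    sex: Sex
    obesity: bool

    @property
    def label(self) -> str:
        who = "girls" if self.sex is Sex.FEMALE else "boys"
        return f"{who} {'with' if self.obesity else 'without'} obesity"


#: canonical reporting order for the four strata
STRATA: tuple[Stratum, ...] = (
    Stratum(Sex.FEMALE, False),
    Stratum(Sex.FEMALE, True),
    Stratum(Sex.MALE, False),
    Stratum(Sex.MALE, True),
)

ALL_CHILDREN = "all children"


@dataclass
class StudyConfig:
    """Analysis-wide settings.

    ccf_threshold_pct
        half-width, in percent of measured REE, of the band inside which a
        prediction counts as correctly classified (default 10).
    ci_level
        confidence level for the exact binomial intervals (default 0.95).
    rq_min, rq_max
        physiological plausibility band for the respiratory quotient;
        subjects strictly outside it are excluded.
    max_age_years
        upper eligibility bound, inclusive.
    equation_ids
        equations to evaluate; None means the full registry.
    rounding
        decimals used by the single display-rounding routine for report
        cells (computation is always full precision).
    rng_seed
        seed threaded through every stochastic stage.
    """

    ccf_threshold_pct: float = 10.0
    ci_level: float = 0.95
    rq_min: float = 0.67
    rq_max: float = 1.3
    max_age_years: float = 18.0
    equation_ids: Sequence[str] | None = None
    rounding: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.ci_level < 1.0):
            raise ConfigurationError("ci_level must be in (0, 1)")
        if self.ccf_threshold_pct <= 0:
            raise ConfigurationError("ccf_threshold_pct must be positive")
        if self.rq_min >= self.rq_max:
            raise ConfigurationError("rq_min must be below rq_max")


@dataclass
class Subject:
    """One child: identity, anthropometry, and calorimetry outcome.

    ``mree_kcal_d`` and ``rq`` may be absent at load time (they can be filled
    in later from a calorimetry trace); the derived fields ``bmi_kg_m2``,
    ``bmi_sds`` and ``weight_status`` are populated by the anthropometry
    stage.
    """

    id: str
    sex: Sex
    age_years: float
    weight_kg: float
    height_cm: float
    mree_kcal_d: float | None = None
    rq: float | None = None
    bmi_kg_m2: float | None = None
    bmi_sds: float | None = None
    weight_status: WeightStatus | None = None

    def __post_init__(self):
        self.sex = parse_sex(self.sex)
        for name in ("age_years", "weight_kg", "height_cm"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValidationError(f"subject {self.id!r}: {name} must be a positive number, got {v!r}")
        if self.mree_kcal_d is not None and self.mree_kcal_d <= 0:
            raise ValidationError(f"subject {self.id!r}: mree_kcal_d must be positive")

    @property
    def stratum(self) -> Stratum:
        if self.weight_status is None:
            raise StateError(f"subject {self.id!r}: weight_status not derived yet")
        return Stratum(self.sex, self.weight_status is WeightStatus.OBESITY)


@dataclass(frozen=True)
class Exclusion:
    """A rejected subject together with a machine-readable reason code."""

    subject: Subject
    reason: str


# --------------------------------------------------------------------------
# cohort CSV schema
# --------------------------------------------------------------------------

COHORT_COLUMNS = ("id", "sex", "age_years", "weight_kg", "height_cm", "mree_kcal_d", "rq")
_REQUIRED = ("id", "sex", "age_years", "weight_kg", "height_cm")


def load_cohort(path: str | Path, config: StudyConfig | None = None) -> list[Subject]:
    """Read a cohort CSV into Subject records.

    The file must carry a header with at least the columns id, sex,
    age_years, weight_kg, height_cm; mree_kcal_d and rq are optional.
    Derived fields are left unset.  Invalid rows raise a ValidationError
    whose message cites the offending 1-based data row numbers.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")

    subjects: list[Subject] = []
    problems: list[str] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            mree = row.get("mree_kcal_d")
            rq = row.get("rq")
            subjects.append(Subject(
                id=str(row["id"]),
                sex=row["sex"],
                age_years=float(row["age_years"]),
                weight_kg=float(row["weight_kg"]),
                height_cm=float(row["height_cm"]),
                mree_kcal_d=None if mree is None or pd.isna(mree) else float(mree),
                rq=None if rq is None or pd.isna(rq) else float(rq),
            ))
        except (ValidationError, TypeError, ValueError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise ValidationError(f"{path}: {len(problems)} invalid row(s): " + "; ".join(problems))
    return subjects


def write_cohort(subjects: Iterable[Subject], path: str | Path) -> Path:
    """Write subjects to the canonical cohort CSV (full float precision)."""
    path = Path(path)
    rows = []
    for s in subjects:
        rows.append({
            "id": s.id,
            "sex": s.sex.value,
            "age_years": repr(s.age_years),
            "weight_kg": repr(s.weight_kg),
            "height_cm": repr(s.height_cm),
            "mree_kcal_d": "" if s.mree_kcal_d is None else repr(s.mree_kcal_d),
            "rq": "" if s.rq is None else repr(s.rq),
        })
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)
    return path


# --------------------------------------------------------------------------
# eligibility and stratification
# --------------------------------------------------------------------------

def apply_eligibility(
    subjects: Sequence[Subject], config: StudyConfig | None = None
) -> tuple[list[Subject], list[Exclusion]]:
    """Split subjects into kept and excluded per the eligibility rules.

    Kept: age <= max_age_years (inclusive) and RQ inside [rq_min, rq_max]
    (the exclusion is strict: RQ < rq_min or RQ > rq_max).  A missing RQ
    excludes with reason ``rq_missing``.  kept + excluded partition the input.
    """
    config = config or StudyConfig()
    kept: list[Subject] = []
    excluded: list[Exclusion] = []
    for s in subjects:
        if s.age_years > config.max_age_years:
            excluded.append(Exclusion(s, "age_out_of_range"))
        elif s.rq is None:
            excluded.append(Exclusion(s, "rq_missing"))
        elif s.rq < config.rq_min or s.rq > config.rq_max:
            excluded.append(Exclusion(s, "rq_out_of_range"))
        else:
            kept.append(s)
    return kept, excluded


def stratify(subjects: Sequence[Subject]) -> dict[Stratum, list[Subject]]:
    """Partition subjects into the four sex x obesity strata.

    Every subject must already carry a derived weight_status.  The result
    always contains all four strata (possibly with empty lists), in the
    canonical reporting order.
    """
    groups: dict[Stratum, list[Subject]] = {st: [] for st in STRATA}
    for s in subjects:
        groups[s.stratum].append(s)  # raises StateError if not derived
    return groups
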