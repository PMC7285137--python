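"""BMI, LMS growth-reference z-scores, and weight-status classification.

The LMS method summarises a growth reference at each age by three
parameters: L (Box-Cox power), M (median) and S (coefficient of variation).
A measurement x converts to a standard-deviation score (SDS, z-score) by

    z = ((x/M)**L - 1) / (L*S)        when |L| is not ~0
    z = ln(x/M) / S                   in the L -> 0 limit

Weight status follows the SDS cutoffs used for Italian pediatric growth
references: underweight below -1.644 SDS (5th centile), overweight at or
above 1.036 (85th), obesity at or above 1.644 (95th).

The national reference tables themselves are licensed data and are not
shipped; :func:`synthetic_growth_reference` builds a smooth synthetic
stand-in spanning ages 2-20 so the whole pipeline runs self-contained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DomainError,
    OutOfReferenceError,
    SchemaError,
    Sex,
    ValidationError,
    WeightStatus,
    parse_sex,
)

#: below this |L| the Box-Cox branch switches to its log limit
_L_TOLERANCE = 1e-7


@dataclass(frozen=True)
class WeightStatusCutoffs:
    """SDS boundaries of the four BMI classes (left-closed at each bound)."""

    underweight_lt: float = -1.644
    overweight_ge: float = 1.036
    obesity_ge: float = 1.644

    def __post_init__(self):
        if not (self.underweight_lt < self.overweight_ge < self.obesity_ge):
            raise ValidationError("cutoffs must be ordered underweight < overweight < obesity")


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index, kg/m2."""
    if weight_kg <= 0 or height_cm <= 0:
        raise DomainError("weight and height must be positive")
    return weight_kg / (height_cm / 100.0) ** 2


def lms_zscore(x: float, L: float, M: float, S: float) -> float:
    """Standard-deviation score of x under an LMS triple."""
    if x <= 0 or M <= 0 or S <= 0:
        raise DomainError("x, M and S must be positive")
    if abs(L) > _L_TOLERANCE:
        return ((x / M) ** L - 1.0) / (L * S)
    return math.log(x / M) / S


def lms_inverse(z: float, L: float, M: float, S: float) -> float:
    """Measurement value at a given SDS: x = M*(1 + L*S*z)**(1/L)."""
    if M <= 0 or S <= 0:
        raise DomainError("M and S must be positive")
    if abs(L) > _L_TOLERANCE:
        base = 1.0 + L * S * z
        if base <= 0:
            raise DomainError(f"z={z} outside the support of the Box-Cox transform")
        return M * base ** (1.0 / L)
    return M * math.exp(S * z)


def classify_weight_status(
    bmi_sds: float, cutoffs: WeightStatusCutoffs | None = None
) -> WeightStatus:
    """Map a BMI SDS onto the four-class weight status (exhaustive, exclusive)."""
    if bmi_sds is None or not math.isfinite(bmi_sds):
        raise DomainError(f"bmi_sds must be finite, got {bmi_sds!r}")
    c = cutoffs or WeightStatusCutoffs()
    if bmi_sds < c.underweight_lt:
        return WeightStatus.UNDERWEIGHT
    if bmi_sds < c.overweight_ge:
        return WeightStatus.NORMAL
    if bmi_sds < c.obesity_ge:
        return WeightStatus.OVERWEIGHT
    return WeightStatus.OBESITY


# --------------------------------------------------------------------------
# age-indexed reference table
# --------------------------------------------------------------------------

LMS_MEASURES = ("bmi", "weight", "height")


class LMSReference:
    """A growth-reference table: (measure, sex, age) -> (L, M, S).

    Stores one strictly age-increasing grid per (measure, sex) and linearly
    interpolates L, M and S in age.  No extrapolation: ages outside the grid
    raise :class:`OutOfReferenceError`.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"measure", "sex", "age_years", "L", "M", "S"}
        missing = required - set(frame.columns)
        if missing:
            raise SchemaError(f"LMS table missing column(s): {', '.join(sorted(missing))}")
        frame = frame.copy()
        frame["sex"] = frame["sex"].map(parse_sex)
        self._grids: dict[tuple[str, Sex], tuple[np.ndarray, np.ndarray]] = {}
        for (measure, sex), grp in frame.groupby(["measure", "sex"], sort=False):
            grp = grp.sort_values("age_years")
            ages = grp["age_years"].to_numpy(float)
            lms = grp[["L", "M", "S"]].to_numpy(float)
            if len(ages) < 2 or np.any(np.diff(ages) <= 0):
                raise ValidationError(f"ages must be strictly increasing for ({measure}, {sex.value})")
            if np.any(lms[:, 1] <= 0) or np.any(lms[:, 2] <= 0):
                raise ValidationError(f"M and S must be positive for ({measure}, {sex.value})")
            self._grids[(str(measure), sex)] = (ages, lms)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LMSReference":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> Path:
        rows = []
        for (measure, sex), (ages, lms) in self._grids.items():
            for age, (L, M, S) in zip(ages, lms):
                rows.append((measure, sex.value, age, L, M, S))
        pd.DataFrame(rows, columns=["measure", "sex", "age_years", "L", "M", "S"]).to_csv(
            Path(path), index=False
        )
        return Path(path)

    def age_range(self, measure: str, sex: Sex) -> tuple[float, float]:
        ages, _ = self._grid(measure, sex)
        return float(ages[0]), float(ages[-1])

    def _grid(self, measure: str, sex: Sex):
        try:
            return self._grids[(measure, parse_sex(sex))]
        except KeyError:
            raise OutOfReferenceError(f"no reference grid for ({measure}, {sex})") from None

    def lms_at(self, measure: str, sex: Sex, age_years: float) -> tuple[float, float, float]:
        """Linearly interpolated (L, M, S) at an exact age."""
        ages, lms = self._grid(measure, sex)
        if not (ages[0] <= age_years <= ages[-1]):
            raise OutOfReferenceError(
                f"age {age_years} outside reference range [{ages[0]}, {ages[-1]}] for {measure}"
            )
        L, M, S = (float(np.interp(age_years, ages, lms[:, j])) for j in range(3))
        return L, M, S


def zscore_for_age(
    reference: LMSReference, measure: str, sex: Sex, age_years: float, x: float
) -> float:
    """SDS of measurement x at an exact age, via interpolated L, M, S."""
    L, M, S = reference.lms_at(measure, sex, age_years)
    return lms_zscore(x, L, M, S)


def value_for_zscore(
    reference: LMSReference, measure: str, sex: Sex, age_years: float, z: float
) -> float:
    """Inverse of :func:`zscore_for_age`: the measurement at a given SDS."""
    L, M, S = reference.lms_at(measure, sex, age_years)
    return lms_inverse(z, L, M, S)


def derive_anthropometry(
    subjects,
    reference: LMSReference,
    cutoffs: WeightStatusCutoffs | None = None,
):
    """Fill bmi_kg_m2, bmi_sds and weight_status on each subject, in place."""
    cutoffs = cutoffs or WeightStatusCutoffs()
    for s in subjects:
        s.bmi_kg_m2 = compute_bmi(s.weight_kg, s.height_cm)
        s.bmi_sds = zscore_for_age(reference, "bmi", s.sex, s.age_years, s.bmi_kg_m2)
        s.weight_status = classify_weight_status(s.bmi_sds, cutoffs)
    return subjects


# --------------------------------------------------------------------------
# synthetic reference fixture
# --------------------------------------------------------------------------

def _height_median(sex: Sex, age: float) -> float:
    # piecewise-linear growth curves, cm; plateau after the pubertal spurt
    if sex is Sex.FEMALE:
        if age <= 13.0:
            return 85.0 + (163.0 - 85.0) * (age - 2.0) / 11.0
        return min(163.0 + 0.6 * (age - 13.0), 166.0)
    if age <= 14.0:
        return 84.0 + (160.0 - 84.0) * (age - 2.0) / 12.0
    return min(160.0 + 5.0 * (age - 14.0), 175.0)


def synthetic_growth_reference(
    age_min: float = 2.0, age_max: float = 20.0, step: float = 0.5
) -> LMSReference:
    """Smooth SYNTHETIC LMS reference for BMI, weight and height, ages 2-20.

    A stand-in for national growth tables, built so that (a) BMI medians
    rise gently with age, (b) the right-skew of pediatric BMI is encoded by
    a negative Box-Cox power (L = -1.5, S = 0.13), which places ~99th-centile
    BMI near the values seen in severely obese clinic populations, and (c)
    height follows near-linear growth with a pubertal plateau (L = 1,
    S = 0.04).  It is NOT a published reference and must not be used for
    clinical classification.
    """
    ages = np.arange(age_min, age_max + 1e-9, step)
    rows = []
    for sex in (Sex.FEMALE, Sex.MALE):
        for age in ages:
            h_m = _height_median(sex, age)
            bmi_m = 15.3 + 0.38 * (age - 2.0) if sex is Sex.FEMALE else 15.1 + 0.37 * (age - 2.0)
            w_m = bmi_m * (h_m / 100.0) ** 2
            rows.append(("bmi", sex.value, age, -1.5, bmi_m, 0.13))
            rows.append(("height", sex.value, age, 1.0, h_m, 0.04))
            rows.append(("weight", sex.value, age, -1.0, w_m, 0.12))
    return LMSReference(
        pd.DataFrame(rows, columns=["measure", "sex", "age_years", "L", "M", "S"])
    )
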