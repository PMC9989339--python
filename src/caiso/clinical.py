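"""Reference-standard vascular-calcification calls from ABI and ba-PWV.

Two deterministic classifiers:

* peripheral artery disease (PAD, a proxy for intimal calcification):
  ankle-brachial index ABI ≤ 0.9 or ABI ≥ 1.3;
* arteriosclerosis (a proxy for medial artery calcification): brachial-ankle
  pulse wave velocity ba-PWV ≥ 1800 cm/s, or exceeding a sex-specific
  quadratic-in-age threshold (female: 0.16·age² − 4.40·age + 977.52 cm/s;
  male: 0.20·age² − 12.13·age + 1341.34 cm/s).

Missing inputs yield a missing call (NaN / None), never an imputed one.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

FEMALE = "female"
MALE = "male"

_PWV_QUAD = {
    FEMALE: (0.16, -4.40, 977.52),
    MALE: (0.20, -12.13, 1341.34),
}

#: absolute ba-PWV cutoff, cm/s
PWV_ABSOLUTE_CUTOFF = 1800.0

# closed set of clause labels recorded in every call
CLAUSE_ABI_LOW = "abi<=0.9"
CLAUSE_ABI_HIGH = "abi>=1.3"
CLAUSE_NONE = "none"
CLAUSE_PWV_ABS = "ba_pwv>=1800"
CLAUSE_PWV_QUAD = "ba_pwv>age_sex_threshold"


@dataclass(frozen=True)
class CalcificationCall:
    pad_present: bool | None
    arteriosclerosis_present: bool | None
    pwv_threshold_used: float
    rule_fired: str


def _norm_sex(sex: str) -> str:
    s = str(sex).strip().lower()
    if s in ("f", "female"):
        return FEMALE
    if s in ("m", "male"):
        return MALE
    raise DataError(f"unknown sex label {sex!r}")


def classify_pad(abi: float, two_sided: bool = True) -> tuple[bool, str]:
    """PAD call from the ankle-brachial index.

    The default is the two-sided definition (ABI ≤ 0.9 or ≥ 1.3).  The
    one-sided legacy mode (``two_sided=False``) counts only ABI ≤ 0.9,
    matching summary tables that tabulate "No PAD" as ABI > 0.9.
    """
    if not math.isfinite(abi) or abi <= 0:
        raise DataError(f"ABI must be positive and finite, got {abi}")
    if abi <= 0.9:
        return True, CLAUSE_ABI_LOW
    if two_sided and abi >= 1.3:
        return True, CLAUSE_ABI_HIGH
    return False, CLAUSE_NONE


def pwv_threshold(age: float, sex: str) -> float:
    """Sex-specific quadratic-in-age ba-PWV threshold, cm/s."""
    if not math.isfinite(age) or age < 18:
        raise DataError(f"age must be ≥18 years, got {age}")
    a, b, c = _PWV_QUAD[_norm_sex(sex)]
    return a * age * age + b * age + c


def classify_arteriosclerosis(ba_pwv: float, age: float, sex: str) -> tuple[bool, str, float]:
    """Medial-calcification call: ba-PWV ≥ 1800 cm/s or above the age/sex quadratic.

    Returns ``(present, clause, threshold_used)``; the quadratic clause is a
    strict inequality, the absolute cutoff is inclusive.
    """
    if not math.isfinite(ba_pwv) or ba_pwv <= 0:
        raise DataError(f"ba-PWV must be positive and finite, got {ba_pwv}")
    thr = pwv_threshold(age, sex)
    if ba_pwv >= PWV_ABSOLUTE_CUTOFF:
        return True, CLAUSE_PWV_ABS, thr
    if ba_pwv > thr:
        return True, CLAUSE_PWV_QUAD, thr
    return False, CLAUSE_NONE, thr


def classify_subject(
    abi: float | None,
    ba_pwv: float | None,
    age: float | None,
    sex: str | None,
    pad_two_sided: bool = True,
) -> CalcificationCall:
    """Joint call for one subject; missing inputs give missing components."""
    if abi is None or (isinstance(abi, float) and math.isnan(abi)):
        pad, pad_clause = None, "missing_abi"
    else:
        pad, pad_clause = classify_pad(float(abi), pad_two_sided)

    missing_pwv = ba_pwv is None or (isinstance(ba_pwv, float) and math.isnan(ba_pwv))
    missing_age = age is None or (isinstance(age, float) and math.isnan(age))
    missing_sex = sex is None or (isinstance(sex, float) and math.isnan(sex))
    if missing_pwv or missing_age or missing_sex:
        art, art_clause, thr = None, "missing_pwv", float("nan")
    else:
        art, art_clause, thr = classify_arteriosclerosis(float(ba_pwv), float(age), sex)
    rule = f"pad:{pad_clause};arteriosclerosis:{art_clause}"
    return CalcificationCall(
        pad_present=pad,
        arteriosclerosis_present=art,
        pwv_threshold_used=thr,
        rule_fired=rule,
    )


def classify_cohort(cohort: pd.DataFrame, pad_two_sided: bool = True) -> pd.DataFrame:
    """Append pad/arteriosclerosis calls to a cohort table.

    Operates on columns ``abi``, ``ba_pwv_cm_s``, ``age_years``, ``sex``;
    returns a copy with ``pad_present``, ``arteriosclerosis_present``,
    ``pwv_threshold_used`` and ``rule_fired`` columns.
    """
    out = cohort.copy()
    pads, arts, thrs, rules = [], [], [], []
    for _, row in cohort.iterrows():
        call = classify_subject(
            row.get("abi"),
            row.get("ba_pwv_cm_s"),
            row.get("age_years"),
            row.get("sex"),
            pad_two_sided=pad_two_sided,
        )
        pads.append(call.pad_present)
        arts.append(call.arteriosclerosis_present)
        thrs.append(call.pwv_threshold_used)
        rules.append(call.rule_fired)
    out["pad_present"] = np.array(pads, dtype=object)
    out["arteriosclerosis_present"] = np.array(arts, dtype=object)
    out["pwv_threshold_used"] = thrs
    out["rule_fired"] = rules
    return out
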