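"""RECIST 1.1 per-lobe response and CTCAE-style laboratory toxicity.

Because the trial compares the two liver lobes of the same patient, each
lobe's target lesions (up to three, each >= 30 mm at baseline) are treated
as an independent lesion set and classified by the sum of their longest
diameters:

* CR — all target lesions disappeared (sum 0);
* PD — sum grew >= 20% from the nadir AND by >= 5 mm absolute;
* PR — sum shrank >= 30% from baseline (unless PD);
* SD — otherwise.

Laboratory toxicity is graded against a configurable threshold table in the
style of CTCAE v5 and attributed to treatment only when the worst follow-up
grade exceeds the baseline grade (the baseline-delta rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GradingRule",
    "ToxicityEvent",
    "recist_classify",
    "classify_cohort_response",
    "grade_value",
    "attribute_toxicity",
    "toxicity_grade_table",
    "DEFAULT_GRADING_RULES",
]

CATEGORIES = ("CR", "PR", "SD", "PD")


def recist_classify(sum_baseline: float, sum_current: float, sum_nadir: float) -> str:
    """Classify one lesion-set measurement against baseline and nadir sums.

    PD takes precedence over PR; the nadir is the minimum of all prior sums
    including baseline.
    """
    if min(sum_baseline, sum_current, sum_nadir) < 0:
        raise ValueError("diameter sums must be non-negative")
    if sum_nadir > sum_baseline:
        raise ValueError("nadir cannot exceed the baseline sum")
    if sum_current == 0:
        return "CR"
    if sum_current >= 1.2 * sum_nadir and sum_current - sum_nadir >= 5.0:
        return "PD"
    if sum_current <= 0.7 * sum_baseline:
        return "PR"
    return "SD"


def _lobe_sums(diam: pd.DataFrame) -> pd.DataFrame:
    # a missed assessment (NaN) must propagate to the lobe sum, not read as 0
    return diam.groupby(["patient_id", "lobe"])[
        ["diameter_baseline", "diameter_3mo", "diameter_6mo"]
    ].agg(lambda s: s.sum(skipna=False))


def classify_cohort_response(
    diameters: pd.DataFrame, ia_lobes: Mapping[str, str]
) -> dict[str, pd.DataFrame]:
    """Per-lobe response tables (category x arm) at 3 and 6 months.

    ``diameters`` is the per-lesion table with columns patient_id, lobe,
    diameter_baseline, diameter_3mo, diameter_6mo (mm); NaN diameters mark a
    missed assessment and exclude the patient at that timepoint.  Columns are
    the arms (control, intra-arterial); these tables feed Fisher's exact
    test.
    """
    sums = _lobe_sums(diameters)
    tables = {}
    for timepoint, col in (("3mo", "diameter_3mo"), ("6mo", "diameter_6mo")):
        counts = {arm: dict.fromkeys(CATEGORIES, 0) for arm in ("control", "ia")}
        for patient_id, group in sums.groupby(level="patient_id"):
            # available-case per timepoint: a patient missing this
            # assessment (or a lobe) is excluded here but may count at the
            # other timepoint
            if len(group) != 2 or group[["diameter_baseline", col]].isna().any().any():
                continue
            for (_, lobe), row in group.iterrows():
                baseline = row["diameter_baseline"]
                prior = [baseline]
                if timepoint == "6mo" and not np.isnan(row["diameter_3mo"]):
                    prior.append(row["diameter_3mo"])
                category = recist_classify(baseline, row[col], min(prior))
                arm = "ia" if ia_lobes[patient_id] == lobe else "control"
                counts[arm][category] += 1
        table = pd.DataFrame(counts)
        tables[timepoint] = table[table.sum(axis=1) > 0]  # drop unobserved categories
    return tables


@dataclass(frozen=True)
class GradingRule:
    """Threshold table for one analyte.

    ``direction`` is "high" (toxicity = elevation, thresholds compared with
    >=) or "low" (toxicity = depression, compared with <=).  ``thresholds``
    lists the grade 1..4 bounds in analyte units; a shorter list means the
    higher grades are not defined for that analyte.
    """

    analyte: str
    direction: str
    thresholds: tuple[float, ...]
    unit: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("high", "low"):
            raise ValueError("direction must be 'high' or 'low'")
        if not 1 <= len(self.thresholds) <= 4:
            raise ValueError("1 to 4 grade thresholds required")
        diffs = np.diff(self.thresholds)
        if self.direction == "high" and np.any(diffs <= 0):
            raise ValueError("'high' thresholds must be strictly increasing")
        if self.direction == "low" and np.any(diffs >= 0):
            raise ValueError("'low' thresholds must be strictly decreasing")


def grade_value(value: float, rule: GradingRule) -> int:
    """Grade 0-4 of a laboratory value: the highest threshold crossed.

    Bounds are closed: a value exactly at a threshold receives that grade.
    """
    grade = 0
    for g, threshold in enumerate(rule.thresholds, start=1):
        crossed = value >= threshold if rule.direction == "high" else value <= threshold
        if crossed:
            grade = g
    return grade


@dataclass(frozen=True)
class ToxicityEvent:
    patient_id: str
    analyte: str
    baseline_grade: int
    worst_followup_grade: int

    @property
    def treatment_emergent(self) -> bool:
        return self.worst_followup_grade > self.baseline_grade

    def __post_init__(self) -> None:
        if not self.treatment_emergent:
            raise ValueError("toxicity events require worst follow-up grade > baseline grade")


def attribute_toxicity(
    baseline: Mapping[str, float] | pd.Series,
    followup: Mapping[str, Sequence[float]] | pd.DataFrame,
    rules: Mapping[str, GradingRule],
    patient_id: str = "",
) -> list[ToxicityEvent]:
    """Treatment-emergent toxicity per analyte under the baseline-delta rule.

    ``baseline`` maps analyte -> baseline value; ``followup`` maps analyte ->
    series of follow-up values.  An event is emitted only when the worst
    follow-up grade exceeds the baseline grade.
    """
    events = []
    for analyte, series in dict(followup).items():
        if analyte not in rules:
            raise ValueError(f"no grading rule for analyte {analyte!r}")
        if analyte not in dict(baseline):
            raise ValueError(f"no baseline value for analyte {analyte!r}")
        values = [v for v in np.atleast_1d(series) if np.isfinite(v)]
        if not values:
            raise ValueError(f"no follow-up observations for analyte {analyte!r}")
        rule = rules[analyte]
        base_grade = grade_value(float(dict(baseline)[analyte]), rule)
        worst = max(grade_value(float(v), rule) for v in values)
        if worst > base_grade:
            events.append(ToxicityEvent(patient_id, analyte, base_grade, worst))
    return events


def toxicity_grade_table(
    events: Iterable[ToxicityEvent], analytes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Patients per analyte at each worst treatment-emergent grade (1-4)."""
    order = list(analytes) if analytes is not None else sorted(ANALYTE_ORDER)
    table = pd.DataFrame(0, index=order, columns=[1, 2, 3, 4])
    for ev in events:
        if ev.analyte in table.index:
            table.loc[ev.analyte, ev.worst_followup_grade] += 1
    return table


# ---------------------------------------------------------------------------
# Default grading table.
#
# The thresholds below are an APPROXIMATE CTCAE-v5-style table for the
# analytes of a hepatic/haematological/renal safety panel, expressed in SI
# units.  Enzyme bounds are multiples of the upper limit of normal; counts
# are absolute.  Real analyses should load a site-verified table.

ANALYTE_ORDER = (
    "albumin", "alat", "asat", "ggt", "alp", "bilirubin",
    "hemoglobin", "mcv", "thrombocytes", "leukocytes", "neutrophils", "lymphocytes",
    "egfr", "creatinine", "urea",
)

_ULN = {"alat": 40.0, "asat": 40.0, "ggt": 60.0, "alp": 115.0, "bilirubin": 21.0,
        "creatinine": 110.0}

DEFAULT_GRADING_RULES: dict[str, GradingRule] = {
    "albumin": GradingRule("albumin", "low", (34.9, 29.9, 19.9), "g/L"),
    "alat": GradingRule("alat", "high",
                        tuple(m * _ULN["alat"] for m in (1.0, 3.0, 5.0, 20.0)), "U/L"),
    "asat": GradingRule("asat", "high",
                        tuple(m * _ULN["asat"] for m in (1.0, 3.0, 5.0, 20.0)), "U/L"),
    "ggt": GradingRule("ggt", "high",
                       tuple(m * _ULN["ggt"] for m in (1.0, 2.5, 5.0, 20.0)), "U/L"),
    "alp": GradingRule("alp", "high",
                       tuple(m * _ULN["alp"] for m in (1.0, 2.5, 5.0, 20.0)), "U/L"),
    "bilirubin": GradingRule("bilirubin", "high",
                             tuple(m * _ULN["bilirubin"] for m in (1.0, 1.5, 3.0, 10.0)),
                             "umol/L"),
    "hemoglobin": GradingRule("hemoglobin", "low", (119.9, 99.9, 79.9, 64.9), "g/L"),
    "mcv": GradingRule("mcv", "high", (100.1, 110.0, 120.0, 130.0), "fL"),
    "thrombocytes": GradingRule("thrombocytes", "low", (149.9, 74.9, 49.9, 24.9), "1e9/L"),
    "leukocytes": GradingRule("leukocytes", "low", (3.99, 2.99, 1.99, 0.99), "1e9/L"),
    "neutrophils": GradingRule("neutrophils", "low", (1.79, 1.49, 0.99, 0.49), "1e9/L"),
    "lymphocytes": GradingRule("lymphocytes", "low", (0.99, 0.79, 0.49, 0.19), "1e9/L"),
    "egfr": GradingRule("egfr", "low", (89.9, 59.9, 29.9, 14.9), "mL/min/1.73m2"),
    "creatinine": GradingRule("creatinine", "high",
                              tuple(m * _ULN["creatinine"] for m in (1.0, 1.5, 3.0, 6.0)),
                              "umol/L"),
    "urea": GradingRule("urea", "high", (8.1, 12.5, 17.0, 34.0), "mmol/L"),
}
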