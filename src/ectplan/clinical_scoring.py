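"""Deterministic clinical scoring rules of the feline cSCC trial.

Covers the WHO TNM-based staging of nasal-planum tumours (stage = T category
because all trial patients were N0M0), the modified RECIST response classes,
the five-level anorexia grading, the alternating-then-capped group
allocation, and body-surface-area bleomycin dosing.

Boundary conventions are fixed constants of this module:

* response cut-offs are inclusive (change <= -30% -> PR, change >= +20% ->
  PD), and any rounding happens after classification, never before;
* tumour size 2-5 cm (closed interval) is T2, strictly above 5 cm is T3;
* invasion depth dominates size when both criteria apply (deep invasion is
  sufficient for T4 regardless of diameter);
* anorexia grade intervals have closed lower bounds so that worsening an
  observation can never lower the grade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "Stage",
    "NodeStatus",
    "MetastasisStatus",
    "Response",
    "Group",
    "StagingInput",
    "LesionMeasurement",
    "AnorexiaObservation",
    "PatientRecord",
    "stage_who",
    "classify_response",
    "grade_anorexia",
    "allocate_group",
    "bleomycin_dose",
    "feline_bsa_m2",
    "records_to_dataframe",
    "dataframe_to_records",
    "write_cohort_csv",
    "read_cohort_csv",
]


class Stage(IntEnum):
    I = 1
    II = 2
    III = 3
    IV = 4


class NodeStatus(str, Enum):
    N0 = "N0"
    N1 = "N1"


class MetastasisStatus(str, Enum):
    M0 = "M0"
    M1 = "M1"


class Response(str, Enum):
    CR = "CR"  # complete response: eradication with re-epithelialization
    PR = "PR"  # partial response: >= 30% shrinkage of summed diameters
    SD = "SD"  # stable disease
    PD = "PD"  # progressive disease: >= 20% growth
    NE = "NE"  # not evaluable


class Group(str, Enum):
    STANDARD = "standard"
    THIN = "thin"


@dataclass(frozen=True)
class StagingInput:
    """Primary-tumour findings feeding the WHO T category."""

    tumor_size_cm: float
    in_situ: bool = False
    minimally_invasive: bool = False
    subcutis_invasion: bool = False
    deep_invasion: bool = False  # fascia, muscle or bone
    node_status: NodeStatus = NodeStatus.N0
    metastasis: MetastasisStatus = MetastasisStatus.M0

    def __post_init__(self) -> None:
        if self.tumor_size_cm < 0:
            raise ValueError("tumor size must be non-negative")
        if self.deep_invasion and self.in_situ:
            raise ValueError("in-situ tumour cannot show deep invasion")


def stage_who(inp: StagingInput) -> Stage:
    """WHO stage for feline cSCC; defined only for N0M0 disease.

    T1 (< 2 cm) -> I; T2 (2-5 cm or minimally invasive) -> II; T3 (> 5 cm or
    subcutis invasion) -> III; T4 (fascia/muscle/bone invasion) -> IV.
    Invasion depth takes precedence over diameter.
    """
    if inp.node_status is not NodeStatus.N0 or inp.metastasis is not MetastasisStatus.M0:
        raise ValueError(
            "stage mapping undefined for nodal/distant disease in this scheme"
        )
    if inp.in_situ:
        raise ValueError("no stage assigned to Tis (carcinoma in situ)")
    if inp.deep_invasion:
        return Stage.IV
    if inp.subcutis_invasion or inp.tumor_size_cm > 5.0:
        return Stage.III
    if inp.minimally_invasive or inp.tumor_size_cm >= 2.0:
        return Stage.II
    return Stage.I


@dataclass(frozen=True)
class LesionMeasurement:
    """Sum of lesion diameters at one visit."""

    time_days: float
    sum_diameters_mm: float
    eradicated_with_reepithelialization: bool = False

    def __post_init__(self) -> None:
        if self.sum_diameters_mm < 0:
            raise ValueError("sum of diameters must be non-negative")
        if self.eradicated_with_reepithelialization and self.sum_diameters_mm != 0:
            raise ValueError("an eradicated lesion has zero residual diameter")


#: Response cut-offs on the fractional change of summed diameters.
PR_CHANGE = -0.30
PD_CHANGE = +0.20


def classify_response(
    baseline: LesionMeasurement, best_followup: LesionMeasurement
) -> Response:
    """Modified RECIST class from baseline and best follow-up measurements."""
    if baseline.sum_diameters_mm <= 0:
        raise ValueError("baseline sum of diameters must be positive")
    if best_followup.eradicated_with_reepithelialization:
        return Response.CR
    change = (
        best_followup.sum_diameters_mm - baseline.sum_diameters_mm
    ) / baseline.sum_diameters_mm
    if change >= PD_CHANGE:
        return Response.PD
    if change <= PR_CHANGE:
        return Response.PR
    return Response.SD


@dataclass(frozen=True)
class AnorexiaObservation:
    """Post-treatment appetite course of one patient."""

    complete_anorexia_days: float = 0.0
    anorexia_days: float = 0.0
    weight_loss_fraction: float = 0.0
    feeding_support: bool = False  # IV fluids, tube feeding or force-feeding
    parenteral_nutrition: bool = False
    died: bool = False

    def __post_init__(self) -> None:
        if self.complete_anorexia_days < 0 or self.anorexia_days < 0:
            raise ValueError("durations must be non-negative")
        if self.complete_anorexia_days > self.anorexia_days:
            raise ValueError("complete anorexia cannot outlast anorexia")
        if not 0.0 <= self.weight_loss_fraction <= 1.0:
            raise ValueError("weight loss fraction must be in [0, 1]")


def grade_anorexia(obs: AnorexiaObservation) -> int:
    """Five-level anorexia grade, highest applicable criterion wins.

    5: death; 4: parenteral nutrition or complete anorexia > 5 days;
    3: anorexia >= 3 days with >= 10% weight loss or feeding support;
    2: complete anorexia >= 2 days; 1: anything milder (complete anorexia
    under 48 h).
    """
    if obs.died:
        return 5
    if obs.parenteral_nutrition or obs.complete_anorexia_days > 5.0:
        return 4
    if obs.anorexia_days >= 3.0 and (
        obs.weight_loss_fraction >= 0.10 or obs.feeding_support
    ):
        return 3
    if obs.complete_anorexia_days >= 2.0:
        return 2
    return 1


def allocate_group(enrollment_index: int, cap_standard: int = 15) -> Group:
    """Alternating allocation (standard first) until the standard arm is full.

    The trial alternated patients between the arms and, once the standard
    arm reached its cap, enrolled everyone else in the thin-needle arm.
    The cap is reached at enrollment index 2 x cap - 1; totals are invariant
    to which arm starts the alternation.
    """
    if enrollment_index < 1:
        raise ValueError("enrollment index is 1-based")
    if enrollment_index <= 2 * cap_standard:
        return Group.STANDARD if enrollment_index % 2 == 1 else Group.THIN
    return Group.THIN


#: Bleomycin dose per square metre of body surface (IU/m^2).
BLEOMYCIN_IU_PER_M2 = 15_000.0
#: Feline body-surface-area constant: BSA[m^2] = K * (weight[g])^(2/3) * 1e-4.
FELINE_BSA_K = 10.1


def feline_bsa_m2(weight_kg: float) -> float:
    """Feline body surface area (m^2) from the standard allometric formula."""
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    return FELINE_BSA_K * (weight_kg * 1000.0) ** (2.0 / 3.0) * 1e-4


def bleomycin_dose(weight_kg: float) -> int:
    """Intravenous bleomycin dose (IU) at 15,000 IU/m^2, rounded to 1 IU."""
    return round(BLEOMYCIN_IU_PER_M2 * feline_bsa_m2(weight_kg))


# ---------------------------------------------------------------------------
# patient records and the cohort CSV schema


@dataclass
class PatientRecord:
    """One cat of the (real or synthetic) cohort."""

    id: str
    group: Group
    sex: str  # "M" / "F"
    age_years: float
    weight_kg: float
    fiv_positive: bool
    stage: Stage
    baseline: LesionMeasurement
    best_followup: Optional[LesionMeasurement]
    response: Response
    anorexia_grade: int
    n_sessions: int
    survival_days: float
    event_observed: bool

    def __post_init__(self) -> None:
        if self.survival_days <= 0:
            raise ValueError("survival time must be positive")
        if not 1 <= self.anorexia_grade <= 5:
            raise ValueError("anorexia grade must be 1..5")
        if self.n_sessions < 1:
            raise ValueError("at least one treatment session")
        if self.best_followup is not None and self.response is not Response.NE:
            expected = classify_response(self.baseline, self.best_followup)
            if expected is not self.response:
                raise ValueError(
                    f"response {self.response.value} inconsistent with measurements "
                    f"(classifier says {expected.value})"
                )


COHORT_COLUMNS = [
    "id",
    "group",
    "sex",
    "age_years",
    "weight_kg",
    "fiv_positive",
    "stage",
    "baseline_sum_diameters_mm",
    "best_followup_sum_diameters_mm",
    "eradicated",
    "response",
    "anorexia_grade",
    "n_sessions",
    "survival_days",
    "event_observed",
]


def records_to_dataframe(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "group": r.group.value,
                "sex": r.sex,
                "age_years": round(r.age_years, 1),
                "weight_kg": round(r.weight_kg, 2),
                "fiv_positive": int(r.fiv_positive),
                "stage": int(r.stage),
                "baseline_sum_diameters_mm": round(r.baseline.sum_diameters_mm, 1),
                "best_followup_sum_diameters_mm": (
                    round(r.best_followup.sum_diameters_mm, 1)
                    if r.best_followup is not None
                    else ""
                ),
                "eradicated": (
                    int(r.best_followup.eradicated_with_reepithelialization)
                    if r.best_followup is not None
                    else 0
                ),
                "response": r.response.value,
                "anorexia_grade": int(r.anorexia_grade),
                "n_sessions": int(r.n_sessions),
                "survival_days": round(r.survival_days, 1),
                "event_observed": int(r.event_observed),
            }
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def dataframe_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        followup_raw = row["best_followup_sum_diameters_mm"]
        has_followup = not (
            followup_raw is None
            or (isinstance(followup_raw, str) and followup_raw == "")
            or (isinstance(followup_raw, float) and math.isnan(followup_raw))
        )
        best = (
            LesionMeasurement(
                time_days=0.0,
                sum_diameters_mm=float(followup_raw),
                eradicated_with_reepithelialization=bool(int(row["eradicated"])),
            )
            if has_followup
            else None
        )
        records.append(
            PatientRecord(
                id=str(row["id"]),
                group=Group(row["group"]),
                sex=str(row["sex"]),
                age_years=float(row["age_years"]),
                weight_kg=float(row["weight_kg"]),
                fiv_positive=bool(int(row["fiv_positive"])),
                stage=Stage(int(row["stage"])),
                baseline=LesionMeasurement(0.0, float(row["baseline_sum_diameters_mm"])),
                best_followup=best,
                response=Response(row["response"]),
                anorexia_grade=int(row["anorexia_grade"]),
                n_sessions=int(row["n_sessions"]),
                survival_days=float(row["survival_days"]),
                event_observed=bool(int(row["event_observed"])),
            )
        )
    return records


def write_cohort_csv(records: Sequence[PatientRecord], path) -> None:
    records_to_dataframe(records).to_csv(path, index=False, lineterminator="\n")


def read_cohort_csv(path) -> list[PatientRecord]:
    df = pd.read_csv(path, dtype={"best_followup_sum_diameters_mm": "object"})
    return dataframe_to_records(df)
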