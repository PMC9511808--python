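import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ectplan import (
    Group,
    LesionMeasurement,
    Response,
    Stage,
    StagingInput,
    allocate_group,
    bleomycin_dose,
    classify_response,
    grade_anorexia,
    read_cohort_csv,
    stage_who,
    write_cohort_csv,
)
from ectplan.clinical_scoring import (
    AnorexiaObservation,
    MetastasisStatus,
    NodeStatus,
    feline_bsa_m2,
)
from ectplan.synthetic_cohort import generate_cohort


# --- staging -----------------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs,expected",
    [
        (dict(tumor_size_cm=1.5), Stage.I),
        (dict(tumor_size_cm=1.99), Stage.I),
        (dict(tumor_size_cm=2.0), Stage.II),
        (dict(tumor_size_cm=3.0), Stage.II),
        (dict(tumor_size_cm=5.0), Stage.II),
        (dict(tumor_size_cm=1.0, minimally_invasive=True), Stage.II),
        (dict(tumor_size_cm=5.1), Stage.III),
        (dict(tumor_size_cm=1.0, subcutis_invasion=True), Stage.III),
        (dict(tumor_size_cm=1.0, deep_invasion=True), Stage.IV),
        (dict(tumor_size_cm=6.0, deep_invasion=True), Stage.IV),
    ],
)
def test_who_stage_from_t_category(kwargs, expected):
    assert stage_who(StagingInput(**kwargs)) is expected


def test_stage_undefined_for_nodal_or_distant_disease():
    with pytest.raises(ValueError, match="undefined for nodal/distant"):
        stage_who(StagingInput(1.0, node_status=NodeStatus.N1))
    with pytest.raises(ValueError, match="undefined for nodal/distant"):
        stage_who(StagingInput(1.0, metastasis=MetastasisStatus.M1))


def test_no_stage_for_carcinoma_in_situ():
    with pytest.raises(ValueError, match="Tis"):
        stage_who(StagingInput(0.5, in_situ=True))


# --- response ----------------------------------------------------------------


@pytest.mark.parametrize(
    "baseline,followup,expected",
    [
        (20.0, 12.0, Response.PR),  # -40%
        (20.0, 14.0, Response.PR),  # exactly -30%: inclusive
        (20.0, 14.1, Response.SD),
        (20.0, 20.0, Response.SD),
        (20.0, 23.9, Response.SD),
        (20.0, 24.0, Response.PD),  # exactly +20%: inclusive
        (20.0, 25.0, Response.PD),
    ],
)
def test_response_boundaries(baseline, followup, expected):
    assert (
        classify_response(
            LesionMeasurement(0.0, baseline), LesionMeasurement(30.0, followup)
        )
        is expected
    )


def test_eradication_with_reepithelialization_is_cr():
    cr = LesionMeasurement(60.0, 0.0, eradicated_with_reepithelialization=True)
    assert classify_response(LesionMeasurement(0.0, 20.0), cr) is Response.CR


def test_zero_baseline_rejected():
    with pytest.raises(ValueError):
        classify_response(LesionMeasurement(0.0, 0.0), LesionMeasurement(30.0, 5.0))


# --- anorexia ----------------------------------------------------------------


@pytest.mark.parametrize(
    "obs,grade",
    [
        (AnorexiaObservation(1.5, 1.5), 1),
        (AnorexiaObservation(2.0, 2.0), 2),
        (AnorexiaObservation(2.5, 2.5), 2),
        (AnorexiaObservation(0.0, 4.0, feeding_support=True), 3),
        (AnorexiaObservation(0.0, 4.0, weight_loss_fraction=0.12), 3),
        (AnorexiaObservation(6.0, 6.0), 4),
        (AnorexiaObservation(0.0, 1.0, parenteral_nutrition=True), 4),
        (AnorexiaObservation(died=True), 5),
    ],
)
def test_anorexia_grades(obs, grade):
    assert grade_anorexia(obs) == grade


def test_inconsistent_anorexia_observation_rejected():
    with pytest.raises(ValueError):
        AnorexiaObservation(complete_anorexia_days=4.0, anorexia_days=2.0)


@st.composite
def observations(draw):
    complete = draw(st.floats(0.0, 10.0))
    extra = draw(st.floats(0.0, 10.0))
    return AnorexiaObservation(
        complete_anorexia_days=complete,
        anorexia_days=complete + extra,
        weight_loss_fraction=draw(st.floats(0.0, 0.5)),
        feeding_support=draw(st.booleans()),
        parenteral_nutrition=draw(st.booleans()),
        died=draw(st.booleans()),
    )


@settings(max_examples=200, deadline=None, derandomize=True)
@given(obs=observations(), bump_days=st.floats(0.0, 5.0))
def test_worsening_never_lowers_anorexia_grade(obs, bump_days):
    worse = AnorexiaObservation(
        complete_anorexia_days=obs.complete_anorexia_days + bump_days,
        anorexia_days=obs.anorexia_days + bump_days,
        weight_loss_fraction=min(1.0, obs.weight_loss_fraction + 0.05),
        feeding_support=True,
        parenteral_nutrition=obs.parenteral_nutrition,
        died=obs.died,
    )
    assert grade_anorexia(worse) >= grade_anorexia(obs)


# --- allocation and dosing ---------------------------------------------------


def test_alternating_allocation_totals():
    groups = [allocate_group(i) for i in range(1, 53)]
    assert sum(g is Group.STANDARD for g in groups) == 15
    assert sum(g is Group.THIN for g in groups) == 37
    assert groups[0] is Group.STANDARD and groups[1] is Group.THIN
    assert all(g is Group.THIN for g in groups[30:])


def test_allocation_index_is_one_based():
    with pytest.raises(ValueError):
        allocate_group(0)


def test_bleomycin_dose_for_average_cat():
    # 4 kg cat: BSA = 10.1 * 4000^(2/3) * 1e-4 = 0.2545 m^2 -> 3818 IU
    assert feline_bsa_m2(4.0) == pytest.approx(0.25450, abs=5e-5)
    assert bleomycin_dose(4.0) == 3818


def test_bleomycin_dose_strictly_increasing():
    weights = [2.0, 3.0, 4.0, 5.5, 7.0]
    doses = [bleomycin_dose(w) for w in weights]
    assert doses == sorted(doses) and len(set(doses)) == len(doses)


def test_bleomycin_rejects_nonpositive_weight():
    with pytest.raises(ValueError):
        bleomycin_dose(0.0)


# --- cohort CSV schema -------------------------------------------------------


def test_cohort_csv_round_trip(tmp_path):
    records = generate_cohort(seed=3)
    path = tmp_path / "cohort.csv"
    write_cohort_csv(records, path)
    back = read_cohort_csv(path)
    assert len(back) == len(records)
    for a, b in zip(records, back):
        assert (a.id, a.group, a.stage, a.response, a.anorexia_grade) == (
            b.id,
            b.group,
            b.stage,
            b.response,
            b.anorexia_grade,
        )
        assert b.survival_days == pytest.approx(a.survival_days, abs=0.05)
        assert a.event_observed == b.event_observed


def test_cohort_csv_missing_column_rejected(tmp_path):
    import pandas as pd

    records = generate_cohort(seed=3)
    path = tmp_path / "cohort.csv"
    write_cohort_csv(records, path)
    df = pd.read_csv(path).drop(columns=["response"])
    bad = tmp_path / "bad.csv"
    df.to_csv(bad, index=False)
    with pytest.raises(ValueError, match="missing columns"):
        read_cohort_csv(bad)
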