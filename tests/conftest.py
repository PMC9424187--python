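import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from healthspan.panel_data import (
    ActivityResponse,
    EventRecord,
    EventKind,
    Frequency,
    PanelDataset,
    ParticipantRecord,
    Sex,
    State,
    WaveObservation,
)
from healthspan.transition_model import ABSENT, TransitionParams

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

#: fixed seed convention for every stochastic test (study baseline date)
SEED = 20061201


def activities(v=Frequency.none, h=Frequency.none, n=Frequency.none):
    return (
        ActivityResponse("volunteering", v),
        ActivityResponse("hobby", h),
        ActivityResponse("neighborhood", n),
    )


def participant(pid="p1", sex=Sex.male, age=70.0, acts=None, **kw) -> ParticipantRecord:
    return ParticipantRecord(
        id=pid, sex=sex, baseline_age=age, activities=acts or activities(), **kw
    )


@pytest.fixture
def tiny_dataset() -> PanelDataset:
    """Three participants: one survivor, one death, one emigration."""
    parts = [
        participant("a", Sex.male, 70.0, activities(Frequency.weekly_plus)),
        participant("b", Sex.female, 75.0),
        participant("c", Sex.male, 68.0, activities(h=Frequency.lt_monthly)),
    ]
    waves = [
        WaveObservation("a", 0, State.nondisabled),
        WaveObservation("a", 12, State.nondisabled),
        WaveObservation("a", 24, State.disabled),
        WaveObservation("b", 0, State.nondisabled),
        WaveObservation("b", 12, State.nondisabled),
        WaveObservation("c", 0, State.nondisabled),
    ]
    events = [
        EventRecord("a", EventKind.disability_cert, 20),
        EventRecord("b", EventKind.death, 18),
        EventRecord("c", EventKind.emigration, 10),
    ]
    return PanelDataset.from_records(parts, waves, events)


@pytest.fixture
def moderate_params() -> TransitionParams:
    """Plausible illness-death parameters with recovery (per-month logits)."""
    return TransitionParams(
        a_nd_dis=-13.5, b_nd_dis=0.10,
        a_nd_dead=-13.6, b_nd_dead=0.10,
        a_dis_nd=-1.9, b_dis_nd=-0.02,
        a_dis_dead=-11.2, b_dis_dead=0.09,
    )


@pytest.fixture
def no_transition_params() -> TransitionParams:
    return TransitionParams(ABSENT, 0.0, ABSENT, 0.0, ABSENT, 0.0, ABSENT, 0.0)


def pair_dataset(s0: State, s1: State, gap: int, age: float = 70.0) -> PanelDataset:
    """One participant observed in s0 at month 0 and s1 at month ``gap``."""
    return PanelDataset.from_records(
        [participant("x", Sex.male, age)],
        [WaveObservation("x", 0, s0), WaveObservation("x", gap, s1)],
    )


def death_dataset(s0: State, death_month: int, age: float = 70.0) -> PanelDataset:
    """One participant observed in s0 at month 0, dying at ``death_month``."""
    return PanelDataset.from_records(
        [participant("x", Sex.male, age)],
        [WaveObservation("x", 0, s0)],
        [EventRecord("x", EventKind.death, death_month)],
    )
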