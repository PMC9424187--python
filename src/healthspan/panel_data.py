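"""Panel-data containers, CSV I/O, deterministic coding rules and the exclusion cascade.

The study design this module serves: a cohort of community-dwelling adults
aged >= 65 answers a baseline questionnaire (social-activity frequencies,
smoking, BMI, walking time, a five-item depression screen, disease history)
and is then followed through a care-needs registry.  Observed follow-up data
are annual wave states (non-disabled / disabled, where "disabled" means
certified at care level 2 or higher), plus month-dated death, first
disability certification, and emigration events.

Everything here is deterministic bookkeeping: typed records, CSV round-trip,
the exposure / depression / risk-count coding rules, the ordered exclusion
cascade with exact accounting, and the descriptive baseline / outcome tables.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Sex",
    "Frequency",
    "Smoking",
    "Walking",
    "State",
    "EventKind",
    "NcdStratum",
    "ActivityResponse",
    "ParticipantRecord",
    "WaveObservation",
    "EventRecord",
    "PanelDataset",
    "ExclusionAccounting",
    "CodingError",
    "PanelValidationError",
    "code_social_participation",
    "code_depression",
    "code_ncd_risk",
    "social_participation_counts",
    "depression_flags",
    "ncd_strata",
    "apply_exclusion_cascade",
    "read_panel_csv",
    "write_panel_csv",
    "outcome_distribution_table",
    "baseline_characteristics_table",
    "FOLLOWUP_MONTHS",
]

#: Total scheduled follow-up, in months (11 annual observation years).
FOLLOWUP_MONTHS = 132


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class Frequency(str, enum.Enum):
    """Response options for each community-activity item."""

    none = "none"
    lt_monthly = "lt_monthly"
    one_to_three_monthly = "1_3_monthly"
    weekly_plus = "weekly_plus"


class Smoking(str, enum.Enum):
    never_former = "never_former"
    current = "current"


class Walking(str, enum.Enum):
    ge_half_hour = "ge_half_hour"
    lt_half_hour = "lt_half_hour"


class State(str, enum.Enum):
    """Living states of the illness-death model; CSV codes 'nd' / 'dis'."""

    nondisabled = "nd"
    disabled = "dis"


class EventKind(str, enum.Enum):
    disability_cert = "disability_cert"
    death = "death"
    emigration = "emigration"


class NcdStratum(str, enum.Enum):
    zero = "zero"
    one = "one"
    two_or_three = "two_or_three"


ACTIVITY_CATEGORIES = ("volunteering", "hobby", "neighborhood")

#: participants.csv column order (also the canonical in-memory order).
PARTICIPANT_COLUMNS = [
    "id",
    "sex",
    "age",
    "vol_freq",
    "hobby_freq",
    "neigh_freq",
    "smoking",
    "bmi",
    "walking",
    "dss1",
    "dss2",
    "dss3",
    "dss4",
    "dss5",
    "hx_htn",
    "hx_dm",
    "hx_stroke",
    "hx_mi",
    "hx_cancer",
    "consent",
    "prevalent_disability",
    "pre_baseline_exit",
]
WAVE_COLUMNS = ["id", "t_months", "state"]
EVENT_COLUMNS = ["id", "kind", "t_months"]

_FREQ_VALUES = {f.value for f in Frequency}
_DSS_VALUES = {"yes", "no"}


class CodingError(ValueError):
    """A deterministic coding rule received a missing or invalid input."""


class PanelValidationError(ValueError):
    """A dataset violates the panel schema or its ordering invariants."""


@dataclass(frozen=True)
class ActivityResponse:
    category: str
    frequency: Frequency | None  # None encodes an explicit missing marker

    def __post_init__(self) -> None:
        if self.category not in ACTIVITY_CATEGORIES:
            raise ValueError(f"unknown activity category {self.category!r}")


@dataclass
class ParticipantRecord:
    """Baseline covariates and administrative flags for one subject.

    ``None`` in any questionnaire field is an explicit missing marker and is
    never silently coerced to a substantive category.
    """

    id: str
    sex: Sex
    baseline_age: float
    activities: tuple[ActivityResponse, ActivityResponse, ActivityResponse]
    smoking: Smoking | None = None
    bmi: float | None = None
    walking: Walking | None = None
    dss_items: tuple[str | None, str | None, str | None, str | None, str | None] = (
        None,
        None,
        None,
        None,
        None,
    )
    disease_history: Mapping[str, bool] = field(
        default_factory=lambda: dict.fromkeys(
            ("hypertension", "diabetes", "stroke", "mi", "cancer"), False
        )
    )
    consent: bool = True
    prevalent_disability: bool = False
    dead_or_moved_pre_baseline: bool = False

    def __post_init__(self) -> None:
        if self.baseline_age < 65:
            raise ValueError(f"participant {self.id}: baseline age {self.baseline_age} < 65")
        if self.bmi is not None and not (10 < self.bmi < 60):
            raise ValueError(f"participant {self.id}: BMI {self.bmi} outside (10, 60)")


@dataclass(frozen=True)
class WaveObservation:
    id: str
    t: int
    state: State


@dataclass(frozen=True)
class EventRecord:
    id: str
    kind: EventKind
    t: int


@dataclass
class ExclusionAccounting:
    """Ordered removal counts for the fixed exclusion cascade."""

    n_initial: int
    steps: list[tuple[str, int]]
    n_final: int

    def __post_init__(self) -> None:
        removed = sum(n for _, n in self.steps)
        if self.n_final != self.n_initial - removed:
            raise ValueError("exclusion accounting does not balance")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["rule", "n_removed"])


class PanelDataset:
    """Participants + annual wave observations + dated terminal events.

    Backed by three pandas DataFrames with fixed schemas (see
    ``PARTICIPANT_COLUMNS`` etc.); row order is canonicalised (participants by
    id, waves/events by id then month) so equality is well defined and the
    CSV round trip is the identity.
    """

    def __init__(
        self,
        participants: pd.DataFrame,
        waves: pd.DataFrame | None = None,
        events: pd.DataFrame | None = None,
        provenance: Sequence[str] = (),
        validate: bool = True,
    ) -> None:
        self.participants = _canon_participants(participants)
        self.waves = _canon_waves(waves)
        self.events = _canon_events(events)
        self.provenance: list[str] = list(provenance)
        if validate:
            self.validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(
        cls,
        participants: Iterable[ParticipantRecord],
        waves: Iterable[WaveObservation] = (),
        events: Iterable[EventRecord] = (),
        provenance: Sequence[str] = (),
    ) -> "PanelDataset":
        prows = []
        for p in participants:
            freq = {a.category: (a.frequency.value if a.frequency else pd.NA) for a in p.activities}
            prows.append(
                {
                    "id": p.id,
                    "sex": p.sex.value,
                    "age": p.baseline_age,
                    "vol_freq": freq.get("volunteering", pd.NA),
                    "hobby_freq": freq.get("hobby", pd.NA),
                    "neigh_freq": freq.get("neighborhood", pd.NA),
                    "smoking": p.smoking.value if p.smoking else pd.NA,
                    "bmi": p.bmi if p.bmi is not None else np.nan,
                    "walking": p.walking.value if p.walking else pd.NA,
                    **{f"dss{i + 1}": (v if v is not None else pd.NA) for i, v in enumerate(p.dss_items)},
                    "hx_htn": bool(p.disease_history.get("hypertension", False)),
                    "hx_dm": bool(p.disease_history.get("diabetes", False)),
                    "hx_stroke": bool(p.disease_history.get("stroke", False)),
                    "hx_mi": bool(p.disease_history.get("mi", False)),
                    "hx_cancer": bool(p.disease_history.get("cancer", False)),
                    "consent": bool(p.consent),
                    "prevalent_disability": bool(p.prevalent_disability),
                    "pre_baseline_exit": bool(p.dead_or_moved_pre_baseline),
                }
            )
        pdf = pd.DataFrame(prows, columns=PARTICIPANT_COLUMNS)
        wdf = pd.DataFrame(
            [{"id": w.id, "t_months": w.t, "state": w.state.value} for w in waves],
            columns=WAVE_COLUMNS,
        )
        edf = pd.DataFrame(
            [{"id": e.id, "kind": e.kind.value, "t_months": e.t} for e in events],
            columns=EVENT_COLUMNS,
        )
        return cls(pdf, wdf, edf, provenance=provenance)

    # -- basic protocol ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.participants)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PanelDataset):
            return NotImplemented
        return (
            self.participants.equals(other.participants)
            and self.waves.equals(other.waves)
            and self.events.equals(other.events)
        )

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def subset(self, ids: Iterable[str], note: str | None = None) -> "PanelDataset":
        keep = set(ids)
        out = PanelDataset(
            self.participants[self.participants["id"].isin(keep)],
            self.waves[self.waves["id"].isin(keep)],
            self.events[self.events["id"].isin(keep)],
            provenance=self.provenance,
            validate=False,
        )
        if note:
            out.log(note)
        return out

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        p, w, e = self.participants, self.waves, self.events
        if p["id"].duplicated().any():
            dup = p.loc[p["id"].duplicated(), "id"].iloc[0]
            raise PanelValidationError(f"duplicate participant id {dup!r}")
        known = set(p["id"])
        for name, df in (("waves", w), ("events", e)):
            orphan = ~df["id"].isin(known)
            if orphan.any():
                raise PanelValidationError(
                    f"{name}: id {df.loc[orphan, 'id'].iloc[0]!r} not in participants"
                )
        bad_t = (w["t_months"] < 0) | (w["t_months"] > FOLLOWUP_MONTHS)
        if bad_t.any():
            row = w[bad_t].iloc[0]
            raise PanelValidationError(
                f"wave for id {row['id']!r}: t_months={row['t_months']} outside [0, {FOLLOWUP_MONTHS}]"
            )
        if w.duplicated(subset=["id", "t_months"]).any():
            raise PanelValidationError("duplicate (id, t_months) wave observation")
        for kind in (EventKind.death, EventKind.emigration):
            sub = e[e["kind"] == kind.value]
            if sub["id"].duplicated().any():
                raise PanelValidationError(f"more than one {kind.value} event for an id")
        # no wave at or after the death month
        deaths = e.loc[e["kind"] == EventKind.death.value, ["id", "t_months"]]
        if len(deaths) and len(w):
            merged = w.merge(deaths.rename(columns={"t_months": "death_t"}), on="id")
            late = merged["t_months"] >= merged["death_t"]
            if late.any():
                row = merged[late].iloc[0]
                raise PanelValidationError(
                    f"id {row['id']!r}: wave at t={row['t_months']} on/after death at t={row['death_t']}"
                )


def _canon_participants(df: pd.DataFrame) -> pd.DataFrame:
    if df is None or len(df) == 0:
        df = pd.DataFrame(columns=PARTICIPANT_COLUMNS)
    missing = [c for c in PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise PanelValidationError(f"participants missing columns: {missing}")
    out = df[PARTICIPANT_COLUMNS].copy()
    out["id"] = out["id"].astype(str)
    out["age"] = out["age"].astype(float)
    out["bmi"] = pd.to_numeric(out["bmi"], errors="coerce").astype(float)
    for c in ("hx_htn", "hx_dm", "hx_stroke", "hx_mi", "hx_cancer", "consent",
              "prevalent_disability", "pre_baseline_exit"):
        out[c] = out[c].astype(bool)
    for c in ("sex", "vol_freq", "hobby_freq", "neigh_freq", "smoking", "walking",
              "dss1", "dss2", "dss3", "dss4", "dss5"):
        out[c] = out[c].astype("string")
        out.loc[out[c].isin(["", "missing"]), c] = pd.NA
    return out.sort_values("id", kind="stable").reset_index(drop=True)


def _canon_waves(df: pd.DataFrame | None) -> pd.DataFrame:
    if df is None or len(df) == 0:
        df = pd.DataFrame(columns=WAVE_COLUMNS)
    out = df[WAVE_COLUMNS].copy()
    out["id"] = out["id"].astype(str)
    out["t_months"] = out["t_months"].astype(int)
    out["state"] = out["state"].astype("string")
    bad = ~out["state"].isin([s.value for s in State])
    if bad.any():
        raise PanelValidationError(f"invalid wave state {out.loc[bad, 'state'].iloc[0]!r}")
    return out.sort_values(["id", "t_months"], kind="stable").reset_index(drop=True)


def _canon_events(df: pd.DataFrame | None) -> pd.DataFrame:
    if df is None or len(df) == 0:
        df = pd.DataFrame(columns=EVENT_COLUMNS)
    out = df[EVENT_COLUMNS].copy()
    out["id"] = out["id"].astype(str)
    out["kind"] = out["kind"].astype("string")
    out["t_months"] = out["t_months"].astype(int)
    bad = ~out["kind"].isin([k.value for k in EventKind])
    if bad.any():
        raise PanelValidationError(f"invalid event kind {out.loc[bad, 'kind'].iloc[0]!r}")
    return out.sort_values(["id", "kind", "t_months"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Coding rules
# ---------------------------------------------------------------------------

def code_social_participation(activities: Sequence[ActivityResponse]) -> int:
    """Number of community-activity categories engaged in (0-3).

    A category counts whenever its frequency is anything other than
    "do not participate" -- participating even less than once a month counts.
    Any missing frequency is a coding error; the caller is expected to treat
    such participants as having unavailable exposure information.
    """
    if len(activities) != 3:
        raise CodingError("expected exactly three activity responses")
    count = 0
    for a in activities:
        if a.frequency is None:
            raise CodingError(f"missing frequency for activity {a.category!r}")
        if a.frequency is not Frequency.none:
            count += 1
    return count


#: Score direction per depression-screen item: items 1, 2 and 4 score 1 for
#: "yes"; items 3 and 5 score 1 for "no".  Implemented exactly as the screen
#: is printed (see docs for discussion of the direction of items 1/2/4).
_DSS_YES_SCORES = (1, 1, 0, 1, 0)


def code_depression(dss_items: Sequence[str]) -> tuple[int, bool]:
    """Five-item depression-screen score (0-5) and the score >= 2 flag."""
    if len(dss_items) != 5:
        raise CodingError("expected exactly five screen items")
    score = 0
    for i, (item, yes_score) in enumerate(zip(dss_items, _DSS_YES_SCORES), start=1):
        if item not in _DSS_VALUES:
            raise CodingError(f"screen item {i} is missing or invalid: {item!r}")
        answered_yes = item == "yes"
        score += yes_score if answered_yes else 1 - yes_score
    return score, score >= 2


def code_ncd_risk(
    smoking: Smoking | None, bmi: float | None, walking: Walking | None
) -> tuple[int, NcdStratum]:
    """Count of non-communicable-disease risk factors and its 3-level stratum.

    Risks: current smoking; BMI < 18.5 or >= 25.0 kg/m2 (boundaries exactly as
    stated: 18.5 itself is not a risk, 25.0 is); walking < 0.5 h/day.
    """
    if smoking is None or bmi is None or walking is None or np.isnan(bmi):
        raise CodingError("smoking, BMI and walking must all be non-missing")
    count = int(smoking is Smoking.current)
    count += int(bmi < 18.5 or bmi >= 25.0)
    count += int(walking is Walking.lt_half_hour)
    stratum = (NcdStratum.zero, NcdStratum.one, NcdStratum.two_or_three, NcdStratum.two_or_three)[count]
    return count, stratum


# -- vectorised coding over a participants frame (missing -> <NA>) ----------

def social_participation_counts(participants: pd.DataFrame) -> pd.Series:
    """Per-participant activity count (Int64, <NA> when any item missing)."""
    freq = participants[["vol_freq", "hobby_freq", "neigh_freq"]]
    any_missing = freq.isna().any(axis=1)
    counts = (freq != Frequency.none.value).sum(axis=1).astype("Int64")
    counts[any_missing] = pd.NA
    return pd.Series(counts.to_numpy(), index=participants["id"].to_numpy(), name="n_activities")


def depression_flags(participants: pd.DataFrame) -> pd.Series:
    """Per-participant depression flag (boolean, <NA> when any item missing)."""
    items = participants[[f"dss{i}" for i in range(1, 6)]]
    any_missing = items.isna().any(axis=1)
    score = sum(
        (items[f"dss{i}"] == ("yes" if d else "no")).fillna(False).astype(int)
        for i, d in zip(range(1, 6), _DSS_YES_SCORES)
    )
    flag = (score >= 2).astype("boolean")
    flag[any_missing] = pd.NA
    return pd.Series(flag.to_numpy(), index=participants["id"].to_numpy(), name="depressed")


def ncd_strata(participants: pd.DataFrame) -> pd.Series:
    """Per-participant risk stratum label (string, <NA> when inputs missing)."""
    p = participants
    missing = p["smoking"].isna() | p["bmi"].isna() | p["walking"].isna()
    count = (
        (p["smoking"] == Smoking.current.value).astype(int)
        + ((p["bmi"] < 18.5) | (p["bmi"] >= 25.0)).astype(int)
        + (p["walking"] == Walking.lt_half_hour.value).astype(int)
    )
    labels = count.map(
        {0: NcdStratum.zero.value, 1: NcdStratum.one.value,
         2: NcdStratum.two_or_three.value, 3: NcdStratum.two_or_three.value}
    ).astype("string")
    labels[missing] = pd.NA
    return pd.Series(labels.to_numpy(), index=p["id"].to_numpy(), name="ncd_stratum")


# ---------------------------------------------------------------------------
# Exclusion cascade
# ---------------------------------------------------------------------------

def apply_exclusion_cascade(raw: PanelDataset) -> tuple[PanelDataset, ExclusionAccounting]:
    """Apply the four baseline exclusions, in their fixed order, with accounting.

    Order: (1) no consent to care-registry review; (2) disability certified
    before follow-up start; (3) died or moved away before follow-up start;
    (4) social-participation information unavailable.  The cascade is
    sequential: each rule's count refers to participants surviving all
    earlier rules.
    """
    p = raw.participants
    n_initial = len(p)
    steps: list[tuple[str, int]] = []
    alive = p

    rules: list[tuple[str, Callable[[pd.DataFrame], pd.Series]]] = [
        ("no_consent", lambda d: ~d["consent"]),
        ("prevalent_disability", lambda d: d["prevalent_disability"]),
        ("pre_baseline_death_or_move", lambda d: d["pre_baseline_exit"]),
        (
            "missing_social_participation",
            lambda d: d[["vol_freq", "hobby_freq", "neigh_freq"]].isna().any(axis=1),
        ),
    ]
    for name, rule in rules:
        mask = rule(alive).astype(bool)
        steps.append((name, int(mask.sum())))
        alive = alive[~mask]

    accounting = ExclusionAccounting(n_initial=n_initial, steps=steps, n_final=len(alive))
    out = raw.subset(
        alive["id"],
        note="exclusion cascade: "
        + ", ".join(f"{name}={n}" for name, n in steps)
        + f"; {n_initial} -> {len(alive)}",
    )
    return out, accounting


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_CSV_NAMES = {"participants": "participants.csv", "waves": "waves.csv", "events": "events.csv"}


def read_panel_csv(directory: str | Path) -> PanelDataset:
    """Read participants.csv / waves.csv / events.csv from ``directory``.

    Malformed rows are reported with their file and line number (header is
    line 1); duplicate participant ids are fatal.
    """
    directory = Path(directory)
    frames = {}
    for key, fname in _CSV_NAMES.items():
        path = directory / fname
        if key == "participants" and not path.exists():
            raise FileNotFoundError(path)
        if path.exists():
            frames[key] = pd.read_csv(
                path, dtype={"id": str}, keep_default_na=True, float_precision="round_trip"
            )
        else:
            frames[key] = None

    p = frames["participants"]
    missing_cols = [c for c in PARTICIPANT_COLUMNS if c not in p.columns]
    if missing_cols:
        raise PanelValidationError(f"participants.csv missing columns: {missing_cols}")
    _check_csv_values(p, "participants.csv")
    if frames["waves"] is not None:
        _check_csv_values(frames["waves"], "waves.csv")
    try:
        ds = PanelDataset(p, frames["waves"], frames["events"])
    except PanelValidationError:
        raise
    ds.log(f"read from {directory}")
    return ds


def _check_csv_values(df: pd.DataFrame, fname: str) -> None:
    checks: dict[str, set[str]] = {}
    if fname == "participants.csv":
        checks = {c: _FREQ_VALUES for c in ("vol_freq", "hobby_freq", "neigh_freq")}
        checks.update({f"dss{i}": _DSS_VALUES for i in range(1, 6)})
        checks["sex"] = {s.value for s in Sex}
        checks["smoking"] = {s.value for s in Smoking}
        checks["walking"] = {w.value for w in Walking}
    elif fname == "waves.csv":
        checks["state"] = {s.value for s in State}
        bad_t = (df["t_months"] < 0) | (df["t_months"] > FOLLOWUP_MONTHS)
        if bad_t.any():
            line = int(df.index[bad_t][0]) + 2
            raise PanelValidationError(
                f"{fname}:{line}: t_months={df.loc[df.index[bad_t][0], 't_months']} "
                f"outside [0, {FOLLOWUP_MONTHS}]"
            )
    for col, allowed in checks.items():
        if col not in df.columns:
            continue
        vals = df[col].astype("string")
        bad = vals.notna() & ~vals.isin(list(allowed) + ["", "missing"])
        if bad.any():
            idx = df.index[bad][0]
            raise PanelValidationError(
                f"{fname}:{int(idx) + 2}: invalid value {df.loc[idx, col]!r} in column {col!r}"
            )


def write_panel_csv(dataset: PanelDataset, directory: str | Path) -> dict[str, Path]:
    """Write the three CSV files; returns the paths written.

    Output is canonical (sorted rows, fixed column order, no index), so the
    write/read round trip is the identity and byte-identical across runs.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for key, df in (
        ("participants", dataset.participants),
        ("waves", dataset.waves),
        ("events", dataset.events),
    ):
        path = directory / _CSV_NAMES[key]
        buf = io.StringIO()
        df.to_csv(buf, index=False, lineterminator="\n")
        path.write_text(buf.getvalue(), encoding="utf-8")
        paths[key] = path
    return paths


# ---------------------------------------------------------------------------
# Descriptive tables
# ---------------------------------------------------------------------------

def final_status(dataset: PanelDataset, horizon_t: int = FOLLOWUP_MONTHS) -> pd.Series:
    """Each participant's status at the horizon: nondisabled / disabled / dead / emigrated.

    Death dominates emigration, which dominates the last observed wave state,
    when records share a month.  Events and waves after the horizon are
    ignored.
    """
    if not (0 <= horizon_t <= FOLLOWUP_MONTHS):
        raise ValueError(f"horizon {horizon_t} outside follow-up")
    ids = dataset.participants["id"]
    status = pd.Series("nondisabled", index=ids.to_numpy(), name="final_status")

    w = dataset.waves[dataset.waves["t_months"] <= horizon_t]
    if len(w):
        last = w.sort_values(["id", "t_months"]).groupby("id")["state"].last()
        disabled = last.index[last == State.disabled.value]
        status[status.index.isin(disabled)] = "disabled"
    e = dataset.events[dataset.events["t_months"] <= horizon_t]
    emig = e.loc[e["kind"] == EventKind.emigration.value, "id"]
    status[status.index.isin(set(emig))] = "emigrated"
    dead = e.loc[e["kind"] == EventKind.death.value, "id"]
    status[status.index.isin(set(dead))] = "dead"
    return status


_STATUS_ORDER = ["nondisabled", "disabled", "dead", "emigrated"]


def outcome_distribution_table(
    dataset: PanelDataset,
    group_of: pd.Series,
    horizon_t: int = FOLLOWUP_MONTHS,
) -> pd.DataFrame:
    """Counts and percentages of final status by sex x exposure group.

    ``group_of`` maps participant id -> group label; participants with a
    missing group are omitted.  Percentages are of the sex-specific total, so
    each sex block (including its Total row) sums to 100 up to display
    rounding.  Full precision is kept internally; round only for display.
    """
    status = final_status(dataset, horizon_t)
    p = dataset.participants.set_index("id")
    df = pd.DataFrame({"sex": p["sex"], "status": status, "group": group_of.reindex(p.index)})
    df = df.dropna(subset=["group"])

    rows = []
    for sex in (Sex.male.value, Sex.female.value):
        sub = df[df["sex"] == sex]
        sex_total = len(sub)
        groups = sorted(sub["group"].unique())
        for st in _STATUS_ORDER + ["total"]:
            row: dict[str, object] = {"sex": sex, "status": st}
            for g in groups:
                cell = sub[(sub["group"] == g)] if st == "total" else sub[
                    (sub["group"] == g) & (sub["status"] == st)
                ]
                row[f"n_{g}"] = len(cell)
                row[f"pct_{g}"] = 100.0 * len(cell) / sex_total if sex_total else np.nan
            n_all = len(sub) if st == "total" else int((sub["status"] == st).sum())
            row["n_total"] = n_all
            row["pct_total"] = 100.0 * n_all / sex_total if sex_total else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def baseline_characteristics_table(dataset: PanelDataset, group_of: pd.Series) -> pd.DataFrame:
    """Baseline descriptive table by exposure group (means/SDs and percentages).

    Row structure: group size, age mean (SD), % men, BMI mean (SD), % current
    smokers, % walking < 0.5 h/day, % depressed, disease-history percentages.
    Covariates missing for a participant are simply omitted from that row's
    denominator; an empty group yields NaN cells rather than an error.
    """
    p = dataset.participants.set_index("id")
    group = group_of.reindex(p.index)
    depressed = depression_flags(dataset.participants).reindex(p.index)

    groups = sorted(g for g in group.dropna().unique())
    rows: list[dict[str, object]] = []

    def stat_row(label: str, values: Callable[[pd.DataFrame], pd.Series], kind: str) -> None:
        row: dict[str, object] = {"characteristic": label}
        for g in groups:
            sub = p[group == g]
            v = values(sub)
            v = v.dropna()
            if kind == "mean_sd":
                row[f"{g}"] = float(v.mean()) if len(v) else np.nan
                row[f"{g}_sd"] = float(v.std(ddof=1)) if len(v) > 1 else np.nan
            else:
                row[f"{g}"] = 100.0 * float(v.mean()) if len(v) else np.nan
                row[f"{g}_sd"] = np.nan
        rows.append(row)

    rows.append(
        {"characteristic": "n", **{f"{g}": int((group == g).sum()) for g in groups}}
    )
    stat_row("age_mean", lambda d: d["age"], "mean_sd")
    stat_row("men_pct", lambda d: (d["sex"] == Sex.male.value).astype(float), "pct")
    stat_row("bmi_mean", lambda d: d["bmi"], "mean_sd")
    stat_row("current_smoker_pct",
             lambda d: (d["smoking"] == Smoking.current.value).astype("Float64").where(d["smoking"].notna()),
             "pct")
    stat_row("walking_lt_half_hour_pct",
             lambda d: (d["walking"] == Walking.lt_half_hour.value).astype("Float64").where(d["walking"].notna()),
             "pct")
    stat_row("depression_pct",
             lambda d: depressed.loc[d.index].astype("Float64"),
             "pct")
    for col, label in (
        ("hx_htn", "hypertension_pct"),
        ("hx_dm", "diabetes_pct"),
        ("hx_stroke", "stroke_pct"),
        ("hx_mi", "mi_pct"),
        ("hx_cancer", "cancer_pct"),
    ):
        stat_row(label, lambda d, c=col: d[c].astype(float), "pct")
    return pd.DataFrame(rows)
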