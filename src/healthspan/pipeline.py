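"""Full study orchestration: coding -> exclusion -> per-group fits -> life tables.

Runs the whole analysis replica on a panel (read from CSV or generated
synthetically): the exposure-count analysis (2 sexes x 4 groups), the
per-activity frequency analysis (2 x 3 activities x 4 levels), and the five
stratified analyses (smoking, BMI, walking, depression, and the
non-communicable-disease risk count).  Stratification is the confounding
control: transition models are refitted within each stratum rather than
covariate-adjusted.  Every reported cell carries its group size and
convergence flag, and all exclusions / missing-stratifier drops are logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from . import mslt, panel_data, synthetic_cohort, transition_model
from .panel_data import PanelDataset, Sex

__all__ = [
    "AnalysisConfig",
    "StudyReport",
    "run_count_exposure_analysis",
    "run_frequency_exposure_analysis",
    "run_stratified_analysis",
    "run_full_study",
    "render_report",
    "STRATIFIERS",
]

log = logging.getLogger("healthspan")

GROUP_LABELS = {0: "none", 1: "one_activity", 2: "two_activities", 3: "three_activities"}
ACTIVITY_LABELS = {"vol_freq": "volunteering", "hobby_freq": "hobby", "neigh_freq": "neighborhood"}
FREQ_ORDER = ["none", "lt_monthly", "1_3_monthly", "weekly_plus"]

#: Strata labels match the published naming for the risk-count analysis.
NCD_LABELS = {"zero": "no risk factor", "one": "one risk factor",
              "two_or_three": "two or three risk factors"}


def _smoking_strata(p: pd.DataFrame) -> pd.Series:
    s = p["smoking"].map({"never_former": "never_former", "current": "current"}).astype("string")
    return pd.Series(s.to_numpy(), index=p["id"].to_numpy())


def _bmi_strata(p: pd.DataFrame) -> pd.Series:
    bmi = p["bmi"]
    s = pd.Series(pd.NA, index=p.index, dtype="string")
    s[(bmi >= 18.5) & (bmi < 25.0)] = "bmi_18.5_to_25"
    s[(bmi < 18.5) | (bmi >= 25.0)] = "bmi_lt_18.5_or_ge_25"
    return pd.Series(s.to_numpy(), index=p["id"].to_numpy())


def _walking_strata(p: pd.DataFrame) -> pd.Series:
    s = p["walking"].astype("string")
    return pd.Series(s.to_numpy(), index=p["id"].to_numpy())


def _depression_strata(p: pd.DataFrame) -> pd.Series:
    d = panel_data.depression_flags(p)
    return d.map({True: "depression", False: "free_of_depression"}).astype("string")


STRATIFIERS = {
    "smoking": _smoking_strata,
    "bmi": _bmi_strata,
    "walking": _walking_strata,
    "depression": _depression_strata,
    "ncd_risk": lambda p: panel_data.ncd_strata(p).map(NCD_LABELS).astype("string"),
}


@dataclass
class AnalysisConfig:
    """Everything a full study run needs; serialisable from TOML."""

    panel_dir: str | None = None                       # read CSVs from here ...
    simulation: synthetic_cohort.SimulationConfig | None = None  # ... or simulate
    index_age: float = 65.0
    x_max: float = 115.0
    h: float = transition_model.MONTH
    bootstrap_B: int = 1000
    bootstrap_seed: int = 20061201
    min_transitions: int = 10
    stratifiers: tuple[str, ...] = tuple(STRATIFIERS)
    run_frequency_analysis: bool = True

    def load_dataset(self) -> PanelDataset:
        if self.panel_dir is not None:
            return panel_data.read_panel_csv(self.panel_dir)
        if self.simulation is not None:
            return synthetic_cohort.generate_dataset(self.simulation)
        raise ValueError("config must give either panel_dir or a simulation config")

    @classmethod
    def from_toml(cls, path: str | Path) -> "AnalysisConfig":
        raw = tomllib.loads(Path(path).read_text())
        cfg = cls()
        an = raw.get("analysis", {})
        for key in ("index_age", "x_max", "bootstrap_B", "bootstrap_seed",
                    "min_transitions", "run_frequency_analysis"):
            if key in an:
                setattr(cfg, key, an[key])
        if "stratifiers" in an:
            unknown = set(an["stratifiers"]) - set(STRATIFIERS)
            if unknown:
                raise ValueError(f"unknown stratifiers: {sorted(unknown)}")
            cfg.stratifiers = tuple(an["stratifiers"])
        if "panel_dir" in raw.get("input", {}):
            cfg.panel_dir = raw["input"]["panel_dir"]
        elif "cohort" in raw or "true_params" in raw or "groups" in raw:
            cfg.simulation = synthetic_cohort.SimulationConfig.from_toml(path)
        else:
            cfg.simulation = synthetic_cohort.default_config()
        return cfg


@dataclass
class StudyReport:
    """All tables and accounting from one full run."""

    exclusion: panel_data.ExclusionAccounting
    baseline_table: pd.DataFrame
    outcome_table: pd.DataFrame
    count_exposure_table: pd.DataFrame
    frequency_exposure_table: pd.DataFrame | None
    stratified_tables: dict[str, pd.DataFrame]
    metadata: dict
    partial: bool = False


def _expectancy_cell(
    dataset: PanelDataset,
    sex: str,
    group_of: pd.Series,
    group: object,
    config: AnalysisConfig,
    seed: int,
) -> dict:
    """Fit one cell and compute its life-table triple with CIs."""
    in_group = pd.Series(
        group_of.reindex(dataset.participants["id"]).to_numpy(),
        index=dataset.participants.index,
    )
    n_cell = int(
        ((dataset.participants["sex"] == sex) & (in_group == group).fillna(False)).sum()
    )
    row: dict = {"sex": sex, "group": str(group), "n": n_cell, "converged": False,
                 "dfle": np.nan, "dfle_lo": np.nan, "dfle_hi": np.nan,
                 "duration": np.nan, "duration_lo": np.nan, "duration_hi": np.nan,
                 "tle": np.nan, "tle_lo": np.nan, "tle_hi": np.nan}
    if n_cell == 0:
        log.warning("cell sex=%s group=%s is empty; marked unavailable", sex, group)
        return row
    try:
        res = transition_model.fit(
            dataset, sex=sex, group_of=group_of, group=group,
            min_transitions=config.min_transitions,
        )
    except Exception as exc:  # noqa: BLE001 - cell failure must not kill the run
        log.warning("fit failed for sex=%s group=%s: %s", sex, group, exc)
        return row
    row["converged"] = res.converged
    if res.dropped:
        log.info("sex=%s group=%s: transitions dropped for sparse support: %s",
                 sex, group, res.dropped)
    if not res.converged:
        log.warning("fit did not converge for sex=%s group=%s; CIs withheld", sex, group)
        return row
    if config.bootstrap_B > 0:
        lt = mslt.bootstrap_ci(res, B=config.bootstrap_B, seed=seed,
                               x0=config.index_age, x_max=config.x_max, h=config.h)
        row.update(dfle_lo=lt.dfle_ci[0], dfle_hi=lt.dfle_ci[1],
                   duration_lo=lt.duration_ci[0], duration_hi=lt.duration_ci[1],
                   tle_lo=lt.tle_ci[0], tle_hi=lt.tle_ci[1])
    else:
        lt = mslt.expectancies(res.params, config.index_age, config.x_max, config.h)
    row.update(dfle=lt.dfle, duration=lt.duration_disabled, tle=lt.tle)
    return row


def _cell_seed(base: int, *labels: object) -> int:
    # stable across processes (unlike hash()) so reruns are byte-identical
    digest = hashlib.sha256("|".join([str(base), *map(str, labels)]).encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def run_count_exposure_analysis(config: AnalysisConfig, dataset: PanelDataset) -> pd.DataFrame:
    """DFLE / duration / TLE by sex x number of activities (0-3)."""
    group_of = panel_data.social_participation_counts(dataset.participants)
    rows = []
    for sex in (Sex.male.value, Sex.female.value):
        for g in range(4):
            row = _expectancy_cell(dataset, sex, group_of, g, config,
                                   _cell_seed(config.bootstrap_seed, "count", sex, g))
            row["group"] = GROUP_LABELS[g]
            rows.append(row)
            log.info("count analysis %s/%s: n=%d dfle=%.2f", sex, GROUP_LABELS[g],
                     row["n"], row["dfle"])
    return pd.DataFrame(rows)


def run_frequency_exposure_analysis(config: AnalysisConfig, dataset: PanelDataset) -> pd.DataFrame:
    """DFLE / duration / TLE by sex x activity type x 4 frequency levels."""
    rows = []
    for col, label in ACTIVITY_LABELS.items():
        freq = dataset.participants[col].astype("string")
        group_of = pd.Series(freq.to_numpy(), index=dataset.participants["id"].to_numpy())
        for sex in (Sex.male.value, Sex.female.value):
            for level in FREQ_ORDER:
                row = _expectancy_cell(dataset, sex, group_of, level, config,
                                       _cell_seed(config.bootstrap_seed, "freq", col, sex, level))
                row["activity"] = label
                row["group"] = level
                rows.append(row)
    out = pd.DataFrame(rows)
    return out[["activity"] + [c for c in out.columns if c != "activity"]]


def run_stratified_analysis(
    config: AnalysisConfig, dataset: PanelDataset, stratifier: str
) -> pd.DataFrame:
    """DFLE table by sex x stratum x exposure count for one stratifier.

    Participants whose stratifier is missing are dropped from this run only,
    with the count logged and recorded in the table attributes.
    """
    if stratifier not in STRATIFIERS:
        raise ValueError(f"unknown stratifier {stratifier!r}; choose from {sorted(STRATIFIERS)}")
    strata = STRATIFIERS[stratifier](dataset.participants)
    missing_ids = strata.index[strata.isna()]
    if len(missing_ids):
        log.info("stratifier %s missing for %d participants; dropped from this run only",
                 stratifier, len(missing_ids))
    analysed = dataset.subset(
        strata.index[strata.notna()],
        note=f"stratified run ({stratifier}): dropped {len(missing_ids)} with missing stratifier",
    )
    strata = strata.dropna()
    group_of = panel_data.social_participation_counts(analysed.participants)

    rows = []
    for stratum in sorted(strata.unique()):
        in_stratum = analysed.subset(strata.index[strata == stratum])
        for sex in (Sex.male.value, Sex.female.value):
            for g in range(4):
                row = _expectancy_cell(
                    in_stratum, sex, group_of, g, config,
                    _cell_seed(config.bootstrap_seed, stratifier, stratum, sex, g),
                )
                row["stratum"] = stratum
                row["group"] = GROUP_LABELS[g]
                rows.append(row)
    out = pd.DataFrame(rows)
    out = out[["stratum"] + [c for c in out.columns if c != "stratum"]]
    out.attrs["n_missing_stratifier"] = int(len(missing_ids))
    return out


def run_full_study(config: AnalysisConfig) -> StudyReport:
    """The whole replica: exclusion, descriptives, all expectancy tables."""
    raw = config.load_dataset()
    dataset, accounting = panel_data.apply_exclusion_cascade(raw)
    log.info("exclusion cascade: %d -> %d", accounting.n_initial, accounting.n_final)
    group_of = panel_data.social_participation_counts(dataset.participants)

    partial = False
    baseline = panel_data.baseline_characteristics_table(dataset, group_of)
    outcome = panel_data.outcome_distribution_table(dataset, group_of)
    count_table = run_count_exposure_analysis(config, dataset)

    freq_table = None
    if config.run_frequency_analysis:
        freq_table = run_frequency_exposure_analysis(config, dataset)

    stratified: dict[str, pd.DataFrame] = {}
    for name in config.stratifiers:
        try:
            stratified[name] = run_stratified_analysis(config, dataset, name)
        except Exception as exc:  # noqa: BLE001
            log.error("stratified analysis %s failed: %s", name, exc)
            partial = True

    metadata = {
        "n_analysed": len(dataset),
        "exclusions": accounting.steps,
        "bootstrap_B": config.bootstrap_B,
        "bootstrap_seed": config.bootstrap_seed,
        "index_age": config.index_age,
        "x_max": config.x_max,
        "config_hash": (config.simulation.config_hash() if config.simulation else None),
        "provenance": list(dataset.provenance),
    }
    return StudyReport(
        exclusion=accounting,
        baseline_table=baseline,
        outcome_table=outcome,
        count_exposure_table=count_table,
        frequency_exposure_table=freq_table,
        stratified_tables=stratified,
        metadata=metadata,
        partial=partial,
    )


def _round_years(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype == float and c not in ("n",):
            out[c] = out[c].round(1)  # display convention: 0.1 years
    return out


def render_report(report: StudyReport, outdir: str | Path) -> dict[str, Path]:
    """Write the report as CSV tables plus a JSON summary; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def write_csv(name: str, df: pd.DataFrame, rounded: bool = False) -> None:
        path = outdir / f"{name}.csv"
        (_round_years(df) if rounded else df).to_csv(path, index=False, lineterminator="\n")
        paths[name] = path

    write_csv("exclusion_accounting", report.exclusion.as_frame())
    write_csv("baseline_characteristics", report.baseline_table)
    write_csv("outcome_distribution", report.outcome_table)
    write_csv("dfle_by_count", report.count_exposure_table, rounded=True)
    if report.frequency_exposure_table is not None:
        write_csv("dfle_by_frequency", report.frequency_exposure_table, rounded=True)
    for name, table in report.stratified_tables.items():
        write_csv(f"dfle_stratified_{name}", table, rounded=True)

    summary = {
        "metadata": report.metadata,
        "partial": report.partial,
        "exclusion": {"n_initial": report.exclusion.n_initial,
                      "steps": report.exclusion.steps,
                      "n_final": report.exclusion.n_final},
    }
    path = outdir / "report.json"
    path.write_text(json.dumps(summary, indent=2, default=str))
    paths["report"] = path
    return paths
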