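"""Coding rules, exclusion cascade, CSV round trip and descriptive tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from healthspan import panel_data as pdt
from healthspan.panel_data import (
    CodingError,
    Frequency,
    PanelDataset,
    PanelValidationError,
    Sex,
    Smoking,
    State,
    Walking,
    apply_exclusion_cascade,
    code_depression,
    code_ncd_risk,
    code_social_participation,
    outcome_distribution_table,
    baseline_characteristics_table,
    read_panel_csv,
    write_panel_csv,
)
from healthspan.synthetic_cohort import cascade_dataset_from_counts, default_config, generate_dataset

from conftest import activities, participant


class TestSocialParticipationCoding:
    @pytest.mark.parametrize(
        "freqs, expected",
        [
            ((Frequency.none, Frequency.none, Frequency.none), 0),
            ((Frequency.lt_monthly, Frequency.none, Frequency.weekly_plus), 2),
            ((Frequency.weekly_plus, Frequency.weekly_plus, Frequency.weekly_plus), 3),
            ((Frequency.one_to_three_monthly, Frequency.none, Frequency.none), 1),
        ],
    )
    def test_counting_rule(self, freqs, expected):
        """Any participation, even less than monthly, counts the category."""
        assert code_social_participation(activities(*freqs)) == expected

    def test_missing_frequency_is_a_coding_error(self):
        acts = activities()
        acts = (acts[0], type(acts[1])("hobby", None), acts[2])
        with pytest.raises(CodingError, match="hobby"):
            code_social_participation(acts)


class TestDepressionCoding:
    @pytest.mark.parametrize(
        "items, score, flag",
        [
            (("yes",) * 5, 3, True),       # items 3 and 5 score 0 for yes
            (("no",) * 5, 2, True),        # items 3 and 5 score 1 for no
            (("no", "no", "yes", "no", "yes"), 0, False),
            (("yes", "yes", "no", "yes", "no"), 5, True),
            (("yes", "no", "yes", "no", "yes"), 1, False),
        ],
    )
    def test_printed_scoring(self, items, score, flag):
        assert code_depression(items) == (score, flag)

    def test_missing_item_errors(self):
        with pytest.raises(CodingError, match="item 4"):
            code_depression(("yes", "no", "yes", None, "no"))

    @given(st.tuples(*[st.sampled_from(["yes", "no"])] * 5))
    def test_score_range_and_threshold(self, items):
        score, flag = code_depression(items)
        assert 0 <= score <= 5
        assert flag == (score >= 2)


class TestNcdRiskCoding:
    @pytest.mark.parametrize(
        "smoking, bmi, walking, expected",
        [
            (Smoking.never_former, 22.0, Walking.ge_half_hour, 0),
            (Smoking.current, 26.0, Walking.lt_half_hour, 3),
            (Smoking.never_former, 18.5, Walking.ge_half_hour, 0),  # boundary: not < 18.5
            (Smoking.never_former, 18.4, Walking.ge_half_hour, 1),
            (Smoking.never_former, 25.0, Walking.ge_half_hour, 1),  # boundary: >= 25.0
            (Smoking.current, 20.0, Walking.ge_half_hour, 1),
        ],
    )
    def test_risk_count(self, smoking, bmi, walking, expected):
        count, stratum = code_ncd_risk(smoking, bmi, walking)
        assert count == expected
        assert stratum.value == {0: "zero", 1: "one", 2: "two_or_three", 3: "two_or_three"}[expected]

    def test_missing_input_errors(self):
        with pytest.raises(CodingError):
            code_ncd_risk(None, 22.0, Walking.ge_half_hour)


class TestExclusionCascade:
    def test_printed_counts_arithmetic(self):
        """The four sequential exclusions take 23,091 to exactly 11,982."""
        raw = cascade_dataset_from_counts(23_091, 6_333, 1_979, 5, 2_792)
        kept, acc = apply_exclusion_cascade(raw)
        assert acc.n_initial == 23_091
        assert [n for _, n in acc.steps] == [6_333, 1_979, 5, 2_792]
        assert acc.n_final == len(kept) == 11_982

    def test_clean_dataset_is_identity(self, tiny_dataset):
        kept, acc = apply_exclusion_cascade(tiny_dataset)
        assert kept == tiny_dataset
        assert all(n == 0 for _, n in acc.steps)

    def test_cascade_is_sequential_not_marginal(self):
        """Participants failing several rules count only at the first one."""
        parts = []
        for i in range(100):
            consent = i >= 10
            # 3 of the 10 non-consenters also have missing exposure; 5 of the
            # consenters have missing exposure
            acts = activities()
            if (i < 3) or (10 <= i < 15):
                acts = (acts[0], type(acts[0])("hobby", None), acts[2])
            parts.append(participant(f"p{i:03d}", consent=consent, acts=acts))
        raw = PanelDataset.from_records(parts)
        kept, acc = apply_exclusion_cascade(raw)
        assert dict(acc.steps)["no_consent"] == 10
        assert dict(acc.steps)["missing_social_participation"] == 5
        assert acc.n_final == 85

    @given(
        flags=st.lists(
            st.tuples(st.booleans(), st.booleans(), st.booleans(), st.booleans()),
            min_size=0,
            max_size=30,
        )
    )
    def test_conservation(self, flags):
        """n_final + sum(removed) == n_initial for any flag configuration."""
        parts = []
        for i, (consent, prev, exited, missing) in enumerate(flags):
            acts = activities()
            if missing:
                acts = (type(acts[0])("volunteering", None), acts[1], acts[2])
            parts.append(
                participant(
                    f"p{i:03d}",
                    consent=consent,
                    prevalent_disability=prev,
                    dead_or_moved_pre_baseline=exited,
                    acts=acts,
                )
            )
        _, acc = apply_exclusion_cascade(PanelDataset.from_records(parts))
        assert acc.n_final + sum(n for _, n in acc.steps) == acc.n_initial


class TestCsvRoundTrip:
    def test_fixture_round_trip(self, tiny_dataset, tmp_path):
        write_panel_csv(tiny_dataset, tmp_path)
        back = read_panel_csv(tmp_path)
        assert back == tiny_dataset

    def test_simulated_round_trip(self, tmp_path):
        ds = generate_dataset(default_config(n=500, seed=3))
        write_panel_csv(ds, tmp_path)
        assert read_panel_csv(tmp_path) == ds

    def test_wave_month_out_of_bounds_rejected(self, tiny_dataset, tmp_path):
        write_panel_csv(tiny_dataset, tmp_path)
        waves = pd.read_csv(tmp_path / "waves.csv")
        waves.loc[0, "t_months"] = 140
        waves.to_csv(tmp_path / "waves.csv", index=False)
        with pytest.raises(PanelValidationError, match="140"):
            read_panel_csv(tmp_path)

    def test_duplicate_ids_fatal(self, tiny_dataset, tmp_path):
        write_panel_csv(tiny_dataset, tmp_path)
        p = pd.read_csv(tmp_path / "participants.csv")
        pd.concat([p, p.iloc[[0]]]).to_csv(tmp_path / "participants.csv", index=False)
        with pytest.raises(PanelValidationError, match="duplicate"):
            read_panel_csv(tmp_path)

    def test_invalid_value_reported_with_line_number(self, tiny_dataset, tmp_path):
        write_panel_csv(tiny_dataset, tmp_path)
        p = pd.read_csv(tmp_path / "participants.csv")
        p.loc[1, "vol_freq"] = "sometimes"
        p.to_csv(tmp_path / "participants.csv", index=False)
        with pytest.raises(PanelValidationError, match="participants.csv:3"):
            read_panel_csv(tmp_path)


class TestDatasetInvariants:
    def test_wave_after_death_rejected(self, tiny_dataset):
        from healthspan.panel_data import EVENT_COLUMNS, WAVE_COLUMNS

        waves = pd.concat(
            [tiny_dataset.waves, pd.DataFrame([{"id": "b", "t_months": 24, "state": "nd"}])]
        )
        with pytest.raises(PanelValidationError, match="death"):
            PanelDataset(tiny_dataset.participants, waves, tiny_dataset.events)

    def test_orphan_wave_rejected(self, tiny_dataset):
        waves = pd.concat(
            [tiny_dataset.waves, pd.DataFrame([{"id": "zz", "t_months": 0, "state": "nd"}])]
        )
        with pytest.raises(PanelValidationError, match="zz"):
            PanelDataset(tiny_dataset.participants, waves, tiny_dataset.events)


class TestOutcomeDistribution:
    def test_single_participant_is_all_of_its_cell(self):
        ds = PanelDataset.from_records(
            [participant("solo")],
            [
                pdt.WaveObservation("solo", 0, State.nondisabled),
                pdt.WaveObservation("solo", 132, State.nondisabled),
            ],
        )
        group_of = pd.Series([0], index=["solo"])
        table = outcome_distribution_table(ds, group_of)
        men = table[table["sex"] == "male"]
        row = men[men["status"] == "nondisabled"].iloc[0]
        assert row["n_0"] == 1 and row["pct_0"] == 100.0

    def test_status_precedence_and_percent_sums(self, tiny_dataset):
        group_of = pdt.social_participation_counts(tiny_dataset.participants)
        table = outcome_distribution_table(tiny_dataset, group_of)
        # b died, c emigrated, a ended disabled
        men = table[table["sex"] == "male"]
        women = table[table["sex"] == "female"]
        assert int(women[women["status"] == "dead"]["n_total"].iloc[0]) == 1
        assert int(men[men["status"] == "emigrated"]["n_total"].iloc[0]) == 1
        assert int(men[men["status"] == "disabled"]["n_total"].iloc[0]) == 1
        for block in (men, women):
            body = block[block["status"] != "total"]
            assert np.isclose(body["pct_total"].sum(), 100.0)


class TestBaselineTable:
    def test_all_male_group_is_100_percent_men(self, tiny_dataset):
        group_of = pdt.social_participation_counts(tiny_dataset.participants)
        table = baseline_characteristics_table(tiny_dataset, group_of)
        men_row = table[table["characteristic"] == "men_pct"].iloc[0]
        assert men_row["1"] == 100.0  # both group-1 members are male

    def test_empty_dataset_does_not_crash(self):
        ds = PanelDataset.from_records([])
        table = baseline_characteristics_table(ds, pd.Series(dtype=object))
        assert "characteristic" in table.columns

    def test_generator_marginals_recovered(self):
        """Group-0 mean age matches its generating distribution closely."""
        ds = generate_dataset(default_config(n=20_000, seed=11))
        group_of = pdt.social_participation_counts(ds.participants)
        table = baseline_characteristics_table(ds, group_of)
        age_row = table[table["characteristic"] == "age_mean"].iloc[0]
        assert abs(age_row["0"] - 75.1) < 0.3
        dep_row = table[table["characteristic"] == "depression_pct"].iloc[0]
        assert abs(dep_row["0"] - 40.2) < 2.0
        assert abs(dep_row["3"] - 14.0) < 2.0
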