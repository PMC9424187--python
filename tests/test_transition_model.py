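"""Step-matrix algebra, interval likelihood against path enumeration, MLE behaviour."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from healthspan.panel_data import (
    EventKind,
    EventRecord,
    PanelDataset,
    Sex,
    State,
    WaveObservation,
)
from healthspan.transition_model import (
    ABSENT,
    DEAD,
    DIS,
    ND,
    TransitionParams,
    fit,
    interval_log_likelihood,
    step_matrices,
    step_matrix,
)

from conftest import death_dataset, pair_dataset, participant


def enumerate_interval_probability(P_seq, s0, s1):
    """Brute-force oracle: sum over all intermediate state paths."""
    total = 0.0
    states = [s0]
    def recurse(state, depth, prob):
        nonlocal total
        if depth == len(P_seq):
            if state == s1:
                total += prob
            return
        for nxt in (ND, DIS, DEAD):
            recurse(nxt, depth + 1, prob * P_seq[depth][state, nxt])
    recurse(s0, 0, 1.0)
    return total


def monthly_sequence(params, age0, k):
    return [step_matrix(params, age0 + u / 12.0) for u in range(k)]


class TestStepMatrix:
    def test_symmetric_logits_give_uniform_rows(self):
        p = TransitionParams(0, 0, 0, 0, 0, 0, 0, 0)
        P = step_matrix(p, 80.0)
        assert np.allclose(P[ND], [1 / 3, 1 / 3, 1 / 3])
        assert np.allclose(P[DIS], [1 / 3, 1 / 3, 1 / 3])

    def test_absent_transitions_give_identity(self, no_transition_params):
        P = step_matrix(no_transition_params, 80.0)
        assert np.allclose(P, np.eye(3), atol=1e-15)

    def test_closed_form_row(self):
        """Direct scalar evaluation of the logit expression at age 70."""
        p = TransitionParams(-5.0, 0.04, -6.0, 0.05, ABSENT, 0.0, ABSENT, 0.0)
        P = step_matrix(p, 70.0)
        e1 = math.exp(-5.0 + 0.04 * 70.0)
        e2 = math.exp(-6.0 + 0.05 * 70.0)
        z = 1.0 + e1 + e2
        assert P[ND, DIS] == pytest.approx(e1 / z, rel=1e-14)
        assert P[ND, DEAD] == pytest.approx(e2 / z, rel=1e-14)
        assert P[ND, ND] == pytest.approx(1.0 / z, rel=1e-14)

    def test_dead_row_exactly_absorbing(self, moderate_params):
        P = step_matrices(moderate_params, np.linspace(65, 114, 50))
        assert np.all(P[:, DEAD] == np.array([0.0, 0.0, 1.0]))

    @given(
        theta=st.lists(
            st.floats(min_value=-30, max_value=4), min_size=4, max_size=4
        ),
        slopes=st.lists(
            st.floats(min_value=-0.3, max_value=0.3), min_size=4, max_size=4
        ),
        age=st.floats(min_value=65, max_value=115),
    )
    def test_rows_stochastic(self, theta, slopes, age):
        p = TransitionParams(
            theta[0], slopes[0], theta[1], slopes[1], theta[2], slopes[2], theta[3], slopes[3]
        )
        P = step_matrices(p, np.array(age))
        assert np.all(P >= 0) and np.all(P <= 1)
        assert np.allclose(P.sum(axis=-1), 1.0, atol=1e-12)

    def test_age_bound_enforced(self, moderate_params):
        with pytest.raises(ValueError, match="age"):
            step_matrix(moderate_params, 50.0)


class TestIntervalLikelihood:
    def test_twelve_step_pair_equals_matrix_power(self, moderate_params):
        """Constant matrix (b=0): the interval likelihood is log [P^12]_{s,s'}."""
        theta = moderate_params.to_array()
        const = theta.copy()
        # fold the age dependence at 70 into the intercepts, zero the slopes
        for a in range(0, 8, 2):
            const[a] = theta[a] + theta[a + 1] * 70.0
            const[a + 1] = 0.0
        p = TransitionParams.from_array(const)
        P = step_matrix(p, 70.0)
        P12 = np.linalg.matrix_power(P, 12)
        for s0, s1 in [(State.nondisabled, State.nondisabled), (State.nondisabled, State.disabled),
                       (State.disabled, State.nondisabled), (State.disabled, State.disabled)]:
            ds = pair_dataset(s0, s1, 12, age=70.0)
            ll = interval_log_likelihood(p, ds)
            i0 = 0 if s0 is State.nondisabled else 1
            i1 = 0 if s1 is State.nondisabled else 1
            assert ll == pytest.approx(math.log(P12[i0, i1]), abs=1e-10)

    @pytest.mark.parametrize("gap", [1, 2, 3])
    @pytest.mark.parametrize("s0", [State.nondisabled, State.disabled])
    @pytest.mark.parametrize("s1", [State.nondisabled, State.disabled])
    def test_short_intervals_match_path_enumeration(self, moderate_params, gap, s0, s1):
        """Age-varying matrices: product equals the exhaustive path sum."""
        ds = pair_dataset(s0, s1, gap, age=82.0)
        ll = interval_log_likelihood(moderate_params, ds)
        P_seq = monthly_sequence(moderate_params, 82.0, gap)
        i0 = 0 if s0 is State.nondisabled else 1
        i1 = 0 if s1 is State.nondisabled else 1
        expected = enumerate_interval_probability(P_seq, i0, i1)
        assert ll == pytest.approx(math.log(expected), abs=1e-12)

    @pytest.mark.parametrize("death_month", [1, 2, 3])
    @pytest.mark.parametrize("s0", [State.nondisabled, State.disabled])
    def test_death_terms_match_path_enumeration(self, moderate_params, s0, death_month):
        """A dated death: alive to m-1 through any path, then the death step."""
        ds = death_dataset(s0, death_month, age=82.0)
        ll = interval_log_likelihood(moderate_params, ds)
        P_seq = monthly_sequence(moderate_params, 82.0, death_month)
        i0 = 0 if s0 is State.nondisabled else 1
        expected = 0.0
        for alive_state in (ND, DIS):
            reach = enumerate_interval_probability(P_seq[:-1], i0, alive_state)
            expected += reach * P_seq[-1][alive_state, DEAD]
        assert ll == pytest.approx(math.log(expected), abs=1e-12)

    def test_certain_paths_have_zero_loglik(self, no_transition_params):
        """All-survivor data under an immovable chain has probability one."""
        parts = [participant(f"p{i}", age=70.0 + i) for i in range(3)]
        waves = [
            WaveObservation(p.id, t, State.nondisabled)
            for p in parts
            for t in range(0, 133, 12)
        ]
        ds = PanelDataset.from_records(parts, waves)
        assert interval_log_likelihood(no_transition_params, ds) == 0.0

    def test_sentinel_transition_is_astronomically_unlikely(self, no_transition_params):
        """Observing a transition the sentinel forbids costs ~50 log units."""
        ds = pair_dataset(State.nondisabled, State.disabled, 12)
        assert interval_log_likelihood(no_transition_params, ds) < -40.0

    def test_underflowed_path_is_minus_inf(self):
        p = TransitionParams(-800.0, 0.0, ABSENT, 0.0, ABSENT, 0.0, ABSENT, 0.0)
        ds = pair_dataset(State.nondisabled, State.disabled, 1)
        assert interval_log_likelihood(p, ds) == -np.inf

    @given(gap=st.integers(min_value=1, max_value=24), age=st.floats(min_value=65, max_value=95))
    def test_loglik_never_positive(self, gap, age):
        p = TransitionParams(-13.5, 0.10, -13.6, 0.10, -1.9, -0.02, -11.2, 0.09)
        ds = pair_dataset(State.nondisabled, State.nondisabled, gap, age=age)
        assert interval_log_likelihood(p, ds) <= 0.0


def _simulated_cell(n=4000, seed=5):
    from healthspan.panel_data import social_participation_counts
    from healthspan.synthetic_cohort import default_config, generate_dataset

    cfg = default_config(n=n, seed=seed)
    cfg.sex_prob_male = 1.0
    cfg.group_probs_by_sex = {"male": (1, 0, 0, 0), "female": (1, 0, 0, 0)}
    ds = generate_dataset(cfg)
    groups = social_participation_counts(ds.participants)
    return ds, groups, cfg.true_params[("male", 0)]


class TestFit:
    def test_loglik_improves_from_initial_point(self):
        ds, groups, true = _simulated_cell()
        res = fit(ds, sex="male", group_of=groups, group=0)
        init = TransitionParams(-4, 0, -4, 0, -4, 0, -4, 0)
        assert res.converged
        assert res.loglik >= interval_log_likelihood(init, ds, sex="male",
                                                     group_of=groups, group=0)
        # and beats the truth's likelihood (MLE property on this sample)
        assert res.loglik >= interval_log_likelihood(true, ds, sex="male",
                                                     group_of=groups, group=0)

    def test_estimates_near_truth(self):
        ds, groups, true = _simulated_cell(n=8000, seed=9)
        res = fit(ds, sex="male", group_of=groups, group=0)
        z = (res.params.to_array() - true.to_array()) / res.se()
        assert np.all(np.abs(z) < 4.0)

    def test_no_recovery_support_drops_transition(self):
        """A dataset without any dis->nd pair pins recovery at the sentinel."""
        parts = [participant(f"p{i}", age=70.0) for i in range(60)]
        waves = []
        events = []
        for i, p in enumerate(parts):
            waves.append(WaveObservation(p.id, 0, State.nondisabled))
            if i % 3 == 0:
                waves.append(WaveObservation(p.id, 12, State.disabled))
            elif i % 3 == 1:
                waves.append(WaveObservation(p.id, 12, State.nondisabled))
                events.append(EventRecord(p.id, EventKind.death, 18))
            else:
                waves.append(WaveObservation(p.id, 12, State.nondisabled))
        ds = PanelDataset.from_records(parts, waves, events)
        res = fit(ds)
        assert "dis_nd" in res.dropped
        assert res.params.a_dis_nd == ABSENT
        assert np.all(res.covariance[4:6] == 0.0)
        assert res.params.a_nd_dis != ABSENT

    def test_doubling_data_halves_covariance(self):
        ds, groups, _ = _simulated_cell(n=1500, seed=13)
        res1 = fit(ds, sex="male", group_of=groups, group=0)

        p2 = ds.participants.copy()
        p2["id"] = "dup_" + p2["id"]
        w2 = ds.waves.copy()
        w2["id"] = "dup_" + w2["id"]
        e2 = ds.events.copy()
        e2["id"] = "dup_" + e2["id"]
        doubled = PanelDataset(
            pd.concat([ds.participants, p2]),
            pd.concat([ds.waves, w2]),
            pd.concat([ds.events, e2]),
        )
        groups2 = pd.concat([groups, pd.Series(groups.to_numpy(), index="dup_" + groups.index)])
        res2 = fit(doubled, sex="male", group_of=groups2, group=0)
        assert np.allclose(res2.params.to_array(), res1.params.to_array(), atol=1e-3)
        ok = np.abs(np.diag(res1.covariance)) > 1e-12
        ratio = np.diag(res2.covariance)[ok] / np.diag(res1.covariance)[ok]
        assert np.allclose(ratio, 0.5, rtol=0.05)

    def test_fit_result_json_round_trip(self, tmp_path):
        ds, groups, _ = _simulated_cell(n=1000, seed=2)
        res = fit(ds, sex="male", group_of=groups, group=0)
        path = tmp_path / "fit.json"
        res.to_json(path)
        from healthspan.transition_model import FitResult

        back = FitResult.from_json(path)
        assert np.allclose(back.params.to_array(), res.params.to_array())
        assert np.allclose(back.covariance, res.covariance)
        assert back.converged == res.converged
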