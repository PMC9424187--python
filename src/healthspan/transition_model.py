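"""Age-parameterised multinomial-logit step matrices and the interval likelihood.

The model is a discrete-time illness-death Markov chain with recovery: two
living states (non-disabled ``nd``, disabled ``dis``) and an absorbing
``dead`` state, stepped on a monthly clock.  For a transient state *i* at age
*x* (years) the per-step probability of moving to *j* is a multinomial logit

    p_ij(x) = exp(a_ij + b_ij x) / (1 + sum_k exp(a_ik + b_ik x)),

with the retention probability p_ii taking the remaining mass.  The four
modelled transitions are nd->dis (incidence), dis->nd (recovery), nd->dead
and dis->dead, each with an intercept and a linear age slope: eight free
parameters per fitted stratum.

Panel data observe the state only at annual waves; death months are known
exactly; emigration right-censors.  The interval likelihood therefore chains
per-month step matrices between observations (integrating over the
unobserved path), in the style of interpolated-Markov-chain (IMaCh)
estimation, and is maximised by quasi-Newton iteration separately for each
sex x exposure group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import fractional_matrix_power
from scipy.optimize import minimize
from statsmodels.tools.numdiff import approx_hess

from .panel_data import EventKind, PanelDataset, Sex, State

__all__ = [
    "ABSENT",
    "PARAM_NAMES",
    "TransitionParams",
    "FitResult",
    "step_matrix",
    "step_matrices",
    "interval_log_likelihood",
    "fit",
    "observed_transition_counts",
]

#: Sentinel intercept encoding a structurally absent transition (odds e^-50).
ABSENT = -50.0

#: Canonical parameter order used by every array interface in this module.
PARAM_NAMES = (
    "a_nd_dis", "b_nd_dis",
    "a_nd_dead", "b_nd_dead",
    "a_dis_nd", "b_dis_nd",
    "a_dis_dead", "b_dis_dead",
)

#: State indices: rows/columns of every 3x3 matrix.
ND, DIS, DEAD = 0, 1, 2
_STATE_INDEX = {State.nondisabled.value: ND, State.disabled.value: DIS}

#: Elementary step of the latent clock, in years (one month).
MONTH = 1.0 / 12.0

#: Age at which logits are centred internally during optimisation.  Pure
#: reparameterisation for conditioning; results are reported on the
#: (intercept at age 0, slope per year) scale.
_AGE_CENTER = 80.0

_TRANSITIONS = ("nd_dis", "nd_dead", "dis_nd", "dis_dead")


class LikelihoodError(ValueError):
    """An observed path has probability zero (or parameters are non-finite)."""


@dataclass(frozen=True)
class TransitionParams:
    """Intercept/slope pairs (logit scale) for the four transitions."""

    a_nd_dis: float
    b_nd_dis: float
    a_nd_dead: float
    b_nd_dead: float
    a_dis_nd: float
    b_dis_nd: float
    a_dis_dead: float
    b_dis_dead: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "TransitionParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (8,):
            raise ValueError("parameter vector must have length 8")
        if not np.all(np.isfinite(theta)):
            raise ValueError("parameters must be finite (use the -50 sentinel for absent transitions)")
        return cls(**dict(zip(PARAM_NAMES, theta.tolist())))

    def __post_init__(self) -> None:
        for n in PARAM_NAMES:
            if not np.isfinite(getattr(self, n)):
                raise ValueError(f"{n} must be finite")


def step_matrices(params: TransitionParams, ages: np.ndarray) -> np.ndarray:
    """Per-step transition matrices at each age; shape ``(len(ages), 3, 3)``.

    Rows are nd/dis/dead and sum to one; the dead row is exactly absorbing.
    Computed with log-sum-exp stabilisation so extreme logits cannot overflow.
    """
    ages = np.asarray(ages, dtype=float)
    t = params.to_array()
    out = np.zeros(ages.shape + (3, 3), dtype=float)
    for row, (k1, k2), (j1, j2) in (
        (ND, (0, 2), (DIS, DEAD)),      # from nd: logits for dis, dead
        (DIS, (4, 6), (ND, DEAD)),      # from dis: logits for nd, dead
    ):
        eta1 = t[k1] + t[k1 + 1] * ages
        eta2 = t[k2] + t[k2 + 1] * ages
        m = np.maximum(0.0, np.maximum(eta1, eta2))
        z = np.exp(-m) + np.exp(eta1 - m) + np.exp(eta2 - m)
        out[..., row, j1] = np.exp(eta1 - m) / z
        out[..., row, j2] = np.exp(eta2 - m) / z
        out[..., row, row] = np.exp(-m) / z
    out[..., DEAD, DEAD] = 1.0
    if not np.all(np.isfinite(out)):
        raise LikelihoodError(f"non-finite step matrix for parameters {t!r}")
    return out


def step_matrix(params: TransitionParams, age: float, h: float = MONTH) -> np.ndarray:
    """Single 3x3 step matrix at ``age`` (years) for a step of ``h`` years.

    The logit parameterisation defines the monthly matrix; other step sizes
    are obtained as the matrix power ``P^(12 h)`` (fractional for sub-monthly
    refinement), keeping the chain consistent across step sizes.
    """
    if not (65.0 <= age <= 115.0):
        raise ValueError(f"age {age} outside supported range [65, 115]")
    P = step_matrices(params, np.array(age))
    if abs(h - MONTH) < 1e-12:
        return P
    Q = fractional_matrix_power(P, 12.0 * h)
    Q = np.real(Q)
    Q = np.clip(Q, 0.0, 1.0)
    Q /= Q.sum(axis=1, keepdims=True)
    Q[DEAD] = (0.0, 0.0, 1.0)
    return Q


# ---------------------------------------------------------------------------
# Interval likelihood on aggregated sufficient cells
# ---------------------------------------------------------------------------

@dataclass
class _IntervalData:
    """Observation pairs aggregated into unique (age-index, gap, states) cells.

    The likelihood of an interval depends only on the start age (months), the
    number of elementary steps, and the endpoint states, so identical cells
    are collapsed with multiplicities.  ``grid0`` is the youngest age (in
    months) needed; step matrices are evaluated once per grid age per call.
    """

    grid0: int                      # age in months of grid index 0
    n_ages: int                     # grid length (covers all products needed)
    max_gap: int                    # longest interval, in steps
    # wave-pair cells: start grid index, gap, start state, end state, count
    wave_cells: np.ndarray          # (m, 5) int
    # death cells: grid index of last wave, months to death, last state, count
    death_cells: np.ndarray         # (m, 4) int
    n_obs_pairs: int = 0

    @classmethod
    def from_dataset(
        cls,
        dataset: PanelDataset,
        sex: Sex | str | None = None,
        group_of: pd.Series | None = None,
        group: object | None = None,
    ) -> "_IntervalData":
        p = dataset.participants
        mask = pd.Series(True, index=p.index)
        if sex is not None:
            sex_val = sex.value if isinstance(sex, Sex) else str(sex)
            mask &= p["sex"] == sex_val
        if group_of is not None and group is not None:
            g = pd.Series(group_of.reindex(p["id"]).to_numpy(), index=p.index)
            mask &= (g == group).fillna(False).astype(bool)
        sub = p[mask]
        ids = sub["id"].to_numpy()
        base_month = np.rint(sub["age"].to_numpy() * 12.0).astype(int)
        base_by_id = dict(zip(ids, base_month))
        keep = set(ids)

        w = dataset.waves
        w = w[w["id"].isin(keep)].sort_values(["id", "t_months"])
        e = dataset.events
        deaths = e[(e["kind"] == EventKind.death.value) & e["id"].isin(keep)]

        wave_rows: list[tuple[int, int, int, int]] = []
        last_wave: dict[str, tuple[int, int]] = {}  # id -> (t, state index)
        wid = w["id"].to_numpy()
        wt = w["t_months"].to_numpy()
        ws = np.array([_STATE_INDEX[s] for s in w["state"].to_numpy()], dtype=int)
        for i in range(len(wid)):
            pid = wid[i]
            if pid in last_wave and last_wave[pid][0] < wt[i]:
                t0, s0 = last_wave[pid]
                wave_rows.append((base_by_id[pid] + t0, wt[i] - t0, s0, ws[i]))
            last_wave[pid] = (wt[i], ws[i])

        death_rows: list[tuple[int, int, int]] = []
        for pid, m in zip(deaths["id"].to_numpy(), deaths["t_months"].to_numpy()):
            if pid not in last_wave:
                raise LikelihoodError(f"death for id {pid!r} with no prior wave observation")
            t0, s0 = last_wave[pid]
            if m <= t0:
                raise LikelihoodError(f"id {pid!r}: death month {m} not after last wave {t0}")
            death_rows.append((base_by_id[pid] + t0, int(m) - t0, s0))

        all_starts = [r[0] for r in wave_rows] + [r[0] for r in death_rows]
        grid0 = min(all_starts) if all_starts else 65 * 12
        max_gap = max([r[1] for r in wave_rows] + [r[1] for r in death_rows], default=1)
        n_ages = (max(all_starts) if all_starts else grid0) - grid0 + max_gap + 1

        def aggregate(rows: list[tuple], width: int) -> np.ndarray:
            if not rows:
                return np.zeros((0, width + 1), dtype=int)
            arr = np.asarray(rows, dtype=int)
            arr[:, 0] -= grid0
            uniq, counts = np.unique(arr, axis=0, return_counts=True)
            return np.column_stack([uniq, counts])

        return cls(
            grid0=grid0,
            n_ages=n_ages,
            max_gap=max_gap,
            wave_cells=aggregate(wave_rows, 4),
            death_cells=aggregate(death_rows, 3),
            n_obs_pairs=len(wave_rows) + len(death_rows),
        )

    def grid_ages(self) -> np.ndarray:
        return (self.grid0 + np.arange(self.n_ages)) / 12.0

    def loglik(self, params: TransitionParams) -> float:
        P = step_matrices(params, self.grid_ages())  # (n_ages, 3, 3)
        # R[k][i] = P(i) P(i+1) ... P(i+k-1); built once per evaluation with
        # k batched matmuls over the whole age grid.
        R = [np.broadcast_to(np.eye(3), P.shape).copy()]
        for k in range(1, self.max_gap + 1):
            prev = R[-1]
            nxt = np.empty_like(prev)
            m = self.n_ages - k
            nxt[:m] = prev[:m] @ P[k - 1 : k - 1 + m]
            nxt[m:] = prev[m:]  # unused tail (would index past the grid)
            R.append(nxt)
        R = np.stack(R)  # (max_gap+1, n_ages, 3, 3)

        total = 0.0
        if len(self.wave_cells):
            i, k, s0, s1, cnt = self.wave_cells.T
            probs = R[k, i, s0, s1]
            if np.any(probs <= 0.0):
                return -np.inf
            total += float(np.dot(cnt, np.log(probs)))
        if len(self.death_cells):
            i, k, s0, cnt = self.death_cells.T
            alive = R[k - 1, i, s0, :2]                      # (m, 2): P(alive in l at m-1)
            pdead = P[i + k - 1][:, :2, DEAD]                # (m, 2): death in final month
            probs = np.einsum("ml,ml->m", alive, pdead)
            if np.any(probs <= 0.0):
                return -np.inf
            total += float(np.dot(cnt, np.log(probs)))
        return total


def interval_log_likelihood(
    params: TransitionParams,
    dataset: PanelDataset,
    sex: Sex | str | None = None,
    group_of: pd.Series | None = None,
    group: object | None = None,
) -> float:
    """Log-likelihood of the panel under ``params`` for one (sex, group) cell.

    Each consecutive wave pair contributes the (s, s') entry of the product
    of monthly step matrices spanning the gap; a death at known month m after
    a wave in state s contributes the probability of being alive in either
    living state at month m-1 times that state's death probability for the
    final month.  Emigration contributes nothing beyond the last wave.
    """
    data = _IntervalData.from_dataset(dataset, sex=sex, group_of=group_of, group=group)
    return data.loglik(params)


def observed_transition_counts(
    dataset: PanelDataset,
    sex: Sex | str | None = None,
    group_of: pd.Series | None = None,
    group: object | None = None,
) -> dict[str, int]:
    """Endpoint-observable support for each transition type.

    nd->dis / dis->nd: wave pairs with those endpoint states; nd->dead /
    dis->dead: deaths whose last observed wave state was nd / dis.  Used to
    decide which transitions have enough support to be fitted.
    """
    data = _IntervalData.from_dataset(dataset, sex=sex, group_of=group_of, group=group)
    counts = dict.fromkeys(_TRANSITIONS, 0)
    for i, k, s0, s1, cnt in data.wave_cells:
        if s0 == ND and s1 == DIS:
            counts["nd_dis"] += int(cnt)
        elif s0 == DIS and s1 == ND:
            counts["dis_nd"] += int(cnt)
    for i, k, s0, cnt in data.death_cells:
        counts["nd_dead" if s0 == ND else "dis_dead"] += int(cnt)
    return counts


# ---------------------------------------------------------------------------
# Maximum likelihood fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Maximum-likelihood estimate for one sex x group cell."""

    params: TransitionParams
    loglik: float
    covariance: np.ndarray          # 8x8 on the (intercept, slope) scale
    converged: bool
    n_obs_pairs: int
    sex: str | None = None
    group: str | None = None
    dropped: tuple[str, ...] = ()   # transitions pinned to the absent sentinel
    n_iter: int = 0

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "sex": self.sex,
            "group": self.group,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_obs_pairs": self.n_obs_pairs,
            "dropped_transitions": list(self.dropped),
            "params": dict(zip(PARAM_NAMES, self.params.to_array().tolist())),
            "covariance": self.covariance.tolist(),
            "param_order": list(PARAM_NAMES),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FitResult":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            params=TransitionParams.from_array(np.array([d["params"][n] for n in PARAM_NAMES])),
            loglik=d["loglik"],
            covariance=np.asarray(d["covariance"], dtype=float),
            converged=d["converged"],
            n_obs_pairs=d["n_obs_pairs"],
            sex=d.get("sex"),
            group=d.get("group"),
            dropped=tuple(d.get("dropped_transitions", ())),
        )


#: Default initial point: every transition rare (intercept -4 at the centring
#: age), no age trend.
_INIT_INTERCEPT = -4.0

# indices of (intercept, slope) per transition in the 8-vector
_TRANS_SLOTS = {"nd_dis": (0, 1), "nd_dead": (2, 3), "dis_nd": (4, 5), "dis_dead": (6, 7)}


def _center(theta: np.ndarray) -> np.ndarray:
    out = theta.copy()
    for a, b in _TRANS_SLOTS.values():
        out[a] = theta[a] + theta[b] * _AGE_CENTER
    return out


def _uncenter(theta_c: np.ndarray) -> np.ndarray:
    out = theta_c.copy()
    for a, b in _TRANS_SLOTS.values():
        out[a] = theta_c[a] - theta_c[b] * _AGE_CENTER
    return out


def fit(
    dataset: PanelDataset,
    sex: Sex | str | None = None,
    group_of: pd.Series | None = None,
    group: object | None = None,
    min_transitions: int = 1,
    init: TransitionParams | None = None,
    maxiter: int = 500,
) -> FitResult:
    """Maximise the interval likelihood for one sex x group cell.

    Transitions with fewer than ``min_transitions`` endpoint-observable
    occurrences are pinned to the absent sentinel (intercept -50, slope 0)
    and excluded from optimisation; their covariance rows/columns are zero.
    Optimisation is quasi-Newton (L-BFGS-B) on age-centred logits; the
    covariance is the inverse of the numerically differentiated observed
    information at the optimum, transformed back to the reporting scale.
    """
    data = _IntervalData.from_dataset(dataset, sex=sex, group_of=group_of, group=group)
    if data.n_obs_pairs == 0:
        raise ValueError("no observation pairs in the requested cell")
    support = observed_transition_counts(dataset, sex=sex, group_of=group_of, group=group)
    dropped = tuple(t for t in _TRANSITIONS if support[t] < min_transitions)

    free = np.ones(8, dtype=bool)
    theta0_c = np.zeros(8)
    for t, (a, b) in _TRANS_SLOTS.items():
        theta0_c[a] = _INIT_INTERCEPT
        if t in dropped:
            free[[a, b]] = False
            theta0_c[[a, b]] = (ABSENT, 0.0)
    if init is not None:
        theta0_c = _center(init.to_array())
        for t in dropped:
            a, b = _TRANS_SLOTS[t]
            theta0_c[[a, b]] = (ABSENT, 0.0)

    def negloglik_c(x_free: np.ndarray) -> float:
        theta_c = theta0_c.copy()
        theta_c[free] = x_free
        return -data.loglik(TransitionParams.from_array(_uncenter(theta_c)))

    ll0 = -negloglik_c(theta0_c[free])
    res = minimize(
        negloglik_c,
        theta0_c[free],
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-6},
    )
    theta_c = theta0_c.copy()
    theta_c[free] = res.x
    loglik = -res.fun
    converged = bool(res.success) and loglik >= ll0 - 1e-9

    cov = np.zeros((8, 8))
    if free.any():
        try:
            H = approx_hess(res.x, negloglik_c)
            H = 0.5 * (H + H.T)
            cov_free = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov_free = np.full((free.sum(), free.sum()), np.nan)
            converged = False
        cov_c = np.zeros((8, 8))
        cov_c[np.ix_(free, free)] = cov_free
        # back-transform: a = a_c - b * center  =>  J = d(raw)/d(centred)
        J = np.eye(8)
        for a, b in _TRANS_SLOTS.values():
            J[a, b] = -_AGE_CENTER
        cov = J @ cov_c @ J.T

    return FitResult(
        params=TransitionParams.from_array(_uncenter(theta_c)),
        loglik=loglik,
        covariance=cov,
        converged=converged,
        n_obs_pairs=data.n_obs_pairs,
        sex=(sex.value if isinstance(sex, Sex) else sex),
        group=None if group is None else str(group),
        dropped=dropped,
        n_iter=int(res.nit),
    )
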