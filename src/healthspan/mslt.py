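"""Multistate life table quantities: occupancy, expectancies, bootstrap CIs.

Given fitted per-month transition matrices P(x), the chain's occupancy from
index age x0 is M_t = P(x0) P(x0+h) ... P(x0+(t-1)h), and the expected years
spent in living state j before the closure age is the trapezoid sum

    e_j(x0) = h * [ 1/2 M_0 + M_1 + ... + M_{T-1} + 1/2 M_T ]_{nd, j},

conditioning on being non-disabled at x0 (the entry cohort is
disability-free by design; a prevalence-weighted variant mixes the rows of
M_t by a supplied initial distribution).  DFLE is e_nd, duration with
disability is e_dis, and total life expectancy is their sum — exactly, since
all three use the same quadrature.

Uncertainty is propagated by a parametric bootstrap: parameter vectors are
drawn from the estimator's asymptotic normal distribution and the
expectancies recomputed per draw; intervals are percentile.  An independent
microsimulation estimator of the same integrals is provided as an oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .transition_model import DEAD, DIS, MONTH, ND, FitResult, TransitionParams, step_matrices

__all__ = [
    "LifeTableResult",
    "occupancy_curve",
    "expectancies",
    "bootstrap_ci",
    "microsim_expectancy",
]

DEFAULT_X0 = 65.0
DEFAULT_XMAX = 115.0


@dataclass
class LifeTableResult:
    """Point expectancies (years) at the index age, with optional 95% CIs."""

    x0: float
    x_max: float
    h: float
    dfle: float
    duration_disabled: float
    tle: float
    conditioning: str = "nd_at_x0"
    dfle_ci: tuple[float, float] | None = None
    duration_ci: tuple[float, float] | None = None
    tle_ci: tuple[float, float] | None = None
    occupancy: np.ndarray | None = None  # (T+1, 3, 3) products, M_0 = I

    def summary(self) -> str:
        def fmt(v: float, ci: tuple[float, float] | None) -> str:
            s = f"{v:6.2f}"
            if ci is not None:
                s += f" (95% CI {ci[0]:.2f}-{ci[1]:.2f})"
            return s

        return (
            f"at age {self.x0:.0f}: DFLE {fmt(self.dfle, self.dfle_ci)} y, "
            f"disabled {fmt(self.duration_disabled, self.duration_ci)} y, "
            f"TLE {fmt(self.tle, self.tle_ci)} y"
        )


def _monthly_grid(x0: float, x_max: float, h: float) -> tuple[np.ndarray, int]:
    T = int(round((x_max - x0) / h))
    if T < 1:
        raise ValueError("x0 must be below x_max by at least one step")
    return x0 + h * np.arange(T), T


def _step_matrices_h(params: TransitionParams, ages: np.ndarray, h: float) -> np.ndarray:
    if abs(h - MONTH) < 1e-12:
        return step_matrices(params, ages)
    # non-monthly step: fractional power of the monthly matrix at each age
    from .transition_model import step_matrix

    return np.stack([step_matrix(params, min(max(a, 65.0), 115.0), h) for a in ages])


def occupancy_curve(
    params: TransitionParams,
    x0: float = DEFAULT_X0,
    x_max: float = DEFAULT_XMAX,
    h: float = MONTH,
) -> np.ndarray:
    """Occupancy matrices M_t = prod_{u<t} P(x0 + u h); shape (T+1, 3, 3)."""
    ages, T = _monthly_grid(x0, x_max, h)
    P = _step_matrices_h(params, ages, h)
    M = np.empty((T + 1, 3, 3))
    M[0] = np.eye(3)
    for t in range(T):
        M[t + 1] = M[t] @ P[t]
    return M


def _expectancies_from_occupancy(M: np.ndarray, h: float, row_weights: np.ndarray) -> tuple[float, float]:
    w = np.ones(len(M))
    w[0] = w[-1] = 0.5
    occ = np.einsum("i,tij->tj", row_weights, M[:, :, :])  # (T+1, 3)
    e = h * (w[:, None] * occ[:, :2]).sum(axis=0)
    return float(e[ND]), float(e[DIS])


def expectancies(
    params: TransitionParams,
    x0: float = DEFAULT_X0,
    x_max: float = DEFAULT_XMAX,
    h: float = MONTH,
    conditioning: str = "nd_at_x0",
    initial_distribution: np.ndarray | None = None,
    keep_occupancy: bool = False,
) -> LifeTableResult:
    """Point DFLE / duration-with-disability / TLE at ``x0`` (years).

    ``conditioning='nd_at_x0'`` starts the chain in the non-disabled state;
    ``'prevalence_weighted'`` mixes the living-state rows of the occupancy by
    ``initial_distribution`` (a length-2 probability vector over nd/dis).
    The life table is closed at ``x_max``; a warning is raised if survival
    there is non-negligible (> 1e-4), since truncation would then be material.
    """
    if conditioning == "nd_at_x0":
        row_weights = np.array([1.0, 0.0, 0.0])
    elif conditioning == "prevalence_weighted":
        if initial_distribution is None:
            raise ValueError("prevalence_weighted conditioning requires initial_distribution")
        d = np.asarray(initial_distribution, dtype=float)
        if d.shape != (2,) or not np.isclose(d.sum(), 1.0):
            raise ValueError("initial_distribution must be a length-2 probability vector")
        row_weights = np.array([d[0], d[1], 0.0])
    else:
        raise ValueError(f"unknown conditioning {conditioning!r}")

    M = occupancy_curve(params, x0, x_max, h)
    surv = float(row_weights @ M[-1] @ np.array([1.0, 1.0, 0.0]))
    if surv > 1e-4:
        warnings.warn(
            f"survival {surv:.2e} at closure age {x_max}: truncation may be material",
            RuntimeWarning,
            stacklevel=2,
        )
    e_nd, e_dis = _expectancies_from_occupancy(M, h, row_weights)
    return LifeTableResult(
        x0=x0,
        x_max=x_max,
        h=h,
        dfle=e_nd,
        duration_disabled=e_dis,
        tle=e_nd + e_dis,
        conditioning=conditioning,
        occupancy=M if keep_occupancy else None,
    )


# ---------------------------------------------------------------------------
# Batched expectancies over many parameter vectors (used by the bootstrap)
# ---------------------------------------------------------------------------

def _expectancies_batch(
    thetas: np.ndarray,
    x0: float,
    x_max: float,
    h: float,
    row_weights: np.ndarray,
) -> np.ndarray:
    """(B, 2) array of (e_nd, e_dis) for a batch of 8-vectors; monthly h only."""
    if abs(h - MONTH) > 1e-12:
        raise ValueError("batched expectancies support the monthly step only")
    ages, T = _monthly_grid(x0, x_max, h)
    B = thetas.shape[0]
    # logits: (B, 4, T) for nd->dis, nd->dead, dis->nd, dis->dead
    a = thetas[:, 0::2][:, :, None]
    b = thetas[:, 1::2][:, :, None]
    eta = a + b * ages[None, None, :]
    P = np.zeros((B, T, 3, 3))
    for row, (i1, i2), (j1, j2) in ((ND, (0, 1), (DIS, DEAD)), (DIS, (2, 3), (ND, DEAD))):
        e1, e2 = eta[:, i1, :], eta[:, i2, :]
        m = np.maximum(0.0, np.maximum(e1, e2))
        z = np.exp(-m) + np.exp(e1 - m) + np.exp(e2 - m)
        P[:, :, row, j1] = np.exp(e1 - m) / z
        P[:, :, row, j2] = np.exp(e2 - m) / z
        P[:, :, row, row] = np.exp(-m) / z
    P[:, :, DEAD, DEAD] = 1.0

    w = np.ones(T + 1)
    w[0] = w[-1] = 0.5
    v = np.broadcast_to(row_weights, (B, 3)).copy()  # occupancy row at t
    acc = w[0] * v
    for t in range(T):
        v = np.einsum("bi,bij->bj", v, P[:, t])
        acc = acc + w[t + 1] * v
    return h * acc[:, :2]


def bootstrap_ci(
    fit: FitResult,
    B: int = 1000,
    seed: int | None = None,
    x0: float = DEFAULT_X0,
    x_max: float = DEFAULT_XMAX,
    h: float = MONTH,
    conditioning: str = "nd_at_x0",
    initial_distribution: np.ndarray | None = None,
) -> LifeTableResult:
    """Percentile parametric-bootstrap 95% CIs for the expectancy triple.

    Draws ``B`` parameter vectors from N(theta_hat, covariance), recomputes
    the expectancies per draw, and takes the 2.5th/97.5th percentiles.  A
    covariance that is not positive semi-definite is repaired by clipping
    negative eigenvalues at zero (with a warning) unless the repair distance
    is large, which is refused.  Parameters pinned at the absent sentinel
    have zero variance and stay pinned in every draw.
    """
    if not fit.converged:
        raise ValueError("refusing to bootstrap from a non-converged fit")
    if B < 1:
        raise ValueError("B must be >= 1")
    point = expectancies(
        fit.params, x0, x_max, h, conditioning=conditioning, initial_distribution=initial_distribution
    )

    cov = 0.5 * (fit.covariance + fit.covariance.T)
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval.min() < -1e-8 * max(eigval.max(), 1.0):
        scale = float(np.abs(eigval).max())
        if eigval.min() < -1e-3 * max(scale, 1.0):
            raise ValueError(f"covariance far from PSD (min eigenvalue {eigval.min():.3g})")
        warnings.warn("covariance repaired to nearest PSD", RuntimeWarning, stacklevel=2)
    eigval = np.clip(eigval, 0.0, None)
    L = eigvec * np.sqrt(eigval)

    rng = np.random.default_rng(seed)
    draws = fit.params.to_array()[None, :] + rng.standard_normal((B, 8)) @ L.T

    if conditioning == "nd_at_x0":
        row_weights = np.array([1.0, 0.0, 0.0])
    else:
        d = np.asarray(initial_distribution, dtype=float)
        row_weights = np.array([d[0], d[1], 0.0])
    e = _expectancies_batch(draws, x0, x_max, h, row_weights)
    dfle, dur = e[:, 0], e[:, 1]
    tle = dfle + dur

    def pct(v: np.ndarray) -> tuple[float, float]:
        return (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))

    return replace(point, dfle_ci=pct(dfle), duration_ci=pct(dur), tle_ci=pct(tle))


# ---------------------------------------------------------------------------
# Microsimulation oracle
# ---------------------------------------------------------------------------

def microsim_expectancy(
    params: TransitionParams,
    x0: float = DEFAULT_X0,
    x_max: float = DEFAULT_XMAX,
    h: float = MONTH,
    N: int = 100_000,
    seed: int | None = None,
) -> dict[str, float]:
    """Monte-Carlo estimate of the expectancy triple by simulating N lives.

    Each trajectory starts non-disabled at ``x0`` and steps through the same
    per-step matrices as the matrix-product calculation; time in each living
    state uses the identical trapezoid convention, so the two estimators
    target exactly the same integral.  Returns means with standard errors
    (sample SD / sqrt(N)).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    ages, T = _monthly_grid(x0, x_max, h)
    P = _step_matrices_h(params, ages, h)
    rng = np.random.default_rng(seed)

    states = np.zeros(N, dtype=np.int8)  # all start nd
    time_nd = np.full(N, 0.5 * h)        # trapezoid: state at t=0 is nd
    time_dis = np.zeros(N)
    for t in range(T):
        alive = states != DEAD
        if not alive.any():
            break
        u = rng.random(N)
        cum = P[t].cumsum(axis=1)
        new = (u[alive, None] > cum[states[alive], :2]).sum(axis=1).astype(np.int8)
        states[alive] = new
        wt = h if t < T - 1 else 0.5 * h
        time_nd += wt * (states == ND)
        time_dis += wt * (states == DIS)

    dfle = float(time_nd.mean())
    dur = float(time_dis.mean())
    tot = time_nd + time_dis
    return {
        "dfle": dfle,
        "duration_disabled": dur,
        "tle": float(tot.mean()),
        "dfle_se": float(time_nd.std(ddof=1) / np.sqrt(N)) if N > 1 else 0.0,
        "duration_se": float(time_dis.std(ddof=1) / np.sqrt(N)) if N > 1 else 0.0,
        "tle_se": float(tot.std(ddof=1) / np.sqrt(N)) if N > 1 else 0.0,
    }
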