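"""Discrete-distribution solvers for 5-point rating scales.

Process-evaluation reports typically print three summaries per Likert item:
the mean, the SD, and the share responding at or above the scale midpoint.
:func:`solve_likert_marginal` inverts these into an actual distribution over
the codes 1–5.  The three summaries over-determine the shape only partially
(four constraints, five probabilities), so the solver picks the maximum-
entropy distribution among exact matches.  Printed triples are sometimes
jointly infeasible — rounded sample statistics need not be moments of any
5-point law — in which case the non-strict solver matches the mean and the
tail mass exactly and brings the SD as close as the scale allows.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq, linprog, minimize
from scipy.special import expit

from .errors import InfeasibleMomentsError

_CODES = np.arange(1.0, 6.0)
_TOL = 1e-9


def _constraint_system(mean: float, sd: float, p_ge3: float):
    A = np.vstack([
        np.ones(5),
        _CODES,
        _CODES ** 2,
        (_CODES >= 3).astype(float),
    ])
    b = np.array([1.0, mean, mean ** 2 + sd ** 2, p_ge3])
    return A, b


def solve_likert_marginal(
    mean: float, sd: float, p_ge3: float, strict: bool = False
) -> np.ndarray:
    """Return probabilities over codes 1–5 matching (mean, SD, P(>=3)).

    With ``strict=True`` an exact match is required and
    :class:`InfeasibleMomentsError` is raised when none exists.  With
    ``strict=False`` the mean and tail mass are always matched exactly and
    the squared-SD gap is minimised (zero whenever the triple is feasible).
    """
    if not 1.0 <= mean <= 5.0:
        raise ValueError(f"mean {mean} outside the 1-5 scale")
    if not 0.0 <= p_ge3 <= 1.0:
        raise ValueError(f"tail mass {p_ge3} is not a probability")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    A, b = _constraint_system(mean, sd, p_ge3)

    feasibility = linprog(np.zeros(5), A_eq=A, b_eq=b, bounds=[(0, 1)] * 5)
    if feasibility.status == 0:
        p = _max_entropy(A, b, start=feasibility.x)
        if np.abs(A @ p - b).max() <= _TOL:
            return p
        return feasibility.x  # LP vertex: exact, less smooth
    if strict:
        raise InfeasibleMomentsError(
            f"no 5-point distribution has mean={mean}, sd={sd}, P(>=3)={p_ge3}"
        )

    # Exact on sum/mean/tail; least-squares on the second moment.
    A3, b3 = A[[0, 1, 3]], b[[0, 1, 3]]
    start = linprog(np.zeros(5), A_eq=A3, b_eq=b3, bounds=[(0, 1)] * 5)
    if start.status != 0:
        raise InfeasibleMomentsError(
            f"no 5-point distribution has mean={mean} and P(>=3)={p_ge3}"
        )
    m2 = b[2]
    res = minimize(
        lambda p: (p @ A[2] - m2) ** 2,
        start.x,
        jac=lambda p: 2.0 * (p @ A[2] - m2) * A[2],
        constraints=[{"type": "eq", "fun": lambda p: A3 @ p - b3,
                      "jac": lambda p: A3}],
        bounds=[(0, 1)] * 5,
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-16},
    )
    p = np.clip(res.x, 0.0, None)
    if np.abs(A3 @ p - b3).max() > _TOL:
        raise InfeasibleMomentsError(
            f"solver failed on mean={mean}, sd={sd}, P(>=3)={p_ge3}"
        )
    return p


def _max_entropy(A: np.ndarray, b: np.ndarray, start: np.ndarray) -> np.ndarray:
    def negentropy(p: np.ndarray) -> float:
        q = np.clip(p, 1e-300, 1.0)
        return float(np.sum(q * np.log(q)))

    res = minimize(
        negentropy,
        np.clip(start, 1e-6, 1.0),
        constraints=[{"type": "eq", "fun": lambda p: A @ p - b, "jac": lambda p: A}],
        bounds=[(0, 1)] * 5,
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    return np.clip(res.x, 0.0, None)


def moments_of(p: np.ndarray) -> tuple[float, float, float]:
    """(mean, SD, P(>=3)) of a distribution over codes 1–5."""
    p = np.asarray(p, dtype=float)
    mean = float(p @ _CODES)
    var = float(p @ _CODES ** 2 - mean ** 2)
    return mean, float(np.sqrt(max(var, 0.0))), float(p[2:].sum())


def conditional_cutpoints(
    marginal: np.ndarray, exposure_rate: float, log_odds: float
) -> np.ndarray:
    """Cutpoints of a two-group cumulative-logit model reproducing a marginal.

    For a binary exposure with prevalence ``exposure_rate`` and a common
    log-odds shift ``log_odds`` (exposed participants shifted toward higher
    categories), solve the four cutpoints ``theta_k`` such that the mixture

        (1 - rate) * expit(theta_k) + rate * expit(theta_k - log_odds)

    equals the marginal CDF at k, for k = 1..4.  The marginal of the
    generated outcome then matches ``marginal`` exactly while the
    exposed/unexposed contrast has odds ratio exp(log_odds).
    """
    marginal = np.asarray(marginal, dtype=float)
    if marginal.shape != (5,):
        raise ValueError("marginal must have 5 categories")
    if not 0.0 <= exposure_rate <= 1.0:
        raise ValueError("exposure_rate is not a probability")
    cdf = np.cumsum(marginal)[:4]
    cutpoints = np.empty(4)
    for k, target in enumerate(cdf):
        if target <= 0.0:
            cutpoints[k] = -40.0
            continue
        if target >= 1.0:
            cutpoints[k] = 40.0
            continue
        mixture = lambda t: ((1.0 - exposure_rate) * expit(t)
                             + exposure_rate * expit(t - log_odds) - target)
        cutpoints[k] = brentq(mixture, -60.0, 60.0, xtol=1e-12)
    return cutpoints


def group_category_probs(cutpoints: np.ndarray, log_odds: float) -> np.ndarray:
    """Category probabilities (rows: unexposed, exposed) implied by
    cumulative-logit cutpoints with a binary shift."""
    cutpoints = np.asarray(cutpoints, dtype=float)
    probs = np.empty((2, 5))
    for row, shift in enumerate((0.0, log_odds)):
        cdf = np.concatenate([expit(cutpoints - shift), [1.0]])
        probs[row] = np.diff(np.concatenate([[0.0], cdf]))
    return np.clip(probs, 0.0, 1.0)
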