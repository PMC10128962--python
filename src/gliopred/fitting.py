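"""Objective functions and bounded estimation of the 4-parameter model.

Three estimation modes are provided:

* ``fit_plain`` — minimize the classical chi-square of the residuals
  (one per measurement, each scaled by the ±1 mm measurement error),
* ``fit_constrained`` — add the ensemble-derived quadratic penalty on the
  decorrelated parameter combinations (a Gaussian/Bayesian prior), which
  makes the problem solvable with as few as 3 measurements,
* ``fit_loose`` — estimate only the pre/post-RT slopes with a continuous
  piecewise-linear fit and map the collapse speed to a regrowth time
  through the empirical power law t_min = a / v_d**b.

Both chi-square objectives are sums of squares, so minimization uses
bound-constrained trust-region least squares with an analytic Jacobian,
restarted from 8 deterministic initial points to guard against the
k–tau ridge of the exponential term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

from .constraint import ConstraintPrior, PowerLaw
from .model import FollowUp, ModelParams, radius_at

__all__ = [
    "Bounds",
    "FitResult",
    "NonConvergenceError",
    "NoCollapseError",
    "chi2",
    "chi2_constraint",
    "fit_plain",
    "fit_constrained",
    "fit_piecewise_linear",
    "fit_loose",
]

# objective values closer than this are treated as ties (smallest tau wins)
_TIE_TOL = 1e-9


class NonConvergenceError(RuntimeError):
    """Every multi-start failed; ``best`` carries the best point found."""

    def __init__(self, message: str, best: Optional[ModelParams] = None):
        super().__init__(message)
        self.best = best


class NoCollapseError(RuntimeError):
    """The fitted post-RT slope shows no shrinkage; no prediction possible."""


@dataclass(frozen=True)
class Bounds:
    """Box bounds on (R0, v, k, tau).

    Defaults: strict positivity (1e-6 lower) everywhere, the physiological
    radial-speed range v in [0.5, 4] mm/yr, and loose caps R0, k <= 100 mm,
    tau <= 20 yr.
    """

    lower: Tuple[float, float, float, float] = (1e-6, 0.5, 1e-6, 1e-6)
    upper: Tuple[float, float, float, float] = (100.0, 4.0, 100.0, 20.0)

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.lower), np.asarray(self.upper)
        if not np.all(lo < hi):
            raise ValueError("lower bounds must be strictly below upper bounds")
        if np.any(lo < 0):
            raise ValueError("all lower bounds must be >= 0")

    def arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.lower, float), np.asarray(self.upper, float)

    def clip(self, theta: np.ndarray) -> np.ndarray:
        lo, hi = self.arrays()
        eps = 1e-10 + 1e-8 * (hi - lo)
        return np.clip(theta, lo + eps, hi - eps)


@dataclass(frozen=True)
class FitResult:
    params: ModelParams
    objective_value: float
    mode: str  # "plain" | "constrained" | "loose"
    converged: bool
    n_points: int


def chi2(params: ModelParams, fu: FollowUp) -> float:
    """Classical objective: sum of squared residuals over sigma^2."""
    if len(fu) == 0:  # pragma: no cover - FollowUp forbids this
        raise ValueError("empty follow-up")
    res = (fu.radii - radius_at(params, fu.times)) / fu.sigma
    return float(np.sum(res**2))


def chi2_constraint(params: ModelParams, prior: ConstraintPrior) -> float:
    """Quadratic penalty on the decorrelated combinations X = T @ p.

    Infinite component sigmas disable the corresponding component
    (the penalty degenerates to the plain fit when all are infinite).
    """
    x = prior.T @ params.as_array()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - prior.mu) / prior.sigma
        z = np.where(np.isinf(prior.sigma), 0.0, z)
    return float(np.sum(z**2))


# ---------------------------------------------------------------------------
# residuals / Jacobian for trust-region least squares


def _model_and_jac(theta: np.ndarray, t: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    R0, v, k, tau = theta
    tpos = np.maximum(t, 0.0)
    e = np.exp(-tpos / tau)
    decay = 1.0 - e  # zero for t < 0
    r = R0 + v * t - k * decay
    jac = np.empty((t.size, 4))
    jac[:, 0] = 1.0
    jac[:, 1] = t
    jac[:, 2] = -decay
    jac[:, 3] = k * e * tpos / tau**2
    return r, jac


def _residual_funcs(fu: FollowUp, prior: Optional[ConstraintPrior]):
    t, robs, sig = fu.times, fu.radii, fu.sigma
    if prior is not None:
        finite = ~np.isinf(prior.sigma)
        T = prior.T[finite]
        mu = prior.mu[finite]
        psig = prior.sigma[finite]

    def fun(theta):
        r, _ = _model_and_jac(theta, t)
        res = (r - robs) / sig
        if prior is None or T.size == 0:
            return res
        return np.concatenate([res, (T @ theta - mu) / psig])

    def jac(theta):
        _, j = _model_and_jac(theta, t)
        j = j / sig
        if prior is None or T.size == 0:
            return j
        return np.vstack([j, T / psig[:, None]])

    return fun, jac


def _multistarts(fu: FollowUp, bounds: Bounds) -> np.ndarray:
    """8 deterministic starts: R0 from the radius nearest RT start,
    v in {0.5, 1, 2, 4}, paired (k, tau) in {(0.25*R0, 0.3), (0.75*R0, 1.5)}."""
    i0 = int(np.argmin(np.abs(fu.times)))
    r0 = fu.radii[i0]
    starts = [
        [r0, v0, kf * r0, tau0]
        for v0 in (0.5, 1.0, 2.0, 4.0)
        for kf, tau0 in ((0.25, 0.3), (0.75, 1.5))
    ]
    return np.array([bounds.clip(np.asarray(s, float)) for s in starts])


def _minimize(fu: FollowUp, prior: Optional[ConstraintPrior], bounds: Bounds, mode: str) -> FitResult:
    fun, jac = _residual_funcs(fu, prior)
    lo, hi = bounds.arrays()
    best = None
    any_ok = False
    for x0 in _multistarts(fu, bounds):
        try:
            sol = least_squares(
                fun, x0, jac=jac, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        obj = float(2.0 * sol.cost)  # cost is 0.5 * sum(residuals^2)
        ok = sol.status > 0
        any_ok = any_ok or ok
        cand = (obj, float(sol.x[3]), sol.x, ok)
        if best is None:
            best = cand
        elif obj < best[0] - _TIE_TOL:
            best = cand
        elif abs(obj - best[0]) <= _TIE_TOL and cand[1] < best[1]:
            best = cand  # tie: report the smallest tau
    if best is None:
        raise NonConvergenceError("all multi-starts raised", best=None)
    params = ModelParams.from_array(best[2])
    if not any_ok:
        raise NonConvergenceError("no multi-start converged", best=params)
    return FitResult(
        params=params,
        objective_value=best[0],
        mode=mode,
        converged=best[3],
        n_points=len(fu),
    )


def fit_plain(fu: FollowUp, bounds: Optional[Bounds] = None) -> FitResult:
    """Bound-constrained minimizer of the classical chi-square.

    Requires at least 4 measurements (one per free parameter); ideally they
    span both sides of RT. Sparser follow-ups need ``fit_constrained``.
    """
    if len(fu) < 4:
        raise ValueError(
            f"plain fit needs >= 4 points, got {len(fu)}; use fit_constrained"
        )
    return _minimize(fu, None, bounds or Bounds(), "plain")


def fit_constrained(
    fu: FollowUp, prior: ConstraintPrior, bounds: Optional[Bounds] = None
) -> FitResult:
    """Minimize chi2 + chi2_constraint; solvable with as few as 1 point."""
    return _minimize(fu, prior, bounds or Bounds(), "constrained")


def fit_piecewise_linear(fu: FollowUp) -> Tuple[float, float, float]:
    """Joint least-squares fit of the continuous piecewise-linear model.

    R(t) = R0 + v*t for t < 0 and R0 + (v - v_d)*t for t >= 0, sharing the
    intercept at t = 0 (a single linear problem in (R0, v, v_d); two
    independent regressions would be underdetermined with 1–2 post-RT
    points). Requires >= 2 points with t <= 0 and >= 2 with t > 0.
    """
    if fu.n_pre < 2 or fu.n_post < 2:
        raise ValueError(
            "piecewise-linear fit needs >= 2 pre-RT and >= 2 post-RT points"
        )
    t = fu.times
    A = np.column_stack([np.ones_like(t), t, -np.maximum(t, 0.0)])
    beta, *_ = np.linalg.lstsq(A, fu.radii, rcond=None)
    return float(beta[0]), float(beta[1]), float(beta[2])


def fit_loose(fu: FollowUp, powerlaw: PowerLaw | Tuple[float, float]) -> float:
    """Loose-constraint regrowth-time estimate (years).

    Fits only the linear terms of the model (pre/post slopes), then maps
    the collapse speed through the empirical power law t_min = a / v_d**b.

    Raises :class:`NoCollapseError` when the fitted v_d is <= 0.
    """
    a, b = (powerlaw.a, powerlaw.b) if isinstance(powerlaw, PowerLaw) else powerlaw
    _, _, v_d = fit_piecewise_linear(fu)
    if v_d <= 1e-9:  # non-positive up to lstsq round-off
        raise NoCollapseError(f"fitted collapse speed {v_d:.3g} <= 0: tumor not shrinking")
    return float(a / v_d**b)
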