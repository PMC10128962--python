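"""Statistical prior built from an ensemble of fitted patients.

The fitted (R0, v, k, tau) of different patients are strongly correlated
(notably v with k, linking pre-RT growth to the RT response). To use that
information as a prior, the raw-parameter sample covariance is
diagonalized; its eigenvector matrix T maps parameters onto decorrelated
combinations X = T @ p whose marginal distributions are approximately
Gaussian. The prior stores T together with the component means and
standard deviations, and optionally the empirical power law relating the
collapse speed v_d = k/tau to the regrowth time, t_min = a / v_d**b,
used by the loose-constraint estimator.

Conventions (the source data leaves both open): eigenvectors are ordered
by decreasing eigenvalue, and each row's sign is fixed so that its
largest-magnitude entry is positive.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
from scipy.optimize import curve_fit

from .model import ParamEnsemble

__all__ = [
    "PowerLaw",
    "ConstraintPrior",
    "DegenerateEnsembleError",
    "pearson_correlations",
    "build_prior",
    "leave_one_out_prior",
    "fit_powerlaw",
    "save_prior",
    "load_prior",
]

logger = logging.getLogger(__name__)


class DegenerateEnsembleError(ValueError):
    """The ensemble covariance is (numerically) rank deficient."""


@dataclass(frozen=True)
class PowerLaw:
    """t_min = a / v_d**b, with a in yr*(mm/yr)**b and b dimensionless."""

    a: float
    b: float


@dataclass(frozen=True)
class ConstraintPrior:
    """Decorrelation transform plus per-component Gaussian statistics.

    T rows are eigenvectors of the ensemble covariance of the raw
    parameters; mu/sigma are the sample mean and SD of each component of
    X = T @ p over the source ensemble. Component sigmas may be 0 (a
    degenerate, exactly-pinned component, useful for synthetic sampling)
    or +inf (component disabled in the penalty).
    """

    T: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    source_ids: Tuple[str, ...] = ()
    powerlaw: Optional[PowerLaw] = None

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if T.shape != (4, 4) or mu.shape != (4,) or sigma.shape != (4,):
            raise ValueError("prior must have a 4x4 T and length-4 mu, sigma")
        if not np.allclose(T @ T.T, np.eye(4), atol=1e-8):
            raise ValueError("T must be orthogonal (T @ T.T = I to 1e-8)")
        if np.any(sigma < 0) or np.any(np.isnan(sigma)):
            raise ValueError("component sigmas must be >= 0")
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "source_ids", tuple(self.source_ids))

    def transform(self, p: np.ndarray) -> np.ndarray:
        """Map raw parameters to decorrelated components, X = T @ p."""
        return self.T @ np.asarray(p, dtype=float)

    def inverse(self, x: np.ndarray) -> np.ndarray:
        """Map components back to raw parameters, p = T.T @ X."""
        return self.T.T @ np.asarray(x, dtype=float)


def pearson_correlations(ens: ParamEnsemble) -> np.ndarray:
    """4x4 Pearson correlation matrix of (R0, v, k, tau) across patients."""
    if len(ens) < 3:
        raise ValueError("need >= 3 entries for correlations")
    return np.corrcoef(ens.to_array().T)


def build_prior(ens: ParamEnsemble, powerlaw: Optional[PowerLaw] = None) -> ConstraintPrior:
    """Diagonalize the raw-parameter covariance and fit component Gaussians.

    mu_i/sigma_i are the sample mean and SD (ddof=1) of x_i = (T @ p)_i over
    the ensemble — the maximum-likelihood Gaussian fit, free of the binning
    a histogram fit would introduce.
    """
    if len(ens) < 5:
        raise ValueError("need >= 5 entries to build a prior")
    P = ens.to_array()
    cov = np.cov(P.T, ddof=1)
    w, V = np.linalg.eigh(cov)
    if w[0] <= 1e-12 * w[-1]:
        raise DegenerateEnsembleError(
            f"covariance is rank deficient (eigenvalues {w})"
        )
    order = np.argsort(w)[::-1]
    T = V[:, order].T
    # deterministic sign: largest-magnitude entry of each row positive
    for i in range(4):
        if T[i, np.argmax(np.abs(T[i]))] < 0:
            T[i] = -T[i]
    X = P @ T.T
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=1)
    return ConstraintPrior(
        T=T, mu=mu, sigma=sigma, source_ids=ens.patient_ids, powerlaw=powerlaw
    )


def leave_one_out_prior(ens: ParamEnsemble, excluded: str) -> ConstraintPrior:
    """Prior rebuilt with one patient held out (for unbiased validation)."""
    reduced = ens.without(excluded)
    if len(reduced) < 5:
        raise ValueError("fewer than 5 entries remain after exclusion")
    return build_prior(reduced)


def fit_powerlaw(ens: ParamEnsemble, method: str = "direct") -> PowerLaw:
    """Fit t_min = a / v_d**b across the ensemble.

    method="direct" (default): unweighted nonlinear least squares in linear
    space, seeded by the log-log solution. method="loglog": ordinary least
    squares of ln(t_min) on ln(v_d).

    Entries with non-finite t_min or v_d <= 0 are skipped (count logged).
    """
    P = ens.to_array()
    v_d = P[:, 2] / P[:, 3]
    t_min = ens.t_min_values()
    keep = np.isfinite(t_min) & (t_min > 0) & (v_d > 0)
    skipped = int(np.sum(~keep))
    if skipped:
        logger.warning("fit_powerlaw: skipped %d entries without a finite t_min", skipped)
    v_d, t_min = v_d[keep], t_min[keep]
    if v_d.size < 3:
        raise ValueError("need >= 3 usable entries for the power-law fit")
    slope, intercept = np.polyfit(np.log(v_d), np.log(t_min), 1)
    a0, b0 = float(np.exp(intercept)), float(-slope)
    if method == "loglog":
        return PowerLaw(a0, b0)
    if method != "direct":
        raise ValueError(f"unknown method {method!r}")
    popt, _ = curve_fit(lambda v, a, b: a / v**b, v_d, t_min, p0=[a0, b0])
    return PowerLaw(float(popt[0]), float(popt[1]))


# ---------------------------------------------------------------------------
# serialization (JSON; lossless at double precision)


def save_prior(prior: ConstraintPrior, path: Union[str, Path]) -> None:
    payload = {
        "T": [[float(x) for x in row] for row in prior.T],
        "mu": [float(x) for x in prior.mu],
        "sigma": [float(x) for x in prior.sigma],
        "source_ids": list(prior.source_ids),
        "powerlaw": (
            None if prior.powerlaw is None
            else {"a": prior.powerlaw.a, "b": prior.powerlaw.b}
        ),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_prior(path: Union[str, Path]) -> ConstraintPrior:
    payload = json.loads(Path(path).read_text())
    pl = payload.get("powerlaw")
    return ConstraintPrior(
        T=np.array(payload["T"], dtype=float),
        mu=np.array(payload["mu"], dtype=float),
        sigma=np.array(payload["sigma"], dtype=float),
        source_ids=tuple(payload.get("source_ids", ())),
        powerlaw=None if pl is None else PowerLaw(float(pl["a"]), float(pl["b"])),
    )
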