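"""Monte-Carlo virtual-patient studies and truncated-follow-up validation.

A virtual patient is a parameter vector treated as ground truth. Noisy
radii are simulated at a prescribed MRI schedule, the model is re-fitted
under the ensemble prior (or the loose slope-based estimator), and the
distribution of regrowth-time estimates is summarized by its mean and
[5th, 95th] percentile interval.

Reproducibility: each study owns one seed; replicate RNG streams are
spawned deterministically by replicate index, so enlarging ``n_reps``
never reshuffles earlier replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from .constraint import ConstraintPrior, PowerLaw, build_prior, leave_one_out_prior
from .fitting import (
    Bounds,
    NoCollapseError,
    NonConvergenceError,
    fit_constrained,
    fit_loose,
    fit_plain,
)
from .model import (
    NO_SHRINKAGE,
    FollowUp,
    ModelParams,
    ParamEnsemble,
    radius_at,
    regrowth_time,
)

__all__ = [
    "MeasurementDesign",
    "PredictionDistribution",
    "UnstablePredictionError",
    "simulate_measurements",
    "mc_predict",
    "mc_predict_loose",
    "cohort_study",
    "validate_truncated",
]

SeedLike = Union[int, np.random.SeedSequence]


class UnstablePredictionError(RuntimeError):
    """More than half the replicates were degenerate; ``partial`` holds
    the distribution computed from the finite ones."""

    def __init__(self, message: str, partial: Optional["PredictionDistribution"]):
        super().__init__(message)
        self.partial = partial


@dataclass(frozen=True)
class MeasurementDesign:
    """MRI measurement times (years relative to RT start) and noise SD (mm)."""

    times: Tuple[float, ...]
    sigma: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        if len(self.times) == 0:
            raise ValueError("design needs at least one measurement time")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("design times must be strictly increasing")
        if not (self.sigma > 0):
            raise ValueError("design sigma must be > 0")

    @classmethod
    def from_months(cls, months, sigma: float = 1.0) -> "MeasurementDesign":
        return cls(tuple(m / 12.0 for m in months), sigma)

    @property
    def n_pre(self) -> int:
        return int(np.sum(np.asarray(self.times) <= 0))

    @property
    def n_post(self) -> int:
        return int(np.sum(np.asarray(self.times) > 0))


@dataclass(frozen=True)
class PredictionDistribution:
    """Monte-Carlo sample of regrowth-time estimates (years)."""

    samples: Tuple[float, ...]
    mean: float
    interval: Tuple[float, float]
    n_reps: int
    n_degenerate: int
    seed: Optional[int]

    def __post_init__(self) -> None:
        if self.n_reps != len(self.samples) + self.n_degenerate:
            raise ValueError("n_reps must equal finite samples + degenerate count")


def simulate_measurements(
    truth: ModelParams,
    design: MeasurementDesign,
    rng: np.random.Generator,
    patient_id: str = "virtual",
) -> FollowUp:
    """Noisy follow-up: model radii plus i.i.d. Gaussian(0, sigma^2) noise."""
    t = np.asarray(design.times)
    r = radius_at(truth, t) + rng.normal(0.0, design.sigma, size=t.size)
    return FollowUp(patient_id, tuple(zip(t, r)), sigma=design.sigma)


def _seed_sequence(seed: SeedLike) -> Tuple[np.random.SeedSequence, Optional[int]]:
    if isinstance(seed, np.random.SeedSequence):
        return seed, None
    return np.random.SeedSequence(int(seed)), int(seed)


def _summarize(
    samples: list, n_reps: int, n_degenerate: int, seed: Optional[int]
) -> PredictionDistribution:
    finite = np.asarray(samples, dtype=float)
    if finite.size == 0:
        raise UnstablePredictionError("no finite replicate at all", None)
    lo, hi = np.percentile(finite, [5.0, 95.0])
    dist = PredictionDistribution(
        samples=tuple(finite),
        mean=float(finite.mean()),
        interval=(float(lo), float(hi)),
        n_reps=n_reps,
        n_degenerate=n_degenerate,
        seed=seed,
    )
    if n_degenerate > 0.5 * n_reps:
        raise UnstablePredictionError(
            f"{n_degenerate}/{n_reps} degenerate replicates", dist
        )
    return dist


def mc_predict(
    truth: ModelParams,
    design: MeasurementDesign,
    prior: ConstraintPrior,
    n_reps: int = 1000,
    seed: SeedLike = 0,
    bounds: Optional[Bounds] = None,
) -> PredictionDistribution:
    """Constrained-fit Monte-Carlo prediction of the regrowth time.

    Each replicate simulates noisy measurements, minimizes
    chi2 + chi2_constraint, and records the closed-form regrowth time.
    Replicates hitting the no-shrinkage sentinel or failing to converge
    count as degenerate and are excluded from the summary.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a stable distribution")
    ss, seed_int = _seed_sequence(seed)
    children = ss.spawn(n_reps)
    samples: list = []
    n_deg = 0
    for child in children:
        rng = np.random.default_rng(child)
        fu = simulate_measurements(truth, design, rng)
        try:
            res = fit_constrained(fu, prior, bounds)
            t_min = regrowth_time(res.params)
        except NonConvergenceError:
            t_min = NO_SHRINKAGE
        if t_min is NO_SHRINKAGE:
            n_deg += 1
        else:
            samples.append(t_min)
    return _summarize(samples, n_reps, n_deg, seed_int)


def mc_predict_loose(
    truth: ModelParams,
    design: MeasurementDesign,
    powerlaw: Union[PowerLaw, Tuple[float, float]],
    n_reps: int = 1000,
    seed: SeedLike = 0,
) -> PredictionDistribution:
    """Monte-Carlo prediction with the loose slope/power-law estimator.

    Requires a design with >= 2 pre-RT (t <= 0) and >= 2 post-RT points.
    Replicates whose fitted collapse speed is <= 0 count as degenerate.
    """
    if design.n_pre < 2 or design.n_post < 2:
        raise ValueError("loose prediction needs >= 2 pre-RT and >= 2 post-RT points")
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a stable distribution")
    ss, seed_int = _seed_sequence(seed)
    children = ss.spawn(n_reps)
    samples: list = []
    n_deg = 0
    for child in children:
        rng = np.random.default_rng(child)
        fu = simulate_measurements(truth, design, rng)
        try:
            samples.append(fit_loose(fu, powerlaw))
        except NoCollapseError:
            n_deg += 1
    return _summarize(samples, n_reps, n_deg, seed_int)


def cohort_study(
    ens: ParamEnsemble,
    design: MeasurementDesign,
    prior: ConstraintPrior,
    n_reps: int = 1000,
    seed: int = 0,
    method: str = "constrained",
    powerlaw: Optional[Union[PowerLaw, Tuple[float, float]]] = None,
    bounds: Optional[Bounds] = None,
) -> pd.DataFrame:
    """Run one Monte-Carlo prediction per ensemble entry (virtual cohort).

    Returns a table with columns patient_id, truth_tmin_yr, mean_tmin_yr,
    p05_yr, p95_yr, n_degenerate, seed. Deterministic given ``seed`` (one
    independent substream per patient).
    """
    if method not in ("constrained", "loose"):
        raise ValueError(f"unknown method {method!r}")
    if method == "loose" and powerlaw is None:
        powerlaw = prior.powerlaw
        if powerlaw is None:
            raise ValueError("loose method needs a power law")
    root = np.random.SeedSequence(int(seed))
    rows = []
    for entry, child in zip(ens, root.spawn(len(ens))):
        truth_tmin = entry.t_min
        if truth_tmin is None:
            t = regrowth_time(entry.params)
            truth_tmin = math.nan if t is NO_SHRINKAGE else t
        if method == "constrained":
            dist = mc_predict(entry.params, design, prior, n_reps, seed=child, bounds=bounds)
        else:
            dist = mc_predict_loose(entry.params, design, powerlaw, n_reps, seed=child)
        rows.append(
            {
                "patient_id": entry.patient_id,
                "truth_tmin_yr": truth_tmin,
                "mean_tmin_yr": dist.mean,
                "p05_yr": dist.interval[0],
                "p95_yr": dist.interval[1],
                "n_degenerate": dist.n_degenerate,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)


def validate_truncated(
    fu: FollowUp, ens: ParamEnsemble, bounds: Optional[Bounds] = None
) -> Tuple[float, float]:
    """Compare the regrowth time from a truncated vs the full follow-up.

    The truncated estimate uses all pre-RT points (t <= 0) plus the first
    post-RT point under the constrained fit, with the prior rebuilt
    leaving this patient out of the ensemble if present (avoids mixing
    training and test data). The full estimate is the plain fit on all
    points. Returns (t_min_truncated, t_min_full); either may be NaN when
    the corresponding fit shows no shrinkage.
    """
    if fu.n_pre < 2 or fu.n_post < 1 or len(fu) < 5:
        raise ValueError(
            "truncated validation needs >= 2 pre-RT points, >= 1 post-RT point "
            "and >= 5 points in total"
        )
    if fu.patient_id in ens.patient_ids:
        prior = leave_one_out_prior(ens, fu.patient_id)
    else:
        prior = build_prior(ens)
    t = fu.times
    first_post = np.flatnonzero(t > 0)[0]
    mask = (t <= 0) | (np.arange(t.size) == first_post)
    truncated = fit_constrained(fu.subset(mask), prior, bounds)
    full = fit_plain(fu, bounds)

    def _tmin(params: ModelParams) -> float:
        val = regrowth_time(params)
        return math.nan if val is NO_SHRINKAGE else val

    return _tmin(truncated.params), _tmin(full.params)
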