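"""Synthetic virtual patients and follow-up generation.

Emulates the kind of longitudinal data the model is fitted to in the
clinic: a handful of pre-RT radius measurements on the linear growth
branch, then post-RT measurements spanning the shrink-and-regrow phase
over 1–8 years, all with ~1 mm Gaussian measurement noise. Virtual
patients are drawn from the ensemble prior (independent Gaussians in the
decorrelated basis, mapped back and rejection-sampled against the
physical bounds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .constraint import ConstraintPrior
from .fitting import Bounds
from .model import FollowUp, ModelParams, radius_at
from .montecarlo import MeasurementDesign

__all__ = ["ScheduleSpec", "SamplingError", "sample_virtual_patient",
           "generate_followup", "random_schedule"]

logger = logging.getLogger(__name__)


class SamplingError(RuntimeError):
    """Rejection budget exhausted while drawing a virtual patient."""


@dataclass(frozen=True)
class ScheduleSpec:
    """An MRI measurement schedule: explicit times, or counts and spans.

    With counts/spans, pre-RT times are evenly spread over
    [-pre_span, 0] and post-RT times over [first_post, post_span]
    (first_post defaults to 3 months). ``times`` overrides everything.
    """

    pre_count: int = 4
    pre_span: float = 1.5  # years before RT covered by pre-RT points
    post_count: int = 10
    post_span: float = 6.0  # years after RT covered by post-RT points
    sigma: float = 1.0
    first_post: float = 0.25
    times: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.times is not None:
            object.__setattr__(self, "times", tuple(float(t) for t in self.times))
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("explicit times must be strictly increasing")
            return
        if self.pre_count < 0 or self.post_count < 0:
            raise ValueError("counts must be >= 0")
        if self.pre_count + self.post_count < 1:
            raise ValueError("schedule must contain at least one measurement")
        if self.pre_span <= 0 or self.post_span <= 0:
            raise ValueError("spans must be > 0")
        if not (self.sigma > 0):
            raise ValueError("sigma must be > 0")

    def build_times(self) -> Tuple[float, ...]:
        if self.times is not None:
            return self.times
        pre = np.linspace(-self.pre_span, 0.0, self.pre_count) if self.pre_count else np.array([])
        post = (
            np.linspace(self.first_post, self.post_span, self.post_count)
            if self.post_count
            else np.array([])
        )
        return tuple(np.concatenate([pre, post]))


def random_schedule(rng: np.random.Generator, sigma: float = 1.0) -> ScheduleSpec:
    """Draw a realistic clinical schedule: 2–10 pre-RT points over up to
    ~3 years, 5–20 post-RT points spanning 1–8 years."""
    return ScheduleSpec(
        pre_count=int(rng.integers(2, 11)),
        pre_span=float(rng.uniform(0.5, 3.0)),
        post_count=int(rng.integers(5, 21)),
        post_span=float(rng.uniform(1.0, 8.0)),
        sigma=sigma,
    )


def sample_virtual_patient(
    prior: ConstraintPrior,
    bounds: Optional[Bounds] = None,
    rng: Optional[np.random.Generator] = None,
    max_attempts: int = 1000,
) -> ModelParams:
    """Draw one parameter vector from the ensemble prior.

    Components x_i ~ Gaussian(mu_i, sigma_i) independently; p = T.T @ x;
    rejected and redrawn until p satisfies the physical bounds.
    """
    bounds = bounds or Bounds()
    rng = rng or np.random.default_rng()
    if np.any(np.isinf(prior.sigma)):
        raise ValueError("cannot sample from a prior with infinite sigmas")
    lo, hi = bounds.arrays()
    for _ in range(max_attempts):
        x = prior.mu + prior.sigma * rng.standard_normal(4)
        p = prior.inverse(x)
        if np.all(p >= lo) and np.all(p <= hi):
            return ModelParams.from_array(p)
    raise SamplingError(f"no draw satisfied the bounds in {max_attempts} attempts")


def generate_followup(
    params: ModelParams,
    schedule: ScheduleSpec,
    rng: np.random.Generator,
    patient_id: str = "synthetic",
    max_redraws: int = 100,
) -> FollowUp:
    """Simulate a follow-up on the schedule's times; non-physical negative
    radii are redrawn point-wise (count logged)."""
    design = MeasurementDesign(schedule.build_times(), schedule.sigma)
    t = np.asarray(design.times)
    clean = radius_at(params, t)
    radii = clean + rng.normal(0.0, design.sigma, size=t.size)
    redraws = 0
    for i in np.flatnonzero(radii <= 0):
        for _ in range(max_redraws):
            redraws += 1
            radii[i] = clean[i] + rng.normal(0.0, design.sigma)
            if radii[i] > 0:
                break
        else:
            raise SamplingError(
                f"could not draw a positive radius at t={t[i]:.2f}"
            )
    if redraws:
        logger.debug("generate_followup: redrew %d negative radii", redraws)
    return FollowUp(patient_id, tuple(zip(t, radii)), sigma=design.sigma)
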