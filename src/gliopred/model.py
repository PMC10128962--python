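"""Analytical model of low-grade-glioma radius dynamics around radiotherapy.

The mean radiological tumor radius of a diffuse low-grade glioma grows
linearly before radiotherapy (RT). After RT (``t = 0`` is the start of the
~6-week treatment) a fraction of the tumor decays exponentially while the
residual linear growth continues, so the radius follows

    R(t) = R0 + v*t - k*(1 - exp(-t/tau))   for t >= 0
    R(t) = R0 + v*t                          for t <  0

with four patient-specific parameters: ``R0`` the radius at RT start (mm),
``v`` the asymptotic radial growth speed (mm/yr), ``k`` the amplitude of the
RT-induced decay (mm) and ``tau`` its characteristic time (yr). The death
term is null before RT, hence the piecewise (continuous) definition.

The clinically relevant derived quantity is the regrowth time: the moment
the radius reaches its post-RT minimum and the tumor resumes growing,

    t_min = tau * ln(k / (tau * v)),

defined whenever k/(tau*v) > 1; otherwise the radius never shrinks and
``regrowth_time`` returns ``None`` (the "no-shrinkage" sentinel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "ModelParams",
    "FollowUp",
    "ParamEnsemble",
    "EnsembleEntry",
    "DerivedQuantities",
    "NO_SHRINKAGE",
    "radius_at",
    "regrowth_time",
    "collapse_speed",
    "taylor_coefficients",
    "derived_quantities",
]

#: Sentinel returned by :func:`regrowth_time` when the model never shrinks.
NO_SHRINKAGE: None = None

PARAM_NAMES = ("R0", "v", "k", "tau")


@dataclass(frozen=True)
class ModelParams:
    """The 4-tuple (R0, v, k, tau) defining one tumor trajectory.

    Units: R0 and k in mm, v in mm/yr, tau in years.
    """

    R0: float
    v: float
    k: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.R0 > 0):
            raise ValueError(f"R0 must be > 0, got {self.R0}")
        if not (self.k >= 0):
            raise ValueError(f"k must be >= 0, got {self.k}")
        if not (self.tau > 0):
            raise ValueError(f"tau must be > 0, got {self.tau}")

    def as_array(self) -> np.ndarray:
        return np.array([self.R0, self.v, self.k, self.tau], dtype=float)

    @classmethod
    def from_array(cls, theta: Sequence[float]) -> "ModelParams":
        R0, v, k, tau = (float(x) for x in theta)
        return cls(R0, v, k, tau)


@dataclass(frozen=True)
class FollowUp:
    """One patient's longitudinal radius measurements.

    ``measurements`` is an ordered sequence of (t, R) pairs with t in years
    relative to RT start and R the mean radiological radius in mm. ``sigma``
    is the measurement standard deviation (the clinical ±1 mm convention).
    """

    patient_id: str
    measurements: Tuple[Tuple[float, float], ...]
    sigma: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "measurements",
            tuple((float(t), float(r)) for t, r in self.measurements),
        )
        if len(self.measurements) < 1:
            raise ValueError(f"patient {self.patient_id!r}: empty follow-up")
        t = self.times
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"patient {self.patient_id!r}: times must be strictly increasing"
            )
        if np.any(self.radii <= 0):
            raise ValueError(f"patient {self.patient_id!r}: all radii must be > 0")
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.measurements], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([r for _, r in self.measurements], dtype=float)

    @property
    def n_pre(self) -> int:
        """Number of measurements at or before RT start (t <= 0)."""
        return int(np.sum(self.times <= 0))

    @property
    def n_post(self) -> int:
        """Number of measurements strictly after RT start (t > 0)."""
        return int(np.sum(self.times > 0))

    def __len__(self) -> int:
        return len(self.measurements)

    def subset(self, mask: Sequence[bool]) -> "FollowUp":
        """Return a follow-up restricted to the measurements where mask holds."""
        kept = tuple(m for m, keep in zip(self.measurements, mask) if keep)
        return FollowUp(self.patient_id, kept, self.sigma)


@dataclass(frozen=True)
class EnsembleEntry:
    patient_id: str
    params: ModelParams
    t_min: Optional[float] = None  # tabulated regrowth time, if known


@dataclass(frozen=True)
class ParamEnsemble:
    """A set of fitted model parameters across patients."""

    entries: Tuple[EnsembleEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        if len(self.entries) < 2:
            raise ValueError("ensemble needs at least 2 entries")
        ids = [e.patient_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("patient_ids must be unique")

    @property
    def patient_ids(self) -> Tuple[str, ...]:
        return tuple(e.patient_id for e in self.entries)

    def to_array(self) -> np.ndarray:
        """(n, 4) array of raw parameters, rows ordered as stored."""
        return np.vstack([e.params.as_array() for e in self.entries])

    def t_min_values(self, recompute: bool = False) -> np.ndarray:
        """Regrowth times per entry: tabulated when present, else recomputed.

        Entries whose model never shrinks map to NaN.
        """
        out = []
        for e in self.entries:
            if e.t_min is not None and not recompute:
                out.append(e.t_min)
            else:
                t = regrowth_time(e.params)
                out.append(math.nan if t is NO_SHRINKAGE else t)
        return np.array(out, dtype=float)

    def without(self, patient_id: str) -> "ParamEnsemble":
        if patient_id not in self.patient_ids:
            raise KeyError(f"patient {patient_id!r} not in ensemble")
        return ParamEnsemble(
            tuple(e for e in self.entries if e.patient_id != patient_id)
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[EnsembleEntry]:
        return iter(self.entries)


@dataclass(frozen=True)
class DerivedQuantities:
    """Quantities derived from the quadratic expansion of the model at t=0+."""

    v_d: float  # collapse speed k/tau, mm/yr
    epsilon: float  # curvature v_d/tau, mm/yr^2
    t_min: Optional[float]  # regrowth time in years, or None (no shrinkage)


ArrayLike = Union[float, Sequence[float], np.ndarray]


def radius_at(params: ModelParams, t: ArrayLike) -> Union[float, np.ndarray]:
    """Model radius (mm) at time(s) ``t`` (years relative to RT start).

    Piecewise: purely linear growth for t < 0 (the death term is null before
    RT); linear growth plus exponential decay for t >= 0. Continuous at 0.
    """
    tt = np.asarray(t, dtype=float)
    linear = params.R0 + params.v * tt
    # decay evaluated only at t >= 0 (clipping avoids exp overflow for t << 0)
    decay = -np.expm1(-np.maximum(tt, 0.0) / params.tau)
    r = linear - params.k * decay
    if np.isscalar(t) or (isinstance(t, np.ndarray) and t.ndim == 0):
        return float(r)
    return r


def regrowth_time(params: ModelParams) -> Optional[float]:
    """Regrowth time t_min = tau*ln(k/(tau*v)), or ``None`` if never shrinking.

    The post-RT radius has a minimum only when the initial collapse speed
    k/tau exceeds the growth speed v, i.e. k/(tau*v) > 1. At equality the
    minimum sits exactly at t = 0 and 0.0 is returned.
    """
    if params.tau <= 0 or params.v <= 0:
        raise ValueError("regrowth time requires tau > 0 and v > 0")
    ratio = params.k / (params.tau * params.v)
    if ratio < 1:
        return NO_SHRINKAGE
    return params.tau * math.log(ratio)


def collapse_speed(params: ModelParams) -> float:
    """Initial post-RT shrinkage speed v_d = k/tau (mm/yr)."""
    return params.k / params.tau


def taylor_coefficients(params: ModelParams) -> Tuple[float, float, float]:
    """(constant, slope, curvature) of the model expanded at t = 0+.

    R(t) = R0 + (v - v_d)*t + eps*t^2/2 + O(t^3) with v_d = k/tau and
    eps = v_d/tau.
    """
    v_d = collapse_speed(params)
    return params.R0, params.v - v_d, v_d / params.tau


def derived_quantities(params: ModelParams) -> DerivedQuantities:
    v_d = collapse_speed(params)
    return DerivedQuantities(v_d=v_d, epsilon=v_d / params.tau, t_min=regrowth_time(params))
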