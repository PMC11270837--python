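"""In-memory data model for first-passage ensembles from biased simulations.

The survival analysis here treats each simulation as a single-barrier escape
process: a trajectory either crosses the barrier at a first-passage time
``t_i`` (an observed event) or is right-censored at its total simulated time
``T_i``.  Biased trajectories additionally carry the history of the bias
energy ``V_i(t)`` they experienced, which the estimators turn into a
rate-scaling function ``f(t)`` and its running integral
``Gamma(t) = \\int_0^t f(t') dt'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "NoDataError",
    "UnidentifiableRateError",
    "TransitionRecord",
    "BiasTrace",
    "Ensemble",
    "ScalingFunction",
    "RateEstimate",
    "EmpiricalCDF",
    "empirical_cdf",
    "survival_from_cdf",
]

_METHODS = {"unbiased", "imetad", "ktr", "eatr"}
_FITS = {"likelihood", "cdf"}


class NoDataError(ValueError):
    """Raised when an operation receives no usable data."""


class UnidentifiableRateError(NoDataError):
    """Raised when a rate cannot be identified (e.g. zero observed events)."""


@dataclass(frozen=True)
class TransitionRecord:
    """First-passage or censoring time of one trajectory.

    ``transitioned=True`` means a barrier crossing was observed at ``time``;
    ``transitioned=False`` means the trajectory ran for ``time`` without
    crossing and contributes only survival probability to the likelihood.
    Times are in the simulation time unit tau.
    """

    time: float
    transitioned: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time <= 0.0:
            raise ValueError(f"record time must be finite and > 0, got {self.time}")


@dataclass
class BiasTrace:
    """Time series of the bias energy experienced by one trajectory.

    ``times`` is a strictly increasing grid starting at 0 (tau); ``values``
    holds the instantaneous bias energy V(t) on that grid; ``beta`` is the
    inverse temperature in inverse energy units.  Between grid points the
    bias is taken piecewise-constant at the last recorded value (MetaD-style
    stepwise deposition); ``value_at(..., mode="linear")`` interpolates
    instead for densely logged traces.  Beyond the last grid point the bias
    is frozen at its final value.

    Set ``strict=False`` to skip the repulsive-bias checks (values >= 0 and
    values[0] == 0) for general inputs such as constant external biases.
    """

    times: np.ndarray
    values: np.ndarray
    beta: float = 1.0
    strict: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size == 0:
            raise NoDataError("empty bias trace")
        if self.times[0] != 0.0:
            raise ValueError("bias trace must start at t = 0")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("bias trace times must be strictly increasing")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError("beta must be positive and finite")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("bias values must be finite")
        if self.strict:
            if self.values[0] != 0.0:
                raise ValueError(
                    "no bias before the first deposition: values[0] must be 0 "
                    "(pass strict=False for general inputs)"
                )
            if np.any(self.values < 0):
                raise ValueError(
                    "repulsive bias must be >= 0 (pass strict=False to override)"
                )

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def value_at(self, t, mode: str = "previous") -> np.ndarray:
        """Bias at time(s) ``t``; frozen at the final value beyond the grid."""
        t = np.asarray(t, dtype=float)
        if mode == "previous":
            idx = np.searchsorted(self.times, t, side="right") - 1
            idx = np.clip(idx, 0, self.times.size - 1)
            return self.values[idx]
        if mode == "linear":
            return np.interp(t, self.times, self.values)
        raise ValueError(f"unknown interpolation mode {mode!r}")

    def running_max(self) -> np.ndarray:
        return np.maximum.accumulate(self.values)


@dataclass
class Ensemble:
    """A set of trajectories: transition records plus (optionally) bias traces.

    All traces must share the same inverse temperature.  Each trace must
    cover its trajectory's event/censoring time (the simulator appends the
    termination time to the deposition grid to guarantee this).
    """

    records: list[TransitionRecord]
    traces: list[BiasTrace] | None = None
    label: str = ""
    beta: float = field(default=1.0)

    def __post_init__(self) -> None:
        self.records = list(self.records)
        if len(self.records) == 0:
            raise NoDataError("an ensemble needs at least one trajectory")
        if self.traces is not None:
            self.traces = list(self.traces)
            if len(self.traces) != len(self.records):
                raise ValueError("records and traces must be parallel lists")
            betas = {t.beta for t in self.traces}
            if len(betas) > 1:
                raise ValueError(f"all traces must share one beta, got {sorted(betas)}")
            self.beta = self.traces[0].beta
            for i, (rec, tr) in enumerate(zip(self.records, self.traces)):
                if tr.duration < rec.time * (1.0 - 1e-9) - 1e-12:
                    raise ValueError(
                        f"trace {i} ends at {tr.duration} before its record "
                        f"time {rec.time}"
                    )
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError("beta must be positive and finite")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def n_transitioned(self) -> int:
        return sum(r.transitioned for r in self.records)

    @property
    def is_complete(self) -> bool:
        """True when every trajectory transitioned (M == N)."""
        return self.n_transitioned == self.n

    @property
    def times(self) -> np.ndarray:
        """Event or censoring time of every trajectory, in input order."""
        return np.array([r.time for r in self.records])

    @property
    def event_mask(self) -> np.ndarray:
        return np.array([r.transitioned for r in self.records], dtype=bool)

    def event_times(self, sort: bool = True) -> np.ndarray:
        t = self.times[self.event_mask]
        return np.sort(t) if sort else t

    def censored_times(self) -> np.ndarray:
        return self.times[~self.event_mask]

    def subset(self, indices: Sequence[int]) -> "Ensemble":
        """A new ensemble from trajectory indices (records and traces jointly)."""
        idx = list(indices)
        recs = [self.records[i] for i in idx]
        trs = None if self.traces is None else [self.traces[i] for i in idx]
        return Ensemble(recs, trs, label=self.label, beta=self.beta)


@dataclass
class ScalingFunction:
    """A rate-scaling function f(t) >= 0 with its running integral Gamma(t).

    The survival model is S(t) = exp(-k0 * Gamma(t)); with zero bias f == 1
    and Gamma(t) = t, recovering the homogeneous Poisson process.
    """

    times: np.ndarray
    f: np.ndarray
    Gamma: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        self.Gamma = np.asarray(self.Gamma, dtype=float)
        if not (self.times.shape == self.f.shape == self.Gamma.shape):
            raise ValueError("times, f and Gamma must have identical shapes")
        if self.times[0] != 0.0 or self.Gamma[0] != 0.0:
            raise ValueError("scaling function must start with t=0, Gamma=0")
        if np.any(self.f < 0):
            raise ValueError("f must be nonnegative")
        if np.any(np.diff(self.Gamma) < 0):
            raise ValueError("Gamma must be nondecreasing")

    @classmethod
    def from_f(cls, times, f, quadrature: str = "trapezoid") -> "ScalingFunction":
        times = np.asarray(times, dtype=float)
        f = np.asarray(f, dtype=float)
        return cls(times, f, cumulative_quadrature(times, f, quadrature))

    def f_at(self, t) -> np.ndarray:
        """Step (previous-value) lookup of f, frozen beyond the grid."""
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.times, t, side="right") - 1, 0, self.times.size - 1)
        return self.f[idx]

    def Gamma_at(self, t) -> np.ndarray:
        """Piecewise-linear Gamma; extrapolates with slope f[-1] beyond the grid."""
        t = np.asarray(t, dtype=float)
        out = np.interp(t, self.times, self.Gamma)
        tail = t > self.times[-1]
        if np.any(tail):
            out = np.where(tail, self.Gamma[-1] + (t - self.times[-1]) * self.f[-1], out)
        return out


def cumulative_quadrature(times: np.ndarray, f: np.ndarray, quadrature: str) -> np.ndarray:
    """Running integral of ``f`` over ``times`` (trapezoid or left rectangle)."""
    dt = np.diff(times)
    if quadrature == "trapezoid":
        seg = 0.5 * (f[:-1] + f[1:]) * dt
    elif quadrature == "rectangle":
        seg = f[:-1] * dt
    else:
        raise ValueError(f"unknown quadrature {quadrature!r}")
    return np.concatenate(([0.0], np.cumsum(seg)))


@dataclass
class RateEstimate:
    """A fitted transition rate: k0 in 1/tau, biasing efficiency gamma in [0,1].

    ``method`` names the rate-scaling model, ``fit`` how it was fitted
    (likelihood maximization or least-squares CDF fit).  ``degenerate`` is set
    when the likelihood was numerically flat in gamma (e.g. zero bias, or an
    effectively time-independent bias such as converged OPES flooding), in
    which case gamma is not meaningful on its own.
    """

    k0: float
    gamma: float
    method: str
    fit: str = "likelihood"
    loglik: float | None = None
    ks_pvalue: float | None = None
    k0_log10_err: float | None = None
    gamma_err: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k0) and self.k0 > 0):
            raise ValueError(f"k0 must be positive and finite, got {self.k0}")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {sorted(_METHODS)}")
        if self.fit not in _FITS:
            raise ValueError(f"fit must be one of {sorted(_FITS)}")

    @property
    def log10_k0(self) -> float:
        return float(np.log10(self.k0))


@dataclass
class EmpiricalCDF:
    """Right-continuous empirical CDF of observed transition times.

    Censored trajectories enter the denominator N but never the step count,
    so the CDF plateaus at M/N beyond the last event.  Ties step by k/N.
    """

    sorted_event_times: np.ndarray
    n_total: int

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        counts = np.searchsorted(self.sorted_event_times, t, side="right")
        return counts / self.n_total

    @property
    def plateau(self) -> float:
        return self.sorted_event_times.size / self.n_total


def empirical_cdf(records: Iterable[TransitionRecord]) -> EmpiricalCDF:
    """Empirical CDF: #(transitions before t) / N, censored records in N only."""
    records = list(records)
    if len(records) == 0:
        raise NoDataError("cannot build an empirical CDF from no records")
    events = np.sort([r.time for r in records if r.transitioned])
    return EmpiricalCDF(np.asarray(events, dtype=float), len(records))


def survival_from_cdf(cdf_value):
    """Survival probability S = 1 - CDF."""
    c = np.asarray(cdf_value, dtype=float)
    if np.any(c < 0) or np.any(c > 1):
        raise ValueError("CDF values must lie in [0, 1]")
    out = 1.0 - c
    return float(out) if np.isscalar(cdf_value) or out.ndim == 0 else out
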