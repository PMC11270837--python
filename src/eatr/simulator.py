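"""Ground-truth test data: 1D overdamped Langevin dynamics with optional
WT-MetaD or OPES-flooding bias on the matched-harmonic barrier potential.

The potential joins two harmonic branches of equal curvature at the midpoint
x_b = (x0+x1)/2:

    U(x) = kappa/2 (x-x0)^2                for x <  x_b
    U(x) = dU - kappa/2 (x-x1)^2           for x >= x_b

with kappa = 4 dU / (x1-x0)^2 fixed by continuity of U and U' at x_b,
U(x0) = 0 and U(x1) = dU.  With the reference parameters (x0=-3, x1=3,
dU=8 kBT, D=0.02) the Smoluchowski-limit Kramers rate is 9.49e-7 / tau.

First passage is recorded when the walker reaches an absorbing boundary on
the product side of the barrier (default x1 + 4 sqrt(kBT/kappa), where the
outer integrand of the Kramers mean-first-passage integral has converged;
absorbing exactly at the barrier top would double the rate, since the
committor there is 1/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from . import _kernels
from .model import BiasTrace, Ensemble, NoDataError, TransitionRecord

__all__ = [
    "PotentialSpec",
    "LangevinParams",
    "MetaDParams",
    "OPESParams",
    "potential_energy",
    "potential_force",
    "kramers_rate_closed",
    "kramers_rate_numeric",
    "MetaDBias",
    "OPESBias",
    "run_langevin",
    "run_ensemble",
    "sample_first_passage_times",
    "synthetic_biased_ensemble",
    "pmf_from_histogram",
    "committor_binning",
]


@dataclass(frozen=True)
class PotentialSpec:
    """Matched-harmonic barrier: well at ``x0``, barrier top at ``x1``,
    height ``dU`` (same energy units as kBT elsewhere)."""

    x0: float = -3.0
    x1: float = 3.0
    dU: float = 8.0

    def __post_init__(self) -> None:
        if not self.x0 < self.x1:
            raise ValueError("need x0 < x1")
        if self.dU < 0:
            raise ValueError("barrier height must be nonnegative")

    @property
    def xb(self) -> float:
        """Matching point from continuity of U and U' (equal curvatures)."""
        return 0.5 * (self.x0 + self.x1)

    @property
    def kappa(self) -> float:
        """Curvature of both branches, 4 dU / (x1-x0)^2."""
        return 4.0 * self.dU / (self.x1 - self.x0) ** 2

    def default_absorbing(self, kBT: float = 1.0) -> float:
        if self.kappa == 0:
            return self.x1
        return self.x1 + 4.0 * math.sqrt(kBT / self.kappa)


@dataclass(frozen=True)
class LangevinParams:
    """Overdamped (Smoluchowski) dynamics parameters.

    dt in tau, diffusion coefficient D in length^2/tau*... (reduced units:
    D = kBT/zeta with friction zeta), thermal energy kBT, the RNG seed, the
    start position (defaults to the well minimum) and the absorbing boundary
    (defaults to the converged product-side position).
    """

    dt: float = 0.01
    D: float = 0.02
    kBT: float = 1.0
    seed: int = 0
    x_init: float | None = None
    absorbing_boundary: float | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.D < 0:
            raise ValueError("D must be nonnegative")
        if self.kBT <= 0:
            raise ValueError("kBT must be positive")

    @property
    def zeta(self) -> float:
        """Friction coefficient kBT / D."""
        return self.kBT / self.D


@dataclass(frozen=True)
class MetaDParams:
    """Well-tempered MetaD: Gaussian hills of width ``sigma`` and initial
    height ``height`` every ``pace`` integration steps; ``biasfactor``
    lambda = (T+DeltaT)/T controls tempering (inf => untempered)."""

    height: float = 1.0
    sigma: float = 0.5
    pace: int = 100_000
    biasfactor: float = 2.0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.sigma <= 0:
            raise ValueError("hill height and width must be positive")
        if self.pace < 1:
            raise ValueError("pace must be >= 1 step")
        if not (self.biasfactor > 1.0):
            raise ValueError("biasfactor must exceed 1 (use inf for untempered)")

    def kb_delta_t(self, kBT: float) -> float:
        """kB*DeltaT = (lambda - 1) kBT; inf for untempered hills."""
        if math.isinf(self.biasfactor):
            return math.inf
        return (self.biasfactor - 1.0) * kBT


@dataclass(frozen=True)
class OPESParams:
    """OPES flooding: bias capped by the ``barrier`` parameter DeltaE, built
    from an on-the-fly kernel density estimate updated every ``update_pace``
    steps; no kernels are added inside ``exclusion_region``."""

    barrier: float = 4.0
    biasfactor: float = 2.0
    kernel_sigma: float = 0.5
    update_pace: int = 10_000
    exclusion_region: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.barrier <= 0:
            raise ValueError("barrier must be positive")
        if not (self.biasfactor > 1.0):
            raise ValueError("biasfactor must exceed 1")
        if self.kernel_sigma <= 0 or self.update_pace < 1:
            raise ValueError("invalid kernel parameters")

    def epsilon(self, kBT: float = 1.0) -> float:
        """epsilon = exp(-beta DeltaE / (1 - 1/lambda)); not a free knob."""
        cfac = (1.0 - 1.0 / self.biasfactor) * kBT
        return math.exp(-self.barrier / cfac)


# ---------------------------------------------------------------------------
# potential and Kramers rates

def potential_energy(spec: PotentialSpec, x):
    x = np.asarray(x, dtype=float)
    u = np.where(
        x < spec.xb,
        0.5 * spec.kappa * (x - spec.x0) ** 2,
        spec.dU - 0.5 * spec.kappa * (x - spec.x1) ** 2,
    )
    return float(u) if u.ndim == 0 else u


def potential_force(spec: PotentialSpec, x):
    x = np.asarray(x, dtype=float)
    f = np.where(x < spec.xb, -spec.kappa * (x - spec.x0), spec.kappa * (x - spec.x1))
    return float(f) if f.ndim == 0 else f


def kramers_rate_closed(spec: PotentialSpec, D: float, kBT: float = 1.0) -> float:
    """Smoluchowski-limit Kramers rate for harmonic well and barrier:
    k = D sqrt(kappa_well * kappa_barrier) / (2 pi kBT) * exp(-dU/kBT)."""
    kw = kb = spec.kappa
    return D * math.sqrt(kw * kb) / (2.0 * math.pi * kBT) * math.exp(-spec.dU / kBT)


def kramers_rate_numeric(
    spec: PotentialSpec,
    D: float,
    kBT: float = 1.0,
    x_start: float | None = None,
    x_absorb: float | None = None,
) -> float:
    """Kramers rate from the mean-first-passage double integral,

        1/k = (1/D) int_{x_start}^{x_absorb} dx e^{U(x)/kBT}
                      int_{-inf}^{x} dy e^{-U(y)/kBT},

    evaluated by adaptive quadrature.  The absorbing point defaults to the
    converged product-side boundary; agreement with the closed form is at
    the 1% level for barriers of a few kBT and better for high barriers.
    """
    beta = 1.0 / kBT
    a = spec.x0 if x_start is None else x_start
    b = spec.default_absorbing(kBT) if x_absorb is None else x_absorb
    # flat potential (dU=0): free diffusion with a reflecting wall at x0
    sig = math.sqrt(kBT / spec.kappa) if spec.kappa > 0 else 0.0
    lo = spec.x0 - 10.0 * sig

    def inner(x):
        val, err = quad(lambda y: np.exp(-beta * potential_energy(spec, y)), lo, x, limit=200)
        return val

    tau, err = quad(
        lambda x: np.exp(beta * potential_energy(spec, x)) * inner(x), a, b, limit=300
    )
    if not np.isfinite(tau) or tau <= 0 or err > 1e-6 * abs(tau):
        raise RuntimeError("Kramers quadrature did not converge")
    return D / tau


# ---------------------------------------------------------------------------
# Python-side bias engines (reference implementations of the bias formulas,
# used for fixtures and for cross-checking the compiled kernels)

class MetaDBias:
    """History-dependent Gaussian-hill bias V(xi, t) = sum_j h_j
    exp(-(xi-xi_j)^2 / 2 sigma^2), with well-tempered heights
    h_j = h * exp(-V(xi_j, t_j)/(kB DeltaT))."""

    def __init__(self, params: MetaDParams, kBT: float = 1.0):
        self.params = params
        self.kBT = kBT
        self.times: list[float] = []
        self.centers: list[float] = []
        self.heights: list[float] = []

    def value(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        v = np.zeros_like(x)
        s2 = 2.0 * self.params.sigma**2
        for c, h in zip(self.centers, self.heights):
            v = v + h * np.exp(-((x - c) ** 2) / s2)
        return float(v) if v.ndim == 0 else v

    def deposit(self, x: float, t: float) -> float:
        """Add a hill at ``x``; returns the (tempered) height actually used."""
        kbdt = self.params.kb_delta_t(self.kBT)
        h = self.params.height
        if math.isfinite(kbdt):
            h *= math.exp(-float(self.value(x)) / kbdt)
        self.times.append(t)
        self.centers.append(x)
        self.heights.append(h)
        return h


class OPESBias:
    """OPES-flooding bias from an on-the-fly kernel density estimate.

    With phat the KDE normalized by its maximum on the evaluation grid,

        V(xi) = (1 - 1/lambda) kBT * log((phat(xi)(1-eps) + eps) / eps),

    which is 0 where the KDE vanishes and exactly DeltaE at its mode, so
    sup V - inf V <= DeltaE by construction (the conventional bias formula
    up to the (1-eps) factor and an additive constant).
    """

    def __init__(self, params: OPESParams, kBT: float = 1.0,
                 grid: np.ndarray | None = None):
        self.params = params
        self.kBT = kBT
        if grid is None:
            grid = np.linspace(-10.0, 10.0, 2001)
        self.grid = np.asarray(grid, dtype=float)
        self.kde = np.zeros_like(self.grid)
        self._v = np.zeros_like(self.grid)
        self.times: list[float] = []
        self.centers: list[float] = []

    @property
    def cfac(self) -> float:
        return (1.0 - 1.0 / self.params.biasfactor) * self.kBT

    def update(self, x: float, t: float) -> bool:
        """Add a kernel at ``x`` unless excluded; returns whether it was added."""
        excl = self.params.exclusion_region
        if excl is not None and excl[0] <= x <= excl[1]:
            return False
        self.kde += np.exp(-0.5 * ((self.grid - x) / self.params.kernel_sigma) ** 2)
        eps = self.params.epsilon(self.kBT)
        phat = self.kde / self.kde.max()
        self._v = self.cfac * np.log((phat * (1.0 - eps) + eps) / eps)
        self.times.append(t)
        self.centers.append(x)
        return True

    def value(self, x) -> np.ndarray:
        out = np.interp(np.asarray(x, dtype=float), self.grid, self._v)
        return float(out) if out.ndim == 0 else out

    @property
    def bias_range(self) -> float:
        return float(self._v.max() - self._v.min())


# ---------------------------------------------------------------------------
# trajectory generation

def _bias_grid(spec: PotentialSpec, absorb: float, sigma: float):
    gx0 = spec.x0 - (spec.x1 - spec.x0)
    gx1 = absorb + 1.0
    gdx = min(sigma, 0.5) / 25.0
    ngrid = int(math.ceil((gx1 - gx0) / gdx)) + 1
    return gx0, gdx, ngrid


def run_langevin(
    spec: PotentialSpec,
    params: LangevinParams,
    bias: MetaDParams | OPESParams | None = None,
    max_time: float = 1e6,
    record_stride: int = 0,
    log_time: float = 10.0,
):
    """Integrate one walker; returns (TransitionRecord, BiasTrace, trajectory).

    The Euler-Maruyama update is x <- x + (D/kBT) F(x) dt + sqrt(2 D dt) N(0,1)
    with F = -d(U+V)/dx.  The experienced bias V(x(t), t) is logged every
    ``log_time`` tau (never sparser than one deposition interval), at every
    deposition/update and at the termination time; logged positions are kept
    on the trace (``trace.positions``) so the values can be re-derived from
    the bias engines.  ``trajectory`` is None unless ``record_stride`` > 0
    (positions every that many steps, unbiased runs only).  A fixed seed
    reproduces the trajectory bitwise.
    """
    if max_time <= 0:
        raise ValueError("max_time must be positive")
    x_init = spec.x0 if params.x_init is None else params.x_init
    absorb = (
        spec.default_absorbing(params.kBT)
        if params.absorbing_boundary is None
        else params.absorbing_boundary
    )
    max_steps = int(round(max_time / params.dt))
    common = (
        int(params.seed) % 2**32, x_init, params.dt, params.D, params.kBT,
        spec.x0, spec.x1, spec.xb, spec.kappa, absorb, max_steps,
    )
    traj = None
    if bias is None:
        t, crossed, traj_arr, err, err_step = _kernels.walk_unbiased(
            *common, int(record_stride)
        )
        if err:
            raise FloatingPointError(f"nonfinite coordinate at step {err_step}")
        trace = BiasTrace(np.array([0.0, t]), np.zeros(2), beta=1.0 / params.kBT)
        if record_stride > 0:
            traj = traj_arr
    elif isinstance(bias, MetaDParams):
        kbdt = bias.kb_delta_t(params.kBT)
        inv_kbdt = 0.0 if math.isinf(kbdt) else 1.0 / kbdt
        stride = max(1, min(int(bias.pace), int(round(log_time / params.dt))))
        gx0, gdx, ngrid = _bias_grid(spec, absorb, bias.sigma)
        (t, crossed, hill_t, hill_c, hill_h, tr_t, tr_x, tr_v, err, err_step) = (
            _kernels.walk_metad(
                *common, int(bias.pace), bias.height, bias.sigma, inv_kbdt,
                stride, gx0, gdx, ngrid,
            )
        )
        if err:
            raise FloatingPointError(f"nonfinite coordinate at step {err_step}")
        trace = BiasTrace(tr_t.copy(), tr_v.copy(), beta=1.0 / params.kBT)
        trace.positions = tr_x.copy()
        trace.hills = (hill_t.copy(), hill_c.copy(), hill_h.copy())
    elif isinstance(bias, OPESParams):
        cfac = (1.0 - 1.0 / bias.biasfactor) * params.kBT
        eps = bias.epsilon(params.kBT)
        excl = bias.exclusion_region
        has_excl = excl is not None
        lo, hi = excl if has_excl else (0.0, 0.0)
        stride = max(1, min(int(bias.update_pace), int(round(log_time / params.dt))))
        gx0, gdx, ngrid = _bias_grid(spec, absorb, bias.kernel_sigma)
        (t, crossed, kern_t, kern_c, tr_t, tr_x, tr_v, err, err_step) = (
            _kernels.walk_opes(
                *common, int(bias.update_pace), bias.kernel_sigma, cfac, eps,
                has_excl, lo, hi, stride, gx0, gdx, ngrid,
            )
        )
        if err:
            raise FloatingPointError(f"nonfinite coordinate at step {err_step}")
        trace = BiasTrace(tr_t.copy(), tr_v.copy(), beta=1.0 / params.kBT)
        trace.positions = tr_x.copy()
        trace.kernels = (kern_t.copy(), kern_c.copy())
        trace.opes_grid = (gx0, gdx, ngrid)
    else:
        raise TypeError(f"unsupported bias engine {type(bias).__name__}")
    record = TransitionRecord(time=t, transitioned=bool(crossed))
    return record, trace, traj


def run_ensemble(
    spec: PotentialSpec,
    params: LangevinParams,
    bias: MetaDParams | OPESParams | None = None,
    n: int = 100,
    max_time: float = 1e6,
    label: str = "",
    log_time: float = 10.0,
) -> Ensemble:
    """Run ``n`` independent walkers with per-walker seed streams spawned
    from ``params.seed`` (order-independent, reproducible)."""
    seeds = np.random.SeedSequence(params.seed).generate_state(n)
    records, traces = [], []
    for s in seeds:
        p = LangevinParams(
            dt=params.dt, D=params.D, kBT=params.kBT, seed=int(s),
            x_init=params.x_init, absorbing_boundary=params.absorbing_boundary,
        )
        rec, trace, _ = run_langevin(spec, p, bias=bias, max_time=max_time,
                                     log_time=log_time)
        records.append(rec)
        traces.append(trace)
    return Ensemble(records, traces, label=label)


# ---------------------------------------------------------------------------
# synthetic first-passage sampling from the survival model itself

def sample_first_passage_times(
    k0: float,
    n: int,
    rng: np.random.Generator,
    gamma: float = 1.0,
    bias_times: np.ndarray | None = None,
    bias_values: np.ndarray | None = None,
    beta: float = 1.0,
    max_time: float | None = None,
    quadrature: str = "trapezoid",
):
    """Inverse-CDF draws from S(t) = exp(-k0 Gamma(t)) under a shared bias
    schedule, Gamma(t) = int_0^t exp(gamma beta V(t')) dt'.

    Returns ``(times, transitioned)``; draws beyond ``max_time`` are
    censored there.  With no bias this is exponential sampling.
    """
    from .estimators import _exp_integral

    if k0 <= 0:
        raise ValueError("k0 must be positive")
    if bias_times is None:
        bias_times = np.array([0.0, 1.0])
        bias_values = np.zeros(2)
    bias_times = np.asarray(bias_times, dtype=float)
    s = gamma * beta * np.asarray(bias_values, dtype=float)
    end = bias_times[-1]
    g_end = _exp_integral(bias_times, s, end, quadrature, 700.0)
    slope_end = math.exp(min(s[-1], 700.0))
    targets = -np.log(rng.uniform(size=n)) / k0
    times = np.empty(n)
    for i, target in enumerate(targets):
        if target >= g_end:
            times[i] = end + (target - g_end) / slope_end
        else:
            times[i] = brentq(
                lambda t: _exp_integral(bias_times, s, t, quadrature, 700.0) - target,
                1e-12,
                end,
                xtol=1e-12,
                rtol=1e-14,
            )
    transitioned = np.ones(n, dtype=bool)
    if max_time is not None:
        late = times > max_time
        times[late] = max_time
        transitioned[late] = False
    return times, transitioned


def synthetic_biased_ensemble(
    k0: float,
    gamma: float,
    n: int,
    rng: np.random.Generator,
    bias_times: np.ndarray,
    bias_values: np.ndarray,
    beta: float = 1.0,
    max_time: float | None = None,
    quadrature: str = "trapezoid",
    label: str = "",
) -> Ensemble:
    """An ensemble whose transition times are exact draws from the
    time-dependent survival model at known (k0, gamma) under a shared bias
    schedule.

    Every trajectory carries the *full* schedule as its trace (one shared
    object), so the ensemble-averaged scaling functions reproduce the
    generating f(t) exactly; a trajectory outliving the schedule gets the
    final bias value appended at its own termination time (the same frozen
    tail the sampler assumes).
    """
    bias_times = np.asarray(bias_times, dtype=float)
    bias_values = np.asarray(bias_values, dtype=float)
    times, transitioned = sample_first_passage_times(
        k0, n, rng, gamma=gamma, bias_times=bias_times, bias_values=bias_values,
        beta=beta, max_time=max_time, quadrature=quadrature,
    )
    shared = BiasTrace(bias_times, bias_values, beta=beta, strict=False)
    records, traces = [], []
    for t, ok in zip(times, transitioned):
        records.append(TransitionRecord(time=float(t), transitioned=bool(ok)))
        if t <= bias_times[-1]:
            traces.append(shared)
        else:
            tt = np.append(bias_times, t)
            vv = np.append(bias_values, bias_values[-1])
            traces.append(BiasTrace(tt, vv, beta=beta, strict=False))
    return Ensemble(records, traces, label=label)


# ---------------------------------------------------------------------------
# free-energy and committor analysis of trajectories

def pmf_from_histogram(samples, bins=50, kBT: float = 1.0):
    """Potential of mean force -kBT log P from a normalized histogram.

    Returns ``(bin_centers, pmf)`` with the minimum shifted to zero; empty
    bins are NaN (undefined), never +/-inf.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise NoDataError("no samples")
    hist, edges = np.histogram(samples, bins=bins, density=True)
    if not np.any(hist > 0):
        raise NoDataError("all-empty histogram")
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore"):
        pmf = np.where(hist > 0, -kBT * np.log(np.where(hist > 0, hist, 1.0)), np.nan)
    pmf -= np.nanmin(pmf)
    return centers, pmf


def committor_binning(
    trajectory,
    state_a: tuple[float, float],
    state_b: tuple[float, float],
    bins=30,
):
    """Average forward committor per CV bin from a long trajectory.

    Each frame outside both states is labelled 0/1 by whichever state the
    trajectory visits next; frames after the last state visit are discarded.
    Frames inside A get 0 and inside B get 1 by convention.  Returns
    ``(bin_centers, mean committor)`` with NaN for empty bins.
    """
    x = np.asarray(trajectory, dtype=float)
    in_a = (x >= state_a[0]) & (x <= state_a[1])
    in_b = (x >= state_b[0]) & (x <= state_b[1])
    if not in_a.any() or not in_b.any():
        raise NoDataError("trajectory must visit both states")
    state_idx = np.flatnonzero(in_a | in_b)
    state_val = in_b[state_idx].astype(float)
    nxt = np.searchsorted(state_idx, np.arange(x.size), side="left")
    keep = nxt < state_idx.size
    labels = np.where(keep, state_val[np.minimum(nxt, state_idx.size - 1)], np.nan)
    x, labels = x[keep], labels[keep]
    hist_n, edges = np.histogram(x, bins=bins)
    hist_q, _ = np.histogram(x, bins=edges, weights=labels)
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(invalid="ignore"):
        q = np.where(hist_n > 0, hist_q / np.maximum(hist_n, 1), np.nan)
    return centers, q
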