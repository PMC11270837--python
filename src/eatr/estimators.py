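"""Rate estimators for time-dependent biased simulations.

All estimators share one survival model, S(t) = exp(-k0 * Gamma(t)) with
Gamma(t) = int_0^t f(t') dt', and differ only in the rate-scaling function:

* unbiased          f = 1                        (homogeneous Poisson escape)
* iMetaD            f_i(t) = exp(beta V_i(t))    per trajectory (hyperdynamics)
* KTR               f(t) = exp(gamma beta <max_{t'<=t} V_i(t')>)
* EATR              f(t) = <exp(gamma beta V_i(t))>

where <.> averages over trajectories and gamma in [0, 1] is the CV biasing
efficiency.  For each gamma the optimal rate has the closed form
k0*(gamma) = M / sum_i Gamma(tau_i), so gamma is found by maximizing the
concentrated (profile) log-likelihood with a deterministic grid scan followed
by bounded scalar refinement.  A least-squares fit of the theoretical CDF to
the empirical CDF is available as an alternative to likelihood maximization.

When every trajectory has transitioned, the EATR profile rate uses the
single-average (idempotent) form k0*(gamma) = N / sum_i int_0^{t_i}
exp(gamma beta V_i) dt, which at gamma = 1 is the very same computation as
the iMetaD estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize_scalar
from scipy.special import logsumexp

from .model import (
    BiasTrace,
    Ensemble,
    NoDataError,
    RateEstimate,
    ScalingFunction,
    TransitionRecord,
    UnidentifiableRateError,
    cumulative_quadrature,
    empirical_cdf,
)

__all__ = [
    "FitConfig",
    "CDFFitError",
    "OpesSlopeFit",
    "rate_mle_unbiased",
    "scaling_imetad",
    "rate_imetad",
    "ensemble_grid",
    "scaling_ktr",
    "scaling_eatr",
    "loglik_general",
    "rate_ktr_mle",
    "rate_eatr_mle",
    "survival_theoretical",
    "fit_cdf",
    "opes_slope_fit",
]


@dataclass(frozen=True)
class FitConfig:
    """Numerical settings shared by the likelihood and CDF fits.

    gamma_bounds        closed interval for the biasing efficiency
    gamma_grid_points   grid size of the profile-likelihood scan that seeds
                        the bounded scalar optimizer (makes gamma
                        deterministic even for flat/multi-modal likelihoods)
    quadrature          "trapezoid" (default) or "rectangle" (left rule,
                        exact for stepwise MetaD bias) for int f dt
    max_exponent        cap applied to gamma*beta*V exponents before
                        exponentiation (overflow guard)
    optimizer_tolerance relative tolerance on fitted parameters
    tail                how ensemble averages treat trajectories past their
                        own termination: "riskset" (average over the
                        still-running trajectories; default) or "freeze"
                        (keep them with their final bias value).  The
                        freeze variant underestimates the late-time scaling
                        when escapes are spread over the bias growth.
    """

    gamma_bounds: tuple[float, float] = (0.0, 1.0)
    gamma_grid_points: int = 41
    quadrature: str = "trapezoid"
    max_exponent: float = 700.0
    optimizer_tolerance: float = 1e-8
    tail: str = "riskset"

    def __post_init__(self) -> None:
        lo, hi = self.gamma_bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("gamma_bounds must satisfy 0 <= lo < hi <= 1")
        if self.gamma_grid_points < 3:
            raise ValueError("gamma_grid_points must be >= 3")
        if self.quadrature not in ("trapezoid", "rectangle"):
            raise ValueError("quadrature must be 'trapezoid' or 'rectangle'")
        if self.optimizer_tolerance <= 0:
            raise ValueError("optimizer_tolerance must be > 0")
        if self.tail not in ("riskset", "freeze"):
            raise ValueError("tail must be 'riskset' or 'freeze'")


_DEFAULT = FitConfig()


class CDFFitError(RuntimeError):
    """CDF fit failed to converge; ``fallback`` carries the LM estimate."""

    def __init__(self, message: str, fallback: RateEstimate):
        super().__init__(message)
        self.fallback = fallback


# ---------------------------------------------------------------------------
# quadrature helpers

def _exp_integral(times, exponent, upto, quadrature, max_exponent, strict=True):
    """int_0^upto exp(exponent(t)) dt with exponent sampled on ``times``.

    Rectangle mode treats the exponent as previous-value steps; trapezoid
    mode interpolates the exponent linearly within the partial segment.
    Beyond the grid the integrand is frozen at its last value (or an error
    is raised when ``strict``).
    """
    times = np.asarray(times, dtype=float)
    s = np.minimum(np.asarray(exponent, dtype=float), max_exponent)
    if upto <= 0:
        raise ValueError("integration endpoint must be positive")
    e = np.exp(s)
    end = times[-1]
    tail = 0.0
    if upto > end:
        if strict and upto > end * (1.0 + 1e-9) + 1e-12:
            raise ValueError(f"bias grid ends at {end} before requested time {upto}")
        tail = (upto - end) * e[-1]
        upto = end
    j = int(np.searchsorted(times, upto, side="right")) - 1
    dt = np.diff(times[: j + 1])
    if quadrature == "rectangle":
        val = float(np.dot(e[:j], dt))
        val += e[j] * (upto - times[j])
    elif quadrature == "trapezoid":
        val = float(np.dot(0.5 * (e[:j] + e[1 : j + 1]), dt))
        rem = upto - times[j]
        if rem > 0:
            frac = rem / (times[j + 1] - times[j])
            s_u = s[j] + (s[j + 1] - s[j]) * frac
            val += 0.5 * (e[j] + np.exp(min(s_u, max_exponent))) * rem
    else:
        raise ValueError(f"unknown quadrature {quadrature!r}")
    return val + tail


def _exp_integral_many(times, exponent, upto, quadrature, max_exponent):
    """Vectorized int_0^{u} exp(exponent(t)) dt for an array of endpoints
    ``upto`` sharing one (times, exponent) grid; frozen beyond the grid."""
    times = np.asarray(times, dtype=float)
    s = np.minimum(np.asarray(exponent, dtype=float), max_exponent)
    u = np.asarray(upto, dtype=float)
    e = np.exp(s)
    cum = cumulative_quadrature(times, e, quadrature)
    uc = np.minimum(u, times[-1])
    j = np.clip(np.searchsorted(times, uc, side="right") - 1, 0, times.size - 2)
    # endpoints exactly on the last node land in the final segment with rem=0
    rem = uc - times[j]
    if quadrature == "rectangle":
        partial = e[j] * rem
    else:
        dt = times[j + 1] - times[j]
        frac = np.where(dt > 0, rem / np.where(dt > 0, dt, 1.0), 0.0)
        s_u = np.minimum(s[j] + (s[j + 1] - s[j]) * frac, max_exponent)
        partial = 0.5 * (e[j] + np.exp(s_u)) * rem
    tail = np.where(u > times[-1], (u - times[-1]) * e[-1], 0.0)
    return cum[j] + partial + tail


def _group_traces(ensemble: Ensemble):
    """Group trajectory indices by identical BiasTrace objects.

    Bootstrap resamples and shared-schedule synthetic ensembles repeat trace
    objects; evaluating each unique trace once makes the ensemble averages
    and per-trajectory integrals cheap without changing their values.
    """
    groups: dict[int, list[int]] = {}
    order: list[BiasTrace] = []
    for i, tr in enumerate(ensemble.traces):
        key = id(tr)
        if key not in groups:
            groups[key] = []
            order.append(tr)
        groups[key].append(i)
    return order, [groups[id(tr)] for tr in order]


def _per_trajectory_sum(ensemble: Ensemble, gamma: float, config: FitConfig) -> float:
    """sum_i int_0^{tau_i} exp(gamma beta V_i(t)) dt over all trajectories."""
    times = ensemble.times
    total = 0.0
    for tr, idx in zip(*_group_traces(ensemble)):
        vals = _exp_integral_many(
            tr.times,
            gamma * (tr.beta * tr.values),
            times[idx],
            config.quadrature,
            config.max_exponent,
        )
        total += float(vals.sum())
    return total


# ---------------------------------------------------------------------------
# unbiased and iMetaD estimators

def rate_mle_unbiased(records: Sequence[TransitionRecord]) -> RateEstimate:
    """Censored-exponential MLE: k0 = M / (sum of all event/censoring times).

    With no censoring this is the inverse mean first-passage time.
    """
    records = list(records)
    if len(records) == 0:
        raise NoDataError("no records")
    m = sum(r.transitioned for r in records)
    if m == 0:
        raise UnidentifiableRateError("no observed transitions: rate unidentifiable")
    total = sum(r.time for r in records)
    k0 = m / total
    loglik = m * np.log(k0) - k0 * total
    return RateEstimate(k0=k0, gamma=1.0, method="unbiased", fit="likelihood", loglik=loglik)


def scaling_imetad(trace: BiasTrace, upto: float, config: FitConfig = _DEFAULT):
    """Hyperdynamics rescaling of one trajectory.

    Returns ``(alpha, rescaled_time)`` with rescaled_time =
    int_0^upto exp(beta V(t)) dt and alpha = rescaled_time / upto (>= 1 for
    nonnegative bias).  Raises if the trace does not cover ``upto``.
    """
    rescaled = _exp_integral(
        trace.times,
        trace.beta * trace.values,
        upto,
        config.quadrature,
        config.max_exponent,
    )
    return rescaled / upto, rescaled


def _per_trajectory_alphas(ensemble: Ensemble, config: FitConfig) -> np.ndarray:
    """Overall acceleration factor of each trajectory over its own lifetime."""
    times = ensemble.times
    alphas = np.empty(ensemble.n)
    for tr, idx in zip(*_group_traces(ensemble)):
        vals = _exp_integral_many(
            tr.times, tr.beta * tr.values, times[idx],
            config.quadrature, config.max_exponent,
        )
        alphas[idx] = vals / times[idx]
    return alphas


def _require_traces(ensemble: Ensemble) -> None:
    if ensemble.traces is None:
        raise NoDataError("this estimator needs bias traces")


def rate_imetad(ensemble: Ensemble, config: FitConfig = _DEFAULT) -> RateEstimate:
    """iMetaD estimator: k0 = M / sum_i int_0^{tau_i} exp(beta V_i) dt.

    With M = N this is the standard rescaled-time estimator; censored
    trajectories are handled through the general likelihood, which leaves the
    closed form intact (their rescaled censoring times join the denominator).
    """
    _require_traces(ensemble)
    m = ensemble.n_transitioned
    if m == 0:
        raise UnidentifiableRateError("no observed transitions: rate unidentifiable")
    denom = _per_trajectory_sum(ensemble, 1.0, config)
    k0 = m / denom
    ll = -k0 * denom + m * np.log(k0)
    for rec, tr in zip(ensemble.records, ensemble.traces):
        if rec.transitioned:
            ll += min(tr.beta * float(tr.value_at(rec.time)), config.max_exponent)
    return RateEstimate(k0=k0, gamma=1.0, method="imetad", fit="likelihood", loglik=float(ll))


# ---------------------------------------------------------------------------
# ensemble-level scaling functions (KTR / EATR)

def ensemble_grid(ensemble: Ensemble, max_points: int = 20_000) -> np.ndarray:
    """Union of all trace grids and all event/censoring times (plus t = 0).

    Densely logged ensembles are thinned to about ``max_points`` evenly
    spaced nodes to bound memory; the event/censoring times (and t = 0) are
    always kept exactly.
    """
    _require_traces(ensemble)
    traces, _ = _group_traces(ensemble)
    parts = [tr.times for tr in traces]
    parts.append(ensemble.times)
    parts.append(np.array([0.0]))
    grid = np.unique(np.concatenate(parts))
    if grid.size > max_points:
        keep = grid[np.linspace(0, grid.size - 1, max_points).astype(int)]
        grid = np.unique(np.concatenate([keep, ensemble.times, [0.0]]))
    return grid


def _bias_matrix(ensemble: Ensemble, grid: np.ndarray, running_max: bool = False):
    """beta * V_i on ``grid`` for every *unique* trace, with multiplicities.

    Previous-value lookup on each trace grid; after a trace ends its bias is
    frozen at the final recorded value (running max: at the final maximum).
    Returns ``(rows, weights)`` with sum(weights) == ensemble.n; repeated
    trace objects (bootstrap resamples, shared schedules) are evaluated once.
    """
    traces, members = _group_traces(ensemble)
    rows = np.empty((len(traces), grid.size))
    weights = np.empty(len(traces))
    for i, (tr, idx) in enumerate(zip(traces, members)):
        vals = tr.running_max() if running_max else tr.values
        j = np.clip(np.searchsorted(tr.times, grid, side="right") - 1, 0, tr.times.size - 1)
        rows[i] = tr.beta * vals[j]
        weights[i] = len(idx)
    return rows, weights


def _average_weights(ensemble: Ensemble, grid: np.ndarray, config: FitConfig):
    """Per-unique-trace weight of the ensemble average on each grid time.

    "riskset": each trajectory counts only while still running (tau_i >= t);
    "freeze": every trajectory counts at all times (bias frozen at its
    final recorded value through the trace lookup).  Returns (W, total)
    with W of shape (n_unique, n_grid).
    """
    _, members = _group_traces(ensemble)
    if config.tail == "freeze":
        w = np.array([len(m) for m in members], dtype=float)
        total = np.full(grid.size, ensemble.n, dtype=float)
        return np.repeat(w[:, None], grid.size, axis=1), total
    times = ensemble.times
    rows = np.empty((len(members), grid.size))
    for u, idx in enumerate(members):
        taus = np.sort(times[idx])
        rows[u] = taus.size - np.searchsorted(taus, grid, side="left")
    return rows, rows.sum(axis=0)


def _forward_fill_tail(values: np.ndarray, total: np.ndarray) -> np.ndarray:
    """Past the last time with a nonempty risk set, hold the last value."""
    empty = total == 0
    if np.any(empty):
        last = int(np.argmax(empty)) - 1
        values = values.copy()
        values[empty] = values[max(last, 0)]
    return values


def _ktr_exponent(ensemble, grid, config):
    rows, _ = _bias_matrix(ensemble, grid, running_max=True)
    w, total = _average_weights(ensemble, grid, config)
    safe = np.maximum(total, 1.0)
    return _forward_fill_tail((w * rows).sum(axis=0) / safe, total)


def _eatr_log_mean(rows, w, total, gamma):
    """log <exp(gamma * beta V)> with the weighted (possibly empty) average."""
    safe = np.maximum(total, 1.0)
    with np.errstate(divide="ignore"):
        logf = logsumexp(gamma * rows, axis=0, b=w / safe[None, :])
    return _forward_fill_tail(logf, total)


def scaling_ktr(
    ensemble: Ensemble,
    gamma: float,
    grid: np.ndarray | None = None,
    config: FitConfig = _DEFAULT,
) -> ScalingFunction:
    """KTR scaling: f(t) = exp(gamma * beta * <max_{t'<=t} V_i(t')>)."""
    _check_gamma(gamma, config)
    if grid is None:
        grid = ensemble_grid(ensemble)
    a = _ktr_exponent(ensemble, grid, config)
    f = np.exp(np.minimum(gamma * a, config.max_exponent))
    return ScalingFunction.from_f(grid, f, config.quadrature)


def scaling_eatr(
    ensemble: Ensemble,
    gamma: float,
    grid: np.ndarray | None = None,
    config: FitConfig = _DEFAULT,
) -> ScalingFunction:
    """EATR scaling: f(t) = <exp(gamma * beta * V_i(t))> (log-sum-exp guarded)."""
    _check_gamma(gamma, config)
    if grid is None:
        grid = ensemble_grid(ensemble)
    rows, _ = _bias_matrix(ensemble, grid)
    w, total = _average_weights(ensemble, grid, config)
    logf = _eatr_log_mean(rows, w, total, gamma)
    f = np.exp(np.minimum(logf, config.max_exponent))
    return ScalingFunction.from_f(grid, f, config.quadrature)


def _check_gamma(gamma: float, config: FitConfig) -> None:
    lo, hi = config.gamma_bounds
    if not (lo - 1e-12 <= gamma <= hi + 1e-12):
        raise ValueError(f"gamma={gamma} outside bounds {config.gamma_bounds}")


# ---------------------------------------------------------------------------
# general censored log-likelihood

def loglik_general(
    ensemble: Ensemble,
    scaling: ScalingFunction | Sequence[ScalingFunction],
    k0: float,
) -> float:
    """Censored log-likelihood of the inhomogeneous escape model.

    sum_events [log k0 + log f(t_i) - k0 Gamma(t_i)] - sum_censored k0 Gamma(T_i).
    ``scaling`` is either one ensemble-level ScalingFunction or a list of
    per-trajectory ones (iMetaD).  With f == 1 this is the censored
    exponential log-likelihood.
    """
    if not (np.isfinite(k0) and k0 > 0):
        raise ValueError("k0 must be positive")
    per_traj = not isinstance(scaling, ScalingFunction)
    if per_traj and len(scaling) != ensemble.n:
        raise ValueError("need one scaling function per trajectory")
    ll = 0.0
    for i, rec in enumerate(ensemble.records):
        sf = scaling[i] if per_traj else scaling
        g = float(sf.Gamma_at(rec.time))
        if rec.transitioned:
            ll += np.log(k0) + np.log(float(sf.f_at(rec.time))) - k0 * g
        else:
            ll -= k0 * g
    return float(ll)


# ---------------------------------------------------------------------------
# profile-likelihood optimization over gamma

def _grid_indices(grid: np.ndarray, times: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(grid, times)
    if not np.allclose(grid[idx], times):
        raise AssertionError("record times missing from evaluation grid")
    return idx


def _profile_estimate(
    k0_ell: Callable[[float], tuple[float, float]],
    config: FitConfig,
    gamma: float | None,
    method: str,
) -> RateEstimate:
    """Maximize a concentrated log-likelihood over gamma (grid scan + bounded
    refinement); deterministic by construction.  Sets ``degenerate`` when the
    scan variation is below tolerance."""
    if gamma is not None:
        _check_gamma(gamma, config)
        k0, ell = k0_ell(gamma)
        return RateEstimate(k0=k0, gamma=float(gamma), method=method, loglik=ell)

    lo, hi = config.gamma_bounds
    gs = np.linspace(lo, hi, config.gamma_grid_points)
    ells = np.array([k0_ell(g)[1] for g in gs])
    spread = float(ells.max() - ells.min())
    degenerate = spread < config.optimizer_tolerance * (1.0 + abs(float(ells.max())))
    i = int(np.argmax(ells))
    g_best, ell_best = gs[i], ells[i]
    if not degenerate:
        a, b = gs[max(i - 1, 0)], gs[min(i + 1, gs.size - 1)]
        if b > a:
            res = minimize_scalar(
                lambda g: -k0_ell(g)[1],
                bounds=(a, b),
                method="bounded",
                options={"xatol": max(config.optimizer_tolerance, 1e-10)},
            )
            if res.success and -res.fun >= ell_best:
                g_best, ell_best = float(res.x), float(-res.fun)
    k0, ell = k0_ell(g_best)
    return RateEstimate(
        k0=k0, gamma=float(g_best), method=method, loglik=ell, degenerate=degenerate
    )


def rate_ktr_mle(
    ensemble: Ensemble,
    config: FitConfig = _DEFAULT,
    gamma: float | None = None,
) -> RateEstimate:
    """KTR maximum-likelihood estimate of (k0, gamma).

    For each gamma the rate concentrates to k0*(gamma) = M / sum_i
    Gamma(tau_i); the concentrated log-likelihood is then maximized over
    gamma (pass ``gamma`` to fix it instead).
    """
    _require_traces(ensemble)
    m = ensemble.n_transitioned
    if m == 0:
        raise UnidentifiableRateError("no observed transitions")
    grid = ensemble_grid(ensemble)
    a = _ktr_exponent(ensemble, grid, config)
    idx = _grid_indices(grid, ensemble.times)
    ev = ensemble.event_mask

    def k0_ell(g: float) -> tuple[float, float]:
        lf = np.minimum(g * a, config.max_exponent)
        gam = cumulative_quadrature(grid, np.exp(lf), config.quadrature)
        total = float(gam[idx].sum())
        k0 = m / total
        ell = m * np.log(k0) + float(lf[idx[ev]].sum()) - m
        return k0, float(ell)

    return _profile_estimate(k0_ell, config, gamma, "ktr")


def rate_eatr_mle(
    ensemble: Ensemble,
    config: FitConfig = _DEFAULT,
    gamma: float | None = None,
) -> RateEstimate:
    """EATR maximum-likelihood estimate of (k0, gamma).

    With every trajectory transitioned the profile rate uses the idempotent
    single-average form k0*(gamma) = N / sum_i int_0^{t_i} exp(gamma beta
    V_i) dt — at gamma = 1 this is computation-for-computation the iMetaD
    estimator — while the gamma dependence of the likelihood keeps the
    ensemble-averaged scaling (without that average the likelihood carries no
    gamma information).  With censoring the general concentrated MLE
    k0*(gamma) = M / sum_i Gamma(tau_i) is used.
    """
    _require_traces(ensemble)
    m = ensemble.n_transitioned
    if m == 0:
        raise UnidentifiableRateError("no observed transitions")
    n = ensemble.n
    grid = ensemble_grid(ensemble)
    rows, _ = _bias_matrix(ensemble, grid)
    w, total = _average_weights(ensemble, grid, config)
    idx = _grid_indices(grid, ensemble.times)
    ev = ensemble.event_mask
    complete = ensemble.is_complete

    def k0_ell(g: float) -> tuple[float, float]:
        lf = np.minimum(_eatr_log_mean(rows, w, total, g), config.max_exponent)
        gam = cumulative_quadrature(grid, np.exp(lf), config.quadrature)
        if complete:
            k0 = n / _per_trajectory_sum(ensemble, g, config)
            ell = n * np.log(k0) + float(lf[idx].sum()) - k0 * float(gam[idx].sum())
        else:
            denom = float(gam[idx].sum())
            k0 = m / denom
            ell = m * np.log(k0) + float(lf[idx[ev]].sum()) - m
        return k0, float(ell)

    return _profile_estimate(k0_ell, config, gamma, "eatr")


# ---------------------------------------------------------------------------
# theoretical survival functions and CDF fitting

def survival_theoretical(
    ensemble: Ensemble,
    method: str,
    k0: float,
    gamma: float = 1.0,
    config: FitConfig = _DEFAULT,
) -> Callable[[np.ndarray], np.ndarray]:
    """Model survival function S(t) for the given method and parameters.

    unbiased: exp(-k0 t); iMetaD: <exp(-k0 alpha_i t)> averaged over
    trajectories with each one's overall acceleration factor alpha_i;
    KTR/EATR: exp(-k0 Gamma(t; gamma)).  The returned callable is
    vectorized, equals 1 at t <= 0 and is nonincreasing.
    """
    if not (np.isfinite(k0) and k0 > 0):
        raise ValueError("k0 must be positive")
    if method == "unbiased":
        return lambda t: np.exp(-k0 * np.clip(np.asarray(t, dtype=float), 0.0, None))
    _require_traces(ensemble)
    if method == "imetad":
        # each trajectory contributes one exponential component with its own
        # overall acceleration alpha_i = (1/t_i) int_0^{t_i} exp(beta V_i) dt
        alphas = _per_trajectory_alphas(ensemble, config)

        def s_imetad(t):
            t = np.clip(np.atleast_1d(np.asarray(t, dtype=float)), 0.0, None)
            return np.exp(-k0 * np.outer(alphas, t)).mean(axis=0)

        return s_imetad
    if method in ("ktr", "eatr"):
        builder = scaling_ktr if method == "ktr" else scaling_eatr
        sf = builder(ensemble, gamma, config=config)
        return lambda t: np.exp(-k0 * sf.Gamma_at(np.clip(np.asarray(t, dtype=float), 0.0, None)))
    raise ValueError(f"unknown method {method!r}")


def _lm_estimate(ensemble, method, config, gamma):
    if method == "unbiased":
        return rate_mle_unbiased(ensemble.records)
    if method == "imetad":
        return rate_imetad(ensemble, config)
    if method == "ktr":
        return rate_ktr_mle(ensemble, config, gamma=gamma)
    if method == "eatr":
        return rate_eatr_mle(ensemble, config, gamma=gamma)
    raise ValueError(f"unknown method {method!r}")


def fit_cdf(
    ensemble: Ensemble,
    method: str,
    config: FitConfig = _DEFAULT,
    gamma: float | None = None,
) -> RateEstimate:
    """Least-squares fit of the theoretical CDF to the empirical CDF.

    Residuals are evaluated at the observed event times only (dense regions
    of the distribution weight themselves naturally).  Initial guesses come
    from the matching likelihood estimate; k0 is fitted in log10 and gamma
    within its bounds (for unbiased/iMetaD, or with ``gamma`` given, only k0
    is free).  Raises :class:`CDFFitError` carrying the LM fallback on
    non-convergence.
    """
    t_ev = ensemble.event_times()
    if np.unique(t_ev).size < 2:
        raise NoDataError("CDF fitting needs at least two distinct event times")
    lm = _lm_estimate(ensemble, method, config, gamma)
    f_emp = empirical_cdf(ensemble.records)(t_ev)
    free_gamma = method in ("ktr", "eatr") and gamma is None
    lo, hi = config.gamma_bounds

    # precompute the gamma-independent pieces once; the least-squares loop
    # then only re-exponentiates and re-integrates
    if method == "unbiased":
        theo = lambda k0, g: 1.0 - np.exp(-k0 * t_ev)
    elif method == "imetad":
        alphas = _per_trajectory_alphas(ensemble, config)

        def theo(k0, g):
            return 1.0 - np.exp(-k0 * np.outer(alphas, t_ev)).mean(axis=0)

    elif method in ("ktr", "eatr"):
        grid = ensemble_grid(ensemble)
        idx_ev = _grid_indices(grid, t_ev)
        if method == "ktr":
            a = _ktr_exponent(ensemble, grid, config)
            log_f = lambda g: np.minimum(g * a, config.max_exponent)
        else:
            rows, _ = _bias_matrix(ensemble, grid)
            w, total = _average_weights(ensemble, grid, config)
            log_f = lambda g: np.minimum(
                _eatr_log_mean(rows, w, total, g), config.max_exponent
            )

        def theo(k0, g):
            gam = cumulative_quadrature(grid, np.exp(log_f(g)), config.quadrature)
            return 1.0 - np.exp(-k0 * gam[idx_ev])

    else:
        raise ValueError(f"unknown method {method!r}")

    if free_gamma:
        x0 = [lm.log10_k0, float(np.clip(lm.gamma, lo, hi))]
        bounds = ([-30.0, lo], [30.0, hi])
        resid = lambda x: theo(10.0 ** x[0], x[1]) - f_emp
    else:
        g_fix = 1.0 if gamma is None else float(gamma)
        x0 = [lm.log10_k0]
        bounds = ([-30.0], [30.0])
        resid = lambda x: theo(10.0 ** x[0], g_fix) - f_emp

    res = least_squares(
        resid,
        x0,
        bounds=bounds,
        method="trf",
        xtol=config.optimizer_tolerance,
        ftol=config.optimizer_tolerance,
        gtol=None,
    )
    if not res.success:
        raise CDFFitError(f"CDF fit did not converge: {res.message}", fallback=lm)
    k0_fit = 10.0 ** float(res.x[0])
    g_fit = float(res.x[1]) if free_gamma else (1.0 if gamma is None else float(gamma))
    ll = _loglik_at(ensemble, method, k0_fit, g_fit, config)
    return RateEstimate(
        k0=k0_fit,
        gamma=g_fit,
        method=method,
        fit="cdf",
        loglik=ll,
        degenerate=lm.degenerate,
    )


def _loglik_at(ensemble, method, k0, gamma, config) -> float:
    """Eq-10 style log-likelihood at explicit (k0, gamma)."""
    if method == "unbiased":
        m = ensemble.n_transitioned
        return float(m * np.log(k0) - k0 * ensemble.times.sum())
    if method == "imetad":
        ll = -k0 * _per_trajectory_sum(ensemble, 1.0, config)
        for rec, tr in zip(ensemble.records, ensemble.traces):
            if rec.transitioned:
                ll += np.log(k0) + min(tr.beta * float(tr.value_at(rec.time)), config.max_exponent)
        return float(ll)
    builder = scaling_ktr if method == "ktr" else scaling_eatr
    sf = builder(ensemble, gamma, config=config)
    return loglik_general(ensemble, sf, k0)


# ---------------------------------------------------------------------------
# OPES-slope fit

@dataclass(frozen=True)
class OpesSlopeFit:
    """Result of the slope fit across ensembles with different bias plateaus.

    The observed rate of each ensemble is modelled as
    log k_obs = log k0 + gamma * beta * vbar, so the weighted-regression
    intercept gives k0 and the slope gives gamma.
    """

    k0: float
    gamma: float
    k0_log10_err: float
    gamma_err: float
    bias_measures: np.ndarray
    observed_rates: np.ndarray


def _trace_measure(trace: BiasTrace, kind: str) -> float:
    if kind == "plateau_max":
        return float(trace.values.max())
    if kind == "time_average":
        if trace.times[-1] == 0:
            return float(trace.values[0])
        return float(np.trapezoid(trace.values, trace.times) / trace.times[-1])
    raise ValueError("bias_measure must be 'plateau_max' or 'time_average'")


def opes_slope_fit(
    ensembles: Sequence[Ensemble],
    bias_measure: str = "plateau_max",
    config: FitConfig = _DEFAULT,
) -> OpesSlopeFit:
    """Fit (k0, gamma) from how the observed rate scales with the bias level.

    For effectively time-independent biases (converged OPES flooding) the
    likelihood is flat in gamma; instead, each ensemble run at a different
    barrier parameter contributes one observed rate k_obs (unbiased MLE on
    the raw transition times) and one scalar bias measure vbar (ensemble
    average of the per-trajectory plateau maximum or time-averaged bias).
    A weighted linear regression of log k_obs on beta*vbar (weights = number
    of events) yields gamma (slope, clipped to bounds) and k0 (intercept).
    """
    import statsmodels.api as sm

    ensembles = list(ensembles)
    if len(ensembles) < 3:
        raise NoDataError("slope fit needs at least 3 ensembles")
    x, y, w = [], [], []
    for ens in ensembles:
        _require_traces(ens)
        vbar = float(np.mean([_trace_measure(tr, bias_measure) for tr in ens.traces]))
        x.append(ens.beta * vbar)
        y.append(np.log(rate_mle_unbiased(ens.records).k0))
        w.append(ens.n_transitioned)
    x, y, w = np.asarray(x), np.asarray(y), np.asarray(w, dtype=float)
    if np.ptp(x) <= 0:
        raise NoDataError("bias measures have zero spread; slope unidentifiable")
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    intercept, slope = res.params
    # the weights are true inverse variances (var(log k_obs) ~ 1/M for the
    # exponential MLE), so report unit-scale errors, not the 1-df
    # residual-scaled ones
    se_int, se_slope = res.bse / np.sqrt(res.scale)
    lo, hi = config.gamma_bounds
    return OpesSlopeFit(
        k0=float(np.exp(intercept)),
        gamma=float(np.clip(slope, lo, hi)),
        k0_log10_err=float(se_int / np.log(10.0)),
        gamma_err=float(se_slope),
        bias_measures=x / np.array([e.beta for e in ensembles]),
        observed_rates=np.exp(y),
    )
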