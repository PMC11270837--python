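"""Uncertainty quantification and goodness-of-fit for rate estimates.

Errors follow the resampling scheme used throughout this package: whole
trajectories (record + bias trace jointly) are drawn with replacement to the
original ensemble size, the estimator is re-run, and the standard deviation
of log10 k0 and of gamma across replicates is reported.

Goodness of fit uses Kolmogorov-Smirnov tests: two-sample against a large
synthetic draw from the fitted model (unbiased / iMetaD) or one-sample
against the theoretical CDF (KTR / EATR).  A fit is conventionally taken to
pass at p > 0.05.  Censored trajectories are excluded from KS samples, which
require fully observed event times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from .model import Ensemble, NoDataError, RateEstimate, TransitionRecord
from .estimators import FitConfig, survival_theoretical

__all__ = [
    "BootstrapResult",
    "bootstrap",
    "ks_two_sample",
    "ks_one_sample",
    "sample_from_cdf",
    "ks_model_check",
]

_DEFAULT = FitConfig()


@dataclass
class BootstrapResult:
    """Spread of an estimator across trajectory resamples."""

    replicates: int
    k0_log10_std: float
    gamma_std: float
    estimates: list[RateEstimate]

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.k0_log10_std < 0 or self.gamma_std < 0:
            raise ValueError("standard deviations cannot be negative")


def bootstrap(
    ensemble: Ensemble,
    estimator: Callable[[Ensemble], RateEstimate],
    replicates: int = 100,
    seed: int = 0,
    max_retries: int = 100,
) -> BootstrapResult:
    """Case-resampling bootstrap over whole trajectories.

    Resamples (record, trace) pairs with replacement to the original N and
    re-runs ``estimator``.  A resample on which the estimator fails (e.g. no
    events survive the draw) is redrawn up to ``max_retries`` times before
    the failure propagates.  Fixed ``seed`` gives identical results.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    n = ensemble.n
    estimates: list[RateEstimate] = []
    for _ in range(replicates):
        err: Exception | None = None
        for _attempt in range(max_retries):
            idx = rng.integers(0, n, size=n)
            try:
                estimates.append(estimator(ensemble.subset(idx)))
                break
            except Exception as exc:  # redraw: resample may be degenerate
                err = exc
        else:
            raise RuntimeError(
                f"estimator failed on {max_retries} consecutive resamples"
            ) from err
    log10k = np.array([e.log10_k0 for e in estimates])
    gammas = np.array([e.gamma for e in estimates])
    return BootstrapResult(
        replicates=replicates,
        k0_log10_std=float(np.std(log10k)),
        gamma_std=float(np.std(gammas)),
        estimates=estimates,
    )


def ks_two_sample(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and p-value."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise NoDataError("KS test needs nonempty samples")
    res = sps.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def ks_one_sample(
    records: Sequence[TransitionRecord],
    theoretical_cdf: Callable[[np.ndarray], np.ndarray],
) -> tuple[float, float]:
    """One-sample KS test of observed event times against a model CDF.

    Censored records are excluded (their event times are unobserved).  The
    theoretical CDF must be nondecreasing on the event times; the asymptotic
    Kolmogorov p-value is returned.
    """
    times = np.sort([r.time for r in records if r.transitioned])
    if times.size == 0:
        raise NoDataError("KS test needs at least one observed event")
    f = np.asarray(theoretical_cdf(times), dtype=float)
    if np.any(np.diff(f) < -1e-12):
        raise ValueError("theoretical CDF is not monotone on the event times")
    res = sps.ks_1samp(times, theoretical_cdf, method="asymp")
    return float(res.statistic), float(res.pvalue)


def sample_from_cdf(
    cdf: Callable[[np.ndarray], np.ndarray],
    n: int,
    rng: np.random.Generator,
    t_max: float | None = None,
    grid_points: int = 4096,
) -> np.ndarray:
    """Inverse-CDF sampling on a dense grid (for synthetic KS comparisons)."""
    if t_max is None:
        t_max = 1.0
        for _ in range(200):
            if float(cdf(np.array([t_max]))[-1]) > 1.0 - 1e-8:
                break
            t_max *= 2.0
    grid = np.linspace(0.0, t_max, grid_points)
    f = np.asarray(cdf(grid), dtype=float)
    f, keep = np.unique(f, return_index=True)
    grid = grid[keep]
    u = rng.uniform(0.0, float(f[-1]), size=n)
    return np.interp(u, f, grid)


def ks_model_check(
    ensemble: Ensemble,
    estimate: RateEstimate,
    config: FitConfig = _DEFAULT,
    seed: int = 0,
    n_synth: int = 100_000,
    mode: str = "auto",
) -> tuple[float, float]:
    """KS goodness-of-fit of a rate estimate against its own ensemble.

    ``mode="auto"`` follows the convention used throughout: two-sample with
    a large synthetic draw from the fitted model for unbiased/iMetaD,
    one-sample against the theoretical CDF for KTR/EATR.
    """
    s = survival_theoretical(ensemble, estimate.method, estimate.k0, estimate.gamma, config)
    cdf = lambda t: 1.0 - s(t)
    if mode == "auto":
        mode = "2sample" if estimate.method in ("unbiased", "imetad") else "1sample"
    if mode == "1sample":
        return ks_one_sample(ensemble.records, cdf)
    if mode == "2sample":
        rng = np.random.default_rng(seed)
        synth = sample_from_cdf(cdf, n_synth, rng)
        return ks_two_sample(ensemble.event_times(), synth)
    raise ValueError("mode must be 'auto', '1sample' or '2sample'")
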