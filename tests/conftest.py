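"""Shared fixtures: small hand-built ensembles and trace factories."""

import numpy as np
import pytest

from eatr.model import BiasTrace, Ensemble, TransitionRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def make_record(time, transitioned=True):
    return TransitionRecord(time=time, transitioned=transitioned)


def zero_trace(duration, beta=1.0):
    return BiasTrace(np.array([0.0, duration]), np.zeros(2), beta=beta)


def constant_trace(value, duration, beta=1.0):
    """Constant bias from t=0 (needs the strict override)."""
    return BiasTrace(
        np.array([0.0, duration]), np.array([value, value]), beta=beta, strict=False
    )


def unbiased_ensemble(times, censored=()):
    records = [make_record(t) for t in times]
    records += [make_record(t, transitioned=False) for t in censored]
    traces = [zero_trace(r.time) for r in records]
    return Ensemble(records, traces)


def random_biased_ensemble(rng, n=None, complete=True, beta=1.0):
    """Random piecewise-constant repulsive bias traces with random event times."""
    if n is None:
        n = int(rng.integers(3, 25))
    records, traces = [], []
    for _ in range(n):
        t_end = float(rng.uniform(0.5, 50.0))
        transitioned = True if complete else bool(rng.uniform() < 0.8)
        n_nodes = int(rng.integers(2, 12))
        times = np.concatenate(
            [[0.0], np.sort(rng.uniform(0.0, t_end, n_nodes - 2)), [t_end]]
        )
        times = np.unique(times)
        values = np.concatenate([[0.0], np.cumsum(rng.uniform(0, 1.5, times.size - 1))])
        records.append(make_record(t_end, transitioned))
        traces.append(BiasTrace(times, values, beta=beta))
    return Ensemble(records, traces)
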