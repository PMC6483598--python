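import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def grid_search_period(times, values, window=(15.0, 35.0), step=0.01):
    """Independent brute-force period oracle.

    For each candidate period on a uniform grid, fit intercept + slope +
    cosine/sine at that period by *linear* least squares and record the
    residual sum of squares; return the grid period with minimal RSS. Shares
    no code path with the package's nonlinear fitter.
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    taus = np.arange(window[0], window[1] + step / 2, step)
    best_tau, best_rss = taus[0], np.inf
    ones = np.ones_like(t)
    for tau in taus:
        w = 2 * np.pi * t / tau
        X = np.column_stack([ones, t, np.cos(w), np.sin(w)])
        _, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(rss[0]) if len(rss) else float(np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2))
        if rss < best_rss:
            best_rss, best_tau = rss, float(tau)
    return best_tau


def circular_error(estimated, truth, period):
    """Minimal circular distance |estimated - truth| modulo period (hours)."""
    d = abs(estimated - truth) % period
    return min(d, period - d)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
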