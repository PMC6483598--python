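"""Per-seedling rhythm estimation by FFT-seeded nonlinear least squares.

A luciferase trace from a seedling in constant light is modelled as a linear
baseline plus a sum of cosine components,

    x(t) = b0 + b1 t + sum_k a_k cos(2 pi (t - phi_k) / tau_k),

fitted by iteratively seeding components from the periodogram of the current
residual and jointly refitting all parameters (FFT-NLLS). Component addition
stops when the newest component's amplitude is not distinguishable from zero,
judged by a linearized (Jacobian-based) confidence interval. The circadian
component is the in-window component with the lowest relative amplitude
error, RAE = amplitude confidence half-width / amplitude; seedlings whose
best component has RAE above the rhythmicity cutoff (default 0.6), or no
in-window component at all, are called arrhythmic.

Phase convention: ``phi`` is the time of the component's first peak after
t = 0 (the first dawn of LL), reported in [0, tau).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger("clockscreen.rhythm")

#: minimum samples required of an ingested luminescence trace
MIN_TRACE_SAMPLES = 24
#: minimum samples the fitter itself will accept (short qPCR series are allowed)
MIN_FIT_SAMPLES = 8

__all__ = [
    "Trace",
    "CosineComponent",
    "RhythmFit",
    "DegenerateInputError",
    "detrend",
    "fft_seed",
    "fit_fftnlls",
    "classify_rhythmicity",
]


class DegenerateInputError(ValueError):
    """Raised when a trace is too short or malformed for the requested step."""


@dataclass(frozen=True)
class Trace:
    """One seedling's luminescence time series in constant light.

    ``times`` are hours since the first dawn of LL, strictly increasing;
    ``values`` are arbitrary intensity units of the same length. Gaps in the
    hourly grid are tolerated (fitting uses the actual timestamps) and are
    never interpolated.
    """

    plant_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"times must be strictly increasing (plant {self.plant_id})")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.values))):
            raise ValueError(f"non-finite samples in trace of plant {self.plant_id}")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])

    def validate(self, min_samples: int = MIN_TRACE_SAMPLES) -> "Trace":
        if len(self) < min_samples:
            raise DegenerateInputError(
                f"trace of plant {self.plant_id} has {len(self)} samples; "
                f"at least {min_samples} required"
            )
        return self


@dataclass(frozen=True)
class CosineComponent:
    """One fitted cosine: period tau (h), amplitude a (intensity), phase phi (h).

    ``phi`` lies in [0, tau) and marks the first peak after t = 0.
    ``amplitude_error`` is the symmetric approximate 95% confidence half-width
    of the amplitude from the linearized covariance at the optimum.
    """

    period: float
    amplitude: float
    phase: float
    amplitude_error: float = 0.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.amplitude < 0 or self.amplitude_error < 0:
            raise ValueError("amplitude and amplitude_error must be non-negative")
        if not (0 <= self.phase < self.period):
            raise ValueError("phase must lie in [0, period)")

    @property
    def rae(self) -> float:
        """Relative amplitude error, clipped to [0, 1]."""
        if self.amplitude == 0:
            return 1.0
        return float(np.clip(self.amplitude_error / self.amplitude, 0.0, 1.0))


@dataclass(frozen=True)
class RhythmFit:
    """Result of FFT-NLLS on one trace.

    ``selected`` indexes the circadian component in ``components`` or is None,
    in which case the seedling is arrhythmic by construction and ``period`` /
    ``phase`` / ``rae`` are NaN (RAE reported as 1.0 for bookkeeping).
    """

    plant_id: str
    components: tuple[CosineComponent, ...]
    selected: int | None
    baseline: tuple[float, float]  # intercept, slope of the linear term
    rss: float
    n_obs: int
    converged: bool = True

    @property
    def period(self) -> float:
        return self.components[self.selected].period if self.selected is not None else float("nan")

    @property
    def phase(self) -> float:
        return self.components[self.selected].phase if self.selected is not None else float("nan")

    @property
    def amplitude(self) -> float:
        return (
            self.components[self.selected].amplitude if self.selected is not None else float("nan")
        )

    @property
    def rae(self) -> float:
        return self.components[self.selected].rae if self.selected is not None else 1.0


# ---------------------------------------------------------------------------
# detrending
# ---------------------------------------------------------------------------


def detrend(trace: Trace) -> Trace:
    """Return the residuals of an ordinary least-squares line fit to the trace.

    Removes the baseline drift (luciferin depletion / signal decay) before
    periodogram seeding. The returned values have mean ~0 by construction.
    """
    if len(trace) < 3:
        raise DegenerateInputError(
            f"need at least 3 points to detrend, got {len(trace)} (plant {trace.plant_id})"
        )
    X = np.column_stack([np.ones_like(trace.times), trace.times])
    coef, *_ = np.linalg.lstsq(X, trace.values, rcond=None)
    return replace(trace, values=trace.values - X @ coef)


def _line_coeffs(times: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    X = np.column_stack([np.ones_like(times), times])
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    return float(coef[0]), float(coef[1])


# ---------------------------------------------------------------------------
# periodogram seeding
# ---------------------------------------------------------------------------


def _ls_spectrum(
    times: np.ndarray, values: np.ndarray, freqs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares cosine/sine projection amplitude at each frequency.

    Equivalent to the classical periodogram for uniform sampling but valid for
    arbitrary timestamps. Returns (amplitude, cos-coef, sin-coef) arrays.
    """
    w = 2.0 * np.pi * freqs[:, None] * times[None, :]
    C = np.cos(w)
    S = np.sin(w)
    # solve the 2x2 normal equations per frequency
    cc = np.sum(C * C, axis=1)
    ss = np.sum(S * S, axis=1)
    cs = np.sum(C * S, axis=1)
    cy = C @ values
    sy = S @ values
    det = cc * ss - cs * cs
    # near-singular projections (e.g. at the Nyquist frequency of a uniform
    # grid, where the sine column vanishes) carry no usable seed
    bad = det <= 1e-9 * (cc + ss) ** 2
    det = np.where(bad, np.inf, det)
    A = (cy * ss - sy * cs) / det
    B = (sy * cc - cy * cs) / det
    return np.hypot(A, B), A, B


def fft_seed(
    trace: Trace,
    max_components: int = 6,
    pad_factor: int = 8,
    min_period: float | None = None,
) -> list[CosineComponent]:
    """Initial (tau, a, phi) guesses from descending periodogram peaks.

    Components are peeled off greedily: the dominant spectral peak of the
    current residual is converted to a cosine, subtracted, and the spectrum
    recomputed, up to ``max_components`` times. A flat spectrum (e.g. an
    all-zero residual) yields an empty list.
    """
    t = trace.times
    r = trace.values.astype(float).copy()
    n = len(t)
    if n < 4:
        return []
    span = trace.span
    if span <= 0:
        return []
    dt = float(np.median(np.diff(t)))
    if min_period is None:
        # stay clearly below the (pseudo-)Nyquist period of the sampling grid
        min_period = max(2.5 * dt, span / (n - 1) * 2.5)
    f_max = 1.0 / min_period
    df = 1.0 / (pad_factor * span)
    freqs = np.arange(df, f_max + df, df)
    scale = float(np.sqrt(np.mean(trace.values**2))) or 1.0

    seeds: list[CosineComponent] = []
    for _ in range(max_components):
        amp, A, B = _ls_spectrum(t, r, freqs)
        k = int(np.argmax(amp))
        a_k = float(amp[k])
        if not np.isfinite(a_k) or a_k < 1e-9 * scale:
            break
        f_k = freqs[k]
        tau = 1.0 / f_k
        # a cos(wt) + b sin(wt) = amp * cos(w (t - phi)) with w*phi = atan2(b, a)
        phi = float(np.arctan2(B[k], A[k]) / (2.0 * np.pi * f_k)) % tau
        seeds.append(CosineComponent(period=tau, amplitude=a_k, phase=phi))
        r = r - a_k * np.cos(2.0 * np.pi * (t - phi) / tau)
    return seeds


# ---------------------------------------------------------------------------
# joint nonlinear fit
# ---------------------------------------------------------------------------


def _model(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    y = params[0] + params[1] * t
    for j in range(2, len(params), 3):
        tau, a, phi = params[j : j + 3]
        y = y + a * np.cos(2.0 * np.pi * (t - phi) / tau)
    return y


def _jacobian(params: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = len(t)
    J = np.empty((n, len(params)))
    J[:, 0] = -1.0
    J[:, 1] = -t
    for j in range(2, len(params), 3):
        tau, a, phi = params[j : j + 3]
        arg = 2.0 * np.pi * (t - phi) / tau
        s = np.sin(arg)
        J[:, j] = -a * s * 2.0 * np.pi * (t - phi) / tau**2  # d/dtau
        J[:, j + 1] = -np.cos(arg)  # d/da
        J[:, j + 2] = -a * s * 2.0 * np.pi / tau  # d/dphi
    return J


def _normalize_component(tau: float, a: float, phi: float) -> tuple[float, float, float]:
    """Canonical form: non-negative amplitude, phase in [0, tau)."""
    if a < 0:
        a, phi = -a, phi + tau / 2.0
    return tau, a, phi % tau


def _joint_factor(p: int, dof: int, alpha: float) -> float:
    """Scheffe-type half-width multiplier approximating joint confidence limits.

    The cited rhythm-analysis method judges a cosine component significant
    when its amplitude's *joint* confidence region (over all fitted
    parameters simultaneously) excludes zero. We approximate that region
    from the linearized covariance: the marginal standard error is scaled by
    sqrt(p * F(1-alpha; p, dof)), the classical projection of the joint
    ellipsoid onto one axis. This is deliberately wider than a marginal
    t-interval and is what pushes the RAE of noise fits toward 1.
    """
    return float(np.sqrt(p * stats.f.ppf(1.0 - alpha, p, dof)))


def fit_fftnlls(
    trace: Trace,
    window: tuple[float, float] = (15.0, 35.0),
    alpha_component: float = 0.05,
    max_components: int = 6,
) -> RhythmFit:
    """Fit a sum of cosines to a trace and pick the circadian component.

    Components are added one at a time from periodogram seeds of the current
    residual and all parameters (baseline, slope, and every tau/a/phi) are
    refitted jointly. Addition stops when the newest component's amplitude
    confidence interval (level ``alpha_component``, linearized covariance)
    includes zero, or ``max_components`` is reached.

    The selected component is the one with period inside ``window`` and the
    lowest RAE (ties broken by larger amplitude). If no fitted component lies
    in the window the fit is arrhythmic (``selected is None``). Optimizer
    failure yields a flagged fit with ``converged=False`` and no selection.

    Raises
    ------
    DegenerateInputError
        If the trace has fewer than 8 samples or spans less than one period
        at the low edge of the window.
    """
    if len(trace) < MIN_FIT_SAMPLES:
        raise DegenerateInputError(
            f"trace of plant {trace.plant_id} has {len(trace)} samples; "
            f"at least {MIN_FIT_SAMPLES} required to fit"
        )
    low, high = float(window[0]), float(window[1])
    if not (0 < low < high):
        raise ValueError(f"invalid window {window}")
    if trace.span < low:
        raise DegenerateInputError(
            f"trace of plant {trace.plant_id} spans {trace.span:.1f} h, "
            f"shorter than one window period ({low} h)"
        )

    t = trace.times
    y = trace.values
    n = len(t)
    dt = float(np.median(np.diff(t)))
    tau_lo, tau_hi = max(1.5 * dt, 2.0), 3.0 * trace.span

    b0, b1 = _line_coeffs(t, y)
    params = np.array([b0, b1])
    best: optimize.OptimizeResult | None = None
    accepted = 0
    converged = True

    def residual(p: np.ndarray) -> np.ndarray:
        return y - _model(p, t)

    def jac(p: np.ndarray) -> np.ndarray:
        return _jacobian(p, t, y)

    # a new seed must be spectrally resolvable from every accepted component;
    # otherwise close frequency pairs beat against each other to mimic the
    # amplitude decay of a damped rhythm and destabilize period and phase
    min_freq_sep = 0.8 / trace.span

    for _ in range(max_components):
        resid_trace = replace(trace, values=residual(params))
        seeds = fft_seed(resid_trace, max_components=max_components)
        comp_freqs = [1.0 / params[j] for j in range(2, len(params), 3)]
        seed = next(
            (
                s
                for s in seeds
                if all(abs(1.0 / s.period - f) >= min_freq_sep for f in comp_freqs)
            ),
            None,
        )
        if seed is None:
            break
        tau0 = float(np.clip(seed.period, tau_lo * 1.01, tau_hi * 0.99))
        x0 = np.concatenate([params, [tau0, seed.amplitude, seed.phase]])
        k = accepted + 1
        lb = np.concatenate([[-np.inf, -np.inf], np.tile([tau_lo, -np.inf, -np.inf], k)])
        ub = np.concatenate([[np.inf, np.inf], np.tile([tau_hi, np.inf, np.inf], k)])
        x0 = np.clip(x0, lb, ub)
        try:
            res = optimize.least_squares(
                residual, x0, jac=jac, bounds=(lb, ub), method="trf", x_scale="jac", max_nfev=400
            )
        except Exception:  # pragma: no cover - optimizer blow-up is rare
            logger.warning("optimizer raised for plant %s", trace.plant_id)
            converged = best is not None
            break
        if not res.success:
            if best is None:
                converged = False
            break
        p_params = len(res.x)
        dof = n - p_params
        if dof < 1:
            break
        s2 = 2.0 * res.cost / dof
        JtJ = res.jac.T @ res.jac
        try:
            cov = s2 * np.linalg.pinv(JtJ)
        except np.linalg.LinAlgError:  # pragma: no cover
            break
        crit = _joint_factor(p_params, dof, alpha_component)
        j_new = 2 + 3 * accepted
        se_new = float(np.sqrt(max(cov[j_new + 1, j_new + 1], 0.0)))
        a_new = abs(float(res.x[j_new + 1]))
        if a_new <= crit * se_new:
            break  # newest component's joint amplitude CI includes zero: stop
        params = res.x.copy()
        best = res
        accepted += 1
        if 2.0 * res.cost <= 1e-24 * max(1.0, float(np.sum(y**2))):
            break  # numerically perfect fit; nothing left to seed

    if best is None:
        return RhythmFit(
            plant_id=trace.plant_id,
            components=(),
            selected=None,
            baseline=_line_coeffs(t, y),
            rss=float(np.sum((y - np.poly1d(np.polyfit(t, y, 1))(t)) ** 2)),
            n_obs=n,
            converged=converged,
        )

    x = best.x
    dof = max(n - len(x), 1)
    s2 = 2.0 * best.cost / dof
    cov = s2 * np.linalg.pinv(best.jac.T @ best.jac)
    crit = _joint_factor(len(x), dof, alpha_component)
    comps = []
    for i in range(accepted):
        j = 2 + 3 * i
        tau, a, phi = _normalize_component(*x[j : j + 3])
        se_a = float(np.sqrt(max(cov[j + 1, j + 1], 0.0)))
        comps.append(
            CosineComponent(
                period=float(tau),
                amplitude=float(a),
                phase=float(phi),
                amplitude_error=crit * se_a,
            )
        )
    comps_t = tuple(comps)

    in_window = [i for i, c in enumerate(comps_t) if low <= c.period <= high]
    selected: int | None = None
    if in_window:
        # lowest RAE wins; ties (to float tolerance) go to the larger amplitude
        selected = min(in_window, key=lambda i: (round(comps_t[i].rae, 12), -comps_t[i].amplitude))
    return RhythmFit(
        plant_id=trace.plant_id,
        components=comps_t,
        selected=selected,
        baseline=(float(x[0]), float(x[1])),
        rss=float(2.0 * best.cost),
        n_obs=n,
        converged=True,
    )


def classify_rhythmicity(fit: RhythmFit, cutoff: float = 0.6) -> str:
    """Call a fit 'rhythmic' or 'arrhythmic'.

    Arrhythmic iff no circadian component was selected or its RAE strictly
    exceeds ``cutoff`` (RAE of exactly 0.6 is still rhythmic).
    """
    if fit.selected is None or not fit.converged:
        return "arrhythmic"
    return "arrhythmic" if fit.rae > cutoff else "rhythmic"
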