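"""Comparative-CT (2^-ddCT) quantification and genotype phase comparison.

Relative clock-gene expression over a constant-light time course is
quantified against a reference gene (*IPP2* in the source study) by the
comparative-CT method:

    dCT(t)  = CT_target(t) - CT_reference(t)
    ddCT(t) = dCT(t) - dCT(t_ref)
    rel(t)  = 2 ** (-ddCT(t))

where the reference point ``t_ref`` is the first expression peak of the
replicate, so rel(t_ref) == 1 for every replicate. Rhythm parameters of the
resulting expression series are estimated with the same FFT-NLLS machinery
used for luminescence traces, and genotypes are compared replicate-wise by
Welch's t-test at a Bonferroni-corrected level (0.05 / 3 = 1.67e-2 when
CCA1, TOC1 and a third readout form the family). Phase differences between
genotypes are circular: reported as the signed difference of minimal
magnitude modulo the mean fitted period.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .rhythm import RhythmFit, Trace, classify_rhythmicity, fit_fftnlls

logger = logging.getLogger("clockscreen.qpcr")

__all__ = [
    "CtSeries",
    "ExpressionSeries",
    "GenotypeComparison",
    "delta_delta_ct",
    "pick_reference_point",
    "fit_expression_rhythm",
    "compare_phases",
    "compare_amplitudes",
]


@dataclass(frozen=True)
class CtSeries:
    """Aligned CT values of a target and the reference gene for one replicate."""

    genotype: str
    replicate: str
    target: str
    timepoints: np.ndarray  # ZT hours
    ct_target: np.ndarray
    ct_reference: np.ndarray

    def __post_init__(self) -> None:
        for name in ("timepoints", "ct_target", "ct_reference"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.timepoints) == len(self.ct_target) == len(self.ct_reference)):
            raise ValueError("timepoints, ct_target, ct_reference must align")
        if not np.all(np.diff(self.timepoints) > 0):
            raise ValueError("timepoints must be strictly increasing")

    def dropna(self) -> "CtSeries":
        """Drop timepoints with non-finite CT in either channel, logging each."""
        ok = np.isfinite(self.ct_target) & np.isfinite(self.ct_reference)
        if not ok.all():
            for t in self.timepoints[~ok]:
                logger.info(
                    "%s/%s %s: dropping ZT%g (non-finite CT)",
                    self.genotype, self.replicate, self.target, t,
                )
            return CtSeries(
                self.genotype,
                self.replicate,
                self.target,
                self.timepoints[ok],
                self.ct_target[ok],
                self.ct_reference[ok],
            )
        return self

    @property
    def delta_ct(self) -> np.ndarray:
        return self.ct_target - self.ct_reference


@dataclass(frozen=True)
class ExpressionSeries:
    """2^-ddCT relative expression; exactly 1.0 at the reference timepoint."""

    genotype: str
    replicate: str
    target: str
    timepoints: np.ndarray
    rel_expression: np.ndarray
    reference_point: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "timepoints", np.asarray(self.timepoints, dtype=float))
        object.__setattr__(self, "rel_expression", np.asarray(self.rel_expression, dtype=float))
        if len(self.timepoints) != len(self.rel_expression):
            raise ValueError("timepoints and rel_expression must align")
        if np.any(self.rel_expression <= 0):
            raise ValueError("rel_expression must be positive")


@dataclass(frozen=True)
class GenotypeComparison:
    """Welch comparison of a rhythm parameter between two genotype replicate sets."""

    quantity: str  # "phase" or "amplitude"
    mean_a: float
    mean_b: float
    mean_diff: float  # b - a; circular minimal-magnitude for phase
    p_value: float
    alpha_corrected: float
    significant: bool
    n_a: int
    n_b: int
    excluded: tuple[str, ...] = ()
    mean_period: float = float("nan")
    untestable: bool = False


def pick_reference_point(series: CtSeries) -> float:
    """Timepoint of the replicate's first expression peak (first local max of -dCT).

    Expression is highest where dCT is lowest, so the first local maximum of
    -dCT marks the first peak; ties take the earliest timepoint. For a
    monotone series (no interior peak) the global maximum is returned with a
    warning.
    """
    s = series.dropna()
    if len(s.timepoints) < 3:
        raise ValueError("need at least 3 timepoints to locate a peak")
    v = -s.delta_ct
    n = len(v)
    for i in range(n):
        left_ok = i == 0 or v[i] > v[i - 1]
        right_ok = i == n - 1 or v[i] >= v[i + 1]
        if left_ok and right_ok:
            if i == n - 1 and np.all(np.diff(v) >= 0):
                warnings.warn(
                    f"{s.genotype}/{s.replicate} {s.target}: expression is monotone; "
                    "using the global maximum as reference point",
                    stacklevel=2,
                )
            return float(s.timepoints[i])
    return float(s.timepoints[int(np.argmax(v))])  # pragma: no cover


def delta_delta_ct(series: CtSeries, reference_point: float | None = None) -> ExpressionSeries:
    """Relative expression 2^-ddCT against the replicate's reference timepoint.

    ``reference_point`` defaults to the replicate's first expression peak
    (:func:`pick_reference_point`); if given it must be one of the (finite)
    timepoints.
    """
    s = series.dropna()
    if reference_point is None:
        reference_point = pick_reference_point(s)
    where = np.flatnonzero(np.isclose(s.timepoints, reference_point))
    if where.size == 0:
        raise ValueError(
            f"reference point ZT{reference_point:g} not among timepoints of "
            f"{s.genotype}/{s.replicate} {s.target}"
        )
    dct = s.delta_ct
    ddct = dct - dct[where[0]]
    return ExpressionSeries(
        genotype=s.genotype,
        replicate=s.replicate,
        target=s.target,
        timepoints=s.timepoints,
        rel_expression=np.exp2(-ddct),
        reference_point=float(reference_point),
    )


def fit_expression_rhythm(
    expr: ExpressionSeries,
    window: tuple[float, float] = (15.0, 35.0),
    alpha_component: float = 0.05,
) -> RhythmFit:
    """FFT-NLLS rhythm fit of a relative-expression time course."""
    trace = Trace(
        plant_id=f"{expr.genotype}/{expr.replicate}/{expr.target}",
        times=expr.timepoints,
        values=expr.rel_expression,
    )
    return fit_fftnlls(trace, window=window, alpha_component=alpha_component)


def _circular_wrap(x: float, period: float) -> float:
    """Map x into (-period/2, period/2]."""
    y = x % period
    return y - period if y > period / 2 else y


def _usable_fits(
    exprs, window, rae_cutoff
) -> tuple[list[RhythmFit], list[str]]:
    fits, excluded = [], []
    for e in exprs:
        f = fit_expression_rhythm(e, window=window)
        if classify_rhythmicity(f, cutoff=rae_cutoff) == "arrhythmic":
            label = f"{e.genotype}/{e.replicate}/{e.target}"
            logger.info("excluding arrhythmic replicate %s (rae=%.2f)", label, f.rae)
            excluded.append(label)
        else:
            fits.append(f)
    return fits, excluded


def compare_phases(
    expr_a,
    expr_b,
    alpha_family: float = 0.05,
    m_tests: int = 3,
    window: tuple[float, float] = (15.0, 35.0),
    rae_cutoff: float = 0.6,
) -> GenotypeComparison:
    """Compare fitted expression phases between two genotype replicate sets.

    Each replicate's expression series is rhythm-fitted; arrhythmic replicates
    (RAE above ``rae_cutoff``) are excluded with a log entry. Phases are
    compared on the circle modulo the mean fitted period: every phase is
    unwrapped into the half-period interval around genotype A's phase before a
    two-sided Welch's t-test at ``alpha_family / m_tests``. The reported mean
    difference (B - A) is the signed difference of minimal magnitude; fewer
    than two usable replicates on either side makes the comparison untestable.
    """
    fits_a, excl_a = _usable_fits(expr_a, window, rae_cutoff)
    fits_b, excl_b = _usable_fits(expr_b, window, rae_cutoff)
    excluded = tuple(excl_a + excl_b)
    alpha_corrected = alpha_family / m_tests
    if len(fits_a) < 2 or len(fits_b) < 2:
        return GenotypeComparison(
            quantity="phase",
            mean_a=float("nan"),
            mean_b=float("nan"),
            mean_diff=float("nan"),
            p_value=float("nan"),
            alpha_corrected=alpha_corrected,
            significant=False,
            n_a=len(fits_a),
            n_b=len(fits_b),
            excluded=excluded,
            untestable=True,
        )
    period = float(np.mean([f.period for f in fits_a + fits_b]))
    ref = fits_a[0].phase
    unwrap = lambda p: ref + _circular_wrap(p - ref, period)
    ph_a = np.array([unwrap(f.phase) for f in fits_a])
    ph_b = np.array([unwrap(f.phase) for f in fits_b])
    p = float(stats.ttest_ind(ph_a, ph_b, equal_var=False).pvalue)
    mean_a, mean_b = float(ph_a.mean()), float(ph_b.mean())
    diff = _circular_wrap(mean_b - mean_a, period)
    return GenotypeComparison(
        quantity="phase",
        mean_a=mean_a % period,
        mean_b=mean_b % period,
        mean_diff=diff,
        p_value=p,
        alpha_corrected=alpha_corrected,
        significant=bool(p < alpha_corrected),
        n_a=len(ph_a),
        n_b=len(ph_b),
        excluded=excluded,
        mean_period=period,
    )


def compare_amplitudes(
    expr_a,
    expr_b,
    alpha_family: float = 0.05,
    m_tests: int = 3,
    window: tuple[float, float] = (15.0, 35.0),
    rae_cutoff: float = 0.6,
) -> GenotypeComparison:
    """Compare fitted expression amplitudes between genotypes (Welch, two-sided).

    Reports the effect and p-value without asserting significance beyond the
    Bonferroni flag; replicate-to-replicate variability in expression data
    often leaves amplitude comparisons underpowered.
    """
    fits_a, excl_a = _usable_fits(expr_a, window, rae_cutoff)
    fits_b, excl_b = _usable_fits(expr_b, window, rae_cutoff)
    excluded = tuple(excl_a + excl_b)
    alpha_corrected = alpha_family / m_tests
    if len(fits_a) < 2 or len(fits_b) < 2:
        return GenotypeComparison(
            quantity="amplitude",
            mean_a=float("nan"),
            mean_b=float("nan"),
            mean_diff=float("nan"),
            p_value=float("nan"),
            alpha_corrected=alpha_corrected,
            significant=False,
            n_a=len(fits_a),
            n_b=len(fits_b),
            excluded=excluded,
            untestable=True,
        )
    am_a = np.array([f.amplitude for f in fits_a])
    am_b = np.array([f.amplitude for f in fits_b])
    p = float(stats.ttest_ind(am_a, am_b, equal_var=False).pvalue)
    return GenotypeComparison(
        quantity="amplitude",
        mean_a=float(am_a.mean()),
        mean_b=float(am_b.mean()),
        mean_diff=float(am_b.mean() - am_a.mean()),
        p_value=p,
        alpha_corrected=alpha_corrected,
        significant=bool(p < alpha_corrected),
        n_a=len(am_a),
        n_b=len(am_b),
        excluded=excluded,
    )
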