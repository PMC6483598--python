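"""Synthetic luminescence traces, screen designs, and qPCR time courses.

Every generator is a pure function of (specification, seed), so each
downstream stage can be scored against known ground truth without any
external data. The defaults emulate the screening regime of the decoy
study: hourly imaging across ~5 days of constant light (120 h span), a
damped cosine of circadian period riding on a slowly decaying baseline,
20 first-generation (T1) plants per decoy population with a concurrent
parental-reporter control population, and clock-gene qPCR sampled every
3 h over 48 h in three biological replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .qpcr import CtSeries
from .rhythm import Trace

__all__ = [
    "TraceModel",
    "MixtureComponent",
    "PopulationSpec",
    "ExperimentSpec",
    "ScreenDesign",
    "QpcrGenotypeSpec",
    "SimulatedScreen",
    "simulate_trace",
    "simulate_screen",
    "simulate_qpcr",
    "design_from_dict",
]


@dataclass(frozen=True)
class TraceModel:
    """Damped-cosine luminescence model:

    x(t) = baseline + trend*t + amplitude * exp(-damping*t) * cos(2*pi*(t-phase)/period) + eps

    with eps ~ Normal(0, noise_sd^2) and hourly sampling over ``span`` hours.
    Defaults give a signal-to-noise ratio of about 5 and the gentle amplitude
    decay seen in long constant-light luciferase recordings.
    """

    baseline: float = 100.0
    trend: float = -0.05
    amplitude: float = 20.0
    period: float = 24.2
    phase: float = 1.0
    damping: float = 0.005
    noise_sd: float = 4.0
    sampling: float = 1.0
    span: float = 120.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.damping < 0 or self.noise_sd < 0 or self.sampling <= 0 or self.span <= 0:
            raise ValueError("damping/noise_sd must be >= 0; sampling/span > 0")


def simulate_trace(
    model: TraceModel, seed: int | np.random.Generator, plant_id: str = "sim"
) -> Trace:
    """One seedling's trace; deterministic given the model and seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(0.0, model.span + model.sampling / 2, model.sampling)
    signal = (
        model.baseline
        + model.trend * t
        + model.amplitude
        * np.exp(-model.damping * t)
        * np.cos(2.0 * np.pi * (t - model.phase) / model.period)
    )
    noise = rng.normal(0.0, model.noise_sd, size=t.shape) if model.noise_sd > 0 else 0.0
    return Trace(plant_id=plant_id, times=t, values=signal + noise)


# ---------------------------------------------------------------------------
# screen designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixtureComponent:
    """One subgroup of a mixed decoy population.

    ``fraction`` of the population, shifted by ``period_effect`` /
    ``phase_effect`` hours. Subgroup scatter (``period_sd``) is tighter than
    the whole-population default: plants within one insertion-effect class
    behave alike.
    """

    fraction: float
    period_effect: float = 0.0
    phase_effect: float = 0.0
    period_sd: float = 0.2
    phase_sd: float = 0.5


@dataclass(frozen=True)
class PopulationSpec:
    population_id: str
    n: int = 20
    period_effect: float = 0.0
    phase_effect: float = 0.0
    period_sd: float = 0.4
    phase_sd: float = 0.6
    mixture: tuple[MixtureComponent, ...] | None = None
    arrhythmic_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.mixture is not None:
            object.__setattr__(self, "mixture", tuple(self.mixture))
            total = sum(c.fraction for c in self.mixture)
            if not np.isclose(total, 1.0):
                raise ValueError(
                    f"mixture fractions of {self.population_id} sum to {total}, expected 1"
                )
        if not (0.0 <= self.arrhythmic_fraction <= 1.0):
            raise ValueError("arrhythmic_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ExperimentSpec:
    experiment_id: str
    populations: tuple[PopulationSpec, ...] = ()
    control_n: int = 20
    control_period_mean: float = 24.2
    control_period_sd: float = 0.4
    control_phase_mean: float = 1.0
    control_phase_sd: float = 0.6

    def __post_init__(self) -> None:
        object.__setattr__(self, "populations", tuple(self.populations))


@dataclass(frozen=True)
class ScreenDesign:
    experiments: tuple[ExperimentSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "experiments", tuple(self.experiments))


@dataclass(frozen=True)
class SimulatedScreen:
    """Per-plant metric table, ground truth, and (optionally) raw traces.

    ``metrics`` mirrors the per-plant fit table the rhythm stage would
    produce (period_h, phase_h, rae, ...), letting statistics stages be
    exercised without re-fitting; ``truth`` records each plant's generating
    parameters and subgroup for recovery scoring; ``traces`` is a long-format
    luminescence table (None unless requested); ``layout`` maps plants to
    experiments/populations.
    """

    metrics: pd.DataFrame
    truth: pd.DataFrame
    layout: pd.DataFrame
    traces: pd.DataFrame | None = None


#: truncation bounds for drawn periods; keeps every plant inside the fit window
_PERIOD_BOUNDS = (15.0, 35.0)


def _draw_truncated(rng, mean, sd, size, bounds=_PERIOD_BOUNDS):
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = (out < bounds[0]) | (out > bounds[1])
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, *bounds)


def simulate_screen(
    design: ScreenDesign,
    seed: int,
    traces: bool = False,
    trace_model: TraceModel = TraceModel(),
) -> SimulatedScreen:
    """Draw a full screen: per-plant periods/phases (and optionally traces).

    Plants are drawn population by population; mixture specs split a
    population into subgroups with distinct effects (ground-truth ``group``
    column: 'control', 'bulk', or 'mix<k>'). An ``arrhythmic_fraction`` of
    plants gets an amplitude-zero trace and an RAE above the rhythmicity
    cutoff in the metric table. Deterministic given (design, seed).
    """
    rng = np.random.default_rng(seed)
    metric_rows: list[dict] = []
    truth_rows: list[dict] = []
    trace_frames: list[pd.DataFrame] = []

    def add_plant(exp_id, pop_id, plant_id, is_control, period, phase, group, arrhythmic):
        rae = float(rng.uniform(0.65, 0.95)) if arrhythmic else float(rng.uniform(0.02, 0.30))
        metric_rows.append(
            {
                "experiment_id": exp_id,
                "population_id": pop_id,
                "plant_id": plant_id,
                "is_control": is_control,
                "period_h": float(period),
                "phase_h": float(phase),
                "amplitude": float(trace_model.amplitude * rng.uniform(0.7, 1.3)),
                "rae": rae,
                "rhythmic": not arrhythmic,
                "convergence_flag": True,
            }
        )
        truth_rows.append(
            {
                "experiment_id": exp_id,
                "population_id": pop_id,
                "plant_id": plant_id,
                "is_control": is_control,
                "true_period": float(period),
                "true_phase": float(phase),
                "group": group,
                "arrhythmic": arrhythmic,
            }
        )
        if traces:
            from dataclasses import replace as _replace

            m = _replace(
                trace_model,
                period=float(period),
                phase=float(phase),
                amplitude=0.0 if arrhythmic else trace_model.amplitude,
            )
            tr = simulate_trace(m, rng, plant_id=plant_id)
            trace_frames.append(
                pd.DataFrame(
                    {
                        "experiment_id": exp_id,
                        "population_id": pop_id,
                        "plant_id": plant_id,
                        "time_h": tr.times,
                        "intensity": tr.values,
                    }
                )
            )

    for exp in design.experiments:
        ctrl_periods = _draw_truncated(
            rng, exp.control_period_mean, exp.control_period_sd, exp.control_n
        )
        ctrl_phases = rng.normal(exp.control_phase_mean, exp.control_phase_sd, exp.control_n)
        for i in range(exp.control_n):
            add_plant(
                exp.experiment_id,
                "control",
                f"{exp.experiment_id}_ctrl_{i:03d}",
                True,
                ctrl_periods[i],
                ctrl_phases[i] % ctrl_periods[i],
                "control",
                False,
            )
        for pop in exp.populations:
            n_arr = int(round(pop.arrhythmic_fraction * pop.n))
            arrhythmic_mask = np.zeros(pop.n, dtype=bool)
            if n_arr:
                arrhythmic_mask[rng.choice(pop.n, size=n_arr, replace=False)] = True
            if pop.mixture is None:
                groups = ["bulk"] * pop.n
                periods = _draw_truncated(
                    rng, exp.control_period_mean + pop.period_effect, pop.period_sd, pop.n
                )
                phases = rng.normal(
                    exp.control_phase_mean + pop.phase_effect, pop.phase_sd, pop.n
                )
            else:
                # deterministic counts per component (largest-remainder rounding)
                fr = np.array([c.fraction for c in pop.mixture])
                counts = np.floor(fr * pop.n).astype(int)
                rema = fr * pop.n - counts
                for k in np.argsort(-rema)[: pop.n - counts.sum()]:
                    counts[k] += 1
                groups, periods, phases = [], [], []
                for k, (comp, m) in enumerate(zip(pop.mixture, counts)):
                    groups += [f"mix{k}"] * m
                    periods.append(
                        _draw_truncated(
                            rng,
                            exp.control_period_mean + comp.period_effect,
                            comp.period_sd,
                            m,
                        )
                    )
                    phases.append(
                        rng.normal(exp.control_phase_mean + comp.phase_effect, comp.phase_sd, m)
                    )
                periods = np.concatenate(periods)
                phases = np.concatenate(phases)
            for i in range(pop.n):
                add_plant(
                    exp.experiment_id,
                    pop.population_id,
                    f"{exp.experiment_id}_{pop.population_id}_{i:03d}",
                    False,
                    periods[i],
                    phases[i] % periods[i],
                    groups[i],
                    bool(arrhythmic_mask[i]),
                )

    metrics = pd.DataFrame(metric_rows)
    truth = pd.DataFrame(truth_rows)
    layout = metrics[["plant_id", "experiment_id", "population_id", "is_control"]].copy()
    traces_df = pd.concat(trace_frames, ignore_index=True) if trace_frames else None
    return SimulatedScreen(metrics=metrics, truth=truth, layout=layout, traces=traces_df)


# ---------------------------------------------------------------------------
# qPCR time courses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QpcrGenotypeSpec:
    """Rhythmic expression model for one genotype/target pair.

    log2 relative expression follows ``amplitude_log2 * cos(2*pi*(t-peak_zt)/period)``
    on top of a constant target-vs-reference offset ``base_dct`` (cycles);
    CT noise is i.i.d. Gaussian per well. ``amplitude_log2 = 2`` spans a
    16-fold peak-to-trough range, typical of CCA1 under constant light.
    """

    genotype: str
    target: str = "CCA1"
    peak_zt: float = 1.0
    amplitude_log2: float = 2.0
    base_dct: float = 5.0
    period: float = 24.0
    replicates: int = 3
    ct_noise_sd: float = 0.15
    reference_ct: float = 20.0
    timepoints: tuple[float, ...] = tuple(float(x) for x in range(0, 49, 3))


def simulate_qpcr(specs, seed: int) -> list[CtSeries]:
    """CT tables for each genotype spec; deterministic given (specs, seed).

    The reference gene's CT is constant plus noise; the target's CT is the
    reference level plus ``base_dct`` minus the log2 expression model plus
    noise, so the comparative-CT pipeline should recover the cosine.
    """
    rng = np.random.default_rng(seed)
    out: list[CtSeries] = []
    for spec in specs:
        t = np.asarray(spec.timepoints, dtype=float)
        log2_expr = spec.amplitude_log2 * np.cos(2.0 * np.pi * (t - spec.peak_zt) / spec.period)
        for r in range(spec.replicates):
            ct_ref = spec.reference_ct + rng.normal(0.0, spec.ct_noise_sd, size=t.shape)
            ct_tgt = (
                spec.reference_ct
                + spec.base_dct
                - log2_expr
                + rng.normal(0.0, spec.ct_noise_sd, size=t.shape)
            )
            out.append(
                CtSeries(
                    genotype=spec.genotype,
                    replicate=f"rep{r + 1}",
                    target=spec.target,
                    timepoints=t,
                    ct_target=ct_tgt,
                    ct_reference=ct_ref,
                )
            )
    return out


# ---------------------------------------------------------------------------
# YAML design schema
# ---------------------------------------------------------------------------


def design_from_dict(d: dict[str, Any]) -> ScreenDesign:
    """Build a ScreenDesign from a plain dict (e.g. parsed YAML).

    Schema::

        experiments:
          - experiment_id: E1
            control: {n: 20, period_mean: 24.2, period_sd: 0.4,
                      phase_mean: 1.0, phase_sd: 0.6}
            populations:
              - population_id: P1
                n: 20
                period_effect: 1.5
                phase_effect: 0.0
                arrhythmic_fraction: 0.0
                mixture:            # optional; fractions must sum to 1
                  - {fraction: 0.75, period_effect: 0.3}
                  - {fraction: 0.25, period_effect: 3.0}
    """
    experiments = []
    for e in d.get("experiments", []):
        ctrl = e.get("control", {})
        pops = []
        for p in e.get("populations", []):
            mixture = None
            if p.get("mixture"):
                mixture = tuple(MixtureComponent(**c) for c in p["mixture"])
            pops.append(
                PopulationSpec(
                    population_id=str(p["population_id"]),
                    n=int(p.get("n", 20)),
                    period_effect=float(p.get("period_effect", 0.0)),
                    phase_effect=float(p.get("phase_effect", 0.0)),
                    period_sd=float(p.get("period_sd", 0.4)),
                    phase_sd=float(p.get("phase_sd", 0.6)),
                    mixture=mixture,
                    arrhythmic_fraction=float(p.get("arrhythmic_fraction", 0.0)),
                )
            )
        experiments.append(
            ExperimentSpec(
                experiment_id=str(e["experiment_id"]),
                populations=tuple(pops),
                control_n=int(ctrl.get("n", 20)),
                control_period_mean=float(ctrl.get("period_mean", 24.2)),
                control_period_sd=float(ctrl.get("period_sd", 0.4)),
                control_phase_mean=float(ctrl.get("phase_mean", 1.0)),
                control_phase_sd=float(ctrl.get("phase_sd", 0.6)),
            )
        )
    if not experiments:
        raise ValueError("design must contain at least one experiment")
    return ScreenDesign(experiments=tuple(experiments))
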