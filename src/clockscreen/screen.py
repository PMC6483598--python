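"""Screen statistics: control normalization, QC, Welch/Bonferroni hit calling.

Each imaging experiment (batch) carries a concurrent population of parental
*CCA1p::Luciferase* control seedlings alongside the decoy populations. A batch
is usable only when the sample standard deviation of its control periods is
strictly below the QC cutoff (default 0.75 h). Within a usable batch, the
control mean of a metric is subtracted from every plant (controls included),
putting all experiments on a common normalized scale.

Hit calling compares each decoy population (or subpopulation) to a control
pool with a two-sided Welch's t-test at a Bonferroni-corrected level
alpha_family / m_tests. Following the screen's conventions, the control pool
for period is the normalized wildtype plants, while for phase — where
transgene expression shifts every decoy — it is the entire set of normalized
decoy plants. Significant hits are classed minor or major by the size of the
mean difference (1 h for period, 2 h for phase).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .subpop import SubpopPartition

logger = logging.getLogger("clockscreen.screen")

__all__ = [
    "ScreenBatch",
    "EmptyControlError",
    "METRIC_COLUMNS",
    "MAJOR_CUTOFFS",
    "qc_filter",
    "normalize",
    "call_hits",
    "classify_effect",
]

#: fits-table column per metric name
METRIC_COLUMNS = {"period": "period_h", "phase": "phase_h"}
#: |mean difference| above this (hours) makes a significant hit "major"
MAJOR_CUTOFFS = {"period": 1.0, "phase": 2.0}

HIT_COLUMNS = [
    "population_id",
    "subpop_index",
    "metric",
    "n",
    "mean_diff",
    "p_value",
    "alpha_corrected",
    "significant",
    "effect_class",
    "reason",
]


class EmptyControlError(ValueError):
    """A batch without control plants cannot be QC'd or normalized."""


@dataclass(frozen=True)
class ScreenBatch:
    """One imaging experiment: concurrent controls plus decoy populations.

    ``plants`` is a per-plant metric table with columns ``plant_id``,
    ``population_id``, ``is_control``, ``period_h``, ``phase_h``, ``rae``.
    ``qc_pass`` is None until :func:`qc_filter` has run.
    """

    experiment_id: str
    plants: pd.DataFrame
    qc_pass: bool | None = None
    qc_reason: str = ""

    def __post_init__(self) -> None:
        required = {"plant_id", "population_id", "is_control", "period_h", "phase_h", "rae"}
        missing = required - set(self.plants.columns)
        if missing:
            raise ValueError(f"batch {self.experiment_id} missing columns {sorted(missing)}")
        if self.plants["plant_id"].duplicated().any():
            dup = self.plants.loc[self.plants["plant_id"].duplicated(), "plant_id"].iloc[0]
            raise ValueError(f"plant {dup} appears in more than one row of {self.experiment_id}")

    @property
    def controls(self) -> pd.DataFrame:
        return self.plants[self.plants["is_control"]]

    @property
    def decoys(self) -> pd.DataFrame:
        return self.plants[~self.plants["is_control"]]


def qc_filter(batch: ScreenBatch, sd_cutoff: float = 0.75) -> ScreenBatch:
    """Mark a batch pass/fail on control-period spread.

    Passes iff the sample standard deviation (ddof=1) of the concurrent
    control periods is strictly below ``sd_cutoff``; a batch whose controls
    all share one period (SD = 0) passes. Failing batches must be excluded
    from all downstream statistics.
    """
    periods = batch.controls["period_h"].dropna().to_numpy(dtype=float)
    if periods.size == 0:
        raise EmptyControlError(f"batch {batch.experiment_id} has no control period values")
    sd = float(np.std(periods, ddof=1)) if periods.size > 1 else 0.0
    if sd < sd_cutoff:
        return replace(batch, qc_pass=True, qc_reason=f"control period SD {sd:.3f} < {sd_cutoff}")
    logger.info("batch %s fails QC: control period SD %.3f >= %s", batch.experiment_id, sd, sd_cutoff)
    return replace(batch, qc_pass=False, qc_reason=f"control period SD {sd:.3f} >= {sd_cutoff}")


def normalize(
    batch: ScreenBatch,
    metric: str,
    rae_cutoff: float | None = 0.6,
) -> pd.DataFrame:
    """Subtract the concurrent control mean of ``metric`` from every plant.

    Returns a tidy frame with columns ``plant_id``, ``population_id``,
    ``experiment_id``, ``metric``, ``diff``, ``is_control``. Controls are
    normalized identically, so their diffs average zero within the batch.

    Arrhythmic plants (RAE strictly above ``rae_cutoff``, or a missing
    metric value) carry no meaningful period/phase estimate and are dropped
    with a log entry before the control mean is computed; pass
    ``rae_cutoff=None`` to keep them.
    """
    if metric not in METRIC_COLUMNS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {sorted(METRIC_COLUMNS)}")
    if batch.qc_pass is not True:
        raise ValueError(
            f"batch {batch.experiment_id} has not passed QC (qc_pass={batch.qc_pass})"
        )
    col = METRIC_COLUMNS[metric]
    plants = batch.plants
    usable = plants[col].notna()
    if rae_cutoff is not None:
        usable &= ~(plants["rae"] > rae_cutoff)
    dropped = plants[~usable]
    for _, row in dropped.iterrows():
        logger.info(
            "batch %s: plant %s excluded from %s normalization (rae=%s, %s=%s)",
            batch.experiment_id, row["plant_id"], metric, row["rae"], col, row[col],
        )
    kept = plants[usable]
    ctrl = kept.loc[kept["is_control"], col].to_numpy(dtype=float)
    if ctrl.size == 0:
        raise EmptyControlError(
            f"batch {batch.experiment_id} has no usable control {metric} values"
        )
    ctrl_mean = float(ctrl.mean())
    out = pd.DataFrame(
        {
            "plant_id": kept["plant_id"].to_numpy(),
            "population_id": kept["population_id"].to_numpy(),
            "experiment_id": batch.experiment_id,
            "metric": metric,
            "diff": kept[col].to_numpy(dtype=float) - ctrl_mean,
            "is_control": kept["is_control"].to_numpy(dtype=bool),
        }
    )
    return out.reset_index(drop=True)


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch's t-test p-value (Satterthwaite degrees of freedom)."""
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def classify_effect(
    mean_diff: float,
    significant: bool,
    metric: str,
    major_cutoff: float | None = None,
) -> str:
    """Class a hit: none (not significant), minor, or major (|diff| > cutoff).

    Cutoffs follow the screen's definitions: 1 h for period, 2 h for phase.
    """
    if not significant:
        return "none"
    if major_cutoff is None:
        major_cutoff = MAJOR_CUTOFFS[metric]
    return "major" if abs(mean_diff) > major_cutoff else "minor"


def call_hits(
    records: pd.DataFrame,
    metric: str,
    control_mode: str,
    alpha_family: float = 0.05,
    m_tests: int | None = None,
    partitions: dict[str, SubpopPartition] | None = None,
    major_cutoff: float | None = None,
) -> pd.DataFrame:
    """Welch/Bonferroni hit table over normalized records.

    ``records`` is the output of :func:`normalize` (possibly concatenated
    over batches). Each decoy population is tested against the control pool:
    the normalized wildtype plants (``control_mode='wildtype'``, the screen's
    convention for period) or the normalized decoy plants of the whole family
    (``control_mode='all_decoys'``, the convention for phase).

    ``m_tests`` defaults to the number of decoy populations present — the
    family size for the Bonferroni correction. When ``partitions`` supplies a
    multimodal split for a population, each subpopulation is additionally
    tested against the same corrected alpha (one row per subpopulation with a
    ``subpop_index``). Populations with fewer than two usable plants are
    reported untestable and never significant.
    """
    if metric not in METRIC_COLUMNS:
        raise ValueError(f"unknown metric {metric!r}")
    if control_mode not in ("wildtype", "all_decoys"):
        raise ValueError(f"control_mode must be 'wildtype' or 'all_decoys', got {control_mode!r}")
    decoys = records[~records["is_control"]]
    populations = sorted(decoys["population_id"].unique())
    if m_tests is None:
        m_tests = len(populations)
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    alpha_corrected = alpha_family / m_tests

    if control_mode == "wildtype":
        pool = records.loc[records["is_control"], "diff"].to_numpy(dtype=float)
    else:
        pool = decoys["diff"].to_numpy(dtype=float)

    rows: list[dict] = []

    def test_group(pop: str, subpop_index, values: np.ndarray) -> None:
        row = {
            "population_id": pop,
            "subpop_index": subpop_index,
            "metric": metric,
            "n": int(values.size),
            "mean_diff": float(values.mean()) if values.size else float("nan"),
            "alpha_corrected": alpha_corrected,
            "reason": "",
        }
        if values.size < 2 or pool.size < 2:
            row.update(p_value=float("nan"), significant=False, reason="untestable: n < 2")
            logger.info("population %s (subpop %s) untestable: n=%d", pop, subpop_index, values.size)
        else:
            p = _welch(values, pool)
            row.update(p_value=p, significant=bool(p < alpha_corrected))
        row["effect_class"] = classify_effect(
            row["mean_diff"], row["significant"], metric, major_cutoff
        )
        rows.append(row)

    for pop in populations:
        pop_rows = decoys[decoys["population_id"] == pop]
        test_group(pop, pd.NA, pop_rows["diff"].to_numpy(dtype=float))
        part = (partitions or {}).get(pop)
        if part is not None and part.is_multimodal:
            by_id = pop_rows.set_index("plant_id")["diff"]
            for k, grp in enumerate(part.groups):
                ids = [i for i in grp.plant_ids if i in by_id.index]
                test_group(pop, k, by_id.loc[ids].to_numpy(dtype=float))

    return pd.DataFrame(rows, columns=HIT_COLUMNS)
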