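"""Run configuration: every threshold used by the screen pipeline in one place.

Defaults follow the screening conventions of the decoy-library study design:
a batch is usable only when its concurrent control population has a period
standard deviation below 0.75 h; a seedling is rhythmic only when the relative
amplitude error of its fitted circadian component is at most 0.6; period
effects above 1 h and phase effects above 2 h are "major".
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class RunConfig:
    """Thresholds and knobs for the full screen pipeline.

    All time quantities are decimal hours since the first dawn of constant
    light (LL). The configuration is serialized into every run manifest so
    that outputs carry their own provenance.
    """

    #: QC bound on the sample SD of concurrent control periods (hours, strict <).
    sd_cutoff: float = 0.75
    #: Relative-amplitude-error bound; RAE strictly above this is arrhythmic.
    rae_cutoff: float = 0.6
    #: Circadian period search window for component selection (hours).
    window: tuple[float, float] = (15.0, 35.0)
    #: |mean phase difference| above this is a major phase effect (hours).
    phase_major_cutoff: float = 2.0
    #: |mean period difference| above this is a major period effect (hours).
    period_major_cutoff: float = 1.0
    #: Family-wise significance level before Bonferroni division.
    alpha_family: float = 0.05
    #: Histogram bin width for subpopulation detection (hours).
    bin_width: float = 0.5
    #: Minimum seedlings per surviving subpopulation peak.
    min_n: int = 3
    #: Minimum peak-count minus flanking-trough-count (seedlings).
    min_prominence: int = 3
    #: Minimum number of bins between retained peaks.
    min_separation_bins: int = 2
    #: Maximum cosine components attempted per trace.
    max_components: int = 6
    #: Significance level for accepting a new cosine component.
    alpha_component: float = 0.05
    #: Seed recorded in the manifest; the pipeline itself is deterministic.
    seed: int = 0

    def __post_init__(self) -> None:
        self.window = (float(self.window[0]), float(self.window[1]))
        for name in (
            "sd_cutoff",
            "rae_cutoff",
            "phase_major_cutoff",
            "period_major_cutoff",
            "alpha_family",
            "bin_width",
            "alpha_component",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not (0 < self.window[0] < self.window[1]):
            raise ValueError(f"window must satisfy 0 < low < high, got {self.window}")
        for name in ("min_n", "min_prominence", "min_separation_bins", "max_components"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["window"] = list(self.window)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
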