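"""NNPI stressor-level classification.

Each of the three component metrics is bracketed against three ascending
exceedance cutpoints into an ordered stressor level (low / moderate / high /
very high); boundary values belong to the lower category.  The overall NNPI
for a site is the *highest* level reached by any metric (the max-filter
rule), and the four levels roll up into two combined classes, low-moderate
(LM) vs high-very high (HVH), for site-scale modeling.

Default cutpoints::

    relative cover      <=1   <=15   <=40   >40
    richness            <=5   <=10   <=15   >15
    relative frequency  <=10  <=30   <=60   >60
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd


class StressorLevel(enum.IntEnum):
    """Ordered stressor categories; comparisons follow ecological severity."""

    LOW = 0
    MODERATE = 1
    HIGH = 2
    VERY_HIGH = 3

    def __str__(self) -> str:
        return self.name

    @property
    def combined(self) -> str:
        """Two-class rollup: LM (low-moderate) or HVH (high-very high)."""
        return "LM" if self <= StressorLevel.MODERATE else "HVH"


METRICS = ("rel_cover", "richness", "rel_freq")

_DEFAULT_CUTS = {
    "rel_cover": (1.0, 15.0, 40.0),
    "richness": (5.0, 10.0, 15.0),
    "rel_freq": (10.0, 30.0, 60.0),
}


@dataclass(frozen=True)
class ThresholdMatrix:
    """Per-metric ascending cutpoints (c1, c2, c3); value <= c1 is LOW,
    <= c2 MODERATE, <= c3 HIGH, above c3 VERY_HIGH."""

    rel_cover: tuple[float, float, float] = _DEFAULT_CUTS["rel_cover"]
    richness: tuple[float, float, float] = _DEFAULT_CUTS["richness"]
    rel_freq: tuple[float, float, float] = _DEFAULT_CUTS["rel_freq"]

    def __post_init__(self) -> None:
        for name in METRICS:
            c1, c2, c3 = getattr(self, name)
            if not c1 < c2 < c3:
                raise ValueError(
                    f"{name} cutpoints must ascend strictly; got {(c1, c2, c3)}"
                )

    def cuts(self, metric: str) -> tuple[float, float, float]:
        if metric not in METRICS:
            raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
        return getattr(self, metric)


@dataclass(frozen=True)
class NNPIResult:
    """Per-metric and overall stressor levels for one site-visit."""

    site_id: str
    level_cover: StressorLevel
    level_richness: StressorLevel
    level_freq: StressorLevel
    overall: StressorLevel
    combined: str
    unvegetated: bool = False


def level_for_metric(
    value: float, metric: str, thresholds: ThresholdMatrix | None = None
) -> StressorLevel:
    """Bracket one metric value; boundary values take the lower category."""
    if value < 0:
        raise ValueError(f"{metric} must be non-negative; got {value}")
    c1, c2, c3 = (thresholds or ThresholdMatrix()).cuts(metric)
    if value <= c1:
        return StressorLevel.LOW
    if value <= c2:
        return StressorLevel.MODERATE
    if value <= c3:
        return StressorLevel.HIGH
    return StressorLevel.VERY_HIGH


def combine_level(level: StressorLevel) -> str:
    """LOW/MODERATE -> 'LM'; HIGH/VERY_HIGH -> 'HVH'."""
    return StressorLevel(level).combined


def classify_site(
    nn_richness: float,
    nn_rel_freq: float,
    nn_rel_cover: float,
    thresholds: ThresholdMatrix | None = None,
    site_id: str = "",
) -> NNPIResult:
    """Classify one site from its three metrics via the max-filter rule."""
    thresholds = thresholds or ThresholdMatrix()
    lvl_cover = level_for_metric(nn_rel_cover, "rel_cover", thresholds)
    lvl_rich = level_for_metric(nn_richness, "richness", thresholds)
    lvl_freq = level_for_metric(nn_rel_freq, "rel_freq", thresholds)
    overall = max(lvl_cover, lvl_rich, lvl_freq)
    unvegetated = nn_richness == 0 and nn_rel_freq == 0 and nn_rel_cover == 0
    return NNPIResult(
        site_id=site_id,
        level_cover=lvl_cover,
        level_richness=lvl_rich,
        level_freq=lvl_freq,
        overall=overall,
        combined=overall.combined,
        unvegetated=unvegetated,
    )


def classify_table(
    metrics_df: pd.DataFrame, thresholds: ThresholdMatrix | None = None
) -> pd.DataFrame:
    """Vector version over a site-metrics table.

    Input needs columns site_id, visit_no (optional), nn_richness,
    nn_rel_freq, nn_rel_cover; output appends the per-metric levels,
    overall NNPI, and combined class as strings.
    """
    thresholds = thresholds or ThresholdMatrix()
    out = metrics_df.copy()
    results = [
        classify_site(
            r["nn_richness"], r["nn_rel_freq"], r["nn_rel_cover"],
            thresholds, site_id=str(r["site_id"]),
        )
        for _, r in metrics_df.iterrows()
    ]
    out["level_cover"] = [r.level_cover.name for r in results]
    out["level_richness"] = [r.level_richness.name for r in results]
    out["level_freq"] = [r.level_freq.name for r in results]
    out["overall"] = [r.overall.name for r in results]
    out["combined"] = [r.combined for r in results]
    if "total_richness" in out.columns:
        out["unvegetated"] = out["total_richness"] == 0
    return out
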