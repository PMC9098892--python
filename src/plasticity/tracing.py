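"""Monosynaptic-tracing connectivity ratios.

Starter cells counted on a subset of sections are interpolated to the whole
brain proportionally (``counted * sections_total / sections_imaged``); the
connectivity ratio of a region is its presynaptic cell count divided by the
whole-brain starter estimate. Group summaries are mean ± SEM over brains,
with group-vs-matching-control comparisons delegated to the inference
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import UNDEFINED
from .stats import standard_test

__all__ = [
    "TracingCounts",
    "interpolate_starters",
    "connectivity_ratio",
    "brain_ratios",
    "build_connectivity_table",
]

DEFAULT_COMPARISONS = (("tbi_7d", "control_7d"), ("tbi_42d", "control_42d"))


@dataclass(frozen=True)
class TracingCounts:
    """One brain's starter and per-region presynaptic counts."""

    brain_id: str
    group: str
    starter_counted: int
    starter_sections_imaged: int
    starter_sections_total: int
    region_counts: dict[str, int] = field(default_factory=dict)
    hemispheres: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.starter_counted < 0 or any(v < 0 for v in self.region_counts.values()):
            raise ValueError("cell counts must be >= 0")
        if not 1 <= self.starter_sections_imaged <= self.starter_sections_total:
            raise ValueError("require 1 <= sections_imaged <= sections_total")


def interpolate_starters(counts: TracingCounts) -> float:
    """Whole-brain starter estimate by proportional section scaling."""
    if counts.starter_sections_imaged < 1:
        raise ValueError("at least one imaged section is required")
    return (
        counts.starter_counted
        * counts.starter_sections_total
        / counts.starter_sections_imaged
    )


def connectivity_ratio(region_count: int, starters_whole_brain: float) -> float:
    """Presynaptic count over whole-brain starter count; NaN at 0 starters."""
    if region_count < 0:
        raise ValueError("presynaptic count must be >= 0")
    if starters_whole_brain <= 0:
        return UNDEFINED
    return region_count / starters_whole_brain


def brain_ratios(counts: TracingCounts) -> pd.DataFrame:
    """Connectivity ratios of one brain, one row per region."""
    starters = interpolate_starters(counts)
    rows = [
        {
            "brain_id": counts.brain_id,
            "group": counts.group,
            "region": region,
            "hemisphere": counts.hemispheres.get(region, "contralesional"),
            "presyn_count": n,
            "starters_whole_brain": starters,
            "connectivity_ratio": connectivity_ratio(n, starters),
        }
        for region, n in counts.region_counts.items()
    ]
    return pd.DataFrame(rows)


def build_connectivity_table(
    brains: list[TracingCounts],
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-level connectivity table and group-vs-control comparisons.

    Brains with zero starters are excluded from ratio aggregation (their
    exclusion is visible as a reduced ``n``). The comparison table reports a
    two-tailed t-test per (region, pair) wherever both groups have at least
    two defined ratios.
    """
    if not brains:
        raise ValueError("at least one brain is required")
    per_brain = pd.concat([brain_ratios(b) for b in brains], ignore_index=True)
    per_brain = per_brain.sort_values(["group", "region", "brain_id"], kind="stable")

    rows = []
    for (group, region, hemi), sub in per_brain.groupby(
        ["group", "region", "hemisphere"], sort=True
    ):
        vals = sub["connectivity_ratio"].dropna()
        n = len(vals)
        rows.append(
            {
                "group": group,
                "region": region,
                "hemisphere": hemi,
                "mean_ratio": float(vals.mean()) if n else UNDEFINED,
                "sem": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else UNDEFINED,
                "n_brains": n,
                "n_excluded": int(len(sub) - n),
            }
        )
    table = pd.DataFrame(rows)

    comp_rows = []
    for treat, ctrl in comparisons:
        regions = per_brain.loc[per_brain["group"].isin([treat, ctrl]), "region"].unique()
        for region in sorted(regions):
            a = per_brain.query("group == @treat and region == @region")[
                "connectivity_ratio"
            ].dropna()
            b = per_brain.query("group == @ctrl and region == @region")[
                "connectivity_ratio"
            ].dropna()
            if len(a) < 2 or len(b) < 2:
                continue
            rep = standard_test("t_two_sided", [a.to_numpy(), b.to_numpy()])
            comp_rows.append(
                {
                    "region": region,
                    "group": treat,
                    "control": ctrl,
                    "statistic": rep["statistic"],
                    "p_value": rep["p_value"],
                    "test": rep["test"],
                }
            )
    return table, pd.DataFrame(comp_rows)
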