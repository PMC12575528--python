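"""Threshold-based alpha-synuclein distribution group and subgroup assignment.

A case is alpha-syn positive when its *individually most affected* region
reaches >= 0.3% covered area.  Positive cases are subtyped from two summary
loads: the mean cortical load over the most affected cortical regions
(cingulate gyrus, superior temporal gyrus, middle temporal gyrus, insular
gyrus) and the brainstem summary (substantia nigra or locus coeruleus, or
the mean of both if both are available):

* subgroup C (cortical)              -- cortical mean >= threshold
* subgroup B (brainstem-predominant) -- else, brainstem summary >= threshold
* subgroup A (amygdala-predominant)  -- the residual positive class

Precedence C > B > A: cortical spread dominates because cortical cases
typically also carry a relatively high brainstem load.  A case may be
called negative only if its amygdala was stained (the region most affected
in AD); otherwise it is ineligible, not negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import (
    BRAINSTEM_SUMMARY_REGIONS,
    CORTICAL_SUMMARY_REGIONS,
    RegionRegistry,
    load_registry,
)

__all__ = [
    "GroupThresholds",
    "GroupAssignment",
    "aggregate_region",
    "aggregate_loads",
    "brainstem_summary",
    "cortical_summary",
    "assign_group",
    "assign_groups",
]


@dataclass(frozen=True)
class GroupThresholds:
    positivity_pct: float = 0.3
    cortical_regions: tuple[str, ...] = CORTICAL_SUMMARY_REGIONS
    brainstem_regions: tuple[str, ...] = BRAINSTEM_SUMMARY_REGIONS

    def __post_init__(self) -> None:
        if self.positivity_pct <= 0:
            raise ValueError("positivity threshold must be positive")


@dataclass(frozen=True)
class GroupAssignment:
    subject_id: str
    group: str            # alpha_syn_negative | alpha_syn_positive | none
    subgroup: str         # A | B | C | none
    max_load: float       # percent; nan if no loads
    cortical_mean: float  # percent; nan if no listed cortical region stained
    brainstem_mean: float  # percent; nan if neither SN nor LC stained
    eligible: bool
    reason: str = ""

    def __post_init__(self) -> None:
        positive = self.group == "alpha_syn_positive"
        if positive != (self.subgroup != "none"):
            raise ValueError("subgroup must be set iff the group is positive")
        if not self.eligible and self.group != "none":
            raise ValueError("ineligible subjects carry no group")


def aggregate_region(measurements: pd.DataFrame, registry: RegionRegistry | None = None) -> float:
    """Collapse the annotations of one subject x stain x region to one load.

    QC-failing rows are dropped; the remaining annotation values are
    averaged (the mean of the two squares for substantia nigra and locus
    coeruleus, a passthrough for singly-annotated regions).  Returns NaN
    when no QC-passing measurement exists.
    """
    if measurements.empty:
        return math.nan
    passing = measurements.loc[measurements["qc_flag"] == "pass", "covered_area_pct"]
    if passing.empty:
        return math.nan
    return float(passing.mean())


def aggregate_loads(measurements: pd.DataFrame, registry: RegionRegistry | None = None) -> pd.DataFrame:
    """Aggregate a long measurements table to one row per subject x stain x region."""
    required = {"subject_id", "stain", "region", "covered_area_pct", "qc_flag"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements table lacks columns: {sorted(missing)}")
    passing = measurements[measurements["qc_flag"] == "pass"]
    out = (
        passing.groupby(["subject_id", "stain", "region"], as_index=False)["covered_area_pct"]
        .mean()
    )
    return out


def brainstem_summary(loads: dict[str, float], thresholds: GroupThresholds | None = None) -> float:
    """Substantia nigra, or locus coeruleus, or the mean of both if available."""
    thresholds = thresholds or GroupThresholds()
    values = [loads[r] for r in thresholds.brainstem_regions
              if r in loads and not math.isnan(loads[r])]
    if not values:
        return math.nan
    return float(np.mean(values))


def cortical_summary(loads: dict[str, float], thresholds: GroupThresholds | None = None) -> float:
    """Mean load over the available listed cortical regions."""
    thresholds = thresholds or GroupThresholds()
    values = [loads[r] for r in thresholds.cortical_regions
              if r in loads and not math.isnan(loads[r])]
    if not values:
        return math.nan
    return float(np.mean(values))


def assign_group(
    loads: dict[str, float],
    thresholds: GroupThresholds | None = None,
    subject_id: str = "",
) -> GroupAssignment:
    """Assign one subject's alpha-syn distribution group from regional loads.

    ``loads`` maps region -> aggregated alpha-syn covered area in percent
    (absent or NaN = region not stained).  The >= comparison makes the 0.3%
    boundary inclusive.
    """
    thresholds = thresholds or GroupThresholds()
    clean = {r: v for r, v in loads.items() if v is not None and not math.isnan(v)}
    thr = thresholds.positivity_pct

    cort = cortical_summary(clean, thresholds)
    stem = brainstem_summary(clean, thresholds)

    if not clean:
        return GroupAssignment(subject_id, "none", "none", math.nan, cort, stem,
                               eligible=False, reason="no alpha-syn measurements")
    max_load = float(max(clean.values()))

    if max_load < thr:
        if "amygdala" not in clean:
            return GroupAssignment(
                subject_id, "none", "none", max_load, cort, stem, eligible=False,
                reason="below threshold everywhere but amygdala not stained",
            )
        return GroupAssignment(subject_id, "alpha_syn_negative", "none",
                               max_load, cort, stem, eligible=True)

    reason = ""
    if not math.isnan(cort) and cort >= thr:
        subgroup = "C"
    elif not math.isnan(stem) and stem >= thr:
        subgroup = "B"
    else:
        subgroup = "A"
        if math.isnan(cort):
            reason = "no listed cortical region stained; C could not be tested"
    return GroupAssignment(subject_id, "alpha_syn_positive", subgroup,
                           max_load, cort, stem, eligible=True, reason=reason)


def assign_groups(
    measurements: pd.DataFrame,
    thresholds: GroupThresholds | None = None,
    registry: RegionRegistry | None = None,
) -> pd.DataFrame:
    """Assign every subject in a measurements table (alpha-syn stain only).

    Returns one row per subject: group, subgroup, the three threshold
    statistics, eligibility and reason.
    """
    thresholds = thresholds or GroupThresholds()
    registry = registry or load_registry()
    alpha = measurements[measurements["stain"] == "alpha_syn"]
    agg = aggregate_loads(alpha, registry)
    rows = []
    for subject_id, sub in agg.groupby("subject_id"):
        loads = dict(zip(sub["region"], sub["covered_area_pct"]))
        a = assign_group(loads, thresholds, subject_id=str(subject_id))
        rows.append({
            "subject_id": a.subject_id,
            "group": a.group,
            "subgroup": a.subgroup,
            "max_load": a.max_load,
            "cortical_mean": a.cortical_mean,
            "brainstem_mean": a.brainstem_mean,
            "eligible": a.eligible,
            "reason": a.reason,
        })
    return pd.DataFrame(rows)
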