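"""Group summaries, two-group comparison, posture subsets, Bramwell–Hill.

The unit of analysis is the record (one measurement session), not the
beat; beat-level values are already aggregated upstream. Group
comparison uses Welch's unequal-variance t-test with Satterthwaite
degrees of freedom — the groups' spreads differ visibly, so the pooled-
variance Student test would be inappropriate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .errors import ConfigurationError

__all__ = [
    "GroupSummary", "ComparisonResult", "HemoParams", "MMHG_TO_PA",
    "summarize_group", "compare_groups", "bramwell_hill_pwv",
    "select_height_ordered",
]

MMHG_TO_PA = 133.322


@dataclass(frozen=True)
class GroupSummary:
    group: str
    feature: str
    n_records: int
    mean: float
    min: float
    max: float


@dataclass(frozen=True)
class ComparisonResult:
    feature: str
    t: float
    df: float
    p_value: float
    group_means: Dict[str, float]
    direction: str  # e.g. "diabetes < control"


@dataclass(frozen=True)
class HemoParams:
    """Inputs to the Bramwell–Hill relation (SI units)."""

    pulse_pressure: float   # Pa
    blood_density: float    # kg/m^3
    vessel_volume: float
    volume_change: float    # same units as vessel_volume

    def validate(self) -> None:
        if self.pulse_pressure < 0:
            raise ConfigurationError("pulse_pressure must be >= 0")
        if self.blood_density <= 0:
            raise ConfigurationError("blood_density must be positive")
        if self.vessel_volume <= 0 or self.volume_change <= 0:
            raise ConfigurationError("volumes must be positive")


def summarize_group(cohort: pd.DataFrame, group: str,
                    feature: str) -> Optional[GroupSummary]:
    """Mean/min/max of a record-level feature within one group.

    Returns ``None`` (absent summary) for an empty group.
    """
    vals = cohort.loc[cohort["group"] == group, feature].dropna()
    if vals.empty:
        return None
    return GroupSummary(group=group, feature=feature, n_records=len(vals),
                        mean=float(vals.mean()), min=float(vals.min()),
                        max=float(vals.max()))


def compare_groups(cohort: pd.DataFrame, feature: str,
                   group_col: str = "group") -> ComparisonResult:
    """Welch two-sample t-test on record-level feature values.

    Two-sided p-value; degrees of freedom by Satterthwaite. When both
    groups have zero variance and equal means the comparison is vacuous
    and reported as t = 0, p = 1 by convention.
    """
    groups = [g for g in cohort[group_col].dropna().unique()]
    if len(groups) != 2:
        raise ConfigurationError(
            f"compare_groups needs exactly 2 groups, found {groups}")
    g1, g2 = sorted(groups)
    x = cohort.loc[cohort[group_col] == g1, feature].dropna().to_numpy()
    y = cohort.loc[cohort[group_col] == g2, feature].dropna().to_numpy()
    if len(x) < 2 or len(y) < 2:
        raise ConfigurationError("each group needs >= 2 records")
    means = {g1: float(np.mean(x)), g2: float(np.mean(y))}
    if np.var(x) == 0 and np.var(y) == 0 and means[g1] == means[g2]:
        return ComparisonResult(feature=feature, t=0.0,
                                df=float(len(x) + len(y) - 2), p_value=1.0,
                                group_means=means,
                                direction=f"{g1} = {g2}")
    res = spstats.ttest_ind(x, y, equal_var=False)
    # Satterthwaite df (scipy exposes it on recent versions; recompute
    # for independence from the scipy minor version)
    vx, vy = np.var(x, ddof=1) / len(x), np.var(y, ddof=1) / len(y)
    df = (vx + vy) ** 2 / (vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1))
    if means[g1] < means[g2]:
        direction = f"{g1} < {g2}"
    elif means[g1] > means[g2]:
        direction = f"{g1} > {g2}"
    else:
        direction = f"{g1} = {g2}"
    return ComparisonResult(feature=feature, t=float(res.statistic),
                            df=float(df), p_value=float(res.pvalue),
                            group_means=means, direction=direction)


def bramwell_hill_pwv(params: HemoParams) -> float:
    """Pulse wave velocity from the Bramwell–Hill relation.

    PWV^2 = ΔP·V / (ρ·ΔV): a stiffer vessel (small fractional volume
    change per unit pulse pressure) carries the pressure pulse faster.
    Returns PWV in m/s when inputs are in SI units.
    """
    params.validate()
    return math.sqrt(params.pulse_pressure * params.vessel_volume
                     / (params.blood_density * params.volume_change))


def select_height_ordered(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-subject posture triplets with strictly height-ordered pressures.

    Selects subjects measured at all three heights whose wrist systolic
    pressures satisfy navel > chest > forehead strictly (hydrostatic
    ordering). When a subject has several records at one posture, the
    first by record id is used. Returns the selected records (three rows
    per selected subject); empty result allowed.
    """
    needed = ("navel", "chest", "forehead")
    frames: List[pd.DataFrame] = []
    for _, sub in cohort.groupby("subject_id"):
        picks = {}
        for posture in needed:
            rows = sub[sub["posture"] == posture].sort_values("record_id")
            if rows.empty or pd.isna(rows.iloc[0]["wrist_sbp"]):
                break
            picks[posture] = rows.iloc[0]
        if len(picks) != 3:
            continue
        sbp = [picks[p]["wrist_sbp"] for p in needed]
        if sbp[0] > sbp[1] > sbp[2]:
            frames.append(pd.DataFrame([picks[p] for p in needed]))
    if not frames:
        return cohort.iloc[0:0].copy()
    return pd.concat(frames, ignore_index=True)
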