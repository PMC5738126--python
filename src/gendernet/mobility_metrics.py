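"""Location-based indicators: unique location counts and location entropy.

A participant's week is summarized by the relative time distribution P_u(l)
over the locations l visited that week.  Location entropy

    H_u = - sum_l P_u(l) log P_u(l)

(natural log by default; the base is configurable and cancels in effect-size
comparisons) measures how evenly time is spread across places, and |L(u)| is
the number of unique locations.  Weekly values are averaged per participant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_data import Cohort


@dataclass
class WeeklyLocationDistribution:
    participant: str
    week: int
    p: dict[str, float]  # location -> relative time fraction, positive, sums to 1

    def __post_init__(self) -> None:
        if self.p:
            if any(v <= 0 for v in self.p.values()):
                raise ValueError("time fractions must be positive")
            if abs(sum(self.p.values()) - 1.0) > 1e-9:
                raise ValueError("time fractions must sum to 1")

    @property
    def support(self) -> set[str]:
        return set(self.p)


def location_entropy(dist: WeeklyLocationDistribution | dict, base: float | None = None) -> float:
    """Shannon entropy of the weekly location-visit distribution.

    ``base=None`` means natural log (nats).  Empty distribution -> NaN
    (undefined indicator).  0 <= H <= log |L(u)|.
    """
    p = dist.p if isinstance(dist, WeeklyLocationDistribution) else dist
    if not p:
        return float("nan")
    vals = np.asarray(list(p.values()), dtype=float)
    h = float(-(vals * np.log(vals)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def unique_locations(dist: WeeklyLocationDistribution | dict) -> float:
    """Number of unique locations visited in the week; NaN if empty."""
    p = dist.p if isinstance(dist, WeeklyLocationDistribution) else dist
    return float(len(p)) if p else float("nan")


def mobility_indicator_table(
    cohort: Cohort, locations: pd.DataFrame, base: float | None = None
) -> pd.DataFrame:
    """Per-participant mobility indicators, weekly values averaged.

    ``locations`` uses the locations.csv layout (id, week, location_id,
    time_fraction).  Participants with no location data get NaN rows.
    """
    idx = pd.Index(cohort.ids, name="id")
    out = pd.DataFrame(
        index=idx, columns=["location_entropy", "n_unique_locations"], dtype=float
    )
    if len(locations) == 0:
        return out
    loc = locations[locations["id"].isin(set(cohort.ids))]
    if len(loc) == 0:
        return out
    f = loc["time_fraction"].to_numpy(dtype=float)
    plogp = pd.Series(-f * np.log(f), index=loc.index)
    grouped = loc.groupby(["id", "week"])
    ent = plogp.groupby([loc["id"], loc["week"]]).sum()
    if base is not None:
        ent = ent / math.log(base)
    nloc = grouped.size().astype(float)
    weekly = pd.DataFrame({"location_entropy": ent, "n_unique_locations": nloc})
    per_participant = weekly.groupby(level="id").mean()
    out.loc[per_participant.index, :] = per_participant
    return out.astype(float)
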