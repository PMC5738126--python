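"""Core data model, CSV I/O, weekly aggregation, and cohort-level filtering.

The study cohort is a set of participants with a binary gender label observed
over a contiguous range of weeks through five interaction channels (physical
proximity, Facebook friendship, Facebook feed interactions, calls, texts),
weekly location-visit distributions, and an eleven-trait personality
questionnaire battery.  Every downstream indicator is computed per week and
averaged per individual, so the weekly graph series is the central container.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

FEMALE = "F"
MALE = "M"
GENDERS = (FEMALE, MALE)

#: The five interaction channels, in canonical order.
CHANNELS = ("proximity", "facebook_friend", "facebook_interaction", "call", "text")

#: Channels that carry a directed event stream (initiator known).
DIRECTED_CHANNELS = ("call", "text")

TRAIT_COLUMNS = (
    "neuroticism",
    "conscientiousness",
    "agreeableness",
    "extraversion",
    "openness",
    "self_esteem",
    "narcissism_total",
    "narcissism_admiration",
    "narcissism_rivalry",
    "stress",
    "locus_of_control",
    "satisfaction",
    "loneliness",
)

INTERACTION_COLUMNS = (
    "channel",
    "week",
    "source",
    "target",
    "weight",
    "duration_s",
    "initiator_is_source",
)


class ParseError(ValueError):
    """A malformed row in an input file (message names file and line)."""


class ReferentialIntegrityError(ValueError):
    """A row references a participant id absent from the participants table."""


@dataclass
class Participant:
    id: str
    gender: str
    active_weeks: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {self.gender!r}")


@dataclass
class Cohort:
    """Participants plus the contiguous week range of the observation window."""

    participants: dict[str, Participant]
    week_range: list[int]

    def __post_init__(self) -> None:
        if not self.week_range:
            raise ValueError("week_range must be non-empty")
        wr = list(self.week_range)
        if wr != list(range(wr[0], wr[0] + len(wr))):
            raise ValueError("week_range must be contiguous")
        allowed = set(wr)
        for p in self.participants.values():
            if not set(p.active_weeks) <= allowed:
                raise ValueError(f"active_weeks of {p.id} outside week_range")

    def __len__(self) -> int:
        return len(self.participants)

    @property
    def ids(self) -> list[str]:
        return sorted(self.participants)

    def genders(self) -> dict[str, str]:
        return {pid: p.gender for pid, p in self.participants.items()}

    def n_gender(self, gender: str) -> int:
        return sum(1 for p in self.participants.values() if p.gender == gender)


@dataclass
class InteractionRecord:
    """One aggregated interaction between two participants in one week."""

    channel: str
    week: int
    source: str
    target: str
    weight: int = 1
    duration_s: float | None = None
    initiator_is_source: bool | None = None

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.source == self.target:
            raise ValueError("self-interactions are not allowed")
        if self.weight < 1:
            raise ValueError("weight must be >= 1")
        if (self.duration_s is not None) != (self.channel == "call"):
            raise ValueError("duration_s present iff channel == 'call'")
        if self.initiator_is_source is not None and self.channel not in DIRECTED_CHANNELS:
            raise ValueError("initiator flag only valid for call/text")


@dataclass
class ChannelNetworkSeries:
    """Weekly undirected graphs for one channel.

    Nodes carry a ``gender`` attribute.  For directed channels (call, text)
    a parallel event table retains initiator direction and, for calls,
    per-event durations, which the structural graphs deliberately discard.
    """

    channel: str
    weekly_graphs: dict[int, nx.Graph] = field(default_factory=dict)
    events: pd.DataFrame | None = None

    def aggregate(self, weeks: Iterable[int] | None = None) -> nx.Graph:
        """Union of weekly graphs over ``weeks`` (default: all), weights summed."""
        graphs = self.weekly_graphs
        if weeks is not None:
            weeks = set(weeks)
            graphs = {w: g for w, g in graphs.items() if w in weeks}
        out = nx.Graph()
        for g in graphs.values():
            out.add_nodes_from(g.nodes(data=True))
            for u, v, d in g.edges(data=True):
                w = d.get("weight", 1)
                if out.has_edge(u, v):
                    out[u][v]["weight"] += w
                else:
                    out.add_edge(u, v, weight=w)
        return out


def records_to_frame(records: Iterable[InteractionRecord]) -> pd.DataFrame:
    """Canonical interactions DataFrame from a sequence of records."""
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=list(INTERACTION_COLUMNS))
    return df


def aggregate_weekly(
    interactions: pd.DataFrame | Iterable[InteractionRecord],
    channel: str,
    cohort: Cohort | None = None,
) -> ChannelNetworkSeries:
    """Aggregate interaction rows of one channel into weekly undirected graphs.

    Per week there is one edge per unordered pair with the summed weight.
    Directed channels additionally keep the raw (initiator -> receiver) event
    list with weights and call durations.  If ``cohort`` is given, its
    participants become nodes of every weekly graph (with gender labels), so
    isolates are represented.
    """
    if not isinstance(interactions, pd.DataFrame):
        interactions = records_to_frame(interactions)
    df = interactions[interactions["channel"] == channel] if len(interactions) else interactions
    if len(df) and not (df["channel"] == channel).all():
        raise ValueError("all records must share the given channel")

    events = None
    if channel in DIRECTED_CHANNELS:
        if len(df):
            init_src = df["initiator_is_source"].fillna(True).astype(bool)
            events = pd.DataFrame(
                {
                    "week": df["week"].astype(int).to_numpy(),
                    "initiator": np.where(init_src, df["source"], df["target"]),
                    "receiver": np.where(init_src, df["target"], df["source"]),
                    "weight": df["weight"].astype(int).to_numpy(),
                    "duration_s": df["duration_s"].to_numpy(dtype=float),
                }
            )
        else:
            events = pd.DataFrame(
                columns=["week", "initiator", "receiver", "weight", "duration_s"]
            )

    series = ChannelNetworkSeries(channel=channel, events=events)
    genders = cohort.genders() if cohort is not None else {}

    def _new_graph() -> nx.Graph:
        g = nx.Graph()
        if cohort is not None:
            g.add_nodes_from((pid, {"gender": gen}) for pid, gen in genders.items())
        return g

    if len(df):
        a = df["source"].to_numpy()
        b = df["target"].to_numpy()
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        agg = (
            pd.DataFrame(
                {"week": df["week"].astype(int).to_numpy(), "u": lo, "v": hi,
                 "weight": df["weight"].astype(int).to_numpy()}
            )
            .groupby(["week", "u", "v"], sort=True)["weight"]
            .sum()
            .reset_index()
        )
        for week, sub in agg.groupby("week", sort=True):
            g = _new_graph()
            g.add_weighted_edges_from(
                zip(sub["u"], sub["v"], sub["weight"].astype(int))
            )
            for node in g.nodes:
                if "gender" not in g.nodes[node]:
                    g.nodes[node]["gender"] = None  # non-participant alter
            series.weekly_graphs[int(week)] = g
    return series


def compute_active_weeks(
    cohort: Cohort, interactions: pd.DataFrame, locations: pd.DataFrame
) -> None:
    """Mark a week active if the participant has any interaction row in any
    channel or any location observation that week (in place)."""
    for p in cohort.participants.values():
        p.active_weeks = set()
    if len(interactions):
        for col in ("source", "target"):
            pairs = interactions[[col, "week"]].drop_duplicates()
            for pid, week in pairs.itertuples(index=False):
                if pid in cohort.participants:
                    cohort.participants[pid].active_weeks.add(int(week))
    if len(locations):
        for pid, week in locations[["id", "week"]].drop_duplicates().itertuples(index=False):
            if pid in cohort.participants:
                cohort.participants[pid].active_weeks.add(int(week))


def filter_active(cohort: Cohort, min_active_weeks: int = 4) -> Cohort:
    """Exclude participants with fewer than ``min_active_weeks`` active weeks.

    The default of 4 excludes participants with three active weeks or less.
    """
    kept = {
        pid: Participant(p.id, p.gender, set(p.active_weeks))
        for pid, p in cohort.participants.items()
        if len(p.active_weeks) >= min_active_weeks
    }
    return Cohort(participants=kept, week_range=list(cohort.week_range))


def weekly_average(indicator_by_week: Mapping[int, float]) -> float:
    """Arithmetic mean over the weeks in which the indicator is defined.

    Undefined (NaN) weeks are skipped rather than treated as zeros; an empty
    or all-undefined map yields NaN, the missing-value marker.
    """
    vals = [v for v in indicator_by_week.values() if v is not None and not math.isnan(v)]
    if not vals:
        return float("nan")
    return float(sum(vals) / len(vals))


@dataclass
class CohortData:
    """Fully cross-referenced in-memory model of one study data set."""

    cohort: Cohort
    networks: dict[str, ChannelNetworkSeries]
    interactions: pd.DataFrame
    locations: pd.DataFrame
    traits: pd.DataFrame  # index: participant id; columns: TRAIT_COLUMNS


def _read_csv(path: str | Path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, **kw)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_cohort(
    participants_path: str | Path,
    interactions_path: str | Path,
    locations_path: str | Path,
    traits_path: str | Path,
    n_weeks: int | None = None,
    min_active_weeks: int | None = None,
) -> CohortData:
    """Load the four CSV tables and cross-reference them.

    Interaction, location, or trait rows referencing unknown participant ids
    raise :class:`ReferentialIntegrityError`.  Active weeks are computed from
    interactions and locations; if ``min_active_weeks`` is given the cohort is
    filtered immediately.
    """
    parts = _read_csv(participants_path, dtype={"id": str})
    if set(parts.columns) != {"id", "gender"}:
        raise ParseError(f"{participants_path}: expected columns id,gender")
    if parts["id"].duplicated().any():
        dup = parts.loc[parts["id"].duplicated(), "id"].iloc[0]
        raise ParseError(f"{participants_path}: duplicate participant id {dup!r}")
    bad = ~parts["gender"].isin(GENDERS)
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ParseError(f"{participants_path}:{line}: gender must be F or M")

    interactions = _read_csv(
        interactions_path, dtype={"source": str, "target": str, "channel": str}
    )
    if len(interactions) == 0:
        interactions = pd.DataFrame(columns=list(INTERACTION_COLUMNS))
    missing_cols = set(INTERACTION_COLUMNS) - set(interactions.columns)
    if missing_cols:
        raise ParseError(f"{interactions_path}: missing columns {sorted(missing_cols)}")
    locations = _read_csv(locations_path, dtype={"id": str, "location_id": str})
    if len(locations) == 0:
        locations = pd.DataFrame(columns=["id", "week", "location_id", "time_fraction"])
    traits = _read_csv(traits_path, dtype={"id": str})
    if "id" not in traits.columns:
        raise ParseError(f"{traits_path}: missing id column")
    traits = traits.set_index("id")

    known = set(parts["id"])
    for name, frame, cols in (
        (interactions_path, interactions, ("source", "target")),
        (locations_path, locations, ("id",)),
    ):
        for col in cols:
            if len(frame):
                unknown = frame.loc[~frame[col].isin(known), col]
                if len(unknown):
                    raise ReferentialIntegrityError(
                        f"{name}: unknown participant id {unknown.iloc[0]!r} in column {col}"
                    )
    unknown_traits = set(traits.index) - known
    if unknown_traits:
        raise ReferentialIntegrityError(
            f"{traits_path}: unknown participant id {sorted(unknown_traits)[0]!r}"
        )
    if len(locations):
        sums = locations.groupby(["id", "week"])["time_fraction"].sum()
        off = sums[(sums - 1.0).abs() > 1e-6]
        if len(off):
            pid, week = off.index[0]
            raise ParseError(
                f"{locations_path}: time fractions of id {pid!r} week {week} sum to "
                f"{off.iloc[0]:.6f}, expected 1"
            )

    if n_weeks is None:
        max_week = -1
        if len(interactions):
            max_week = max(max_week, int(interactions["week"].max()))
        if len(locations):
            max_week = max(max_week, int(locations["week"].max()))
        n_weeks = max_week + 1 if max_week >= 0 else 1
    cohort = Cohort(
        participants={
            row.id: Participant(row.id, row.gender) for row in parts.itertuples(index=False)
        },
        week_range=list(range(n_weeks)),
    )
    compute_active_weeks(cohort, interactions, locations)
    if min_active_weeks is not None:
        cohort = filter_active(cohort, min_active_weeks)
        keep = set(cohort.participants)
        if len(interactions):
            interactions = interactions[
                interactions["source"].isin(keep) & interactions["target"].isin(keep)
            ].reset_index(drop=True)
        if len(locations):
            locations = locations[locations["id"].isin(keep)].reset_index(drop=True)
        traits = traits[traits.index.isin(keep)]

    networks = {ch: aggregate_weekly(interactions, ch, cohort) for ch in CHANNELS}
    traits = traits.reindex(cohort.ids)
    return CohortData(cohort, networks, interactions, locations, traits)


@dataclass
class StudyConfig:
    start_date: str = "2013-09-02"  # Monday-aligned study start
    n_weeks: int = 36
    min_active_weeks: int = 4
    seed: int = 0


def load_study_config(path: str | Path) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return StudyConfig(**{k: raw[k] for k in raw if k in StudyConfig.__dataclass_fields__})
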