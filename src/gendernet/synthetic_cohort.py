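"""Synthetic cohort generator with the statistical structure of the study.

The real cohort (166 women, 601 men observed over ~36 weeks through five
interaction channels, weekly location distributions, and an eleven-trait
questionnaire battery) is private, so every downstream stage is exercised on
generated cohorts that plant the quantities the analysis is supposed to
recover:

* trait scores are Normal(mu_gender, 1) with mu_male - mu_female equal to the
  configured signed effect size (unit variance in both groups makes planted
  effects exactly pooled-SD units);
* weekly location distributions are symmetric Dirichlet draws whose
  concentration controls entropy, with a per-gender mean unique-location
  count;
* each channel's weekly edges are sampled per dyad with probability
  p0 * (1 + h) for same-gender and p0 * (1 - h) for mixed dyads, where h in
  [0, 1] is the planted dyadic homophily (triad homophily then emerges and is
  measured, not planted); weights are shifted-Poisson per gender-pair class,
  and calls carry log-normal durations with gender-pair-specific means;
* per-category MCAR missingness removes a participant's raw data in a whole
  feature category at random.

Default parameters are the study conditions: 166/601 gender counts, 36 weeks,
the published trait effect sizes, weekly edge probabilities back-solved from
the published monthly active-dyad fractions (40% proximity, ~2.5% Facebook
friendship, <1% telecom), published mean call durations, and a 5% per-category
missing rate matching 21.5% of participants missing at least one channel.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_data import (
    CHANNELS,
    INTERACTION_COLUMNS,
    TRAIT_COLUMNS,
    ChannelNetworkSeries,
    Cohort,
    CohortData,
    Participant,
    aggregate_weekly,
    compute_active_weeks,
)
from .imputation import CATEGORIES

#: Which channels each feature category masks (for MCAR missingness).
CATEGORY_CHANNELS = {
    "call": ("call", "text"),
    "Facebook": ("facebook_friend", "facebook_interaction"),
    "person-to-person": ("proximity",),
}


class ConfigError(ValueError):
    pass


@dataclass
class LocationProfile:
    mean_unique_locations: float
    concentration: float  # symmetric Dirichlet parameter; higher -> higher entropy


@dataclass
class ChannelProfile:
    weekly_edge_prob: float
    homophily: float  # h in [0, 1]
    weight_mean: dict[str, float] = field(
        default_factory=lambda: {"FF": 2.0, "FM": 2.0, "MM": 2.0}
    )
    #: call only: mean duration (s) per ordered (initiator, receiver) gender pair
    duration_mean_s: dict[str, float] | None = None
    duration_sigma: float = 0.8  # log-normal shape


def _default_channel_profiles() -> dict[str, ChannelProfile]:
    # Weekly edge probabilities p solve 1 - (1 - p)^4 = published monthly
    # active-dyad fraction (0.40 proximity, 0.025 Facebook friendship,
    # 0.008 Facebook feed / texts, 0.006 calls).
    return {
        "proximity": ChannelProfile(0.12, 0.20, {"FF": 3.0, "FM": 3.0, "MM": 3.0}),
        "facebook_friend": ChannelProfile(0.0063, 0.25, {"FF": 1.0, "FM": 1.0, "MM": 1.0}),
        "facebook_interaction": ChannelProfile(0.002, 0.25, {"FF": 3.0, "FM": 2.0, "MM": 1.5}),
        "call": ChannelProfile(
            0.0015,
            0.15,
            {"FF": 2.5, "FM": 2.0, "MM": 1.5},
            duration_mean_s={"MF": 117.0, "FF": 114.56, "MM": 71.52, "FM": 95.0},
        ),
        "text": ChannelProfile(0.002, 0.15, {"FF": 4.0, "FM": 2.5, "MM": 1.5}),
    }


def _default_trait_effects() -> dict[str, float]:
    # Published signed effect sizes (male minus female, pooled-SD units).
    return {
        "neuroticism": -0.635,
        "conscientiousness": -0.436,
        "agreeableness": -0.259,
        "extraversion": -0.118,
        "openness": 0.143,
        "stress": -0.451,
        "self_esteem": 0.423,
        "narcissism_total": 0.349,
        "narcissism_rivalry": 0.334,
        "narcissism_admiration": 0.241,
        "locus_of_control": -0.157,
        "satisfaction": -0.149,
        "loneliness": 0.095,
    }


@dataclass
class GeneratorConfig:
    n_female: int = 166
    n_male: int = 601
    n_weeks: int = 36
    trait_effects: dict[str, float] = field(default_factory=_default_trait_effects)
    location_profiles: dict[str, LocationProfile] = field(
        default_factory=lambda: {
            "F": LocationProfile(12.0, 1.0),
            "M": LocationProfile(10.0, 0.7),
        }
    )
    channel_profiles: dict[str, ChannelProfile] = field(
        default_factory=_default_channel_profiles
    )
    missing_rate: float = 0.05
    n_location_pool: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_female <= 0 or self.n_male <= 0 or self.n_weeks <= 0:
            raise ConfigError("counts must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        for ch, prof in self.channel_profiles.items():
            if not 0 <= prof.homophily <= 1:
                raise ConfigError(f"{ch}: homophily must be in [0, 1]")
            if prof.weekly_edge_prob * (1 + prof.homophily) > 1:
                raise ConfigError(f"{ch}: edge probability with homophily exceeds 1")


def expected_same_gender_fraction(n_female: int, n_male: int, h: float) -> float:
    """Expected fraction of same-gender edges under the planted edge model.

    With n_ss same-gender and n_sd mixed dyads, acceptance proportional to
    (1+h) / (1-h) gives  n_ss(1+h) / (n_ss(1+h) + n_sd(1-h)); strictly
    increasing in h.
    """
    n = n_female + n_male
    n_ss = n_female * (n_female - 1) / 2 + n_male * (n_male - 1) / 2
    n_sd = n_female * n_male
    return n_ss * (1 + h) / (n_ss * (1 + h) + n_sd * (1 - h))


@dataclass
class SyntheticData:
    config: GeneratorConfig
    cohort: Cohort
    networks: dict[str, ChannelNetworkSeries]
    interactions: pd.DataFrame
    locations: pd.DataFrame
    traits: pd.DataFrame
    missing_mask: pd.DataFrame  # participants x categories, True = masked
    truth: dict

    def as_cohort_data(self) -> CohortData:
        return CohortData(
            self.cohort, self.networks, self.interactions, self.locations, self.traits
        )


def _generate_traits(config: GeneratorConfig, ids, female, rng) -> pd.DataFrame:
    n = len(ids)
    cols = {}
    for trait in TRAIT_COLUMNS:
        d = config.trait_effects.get(trait, 0.0)
        mu = np.where(female, -d / 2.0, d / 2.0)
        cols[trait] = rng.normal(mu, 1.0, size=n)
    return pd.DataFrame(cols, index=pd.Index(ids, name="id"))


def _generate_locations(config: GeneratorConfig, ids, female, rng) -> pd.DataFrame:
    rows_id, rows_week, rows_loc, rows_frac = [], [], [], []
    pool = config.n_location_pool
    for pid, is_f in zip(ids, female):
        prof = config.location_profiles["F" if is_f else "M"]
        lam = max(prof.mean_unique_locations - 1.0, 0.0)
        for week in range(config.n_weeks):
            n_l = 1 + rng.poisson(lam)
            n_l = min(n_l, pool)
            locs = rng.choice(pool, size=n_l, replace=False)
            frac = rng.dirichlet(np.full(n_l, prof.concentration))
            rows_id.extend([pid] * n_l)
            rows_week.extend([week] * n_l)
            rows_loc.extend(f"L{j:03d}" for j in locs)
            rows_frac.extend(frac)
    return pd.DataFrame(
        {
            "id": rows_id,
            "week": rows_week,
            "location_id": rows_loc,
            "time_fraction": rows_frac,
        }
    )


def _generate_channel(
    config: GeneratorConfig, channel: str, ids, female, rng
) -> pd.DataFrame:
    prof = config.channel_profiles[channel]
    n = len(ids)
    iu, iv = np.triu_indices(n, k=1)
    same = female[iu] == female[iv]
    n_female_pair = female[iu].astype(int) + female[iv].astype(int)
    p = np.where(same, prof.weekly_edge_prob * (1 + prof.homophily),
                 prof.weekly_edge_prob * (1 - prof.homophily))
    lam_by_class = np.array(
        [prof.weight_mean["MM"], prof.weight_mean["FM"], prof.weight_mean["FF"]]
    )
    lam = np.maximum(lam_by_class[n_female_pair] - 1.0, 0.0)
    frames = []
    ids_arr = np.asarray(ids, dtype=object)
    for week in range(config.n_weeks):
        hit = rng.random(len(iu)) < p
        s_idx, t_idx = iu[hit], iv[hit]
        m = len(s_idx)
        if m == 0:
            continue
        weights = 1 + rng.poisson(lam[hit])
        duration = np.full(m, np.nan)
        init_src = np.full(m, np.nan)
        if channel in ("call", "text"):
            init_src = (rng.random(m) < 0.5).astype(float)
        if channel == "call":
            init_is_f = np.where(init_src == 1.0, female[s_idx], female[t_idx])
            recv_is_f = np.where(init_src == 1.0, female[t_idx], female[s_idx])
            keys = np.array(["MM", "MF", "FM", "FF"])
            pair_key = keys[(init_is_f.astype(int) << 1) | recv_is_f.astype(int)]
            means = np.array([prof.duration_mean_s[k] for k in pair_key])
            sig = prof.duration_sigma
            duration = rng.lognormal(np.log(means) - sig**2 / 2.0, sig)
        frames.append(
            pd.DataFrame(
                {
                    "channel": channel,
                    "week": week,
                    "source": ids_arr[s_idx],
                    "target": ids_arr[t_idx],
                    "weight": weights,
                    "duration_s": duration,
                    "initiator_is_source": init_src,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=list(INTERACTION_COLUMNS))
    return pd.concat(frames, ignore_index=True)


def generate(config: GeneratorConfig) -> SyntheticData:
    """Generate a full synthetic study data set plus its truth record.

    Deterministic in ``config.seed``: one root seed sequence is spawned into
    documented substreams (traits, locations, missingness, then one per
    channel in canonical order), so each component is independently
    reproducible.
    """
    n = config.n_female + config.n_male
    ids = [f"u{i:04d}" for i in range(n)]
    female = np.zeros(n, dtype=bool)
    female[: config.n_female] = True

    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(3 + len(CHANNELS))
    rng_traits = np.random.default_rng(streams[0])
    rng_loc = np.random.default_rng(streams[1])
    rng_miss = np.random.default_rng(streams[2])
    rng_channels = {ch: np.random.default_rng(s) for ch, s in zip(CHANNELS, streams[3:])}

    traits = _generate_traits(config, ids, female, rng_traits)
    locations = _generate_locations(config, ids, female, rng_loc)
    empty = pd.DataFrame(columns=list(INTERACTION_COLUMNS))
    channel_frames = {
        ch: (
            _generate_channel(config, ch, ids, female, rng_channels[ch])
            if ch in config.channel_profiles
            else empty.copy()
        )
        for ch in CHANNELS
    }

    mask = pd.DataFrame(
        rng_miss.random((n, len(CATEGORIES))) < config.missing_rate,
        index=pd.Index(ids, name="id"),
        columns=list(CATEGORIES),
    )
    # apply MCAR masking to the raw tables
    masked_personality = mask.index[mask["personality"]]
    traits.loc[masked_personality, :] = np.nan
    masked_location = set(mask.index[mask["location"]])
    if masked_location:
        locations = locations[~locations["id"].isin(masked_location)].reset_index(drop=True)
    for cat, channels in CATEGORY_CHANNELS.items():
        masked = set(mask.index[mask[cat]])
        if not masked:
            continue
        for ch in channels:
            df = channel_frames[ch]
            if len(df):
                keep = ~(df["source"].isin(masked) | df["target"].isin(masked))
                channel_frames[ch] = df[keep].reset_index(drop=True)

    nonempty = [channel_frames[ch] for ch in CHANNELS if len(channel_frames[ch])]
    if nonempty:
        interactions = pd.concat(nonempty, ignore_index=True)
    else:
        interactions = pd.DataFrame(columns=list(INTERACTION_COLUMNS))

    cohort = Cohort(
        participants={
            pid: Participant(pid, "F" if f else "M") for pid, f in zip(ids, female)
        },
        week_range=list(range(config.n_weeks)),
    )
    compute_active_weeks(cohort, interactions, locations)
    networks = {ch: aggregate_weekly(interactions, ch, cohort) for ch in CHANNELS}

    truth = {
        "seed": config.seed,
        "n_female": config.n_female,
        "n_male": config.n_male,
        "n_weeks": config.n_weeks,
        "trait_effects": dict(config.trait_effects),
        "location_profiles": {
            g: dataclasses.asdict(p) for g, p in config.location_profiles.items()
        },
        "channel_profiles": {
            ch: dataclasses.asdict(p) for ch, p in config.channel_profiles.items()
        },
        "missing_rate": config.missing_rate,
        "expected_same_gender_edge_fraction": {
            ch: expected_same_gender_fraction(
                config.n_female, config.n_male, prof.homophily
            )
            for ch, prof in config.channel_profiles.items()
        },
        "n_masked_by_category": {c: int(mask[c].sum()) for c in CATEGORIES},
    }
    return SyntheticData(
        config=config,
        cohort=cohort,
        networks=networks,
        interactions=interactions,
        locations=locations,
        traits=traits,
        missing_mask=mask,
        truth=truth,
    )


def write_fixture(data: SyntheticData, directory: str | Path) -> dict[str, Path]:
    """Serialize to the cohort CSV dialects plus truth.json.

    Deterministic: same seed produces byte-identical files (rows are written
    in a canonical sort order with a fixed float format).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    parts = pd.DataFrame(
        {"id": data.cohort.ids,
         "gender": [data.cohort.participants[i].gender for i in data.cohort.ids]}
    )
    paths["participants"] = directory / "participants.csv"
    parts.to_csv(paths["participants"], index=False)

    inter = data.interactions.copy()
    if len(inter):
        inter["channel"] = pd.Categorical(inter["channel"], categories=CHANNELS, ordered=True)
        inter = inter.sort_values(
            ["channel", "week", "source", "target"], kind="mergesort"
        )
        inter["channel"] = inter["channel"].astype(str)
        inter["initiator_is_source"] = inter["initiator_is_source"].map(
            lambda v: "" if pd.isna(v) else str(int(v))
        )
    paths["interactions"] = directory / "interactions.csv"
    inter.to_csv(paths["interactions"], index=False, float_format="%.10g",
                 columns=list(INTERACTION_COLUMNS))

    loc = data.locations.sort_values(["id", "week", "location_id"], kind="mergesort")
    paths["locations"] = directory / "locations.csv"
    loc.to_csv(paths["locations"], index=False, float_format="%.12g")

    paths["traits"] = directory / "traits.csv"
    data.traits.sort_index().to_csv(paths["traits"], float_format="%.12g")

    paths["truth"] = directory / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(data.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
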