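"""Synthetic exit-trap campaigns with known directional truth.

Emulates a two-year, two-season field campaign of octagonal emergence
enclosures: per night, three enclosures are stocked with pupae (truncated
normal load, 200-470, mean 345, SD 83), adults emerge, pick a heading from a
von Mises distribution, and are assigned to the exit trap nearest their
heading (a small probability of leaking into a side trap reproduces the
observed heavy corner-vs-side imbalance).  Nightly weather logs emulate a
portable weather station recording every 10 minutes from 18:00 to 06:00,
with seasonal wind regimes: a consistent dry-season NW trade wind and a
weaker, more variable wet-season SW flow.

The default behavioural rule is anemotactic with a seasonal switch — dry
season headings centred downwind of that night's simulated wind, wet season
headings upwind — so the full pipeline can be exercised against a truth
table (per-night intended mean heading, concentration, and the upwind
direction realised by the simulated weather).

Everything is reproducible from a single master seed; each night draws from
a child generator derived from (seed, year, season, night index), so the
campaign is invariant to generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sp_stats

from .dispersal import night_wind_summary
from .trap_records import (
    COMPASS_POINTS,
    CORNER_DIRECTIONS,
    SIDE_DIRECTIONS,
    TrapCountRecord,
    WeatherRecord,
    compass_deg_to_math,
    compass_to_math,
    write_trap_csv,
    write_weather_csv,
)

__all__ = [
    "WindRegime",
    "CampaignConfig",
    "generate_night_weather",
    "generate_enclosure_night",
    "generate_campaign",
    "write_campaign",
    "load_config",
]

TWO_PI = 2.0 * math.pi

# Wet-season captures, chronologically: first morning, same-day afternoon,
# second morning, third morning.  Mornings take check indexes 0, 1, 2 and the
# afternoon 3, so the default analysis window {0, 1} is the two mornings.
CHECK_INDEX_SEQUENCE_WET = (0, 3, 1, 2)

SITES = (("Fulani", "North"), ("Marche", "North"),
         ("Cemetary", "South"), ("Grove", "South"))

_EXACT_KAPPA = 1e8  # above this, von Mises draws collapse to the mean exactly


@dataclass
class WindRegime:
    """Seasonal nightly wind climate.

    mean_from_deg: meteorological mean direction the wind blows from.
    kappa: von Mises concentration of the from-direction.
    mean_speed: grand mean speed in m/s including calm intervals.
    gust_mult: per-reading gust = speed * gust_mult.
    calm_prob: probability a 10-minute interval is dead calm (speed 0).
    rel_humidity / temperature: constants for the season.
    """

    mean_from_deg: float
    kappa: float
    mean_speed: float
    gust_mult: float
    calm_prob: float
    rel_humidity: float
    temperature: float


def _default_wind() -> dict[str, WindRegime]:
    return {
        # Dry season: NW Harmattan, consistent; wet season: weaker SW flow,
        # more variable in direction.  Speeds, gusts, humidity and
        # temperature are the per-season averages of the nightly means.
        "dry": WindRegime(315.0, 4.0, 0.225, 4.5, 0.05, 31.1, 30.8),
        "wet": WindRegime(225.0, 1.0, 0.12, 8.0, 0.15, 94.2, 23.7),
    }


@dataclass
class CampaignConfig:
    """Design and behavioural parameters of one synthetic campaign."""

    seed: int = 0
    nights_per_season: dict[str, int] = field(
        default_factory=lambda: {"dry": 13, "wet": 16}
    )
    years: tuple[int, ...] = (2009, 2010)
    enclosures_per_night: int = 3
    pupae_min: int = 200
    pupae_max: int = 470
    pupae_mean: float = 345.0
    pupae_sd: float = 83.0
    capture_rate: float = 0.2
    p_side: float = 0.036
    kappa: float = 2.0
    heading_rule: str = "anemotactic"        # "anemotactic" or "fixed"
    fixed_mu: float = 3.0 * math.pi / 2.0    # used when heading_rule == "fixed"
    anemotaxis_offset: dict[str, float] = field(
        default_factory=lambda: {"dry": math.pi, "wet": 0.0}
    )
    # chronological wet-season capture split (see CHECK_INDEX_SEQUENCE_WET)
    check_split_wet: tuple[float, ...] = (
        43 / 181, 9 / 181, 119 / 181, 10 / 181
    )
    sex_ratio: float = 0.5                    # probability male
    wind: dict[str, WindRegime] = field(default_factory=_default_wind)
    calm_cutoff: float = 0.1                  # m/s, for the upwind truth
    # "random" draws the nightly orientation; naming one pins it campaign-wide
    orientation: str = "random"

    def validate(self) -> None:
        for name in ("capture_rate", "p_side", "sex_ratio"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        if abs(sum(self.check_split_wet) - 1.0) > 1e-9:
            raise ValueError("check_split_wet proportions must sum to 1")
        if self.heading_rule not in ("anemotactic", "fixed"):
            raise ValueError(f"unknown heading_rule {self.heading_rule!r}")
        if self.orientation not in ("random", "corners_cardinal",
                                    "corners_intermediate"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


def load_config(path) -> CampaignConfig:
    """Load a CampaignConfig from YAML (keys mirror the dataclass fields)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "wind" in raw:
        raw["wind"] = {s: WindRegime(**w) for s, w in raw["wind"].items()}
    if "years" in raw:
        raw["years"] = tuple(raw["years"])
    if "check_split_wet" in raw:
        raw["check_split_wet"] = tuple(raw["check_split_wet"])
    cfg = CampaignConfig(**raw)
    cfg.validate()
    return cfg


def _dump_config(config: CampaignConfig, path) -> None:
    raw = asdict(config)
    raw["years"] = list(config.years)
    raw["check_split_wet"] = list(config.check_split_wet)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def _vonmises(rng: np.random.Generator, mu: float, kappa: float, size: int) -> np.ndarray:
    if kappa >= _EXACT_KAPPA:
        return np.full(size, mu % TWO_PI)
    return np.mod(rng.vonmises(mu, kappa, size=size), TWO_PI)


def generate_night_weather(
    config: CampaignConfig,
    season: str,
    rng: np.random.Generator | int,
    night_date: date = date(2009, 4, 1),
) -> list[WeatherRecord]:
    """One night of 10-minute readings, 18:00 through 06:00 (73 records).

    Directions are von Mises around the seasonal mean-from direction; speeds
    are gamma (shape 2) scaled so the grand mean including calm intervals
    equals the configured seasonal mean.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    regime = config.wind[season]
    n = 73
    start = datetime.combine(night_date, datetime.min.time()) + timedelta(hours=18)
    times = [start + timedelta(minutes=10 * i) for i in range(n)]
    mu_from = math.radians(regime.mean_from_deg)
    dirs_rad = _vonmises(rng, mu_from, regime.kappa, n)
    dirs_deg = np.degrees(dirs_rad) % 360.0
    calm = rng.random(n) < regime.calm_prob
    noncalm_mean = regime.mean_speed / max(1.0 - regime.calm_prob, 1e-12)
    speeds = rng.gamma(shape=2.0, scale=noncalm_mean / 2.0, size=n)
    speeds[calm] = 0.0
    gusts = speeds * regime.gust_mult
    return [
        WeatherRecord(
            timestamp=times[i],
            wind_speed=float(round(speeds[i], 4)),
            gust=float(round(gusts[i], 4)),
            wind_from_deg=float(round(dirs_deg[i], 2)),
            rel_humidity=regime.rel_humidity,
            temperature=regime.temperature,
        )
        for i in range(n)
    ]


def _assign_nearest(headings: np.ndarray, trap_dirs: Sequence[str]) -> np.ndarray:
    """Index of the trap whose direction is angularly nearest each heading.

    Ties (a heading exactly midway between two traps) break toward the
    counterclockwise trap.
    """
    n = headings.size
    best = np.zeros(n, dtype=int)
    best_dist = np.full(n, np.inf)
    best_ccw = np.full(n, np.inf)
    for j, d in enumerate(trap_dirs):
        ang = compass_to_math(d)
        ccw = (ang - headings) % TWO_PI
        dist = np.minimum(ccw, TWO_PI - ccw)
        better = (dist < best_dist - 1e-12) | (
            (np.abs(dist - best_dist) <= 1e-12) & (ccw < best_ccw)
        )
        best[better] = j
        best_dist[better] = dist[better]
        best_ccw[better] = ccw[better]
    return best


def generate_enclosure_night(
    config: CampaignConfig,
    mu: float,
    orientation: str,
    rng: np.random.Generator | int,
    season: str = "dry",
    year: int = 2009,
    night_id: str = "night-0",
    enclosure_id: str = "E1",
    site: str = "Fulani",
    side: str = "North",
) -> list[TrapCountRecord]:
    """Simulate one enclosure-night and emit its full trap-count rows.

    Pupae load ~ truncated normal; the number recovered in exit traps is
    binomial at the capture rate.  Each adult draws a heading ~ von
    Mises(mu, kappa); with probability p_side it lands in the nearest side
    trap, otherwise in the nearest corner trap.  Wet-season captures are
    split multinomially over the collection checks; dry-season adults are
    all recovered at the first morning check.  Zero counts are emitted as
    explicit rows for every trap at every check of the season.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    a = (config.pupae_min - config.pupae_mean) / config.pupae_sd
    b = (config.pupae_max - config.pupae_mean) / config.pupae_sd
    n_pupae = int(round(float(sp_stats.truncnorm.rvs(
        a, b, loc=config.pupae_mean, scale=config.pupae_sd, random_state=rng
    ))))
    n_caught = int(rng.binomial(n_pupae, config.capture_rate))

    corner_dirs = [d for d in COMPASS_POINTS if d in CORNER_DIRECTIONS[orientation]]
    side_dirs = [d for d in COMPASS_POINTS if d in SIDE_DIRECTIONS[orientation]]

    headings = _vonmises(rng, mu, config.kappa, n_caught)
    leaks = rng.random(n_caught) < config.p_side
    trap_of = np.empty(n_caught, dtype=object)
    if (~leaks).any():
        idx = _assign_nearest(headings[~leaks], corner_dirs)
        trap_of[~leaks] = np.array(corner_dirs, dtype=object)[idx]
    if leaks.any():
        idx = _assign_nearest(headings[leaks], side_dirs)
        trap_of[leaks] = np.array(side_dirs, dtype=object)[idx]
    male = rng.random(n_caught) < config.sex_ratio

    if season == "dry":
        checks_emitted = (0,)
        check_of = np.zeros(n_caught, dtype=int)
    else:
        checks_emitted = tuple(sorted(CHECK_INDEX_SEQUENCE_WET))
        chron = rng.choice(
            len(config.check_split_wet), size=n_caught, p=config.check_split_wet
        )
        check_of = np.array(CHECK_INDEX_SEQUENCE_WET, dtype=int)[chron]

    counts: dict[tuple[str, int], list[int]] = {
        (d, c): [0, 0] for d in COMPASS_POINTS for c in checks_emitted
    }
    for i in range(n_caught):
        counts[(trap_of[i], int(check_of[i]))][0 if male[i] else 1] += 1

    rows = []
    for c in checks_emitted:
        for d in COMPASS_POINTS:
            males, females = counts[(d, c)]
            rows.append(TrapCountRecord(
                night_id=night_id,
                enclosure_id=enclosure_id,
                site=site,
                side=side,
                season=season,
                year=year,
                orientation=orientation,
                trap_direction=d,
                trap_class="corner" if d in corner_dirs else "side",
                check_index=c,
                count_male=males,
                count_female=females,
            ))
    return rows


def _split_across_years(total: int, n_years: int) -> list[int]:
    base, rem = divmod(total, n_years)
    # remainder goes to the later years (e.g. 13 dry nights -> 6 + 7)
    return [base + (1 if i >= n_years - rem else 0) for i in range(n_years)]


_SEASON_START = {"dry": (3, 20), "wet": (8, 10)}


def generate_campaign(
    config: CampaignConfig,
) -> tuple[list[TrapCountRecord], list[WeatherRecord], pd.DataFrame]:
    """Generate a full multi-year, two-season campaign.

    Returns (trap records, weather records, truth table).  The truth table
    has one row per enclosure-night: the intended mean heading true_mu, the
    heading concentration true_kappa, and upwind_theta_true — the circular
    mean upwind direction realised by that night's simulated weather.
    """
    config.validate()
    trap_rows: list[TrapCountRecord] = []
    weather: list[WeatherRecord] = []
    truth_rows: list[dict] = []
    for season in ("dry", "wet"):
        totals = _split_across_years(
            config.nights_per_season.get(season, 0), len(config.years)
        )
        for yi, (year, n_nights) in enumerate(zip(config.years, totals)):
            month, day = _SEASON_START[season]
            start = date(year, month, day)
            for k in range(n_nights):
                ss = np.random.SeedSequence(
                    [config.seed, year, 0 if season == "dry" else 1, k]
                )
                rng = np.random.default_rng(ss)
                night_date = start + timedelta(days=k)
                night_id = night_date.isoformat()
                wrecs = generate_night_weather(config, season, rng, night_date)
                wsum = night_wind_summary(wrecs, config.calm_cutoff, night_id)
                upwind = wsum.upwind_theta
                if config.heading_rule == "fixed":
                    mu = config.fixed_mu % TWO_PI
                else:
                    base = upwind
                    if math.isnan(base):
                        # windless night: fall back to the climatological mean
                        base = compass_deg_to_math(
                            config.wind[season].mean_from_deg
                        )
                    mu = (base + config.anemotaxis_offset[season]) % TWO_PI
                draw = ("corners_cardinal", "corners_intermediate")[
                    int(rng.integers(2))
                ]  # drawn unconditionally to keep the rng stream stable
                orientation = (
                    draw if config.orientation == "random" else config.orientation
                )
                site_idx = rng.choice(len(SITES), size=config.enclosures_per_night,
                                      replace=config.enclosures_per_night > len(SITES))
                for e in range(config.enclosures_per_night):
                    site, vside = SITES[int(site_idx[e])]
                    enclosure_id = f"E{e + 1}"
                    trap_rows.extend(generate_enclosure_night(
                        config, mu=mu, orientation=orientation, rng=rng,
                        season=season, year=year, night_id=night_id,
                        enclosure_id=enclosure_id, site=site, side=vside,
                    ))
                    truth_rows.append({
                        "night_id": night_id,
                        "enclosure_id": enclosure_id,
                        "true_mu": mu,
                        "true_kappa": config.kappa,
                        "upwind_theta_true": upwind,
                    })
                weather.extend(wrecs)
    truth = pd.DataFrame(truth_rows)
    return trap_rows, weather, truth


def write_campaign(config: CampaignConfig, out_dir) -> dict[str, Path]:
    """Generate a campaign and write traps.csv, weather.csv, truth.csv and
    the config YAML under out_dir; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, weather, truth = generate_campaign(config)
    paths = {
        "traps": out / "traps.csv",
        "weather": out / "weather.csv",
        "truth": out / "truth.csv",
        "config": out / "campaign_config.yaml",
    }
    write_trap_csv(records, paths["traps"])
    write_weather_csv(weather, paths["weather"])
    truth.to_csv(paths["truth"], index=False)
    _dump_config(config, paths["config"])
    return paths
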