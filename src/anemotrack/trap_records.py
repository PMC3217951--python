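"""Data model, validation and CSV I/O for exit-trap capture campaigns.

This module fixes every angle convention used downstream.  Internally all
angles are radians in the mathematical convention: 0 = magnetic East,
increasing counterclockwise, reduced to [0, 2*pi).  Compass points and
meteorological wind directions (degrees clockwise from North, direction the
wind blows *from*) exist only at the I/O boundary and are converted on entry.

The experimental unit is one enclosure on one night: a cubic emergence
enclosure with eight exit traps, four on the corners and four on the side
centres.  Each night every enclosure is oriented with either a corner trap or
a side trap pointing North, which determines which four compass points are
the "corner" traps used by the analysis.  Counts are recorded per trap, per
collection check, split by sex.  Zero counts must be explicit rows so that a
missing trap is distinguishable from an empty one.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, fields as dc_fields
from datetime import datetime, timedelta
from typing import Iterable, Mapping, Sequence

__all__ = [
    "COMPASS_POINTS",
    "CORNER_DIRECTIONS",
    "SIDE_DIRECTIONS",
    "ORIENTATIONS",
    "SEASONS",
    "SIDES",
    "DEFAULT_CHECKS_PER_SEASON",
    "TRAP_CSV_COLUMNS",
    "WEATHER_CSV_COLUMNS",
    "TrapDataError",
    "TrapCountRecord",
    "WeatherRecord",
    "EnclosureNight",
    "compass_to_math",
    "compass_deg_to_math",
    "read_trap_csv",
    "write_trap_csv",
    "validate_records",
    "read_weather_csv",
    "write_weather_csv",
    "group_weather_by_night",
    "aggregate_enclosure_nights",
]

COMPASS_POINTS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")

_COMPASS_DEG = {
    "N": 0.0, "NE": 45.0, "E": 90.0, "SE": 135.0,
    "S": 180.0, "SW": 225.0, "W": 270.0, "NW": 315.0,
}

ORIENTATIONS = ("corners_cardinal", "corners_intermediate")

CORNER_DIRECTIONS = {
    "corners_cardinal": frozenset({"N", "E", "S", "W"}),
    "corners_intermediate": frozenset({"NE", "SE", "SW", "NW"}),
}
SIDE_DIRECTIONS = {
    o: frozenset(COMPASS_POINTS) - dirs for o, dirs in CORNER_DIRECTIONS.items()
}

SEASONS = ("dry", "wet")
SIDES = ("North", "South")

# Collection checks retained by the analysis: mornings are numbered 0, 1, 2
# in order; the dry season keeps only the first morning, the wet season the
# first two mornings.  Afternoon checks carry later indexes and are excluded.
DEFAULT_CHECKS_PER_SEASON = {"dry": frozenset({0}), "wet": frozenset({0, 1})}

TRAP_CSV_COLUMNS = [
    "night_id", "enclosure_id", "site", "side", "season", "year",
    "orientation", "trap_direction", "trap_class", "check_index",
    "count_male", "count_female",
]

WEATHER_CSV_COLUMNS = [
    "timestamp", "wind_speed_ms", "gust_ms", "wind_from_deg",
    "rel_humidity_pct", "temperature_c",
]


class TrapDataError(ValueError):
    """Raised when a trap or weather record violates the data contract."""


def compass_deg_to_math(deg: float) -> float:
    """Convert a compass bearing (degrees clockwise from North) to math
    convention radians (0 = East, counterclockwise, in [0, 2*pi))."""
    return math.radians((90.0 - deg) % 360.0)


def compass_to_math(direction: str) -> float:
    """Math-convention angle of one of the 8 compass points.

    N = pi/2, E = 0, S = 3*pi/2, W = pi and the intermediates at odd
    multiples of pi/4.
    """
    try:
        deg = _COMPASS_DEG[direction]
    except KeyError:
        raise TrapDataError(f"unknown compass point: {direction!r}") from None
    return compass_deg_to_math(deg)


def expected_trap_class(orientation: str, trap_direction: str) -> str:
    if orientation not in CORNER_DIRECTIONS:
        raise TrapDataError(f"unknown orientation: {orientation!r}")
    return "corner" if trap_direction in CORNER_DIRECTIONS[orientation] else "side"


@dataclass
class TrapCountRecord:
    """Counts of adults by sex for one trap, one enclosure-night, one check."""

    night_id: str
    enclosure_id: str
    site: str
    side: str
    season: str
    year: int
    orientation: str
    trap_direction: str
    trap_class: str
    check_index: int
    count_male: int
    count_female: int

    def validate(self) -> None:
        if self.side not in SIDES:
            raise TrapDataError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.season not in SEASONS:
            raise TrapDataError(f"season must be one of {SEASONS}, got {self.season!r}")
        if self.orientation not in ORIENTATIONS:
            raise TrapDataError(f"unknown orientation: {self.orientation!r}")
        if self.trap_direction not in COMPASS_POINTS:
            raise TrapDataError(f"unknown trap_direction: {self.trap_direction!r}")
        want = expected_trap_class(self.orientation, self.trap_direction)
        if self.trap_class != want:
            raise TrapDataError(
                f"trap_class {self.trap_class!r} inconsistent with orientation "
                f"{self.orientation!r} and trap_direction {self.trap_direction!r} "
                f"(expected {want!r})"
            )
        if self.check_index < 0:
            raise TrapDataError(f"check_index must be >= 0, got {self.check_index}")
        for name in ("count_male", "count_female"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise TrapDataError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def count_total(self) -> int:
        return self.count_male + self.count_female


@dataclass
class WeatherRecord:
    """One reading of the nightly weather log (18:00-06:00 time series)."""

    timestamp: datetime
    wind_speed: float       # m/s
    gust: float             # m/s; independent sensor maximum, may be < speed
    wind_from_deg: float    # meteorological: direction wind comes FROM, CW from N
    rel_humidity: float     # percent
    temperature: float      # degrees C

    def validate(self) -> None:
        if self.wind_speed < 0:
            raise TrapDataError(f"wind_speed must be >= 0, got {self.wind_speed}")
        if not 0.0 <= self.rel_humidity <= 100.0:
            raise TrapDataError(
                f"rel_humidity must be in [0, 100], got {self.rel_humidity}"
            )
        if not 0.0 <= self.wind_from_deg <= 360.0:
            raise TrapDataError(
                f"wind_from_deg must be in [0, 360], got {self.wind_from_deg}"
            )


@dataclass
class EnclosureNight:
    """Corner-trap totals for one enclosure-night, summed over sexes and over
    the collection checks retained for its season."""

    night_id: str
    enclosure_id: str
    orientation: str
    corner_counts: dict[str, int]
    n_total: int
    site: str = ""
    side: str = ""
    season: str = ""
    year: int = 0

    def validate(self) -> None:
        want = CORNER_DIRECTIONS[self.orientation]
        if set(self.corner_counts) != want:
            raise TrapDataError(
                f"corner_counts keys {sorted(self.corner_counts)} do not match the "
                f"corner set {sorted(want)} for orientation {self.orientation!r}"
            )
        if self.n_total != sum(self.corner_counts.values()):
            raise TrapDataError("n_total does not equal the sum of corner_counts")


def _parse_int(value: str, field: str, line_no: int) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise TrapDataError(
            f"row {line_no}: field {field!r} is not an integer: {value!r}"
        ) from None


def read_trap_csv(path) -> list[TrapCountRecord]:
    """Read and validate a trap-count CSV; row order is preserved.

    Errors name the offending row number (1-based, counting the header as
    row 1) and field.
    """
    records: list[TrapCountRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != TRAP_CSV_COLUMNS:
            raise TrapDataError(
                f"unexpected header {reader.fieldnames}; expected {TRAP_CSV_COLUMNS}"
            )
        for row in reader:
            line_no = reader.line_num
            rec = TrapCountRecord(
                night_id=row["night_id"],
                enclosure_id=row["enclosure_id"],
                site=row["site"],
                side=row["side"],
                season=row["season"],
                year=_parse_int(row["year"], "year", line_no),
                orientation=row["orientation"],
                trap_direction=row["trap_direction"],
                trap_class=row["trap_class"],
                check_index=_parse_int(row["check_index"], "check_index", line_no),
                count_male=_parse_int(row["count_male"], "count_male", line_no),
                count_female=_parse_int(row["count_female"], "count_female", line_no),
            )
            try:
                rec.validate()
            except TrapDataError as err:
                raise TrapDataError(f"row {line_no}: {err}") from None
            records.append(rec)
    validate_records(records)
    return records


def validate_records(records: Iterable[TrapCountRecord]) -> None:
    """Cross-row invariants: within one (night, enclosure) the orientation is
    constant and each trap_direction appears at most once per check_index."""
    orient: dict[tuple[str, str], str] = {}
    seen: set[tuple[str, str, str, int]] = set()
    for rec in records:
        key = (rec.night_id, rec.enclosure_id)
        if orient.setdefault(key, rec.orientation) != rec.orientation:
            raise TrapDataError(
                f"enclosure {rec.enclosure_id!r} on night {rec.night_id!r} has "
                "inconsistent orientation across rows"
            )
        dup_key = (rec.night_id, rec.enclosure_id, rec.trap_direction, rec.check_index)
        if dup_key in seen:
            raise TrapDataError(
                f"duplicate row for trap {rec.trap_direction} check "
                f"{rec.check_index} in enclosure {rec.enclosure_id!r} night "
                f"{rec.night_id!r}"
            )
        seen.add(dup_key)


def write_trap_csv(records: Iterable[TrapCountRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRAP_CSV_COLUMNS)
        for rec in records:
            writer.writerow([getattr(rec, f.name) for f in dc_fields(TrapCountRecord)])


def read_weather_csv(path) -> list[WeatherRecord]:
    records: list[WeatherRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != WEATHER_CSV_COLUMNS:
            raise TrapDataError(
                f"unexpected header {reader.fieldnames}; expected {WEATHER_CSV_COLUMNS}"
            )
        for row in reader:
            line_no = reader.line_num
            try:
                rec = WeatherRecord(
                    timestamp=datetime.fromisoformat(row["timestamp"]),
                    wind_speed=float(row["wind_speed_ms"]),
                    gust=float(row["gust_ms"]),
                    wind_from_deg=float(row["wind_from_deg"]),
                    rel_humidity=float(row["rel_humidity_pct"]),
                    temperature=float(row["temperature_c"]),
                )
                rec.validate()
            except (ValueError, TrapDataError) as err:
                raise TrapDataError(f"row {line_no}: {err}") from None
            records.append(rec)
    return records


def write_weather_csv(records: Iterable[WeatherRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(WEATHER_CSV_COLUMNS)
        for rec in records:
            writer.writerow([
                rec.timestamp.isoformat(),
                f"{rec.wind_speed:g}",
                f"{rec.gust:g}",
                f"{rec.wind_from_deg:g}",
                f"{rec.rel_humidity:g}",
                f"{rec.temperature:g}",
            ])


def group_weather_by_night(records: Iterable[WeatherRecord]) -> dict[str, list[WeatherRecord]]:
    """Group weather readings into nights keyed by the ISO date of the evening.

    A night runs 18:00 to 06:00 the next day; shifting timestamps back by 12 h
    lands the whole night on the starting date.
    """
    nights: dict[str, list[WeatherRecord]] = {}
    for rec in records:
        key = (rec.timestamp - timedelta(hours=12)).date().isoformat()
        nights.setdefault(key, []).append(rec)
    return nights


def aggregate_enclosure_nights(
    records: Sequence[TrapCountRecord],
    checks_per_season: Mapping[str, frozenset[int]] | None = None,
) -> list[EnclosureNight]:
    """Collapse per-check, per-sex trap rows to corner-trap totals.

    Side traps are excluded entirely; only the checks configured for each
    season (defaults: first morning for the dry season, first two mornings
    for the wet) contribute.  Every one of the 4 corner traps must be present
    at every retained check — a zero count must be an explicit row.
    """
    checks = dict(DEFAULT_CHECKS_PER_SEASON)
    if checks_per_season:
        checks.update({k: frozenset(v) for k, v in checks_per_season.items()})

    groups: dict[tuple[str, str], list[TrapCountRecord]] = {}
    for rec in records:
        groups.setdefault((rec.night_id, rec.enclosure_id), []).append(rec)

    out: list[EnclosureNight] = []
    for (night_id, enclosure_id) in sorted(groups):
        recs = groups[(night_id, enclosure_id)]
        first = recs[0]
        for name in ("orientation", "site", "side", "season", "year"):
            if any(getattr(r, name) != getattr(first, name) for r in recs):
                raise TrapDataError(
                    f"{name} varies within enclosure {enclosure_id!r} night {night_id!r}"
                )
        included = checks[first.season]
        corner_dirs = CORNER_DIRECTIONS[first.orientation]
        sel = [
            r for r in recs
            if r.check_index in included and r.trap_direction in corner_dirs
        ]
        obs_checks = sorted({r.check_index for r in sel})
        if not obs_checks:
            raise TrapDataError(
                f"enclosure {enclosure_id!r} night {night_id!r} has no rows in the "
                f"retained checks {sorted(included)}"
            )
        for c in obs_checks:
            present = {r.trap_direction for r in sel if r.check_index == c}
            if present != corner_dirs:
                missing = sorted(corner_dirs - present)
                raise TrapDataError(
                    f"enclosure {enclosure_id!r} night {night_id!r} check {c}: "
                    f"missing corner trap rows for {missing} (zero counts must be "
                    "explicit)"
                )
        ordered = [d for d in COMPASS_POINTS if d in corner_dirs]
        counts = {
            d: sum(r.count_total for r in sel if r.trap_direction == d)
            for d in ordered
        }
        en = EnclosureNight(
            night_id=night_id,
            enclosure_id=enclosure_id,
            orientation=first.orientation,
            corner_counts=counts,
            n_total=sum(counts.values()),
            site=first.site,
            side=first.side,
            season=first.season,
            year=first.year,
        )
        en.validate()
        out.append(en)
    return out
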