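"""Dispersal vectors and wind-relative re-projection.

The core per-enclosure-night statistic: every mosquito caught in a corner
exit trap contributes one unit vector pointing in that trap's compass
direction, and component addition over the four corner traps yields the
"dispersal vector" (direction theta, magnitude r).  For an enclosure whose
corner traps sit on the cardinal points this reduces to

    x = N_E - N_W,    y = N_N - N_S

and for the intermediate orientation to

    x = (N_NE + N_SE - N_NW - N_SW) * cos(pi/4)
    y = (N_NE + N_NW - N_SE - N_SW) * sin(pi/4)

with N_d the count in the trap pointing to compass direction d.

Wind enters through a per-night summary: the unweighted circular mean of the
upwind direction over non-calm readings.  Re-projecting a dispersal vector
into the wind frame subtracts that mean, so 0 rad means upwind movement and
pi rad means downwind movement.

A zero-magnitude vector has no direction; theta is NaN, never 0.0, and every
consumer must treat it as undefined.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .trap_records import EnclosureNight, WeatherRecord, compass_deg_to_math

__all__ = [
    "DispersalVector",
    "NightWindSummary",
    "dispersal_components",
    "to_polar",
    "dispersal_vector",
    "compute_dispersal_vectors",
    "night_wind_summary",
    "reproject_to_wind",
    "reproject_all",
    "vectors_to_frame",
]

logger = logging.getLogger(__name__)

_HALF_SQRT2 = math.sqrt(0.5)


@dataclass
class DispersalVector:
    """Direction and magnitude of the capture imbalance for one enclosure-night.

    r is in mosquito-unit-lengths (0 <= r <= n) and is deliberately not
    normalised by n: the Monte-Carlo magnitude filter compares raw r against
    a null at matched n.  theta and theta_rel_wind are NaN when undefined.
    """

    night_id: str
    enclosure_id: str
    x: float
    y: float
    theta: float
    r: float
    n: int
    season: str = ""
    year: int = 0
    side: str = ""
    site: str = ""
    significant: bool | None = None
    theta_rel_wind: float = math.nan


@dataclass
class NightWindSummary:
    """Circular mean upwind direction, mean speed/gust and percent calm for
    one night of 18:00-06:00 readings."""

    night_id: str
    n_records: int
    percent_calm: float          # 0-100
    mean_speed: float            # arithmetic mean over all readings, m/s
    mean_gust: float             # arithmetic mean over all readings, m/s
    upwind_theta: float          # math-convention radians; NaN if undefined


def dispersal_components(en: EnclosureNight) -> tuple[float, float]:
    """Cartesian components of the dispersal vector by component addition."""
    get = en.corner_counts.get
    x = (get("E", 0) - get("W", 0)) + _HALF_SQRT2 * (
        (get("NE", 0) + get("SE", 0)) - (get("NW", 0) + get("SW", 0))
    )
    y = (get("N", 0) - get("S", 0)) + _HALF_SQRT2 * (
        (get("NE", 0) + get("NW", 0)) - (get("SE", 0) + get("SW", 0))
    )
    return float(x), float(y)


def to_polar(x: float, y: float) -> tuple[float, float]:
    """Rectangular to polar; theta in [0, 2*pi), NaN when the vector is null."""
    r = math.hypot(x, y)
    if r == 0.0:
        return math.nan, 0.0
    return math.atan2(y, x) % (2.0 * math.pi), r


def dispersal_vector(en: EnclosureNight) -> DispersalVector:
    x, y = dispersal_components(en)
    theta, r = to_polar(x, y)
    return DispersalVector(
        night_id=en.night_id,
        enclosure_id=en.enclosure_id,
        x=x,
        y=y,
        theta=theta,
        r=r,
        n=en.n_total,
        season=en.season,
        year=en.year,
        side=en.side,
        site=en.site,
    )


def compute_dispersal_vectors(
    enclosure_nights: Iterable[EnclosureNight],
) -> list[DispersalVector]:
    return [dispersal_vector(en) for en in enclosure_nights]


def night_wind_summary(
    records: Sequence[WeatherRecord],
    calm_cutoff: float = 0.1,
    night_id: str = "",
) -> NightWindSummary:
    """Summarise one night of weather readings.

    The upwind direction of reading i is the math-convention angle of the
    compass direction the wind blows from.  Its circular mean is unweighted
    and taken over non-calm readings only (a calm reading carries no defined
    direction).  With every reading calm — or a perfectly balanced direction
    distribution — upwind_theta is NaN and re-projection must skip the night.
    """
    if not records:
        raise ValueError("night_wind_summary requires at least one record")
    speeds = np.array([r.wind_speed for r in records], dtype=float)
    gusts = np.array([r.gust for r in records], dtype=float)
    calm = speeds < calm_cutoff
    percent_calm = 100.0 * float(np.mean(calm))
    upwind = np.array(
        [compass_deg_to_math(r.wind_from_deg) for r in records], dtype=float
    )[~calm]
    if upwind.size == 0:
        theta = math.nan
    else:
        z = np.exp(1j * upwind).sum()
        theta = math.nan if abs(z) < 1e-12 else float(np.angle(z) % (2.0 * math.pi))
    return NightWindSummary(
        night_id=night_id,
        n_records=len(records),
        percent_calm=percent_calm,
        mean_speed=float(speeds.mean()),
        mean_gust=float(gusts.mean()),
        upwind_theta=theta,
    )


def reproject_to_wind(v: DispersalVector, w: NightWindSummary) -> DispersalVector:
    """Rotate a dispersal vector into the wind frame (upwind = 0 rad).

    Magnitude is unchanged.  If either direction is undefined the vector is
    returned with theta_rel_wind = NaN and a warning is logged.
    """
    if math.isnan(v.theta) or math.isnan(w.upwind_theta):
        logger.warning(
            "skipping wind re-projection for enclosure %s night %s: "
            "undefined direction (theta=%r, upwind=%r)",
            v.enclosure_id, v.night_id, v.theta, w.upwind_theta,
        )
        return replace(v, theta_rel_wind=math.nan)
    rel = (v.theta - w.upwind_theta) % (2.0 * math.pi)
    return replace(v, theta_rel_wind=rel)


def reproject_all(
    vectors: Iterable[DispersalVector],
    summaries: Mapping[str, NightWindSummary],
) -> list[DispersalVector]:
    """Re-project each vector using its night's wind summary (keyed by
    night_id); vectors without a matching night keep theta_rel_wind = NaN."""
    out = []
    for v in vectors:
        w = summaries.get(v.night_id)
        if w is None:
            logger.warning("no wind summary for night %s; not re-projected", v.night_id)
            out.append(replace(v, theta_rel_wind=math.nan))
        else:
            out.append(reproject_to_wind(v, w))
    return out


def vectors_to_frame(vectors: Sequence[DispersalVector]) -> pd.DataFrame:
    """Tabular export of dispersal vectors (r_over_n is a convenience only)."""
    rows = []
    for v in vectors:
        rows.append({
            "night_id": v.night_id,
            "enclosure_id": v.enclosure_id,
            "season": v.season,
            "year": v.year,
            "side": v.side,
            "n": v.n,
            "x": v.x,
            "y": v.y,
            "theta_rad": v.theta,
            "r": v.r,
            "r_over_n": v.r / v.n if v.n else math.nan,
            "theta_rel_wind_rad": v.theta_rel_wind,
            "significant": v.significant,
        })
    return pd.DataFrame(rows)
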