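"""End-to-end analysis of one campaign: the canonical workflow.

Order of operations mirrors the experimental analysis: aggregate corner-trap
counts per enclosure-night -> dispersal vectors -> nightly wind summaries ->
wind-relative re-projection -> Monte-Carlo magnitude filter -> descriptive
circular statistics on the significant vectors only -> uniformity tests per
season-year block -> Watson-Williams comparisons (years within season, site
pairs within village side) -> Harrison-Kanji side x season -> Wilcoxon
male-vs-female check on per-trap counts -> wind-rose tables.

Every exclusion (side traps, out-of-window checks, non-significant vectors,
nights without a defined wind direction) is counted in the report, because
the headline sample sizes are products of those filters.  Groupings are
data-driven from the CSV factor columns, never hard-coded to particular
years or sites.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import circstats, dispersal, mc_null, trap_records
from .circstats import CircularTestResult
from .dispersal import DispersalVector

__all__ = ["AnalysisConfig", "run_analysis", "build_wind_rose_table"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    seed: int = 0
    n_sims: int = 1000
    q: float = 0.95
    calm_cutoff: float = 0.1
    per_night_sims: bool = False
    checks_per_season: dict[str, frozenset[int]] | None = None
    wind_rose_bins: int = 16

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "checks_per_season" in raw and raw["checks_per_season"] is not None:
            raw["checks_per_season"] = {
                k: frozenset(v) for k, v in raw["checks_per_season"].items()
            }
        return cls(**raw)


def build_wind_rose_table(
    records: Sequence[trap_records.WeatherRecord],
    n_bins: int = 16,
    calm_cutoff: float = 0.1,
) -> tuple[pd.DataFrame, float]:
    """Bin non-calm readings by the direction the wind comes from.

    Returns (table, percent_calm); the table has one row per bin with the
    bin-centre bearing, the frequency among non-calm readings (summing to 1
    when any exist) and the mean speed in the bin.
    """
    width = 360.0 / n_bins
    speeds = np.array([r.wind_speed for r in records], dtype=float)
    dirs = np.array([r.wind_from_deg for r in records], dtype=float)
    calm = speeds < calm_cutoff
    percent_calm = 100.0 * float(np.mean(calm)) if len(records) else 0.0
    nc_speeds = speeds[~calm]
    nc_dirs = dirs[~calm]
    bins = (np.round(nc_dirs / width).astype(int)) % n_bins
    rows = []
    total = nc_dirs.size
    for b in range(n_bins):
        mask = bins == b
        count = int(mask.sum())
        rows.append({
            "bin_center_deg": b * width,
            "frequency": count / total if total else 0.0,
            "mean_speed": float(nc_speeds[mask].mean()) if count else math.nan,
            "count": count,
        })
    return pd.DataFrame(rows), percent_calm


def _circ_summary(angles: Sequence[float]) -> dict:
    th = [a for a in angles if not math.isnan(a)]
    if not th:
        return {"n": 0, "mean_theta": None, "circ_variance": None, "rbar": None}
    mean, var, rbar = circstats.circ_mean_var(th)
    return {
        "n": len(th),
        "mean_theta": None if math.isnan(mean) else mean,
        "circ_variance": var,
        "rbar": rbar,
    }


def _result_dict(res: CircularTestResult) -> dict:
    df = res.df
    if isinstance(df, tuple):
        df = list(df)
    return {
        "test_name": res.test_name,
        "statistic": None if math.isnan(res.statistic) else res.statistic,
        "df": df,
        "p_value": res.p_value,
        "method_note": res.method_note,
    }


def _result_row(res: CircularTestResult, grouping: str) -> dict:
    d = _result_dict(res)
    d["grouping"] = grouping
    d["df"] = "" if d["df"] is None else (
        ",".join(str(x) for x in d["df"]) if isinstance(d["df"], list) else d["df"]
    )
    return d


def _sanitize(obj):
    """Make a report JSON-safe: NaN -> None, numpy scalars -> python."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def run_analysis(
    trap_csv,
    weather_csv,
    out_dir,
    config: AnalysisConfig | None = None,
) -> dict:
    """Run the full analysis and write the module CSVs plus report.json."""
    cfg = config or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = trap_records.read_trap_csv(trap_csv)
    weather = trap_records.read_weather_csv(weather_csv)

    checks = dict(trap_records.DEFAULT_CHECKS_PER_SEASON)
    if cfg.checks_per_season:
        checks.update(cfg.checks_per_season)
    n_side_rows = sum(1 for r in records if r.trap_class == "side")
    n_excluded_check_rows = sum(
        1 for r in records
        if r.trap_class == "corner" and r.check_index not in checks[r.season]
    )

    nights = trap_records.aggregate_enclosure_nights(records, checks)
    vectors = dispersal.compute_dispersal_vectors(nights)

    by_night = trap_records.group_weather_by_night(weather)
    summaries = {
        night_id: dispersal.night_wind_summary(recs, cfg.calm_cutoff, night_id)
        for night_id, recs in by_night.items()
    }
    vectors = dispersal.reproject_all(vectors, summaries)
    n_unprojected = sum(1 for v in vectors if math.isnan(v.theta_rel_wind))

    vectors, thresholds = mc_null.filter_significant(
        vectors, n_sims=cfg.n_sims, q=cfg.q, seed=cfg.seed,
        per_night=cfg.per_night_sims,
    )
    sig = [v for v in vectors if v.significant and not math.isnan(v.theta)]

    # --- descriptive circular statistics (significant vectors only) ---
    seasons = sorted({v.season for v in vectors})
    years = sorted({v.year for v in vectors})
    descriptive = {"by_season_year": {}, "by_season": {}}
    for s in seasons:
        descriptive["by_season"][s] = {
            "compass": _circ_summary([v.theta for v in sig if v.season == s]),
            "wind_relative": _circ_summary(
                [v.theta_rel_wind for v in sig if v.season == s]
            ),
        }
        for y in years:
            block = [v for v in sig if v.season == s and v.year == y]
            descriptive["by_season_year"][f"{s}-{y}"] = {
                "compass": _circ_summary([v.theta for v in block]),
                "wind_relative": _circ_summary(
                    [v.theta_rel_wind for v in block]
                ),
            }

    test_rows: list[dict] = []
    tests: dict = {
        "hodges_ajne": {}, "watson_williams": {}, "harrison_kanji": {},
        "wilcoxon_sex": None, "skipped": [],
    }

    def skip(name: str, reason: str) -> None:
        logger.info("skipping %s: %s", name, reason)
        tests["skipped"].append({"test": name, "reason": reason})

    # --- uniformity within each season-year block ---
    for s in seasons:
        for y in years:
            key = f"{s}-{y}"
            angles = [v.theta for v in sig if v.season == s and v.year == y]
            if len(angles) < 4:
                skip(f"hodges_ajne[{key}]", f"only {len(angles)} significant vectors")
                continue
            res = circstats.hodges_ajne_test(angles)
            tests["hodges_ajne"][key] = _result_dict(res)
            test_rows.append(_result_row(res, key))

    # --- mean directions between years within each season ---
    for s in seasons:
        groups = []
        labels = []
        for y in years:
            g = [v.theta for v in sig if v.season == s and v.year == y]
            if len(g) >= 2:
                groups.append(g)
                labels.append(str(y))
        key = f"{s}:{' vs '.join(labels)}" if labels else s
        if len(groups) < 2:
            skip(f"watson_williams[{s} between years]", "fewer than 2 usable year groups")
            continue
        try:
            res = circstats.watson_williams_test(groups)
        except ValueError as err:
            skip(f"watson_williams[{key}]", str(err))
            continue
        tests["watson_williams"][key] = _result_dict(res)
        test_rows.append(_result_row(res, key))

    # --- mean directions between site pairs within each village side ---
    sides = sorted({v.side for v in sig})
    for side in sides:
        sites = sorted({v.site for v in sig if v.side == side})
        for s1, s2 in combinations(sites, 2):
            g1 = [v.theta for v in sig if v.site == s1]
            g2 = [v.theta for v in sig if v.site == s2]
            key = f"{side}:{s1} vs {s2}"
            if len(g1) < 2 or len(g2) < 2:
                skip(f"watson_williams[{key}]", "a site has fewer than 2 vectors")
                continue
            try:
                res = circstats.watson_williams_test([g1, g2])
            except ValueError as err:
                skip(f"watson_williams[{key}]", str(err))
                continue
            tests["watson_williams"][key] = _result_dict(res)
            test_rows.append(_result_row(res, key))

    # --- two-factor side x season ---
    hk_angles = [v.theta for v in sig]
    hk_side = [v.side for v in sig]
    hk_season = [v.season for v in sig]
    try:
        hk = circstats.harrison_kanji_test(
            hk_angles, hk_side, hk_season, factor_names=("side", "season")
        )
        tests["harrison_kanji"] = {
            "side": _result_dict(hk[0]),
            "season": _result_dict(hk[1]),
            "interaction": _result_dict(hk[2]),
        }
        test_rows.extend(_result_row(r, "side x season") for r in hk)
    except ValueError as err:
        skip("harrison_kanji[side x season]", str(err))

    # --- sex ratio per exit trap ---
    pair_totals: dict[tuple[str, str, str], list[int]] = {}
    for r in records:
        if r.trap_class == "corner" and r.check_index in checks[r.season]:
            key = (r.night_id, r.enclosure_id, r.trap_direction)
            t = pair_totals.setdefault(key, [0, 0])
            t[0] += r.count_male
            t[1] += r.count_female
    pairs = [tuple(v) for v in pair_totals.values()]
    if pairs:
        res = circstats.wilcoxon_signed_rank(pairs)
        tests["wilcoxon_sex"] = _result_dict(res)
        test_rows.append(_result_row(res, "male vs female per corner trap-night"))

    # --- wind roses per season ---
    night_season = {}
    for r in records:
        night_season.setdefault(r.night_id, r.season)
    wind_report = {}
    rose_frames = []
    for s in seasons:
        recs = [
            rec for night_id, recs_ in by_night.items()
            if night_season.get(night_id) == s for rec in recs_
        ]
        if not recs:
            continue
        rose, pct_calm = build_wind_rose_table(
            recs, cfg.wind_rose_bins, cfg.calm_cutoff
        )
        wind_report[s] = {
            "percent_calm": pct_calm,
            "mean_speed": float(np.mean([r.wind_speed for r in recs])),
            "mean_gust": float(np.mean([r.gust for r in recs])),
            "rose": rose.to_dict(orient="records"),
        }
        rose_frames.append(rose.assign(season=s))

    n_sig = len([v for v in vectors if v.significant])
    report = {
        "counts": {
            "n_enclosure_nights": len(nights),
            "n_vectors": len(vectors),
            "n_significant": n_sig,
            "n_not_significant": len(vectors) - n_sig,
            "n_significant_by_block": {
                f"{s}-{y}": len([v for v in sig if v.season == s and v.year == y])
                for s in seasons for y in years
            },
            "excluded_side_trap_rows": n_side_rows,
            "excluded_check_rows": n_excluded_check_rows,
            "vectors_without_wind_projection": n_unprojected,
        },
        "descriptive": descriptive,
        "tests": tests,
        "wind": wind_report,
        "config": {
            "seed": cfg.seed, "n_sims": cfg.n_sims, "q": cfg.q,
            "calm_cutoff": cfg.calm_cutoff,
            "per_night_sims": cfg.per_night_sims,
            "checks_per_season": {k: sorted(v) for k, v in checks.items()},
        },
    }
    report = _sanitize(report)

    dispersal.vectors_to_frame(vectors).to_csv(
        out / "dispersal_vectors.csv", index=False
    )
    pd.DataFrame(mc_null.thresholds_to_rows(thresholds)).to_csv(
        out / "null_thresholds.csv", index=False
    )
    pd.DataFrame(
        test_rows,
        columns=["test_name", "grouping", "statistic", "df", "p_value", "method_note"],
    ).to_csv(out / "test_results.csv", index=False)
    if rose_frames:
        pd.concat(rose_frames, ignore_index=True).to_csv(
            out / "wind_rose.csv", index=False
        )
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
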