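#!/usr/bin/env python
"""Check the analysis against the generator's known truth, and calibrate
the magnitude filter on a uniform null.

Part 1 compares the wind-relative seasonal means recovered by
02_analyze_campaign.py with the anemotactic rule that generated the data
(downwind = pi for the dry season, upwind = 0 for the wet season).

Part 2 runs the 95% magnitude filter on 1000 enclosure-nights whose
mosquitoes choose corner traps uniformly at random: the flagged fraction
estimates the filter's false-positive rate and should sit near 5%.

Writes results/calibration.json.
"""

import argparse
import json
import math
from pathlib import Path

import numpy as np
from scipy import stats as sp_stats

from anemotrack import mc_null

ROOT = Path(__file__).resolve().parents[1]
TWO_PI = 2.0 * math.pi


def circular_error(theta: float, target: float) -> float:
    return abs((theta - target + math.pi) % TWO_PI - math.pi)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=4242)
    parser.add_argument("--analysis", type=Path, default=ROOT / "results" / "analysis")
    parser.add_argument("--out", type=Path,
                        default=ROOT / "results" / "calibration.json")
    args = parser.parse_args()

    results = {}

    report_path = args.analysis / "report.json"
    if report_path.exists():
        with open(report_path, encoding="utf-8") as fh:
            report = json.load(fh)
        targets = {"dry": math.pi, "wet": 0.0}
        print("wind-relative recovery vs the generating anemotactic rule:")
        for s, target in targets.items():
            w = report["descriptive"]["by_season"][s]["wind_relative"]
            err = circular_error(w["mean_theta"], target)
            results[f"{s}_recovery_error_rad"] = err
            print(f"  {s}: recovered {w['mean_theta']:.3f} rad, truth "
                  f"{target:.3f}, error {err:.3f} rad (n={w['n']})")
    else:
        print(f"no analysis report at {report_path}; run 02_analyze_campaign.py "
              "first (skipping recovery check)")

    rng = np.random.default_rng(args.seed + 2)
    a, b = (200 - 345) / 83, (470 - 345) / 83
    pupae = np.round(sp_stats.truncnorm.rvs(
        a, b, loc=345, scale=83, size=1000, random_state=rng
    )).astype(int)
    ns = rng.binomial(pupae, 0.2)
    cache: dict[int, float] = {}
    flagged = 0
    for n in ns:
        n = int(max(n, 1))
        counts = rng.multinomial(n, [0.25] * 4)
        r = math.hypot(counts[0] - counts[2], counts[1] - counts[3])
        if n not in cache:
            cache[n] = mc_null.null_threshold(
                n, n_sims=1000, q=0.95, seed=args.seed + 3
            ).threshold
        flagged += r > cache[n]
    rate = flagged / 1000
    results["filter_false_positive_rate"] = rate
    print(f"uniform-null filter calibration: {flagged}/1000 flagged "
          f"({rate:.1%}; nominal 5%)")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    with open(args.out, "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=2)
        fh.write("\n")
    print(f"written to {args.out}")


if __name__ == "__main__":
    main()
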