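#!/usr/bin/env python
"""Render the study figures from the Monte-Carlo summary.

Figure 1: mean weight z-scores by age and outcome group with empirical 95%
CIs (the 'trajectory' plot that conditions on the outcome).  Figure 2:
fitted group lines from the outcome-as-covariate mixed model overlaid with
observed group mean weights.  Requires the summary written by
04_monte_carlo_study.py (or re-run it first).
"""

import argparse
from pathlib import Path

import pandas as pd

from collidersim import plots

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--summary", type=Path, default=ROOT / "results" / "study" / "study_summary.csv"
    )
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "figures")
    args = parser.parse_args()

    if not args.summary.exists():
        raise SystemExit(
            f"{args.summary} not found - run analysis/04_monte_carlo_study.py first"
        )
    summary = pd.read_csv(args.summary)
    args.out.mkdir(parents=True, exist_ok=True)
    p1 = plots.plot_zscore_profiles(summary, args.out / "zscore_profiles.png")
    p2 = plots.plot_fitted_lines(summary, args.out / "fitted_trajectories.png")
    print(f"wrote {p1}\nwrote {p2}")


if __name__ == "__main__":
    main()
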