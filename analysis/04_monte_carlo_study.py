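#!/usr/bin/env python
"""Run the full Monte-Carlo comparison of the three methods.

Replicates the simulation study: per scenario, simulate cohorts, apply the
z-score profile, outcome-as-covariate mixed model and two-step analysis,
and summarise every recorded quantity across replicates with empirical 95%
CIs.  Writes the tidy per-replicate estimates, the convergence log, the
study summary and the per-table report CSVs under results/study/.

The full study uses --reps 1000; the default 300 gives Monte-Carlo error
well below the differences of interest at a third of the cost.
"""

import argparse
from pathlib import Path

import collidersim as cs

OUT = Path(__file__).resolve().parents[1] / "results" / "study"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--scenario", choices=["A", "B", "C", "all"], default="all")
    parser.add_argument("--n", type=int, default=1000)
    parser.add_argument("--reps", type=int, default=300)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--estimation", choices=["reml", "ml"], default="reml")
    parser.add_argument("--out", type=Path, default=OUT)
    args = parser.parse_args()

    scenarios = ("A", "B", "C") if args.scenario == "all" else (args.scenario,)
    cfg = cs.StudyConfig(
        scenarios=scenarios,
        n_per_cohort=args.n,
        n_replicates=args.reps,
        master_seed=args.seed,
        estimation=args.estimation.upper(),
        output_dir=args.out,
    )
    out = cs.run_study(cfg)
    summary = out["summary"].set_index(["scenario", "method", "parameter"])

    print(f"{args.reps} replicates of n={args.n} per scenario (seed {args.seed})\n")
    for sid in scenarios:
        inter = summary.loc[(sid, "outcome_covariate", "time:diabetes")]
        orr = summary.loc[(sid, "two_step", "or_growth_rate")]
        disc = int(inter["n_discarded"]) + int(orr["n_discarded"])
        print(
            f"Scenario {sid}: diabetes*age interaction "
            f"{inter['mean']:+.3f} ({inter['centile_2_5']:.3f}, {inter['centile_97_5']:.3f}); "
            f"growth-rate OR {orr['mean']:.3f} "
            f"({orr['centile_2_5']:.3f}, {orr['centile_97_5']:.3f}); "
            f"{disc} discarded fits"
        )
    print(
        "\nOnly scenario A has no causal growth-rate effect: the two-step OR "
        "is null there while the outcome-conditioning interaction is not."
    )
    print(f"Wrote replicate estimates, summary and tables to {cfg.output_dir}")


if __name__ == "__main__":
    main()
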