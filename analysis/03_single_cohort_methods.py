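#!/usr/bin/env python
"""Apply all three analysis methods to a single cohort per scenario.

A narrative preview of the full Monte-Carlo study: for one simulated cohort
each of A (birthweight causes HbA1c; growth rate causally irrelevant),
B (weight at age 1 causes HbA1c) and C (weight at age 2 causes HbA1c),
prints the z-score profile, the outcome-as-covariate mixed-model interaction
and the two-step growth-rate odds ratio, with a reading of each.
"""

import argparse

import numpy as np

import collidersim as cs


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n", type=int, default=1000)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    for sid in "ABC":
        jg = cs.scenario_joint_gaussian(sid)
        cohort = cs.simulate_cohort(jg, args.n, cs.replicate_seed(args.seed, sid, 0))
        long = cs.to_long(cohort)

        profile = cs.zscore_profiles(cohort)
        gaps = profile.separation()
        ocm = cs.outcome_covariate_model(long)
        ts = cs.two_step(cohort)

        print(f"--- Scenario {sid} ---")
        print(
            "z-score gap (diabetic - non-diabetic) by age: "
            + ", ".join(f"{g:+.2f}" for g in gaps)
        )
        if ocm.converged:
            print(
                f"outcome-covariate model: age slope {ocm.payload['time']:.3f} kg/yr, "
                f"diabetes*age interaction {ocm.payload['time:diabetes']:+.3f} kg/yr"
            )
        if ts.converged:
            print(
                f"two-step: OR per 0.1 kg/yr growth = "
                f"{ts.payload['or_growth_rate']:.3f} "
                f"(birthweight-adjusted)"
            )
        print(
            "reading: the z-score gaps shadow the cross-sectional correlations; "
            "only the two-step OR speaks to whether growth rate causes diabetes.\n"
        )


if __name__ == "__main__":
    main()
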