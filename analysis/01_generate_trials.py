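"""Generate the synthetic stand-ins for the two clinical piperaquine trials.

Writes, per site (Sudan n=12, Thailand n=24): the individual-level
demographics CSV (synthetic records reproducing the published cohort
summaries), the "observed" concentration-time CSV produced by the
ground-truth 3-compartment generator, and the per-subject realized truth
parameters as JSON.  Outputs land under results/synthetic_trials/.

Usage: python analysis/01_generate_trials.py [--seed N]
"""

import argparse
import json
from pathlib import Path

import numpy as np

import ppqtwin as pt

FIXTURE_SEED = 20260921  # frozen demographics fixture


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=7,
                        help="seed for the observation noise streams")
    parser.add_argument("--out", type=Path,
                        default=Path("results/synthetic_trials"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for site in ("sudan", "thailand"):
        fixture = pt.make_fixture(site, rng_seed=FIXTURE_SEED)
        profiles, truth = pt.generate_observations(
            fixture, args.seed, return_truth=True
        )
        pt.write_demographics_csv(
            fixture.subjects, args.out / f"{site}_demographics.csv"
        )
        pt.write_observations_csv(
            profiles, args.out / f"{site}_observations.csv"
        )
        with open(args.out / f"{site}_truth_params.json", "w") as fh:
            json.dump(
                {"population": fixture.truth_params, "subjects": truth},
                fh, indent=2,
            )

        weights = [r.observed_body_weight for r in fixture.subjects]
        t_halves = [
            r.t_half / 24.0
            for r in (pt.run_nca(p) for p in profiles)
            if r.t_half is not None
        ]
        print(
            f"{site}: n={fixture.n}, mean weight {np.mean(weights):.1f} kg "
            f"[{min(weights):.0f}-{max(weights):.0f}], NCA median terminal "
            f"t1/2 {np.median(t_halves):.1f} days "
            f"(truth target {fixture.truth_params['site_half_life_target_days']})"
        )
    print(f"wrote synthetic trial data to {args.out}/")


if __name__ == "__main__":
    main()
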