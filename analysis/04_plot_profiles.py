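"""Best-effort figures: mean twin profiles with 95% prediction bands against
the synthetic observed data for two representative patients (one per site).

Usage: python analysis/04_plot_profiles.py [--seed N]
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

import ppqtwin as pt

FIXTURE_SEED = 20260921


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/figures"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    compound = pt.load_compound()
    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharey=True)
    for ax, site in zip(axes, ("sudan", "thailand")):
        fixture = pt.make_fixture(site, rng_seed=FIXTURE_SEED)
        record = fixture.subjects[5]
        obs = [p for p in pt.generate_observations(fixture, args.seed + 1)
               if p.subject_id == record.subject_id][0]
        twins = pt.build_twin_set(
            record, compound,
            pt.TwinDesign(n_subjects=10, n_trials=10, master_seed=args.seed),
            output_times=fixture.sampling_schedule,
        )
        s = pt.summarize_twin_set(twins)
        days = s.times / 24.0
        ax.fill_between(days, s.lower, s.upper, alpha=0.3, color="tab:blue",
                        label="95% prediction interval")
        ax.plot(days, s.center, color="tab:blue", label="mean of 100 twins")
        quant = obs.concentrations > 0
        ax.plot(obs.times[quant] / 24.0, obs.concentrations[quant], "o",
                color="tab:red", ms=4, label="synthetic observed")
        ax.axhline(30.0, ls=":", color="gray", lw=1)
        ax.set_yscale("log")
        ax.set_xlabel("time (days)")
        ax.set_title(f"{site} patient {record.subject_id}")
    axes[0].set_ylabel("piperaquine plasma conc. (ng/mL)")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = args.out / "representative_profiles.png"
    fig.savefig(path, dpi=150)
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
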