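#!/usr/bin/env python
"""Generate a synthetic control study (17 cages, 10 laying weeks) and compare
its summary statistics with a simulated Monte-Carlo cohort, row for row.

The generator emulates the structure of OECD-206-style control reports so the
observed-vs-simulated comparison is a plain table join.  Writes
results/synthetic_control.csv and results/observed_vs_simulated.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from quaildeb import (CohortSpec, StudyConfig, generate_control_study, preset,
                      run_monte_carlo, write_cageweek_csv)

OUT = Path(__file__).resolve().parents[1] / "results"


def summarize(table: pd.DataFrame, label: str) -> dict:
    hatch = [m for xs in table["hatchling_masses_g"] for m in xs]
    return {
        "source": label,
        "eggs_per_bird_per_week": float(table["eggs_laid"].mean()),
        "hatchling_mass_g": float(np.mean(hatch)) if hatch else float("nan"),
        "hatchling_cv": (float(np.std(hatch) / np.mean(hatch))
                         if hatch else float("nan")),
        "food_g_week": float(table["food_g"].mean()),
        "female_mass_end_g": float(table["adult_female_mass_end_g"].mean()),
    }


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=3)
    args = ap.parse_args()
    OUT.mkdir(exist_ok=True)

    observed = generate_control_study(StudyConfig(), seed=args.seed)
    write_cageweek_csv(observed, OUT / "synthetic_control.csv")

    mc = run_monte_carlo(preset("H2"),
                         CohortSpec(n_hens=17, k_R_rate=0.7, seed=args.seed))
    comp = pd.DataFrame([summarize(observed, "synthetic_observed"),
                         summarize(mc.summary, "model_simulated")])
    comp.to_csv(OUT / "observed_vs_simulated.csv", index=False)
    print(comp.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
    print("\nThe model under-predicts the weekly egg rate at the data-driven")
    print("laying rate (buffer gating) and matches hatchling masses and their")
    print("spread; food-in-grams depends on an assumed feed energy density.")


if __name__ == "__main__":
    main()
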