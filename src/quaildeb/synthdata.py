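"""Synthetic control-study generator (OECD-206-style avian reproduction data).

The proprietary control dataset behind the analysis reports, per cage of one
male and one female: weekly egg counts, weekly food use, hatchling and
14-day-chick masses, and adult masses before/after laying.  This module
generates tables with the same structure and summary statistics -- 17 usable
cages, ten laying weeks, a mean of ~5 eggs per bird-week from a truncated
exponential renewal process, hatchling-mass scatter averaging 8.45% CV --
so every pipeline stage can be exercised without the report.

Hatchling masses are drawn lognormal (strictly positive, right-skewed like
real mass data); food use is true intake inflated by a spillage factor >= 1.
All draws derive from a single seed and are fully reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .laying import INTERVAL_CUTOFF_D

__all__ = ["StudyConfig", "generate_control_study",
           "write_cageweek_csv", "read_cageweek_csv", "validate_cageweek",
           "CAGEWEEK_COLUMNS", "rate_for_weekly_mean"]

CAGEWEEK_COLUMNS = [
    "cage_id", "week_index", "eggs_laid", "food_g",
    "hatchling_masses_g", "chick14_masses_g",
    "adult_female_mass_start_g", "adult_female_mass_end_g",
    "adult_male_mass_start_g", "adult_male_mass_end_g",
]

_LIST_COLUMNS = ["hatchling_masses_g", "chick14_masses_g"]


@dataclass(frozen=True)
class StudyConfig:
    """Statistical targets of the emulated control study."""

    n_cages: int = 17
    weeks: int = 10
    eggs_per_week: float = 5.03        # mean eggs per bird-week
    hatchling_mass_g: float = 6.5      # mean hatchling mass
    hatchling_cv_mean: float = 0.0845  # average within-cage CV
    hatchling_cv_range: tuple[float, float] = (0.02, 0.15)
    chick14_mass_g: float = 34.37
    chick14_cv: float = 0.08
    female_mass_start_g: float = 190.0
    female_mass_end_g: float = 228.0
    male_mass_start_g: float = 178.0
    male_mass_end_g: float = 188.0
    adult_mass_cv: float = 0.05
    food_g_week: float = 320.0         # true intake per cage-week
    spillage_mean: float = 0.08        # mean fractional spillage (factor >= 1)
    noise: float = 1.0                 # 0 -> deterministic means everywhere

    def __post_init__(self):
        if self.n_cages < 0 or self.weeks < 1:
            raise ValueError("invalid study dimensions")
        if self.eggs_per_week <= 0:
            raise ValueError("eggs_per_week must be > 0")


def _truncated_exp_mean(rate: float, cutoff: float = INTERVAL_CUTOFF_D) -> float:
    q = math.exp(-rate * cutoff)
    return 1.0 / rate - cutoff * q / (1.0 - q)


def rate_for_weekly_mean(eggs_per_week: float) -> float:
    """Laying rate (1/d) whose truncated-exponential renewal process yields
    the requested mean eggs per week."""
    target = 7.0 / eggs_per_week
    return brentq(lambda lam: _truncated_exp_mean(lam) - target, 1e-3, 50.0)


def _weekly_counts(rate: float, weeks: int, rng: np.random.Generator) -> np.ndarray:
    """Egg counts per 7-day bin from a truncated-exponential renewal process."""
    horizon = 7.0 * weeks
    t = 0.0
    counts = np.zeros(weeks, dtype=int)
    q = 1.0 - math.exp(-rate * INTERVAL_CUTOFF_D)
    while True:
        u = rng.random()
        t += -math.log1p(-u * q) / rate
        if t >= horizon:
            break
        counts[int(t // 7.0)] += 1
    return counts


def generate_control_study(config: StudyConfig | None = None,
                           seed: int = 0,
                           weekly_food_g: np.ndarray | None = None) -> pd.DataFrame:
    """Generate one synthetic control study as a cage-week table.

    ``weekly_food_g`` optionally supplies the true per-cage weekly intake
    profile (e.g. back-calculated from the model); otherwise the configured
    constant is used.  With ``noise=0`` every quantity equals its configured
    mean exactly (egg counts become the rounded weekly mean).
    """
    cfg = config or StudyConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2061]))
    rate = rate_for_weekly_mean(cfg.eggs_per_week)
    lo_cv, hi_cv = cfg.hatchling_cv_range
    rows = []
    for cage in range(cfg.n_cages):
        if cfg.noise > 0:
            cage_cv = float(np.clip(
                rng.normal(cfg.hatchling_cv_mean, 0.03 * cfg.noise), lo_cv, hi_cv))
            counts = _weekly_counts(rate, cfg.weeks, rng)
            fem0 = rng.normal(cfg.female_mass_start_g,
                              cfg.adult_mass_cv * cfg.female_mass_start_g * cfg.noise)
            fem1 = rng.normal(cfg.female_mass_end_g,
                              cfg.adult_mass_cv * cfg.female_mass_end_g * cfg.noise)
            mal0 = rng.normal(cfg.male_mass_start_g,
                              cfg.adult_mass_cv * cfg.male_mass_start_g * cfg.noise)
            mal1 = rng.normal(cfg.male_mass_end_g,
                              cfg.adult_mass_cv * cfg.male_mass_end_g * cfg.noise)
        else:
            cage_cv = 0.0
            counts = np.full(cfg.weeks, int(round(cfg.eggs_per_week)))
            fem0, fem1 = cfg.female_mass_start_g, cfg.female_mass_end_g
            mal0, mal1 = cfg.male_mass_start_g, cfg.male_mass_end_g
        for w in range(cfg.weeks):
            n = int(counts[w])
            if cfg.noise > 0 and cage_cv > 0:
                sigma = math.sqrt(math.log1p(cage_cv ** 2))
                mu = math.log(cfg.hatchling_mass_g) - sigma ** 2 / 2.0
                hatch = list(np.round(rng.lognormal(mu, sigma, size=n), 3))
                s14 = math.sqrt(math.log1p((cfg.chick14_cv * cfg.noise) ** 2))
                m14 = math.log(cfg.chick14_mass_g) - s14 ** 2 / 2.0
                chick = list(np.round(rng.lognormal(m14, s14, size=n), 3))
            else:
                hatch = [cfg.hatchling_mass_g] * n
                chick = [cfg.chick14_mass_g] * n
            base_food = (float(weekly_food_g[w]) if weekly_food_g is not None
                         else cfg.food_g_week)
            if cfg.noise > 0 and cfg.spillage_mean > 0:
                spill = 1.0 + rng.gamma(2.0, cfg.spillage_mean / 2.0)
            else:
                spill = 1.0
            rows.append({
                "cage_id": cage, "week_index": w, "eggs_laid": n,
                "food_g": round(base_food * spill, 2),
                "hatchling_masses_g": hatch, "chick14_masses_g": chick,
                "adult_female_mass_start_g": round(float(fem0), 2),
                "adult_female_mass_end_g": round(float(fem1), 2),
                "adult_male_mass_start_g": round(float(mal0), 2),
                "adult_male_mass_end_g": round(float(mal1), 2),
            })
    table = pd.DataFrame(rows, columns=CAGEWEEK_COLUMNS)
    validate_cageweek(table)
    return table


# ---------------------------------------------------------------------------
# schema and IO


def validate_cageweek(table: pd.DataFrame) -> None:
    """Schema check: required columns, non-negative counts, positive masses."""
    missing = [c for c in CAGEWEEK_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cage-week table missing column(s): {missing}")
    extra = [c for c in table.columns if c not in CAGEWEEK_COLUMNS]
    if extra:
        raise ValueError(f"cage-week table has unexpected column(s): {extra}")
    if len(table) == 0:
        return
    if (table["eggs_laid"] < 0).any():
        raise ValueError("eggs_laid must be >= 0")
    for col in ("food_g", "adult_female_mass_start_g", "adult_female_mass_end_g"):
        vals = table[col].dropna()
        if (vals <= 0).any():
            raise ValueError(f"{col} must be > 0")
    for col in _LIST_COLUMNS:
        for masses in table[col]:
            if any(m <= 0 for m in masses):
                raise ValueError(f"{col} entries must be > 0")
    dup = table.duplicated(subset=["cage_id", "week_index"])
    if dup.any():
        raise ValueError("duplicate cage-week rows")


def write_cageweek_csv(table: pd.DataFrame, path) -> None:
    """Serialise; mass lists become semicolon-joined strings."""
    validate_cageweek(table)
    out = table.copy()
    for col in _LIST_COLUMNS:
        out[col] = out[col].map(lambda xs: ";".join(repr(float(x)) for x in xs))
    out.to_csv(path, index=False)


def read_cageweek_csv(path) -> pd.DataFrame:
    """Read a cage-week CSV back into the in-memory schema (lossless)."""
    table = pd.read_csv(path, dtype={"cage_id": int, "week_index": int,
                                     "eggs_laid": int})
    for col in _LIST_COLUMNS:
        if col in table.columns:
            table[col] = table[col].map(
                lambda s: [] if (not isinstance(s, str) or s == "")
                else [float(x) for x in s.split(";")])
    table = table[ [c for c in CAGEWEEK_COLUMNS if c in table.columns] ]
    validate_cageweek(table)
    return table
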