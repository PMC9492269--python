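"""Monte-Carlo cohorts: inter-individual variability in laying, eggs, physiology.

Three scatter sources reproduce the spread seen in control-study data:

1. inter-egg intervals -- exponential with mean ``1/k_R``, truncated at 10 d;
2. egg size -- truncated-normal scatter (CV 8.45%) around the maternal-effect
   egg energy, bounded by the smallest/largest observed eggs;
3. physiology -- the zoom factor ``z`` drawn with CV 1%, scaling the maximum
   specific assimilation via the covariation rule ``{p_Am} = (z/z0) {p_Am}^0``;
   optionally digestion efficiency ``kap_X ~ Beta(20, 19)``.

Each hen gets one independent, seed-derived random stream per scatter source,
so switching one source off leaves the draws of the others untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import wet_weight
from .embryo import default_egg_bounds, embryo_map
from .laying import EggEvent
from .lifecycle import (DEFAULT_FOOD_ENERGY_DENSITY, ExperimentProtocol,
                        LifecycleResult, ingestion_series, simulate_lifecycle,
                        weekly_egg_counts)
from .params import DEBParams

__all__ = ["CohortSpec", "sample_cohort", "sample_egg_size",
           "run_monte_carlo", "MonteCarloResult", "chick14_weight_map"]

# stream tags: one RNG stream per (seed, replicate, hen, source)
_SRC_Z, _SRC_KAPX, _SRC_INTERVALS, _SRC_EGGSIZE = 0, 1, 2, 3


def _stream(seed: int, replicate: int, hen: int, source: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, replicate, hen, source]))


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of one simulated cohort of hens."""

    n_hens: int = 25
    cv_egg: float = 0.0845          # egg-size CV
    cv_z: float = 0.01              # zoom-factor CV
    k_R_rate: float = 0.7           # egg-laying rate, 1/d at body temperature
    kappaX_beta: tuple[float, float] | None = None  # e.g. (20, 19)
    seed: int = 0

    def __post_init__(self):
        if self.n_hens < 1:
            raise ValueError("n_hens must be >= 1")
        if self.cv_egg < 0 or self.cv_z < 0:
            raise ValueError("CVs must be >= 0")


def sample_cohort(base_params: DEBParams, spec: CohortSpec,
                  replicate: int = 0) -> list[DEBParams]:
    """Per-hen parameter sets: zoom scatter (with p_Am covariation), kap_X scatter."""
    hens = []
    for i in range(spec.n_hens):
        p = base_params
        if spec.cv_z > 0:
            rng = _stream(spec.seed, replicate, i, _SRC_Z)
            z = -1.0
            while z <= 0:
                z = rng.normal(base_params.z, spec.cv_z * base_params.z)
            p = p.replace(z=z, p_Am=base_params.p_Am * z / base_params.z)
        if spec.kappaX_beta is not None:
            rng = _stream(spec.seed, replicate, i, _SRC_KAPX)
            a, b = spec.kappaX_beta
            p = p.replace(kap_X=float(rng.beta(a, b)))
        hens.append(p)
    return hens


def sample_egg_size(E0_maternal: float, cv: float,
                    bounds: tuple[float, float],
                    rng: np.random.Generator) -> float:
    """Truncated-normal egg energy around the maternal-effect mean.

    Values outside ``bounds`` are rejected and redrawn.  Raises if the
    bounds exclude the mean by more than 6 standard deviations.
    """
    lo, hi = bounds
    if lo >= hi:
        raise ValueError("invalid egg-size bounds")
    if cv == 0:
        return E0_maternal
    sd = cv * E0_maternal
    if E0_maternal < lo - 6 * sd or E0_maternal > hi + 6 * sd:
        raise ValueError("egg-size bounds exclude the maternal mean by > 6 SD")
    for _ in range(1000):
        x = rng.normal(E0_maternal, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("egg-size rejection sampling failed to accept a draw")


# ---------------------------------------------------------------------------
# offspring observables

_CHICK_CACHE: dict[tuple, object] = {}


def chick14_weight_map(params: DEBParams, T: float | None = None):
    """Interpolant E_0 -> wet weight 14 d post-hatch at the control-study f.

    Offspring are simulated with the cohort-average physiology; only the egg
    energy (the mother-offspring link) varies between chicks.
    """
    from scipy.interpolate import PchipInterpolator

    from .core import integrate

    key = (params.v, params.p_M, params.E_G, params.kap, params.k_J,
           params.E_Hb, params.p_Am, params.f_B, params.T_A, T)
    if key in _CHICK_CACHE:
        return _CHICK_CACHE[key]
    emap = embryo_map(params, T=T)
    E0s = np.geomspace(emap.E0_range[0] * 1.05, emap.E0_range[1] * 0.95, 12)
    W14 = []
    for E0 in E0s:
        birth = emap.birth_state(E0)
        tr = integrate(birth, (birth.t, birth.t + 14.0), params, f=params.f_B,
                       hyp="none", T=T, rtol=1e-6, dense_step=14.0)
        W14.append(float(tr.wet_weight()[-1]))
    interp = PchipInterpolator(E0s, np.array(W14))
    fn = lambda e0: float(interp(np.clip(e0, E0s[0], E0s[-1])))
    if len(_CHICK_CACHE) > 16:
        _CHICK_CACHE.clear()
    _CHICK_CACHE[key] = fn
    return fn


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class MonteCarloResult:
    """Per-hen lifecycle results plus cohort-level weekly summaries."""

    hens: list[LifecycleResult]
    summary: pd.DataFrame           # one row per hen-week (CageWeekTable schema)
    failures: list[int]

    @property
    def all_eggs(self) -> list[EggEvent]:
        return [e for h in self.hens for e in h.eggs]

    @property
    def eggs_per_bird_per_week(self) -> float:
        return float(np.mean([h.eggs_per_week for h in self.hens]))

    def mean_egg_mass(self, corrected: bool = False) -> float:
        masses = [e.egg_mass_g for e in self.all_eggs]
        m = float(np.mean(masses)) if masses else float("nan")
        return m * 1.08 if corrected else m


def run_monte_carlo(base_params: DEBParams, spec: CohortSpec,
                    protocol: ExperimentProtocol | None = None,
                    hyp: str = "H2", replicate: int = 0,
                    energy_density: float = DEFAULT_FOOD_ENERGY_DENSITY,
                    with_offspring: bool = True) -> MonteCarloResult:
    """Simulate a cohort of hens and aggregate weekly observables.

    Reproducible: the same ``(spec.seed, replicate)`` yields bit-identical
    summaries.  A hen whose solver fails is recorded in ``failures`` and the
    run continues.
    """
    proto = protocol or ExperimentProtocol()
    hen_params = sample_cohort(base_params, spec, replicate=replicate)
    bounds = default_egg_bounds(base_params)
    chick_map = chick14_weight_map(base_params, T=proto.T_b) if with_offspring else None
    emap = embryo_map(base_params, T=proto.T_b)

    hens: list[LifecycleResult] = []
    failures: list[int] = []
    rows = []
    for i, p in enumerate(hen_params):
        rng_int = _stream(spec.seed, replicate, i, _SRC_INTERVALS)
        rng_egg = _stream(spec.seed, replicate, i, _SRC_EGGSIZE)
        sampler = ((lambda e0, _r, rng=rng_egg:
                    sample_egg_size(e0, spec.cv_egg, bounds, rng))
                   if spec.cv_egg > 0 else None)
        try:
            res = simulate_lifecycle(p, hyp, proto, rng=rng_int,
                                     k_R=spec.k_R_rate,
                                     egg_size_sampler=sampler)
        except RuntimeError:
            failures.append(i)
            continue
        hens.append(res)

        counts = weekly_egg_counts(res.eggs, res.timeline["first_egg"],
                                   proto.laying_weeks)
        ing = ingestion_series(res, energy_density=energy_density)
        w_start = wet_weight(res.start_point.state, p)
        w_end = wet_weight(res.end_point.state, p)
        for w in range(proto.laying_weeks):
            t0 = res.timeline["first_egg"] + 7.0 * w
            t1 = t0 + 7.0
            in_wk = (ing["t_d"] >= t0) & (ing["t_d"] < t1)
            food_g = float(np.trapezoid(ing.loc[in_wk, "food_g_d"],
                                        ing.loc[in_wk, "t_d"])) if in_wk.sum() > 1 else float("nan")
            wk_eggs = [e for e in res.eggs if t0 <= e.time < t1]
            hatch = ([emap.birth_weight(e.E_0) for e in wk_eggs]
                     if with_offspring else [])
            chick14 = ([chick_map(e.E_0) for e in wk_eggs]
                       if with_offspring else [])
            rows.append({
                "cage_id": i, "week_index": w, "eggs_laid": int(counts[w]),
                "food_g": food_g,
                "hatchling_masses_g": hatch, "chick14_masses_g": chick14,
                "adult_female_mass_start_g": w_start,
                "adult_female_mass_end_g": w_end,
                "adult_male_mass_start_g": float("nan"),
                "adult_male_mass_end_g": float("nan"),
            })
    summary = pd.DataFrame(rows)
    return MonteCarloResult(hens=hens, summary=summary, failures=failures)
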