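"""Full ontogeny under the avian-reproduction-study protocol.

Timeline (all in days).  Age 0 is fertilization; hatch occurs at ``a_b``.
Chicks experience rich food (the dataset-specific juvenile ``f``) for their
first ~50 days post-hatch, then reference food (f = 1) until the experiment
starts at 112 d post-hatch, after which adults are held at ``f_mf``.
Photostimulation follows 67 d after puberty, the first egg 40 d later, and
laying lasts 10 weeks.  Feeding up-regulation ramps linearly from 25 d
before the first egg to the end of the laying window.

The module also computes the zero-variate prediction table (ages, lengths
and wet weights at life-history events), a weight-specific respiration proxy
used to contrast the two energy-allocation hypotheses, and back-calculated
food ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (OrganismState, Trajectory, compute_fluxes, integrate,
                   physical_length, wet_weight)
from .embryo import embryo_map, initial_egg_energy, simulate_embryo
from .laying import (EggEvent, UpRegulationSchedule, attempt_lay,
                     draw_interval, s_X_at)
from .params import DEBParams

__all__ = [
    "ExperimentProtocol", "LifecycleResult", "OperatingPoint",
    "simulate_lifecycle", "zero_variate_predictions", "respiration_contrast",
    "o2_proxy", "ingestion_series", "male_daily_ingestion",
    "weekly_egg_counts", "OBSERVED_ZERO_VARIATE", "DEFAULT_FOOD_ENERGY_DENSITY",
]

# Metabolizable energy density of feed (J/g) used only to express ingestion in
# grams; the reports never state it, so gram values are relative to this choice.
DEFAULT_FOOD_ENERGY_DENSITY = 11.0e3

#: Observed zero-variate calibration data: ages (d), lengths (cm), weights (g).
OBSERVED_ZERO_VARIATE = {
    "a_b": 23.0,     # age at hatching
    "t_p": 100.0,    # time since hatch at puberty
    "a_m": 2336.0,   # life span
    "L_i": 26.0,     # ultimate total length
    "W_wb": 6.5,     # wet weight at hatch
    "W_w14": 34.37,  # wet weight at 14 d since hatch
    "W_wx": 182.9,   # wet weight at fledging
    "W_wp": 194.2,   # wet weight at puberty
    "W_wi": 200.0,   # ultimate wet weight
}


@dataclass(frozen=True)
class ExperimentProtocol:
    """Timeline and feeding regime of the control reproduction study."""

    age_puberty: float = 100.0           # d post-hatch, nominal (emergent in the model)
    age_experiment_start: float = 112.0  # d post-hatch
    pre_photostim: float = 67.0          # d from puberty to photostimulation
    photostim: float = 40.0              # d from photostimulation to first egg
    laying_weeks: int = 10
    upreg_lead: float = 25.0             # up-regulation starts this long before first egg
    juvenile_f_end: float = 50.0         # d post-hatch; end of rich juvenile feeding
    f_juvenile: float | None = None      # default: params.f_B (control-study chicks)
    f_mid: float = 1.0                   # f between juvenile window and experiment
    f_adult: float | None = None         # default: params.f_mf
    T_b: float = 312.05                  # K
    days_after_puberty: float | None = None  # extend laying so pub->end spans this
    # "lay_end": ramp spans preparation plus laying; "first_egg": ramp tops out
    # at the first egg and holds at s_max through laying
    upreg_ramp_end: str = "lay_end"

    def __post_init__(self):
        for name in ("age_experiment_start", "pre_photostim", "photostim",
                     "upreg_lead", "juvenile_f_end"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.laying_weeks < 1:
            raise ValueError("laying_weeks must be >= 1")

    @property
    def laying_window_d(self) -> float:
        base = 7.0 * self.laying_weeks
        if self.days_after_puberty is not None:
            ext = self.days_after_puberty - self.pre_photostim - self.photostim
            return max(base, ext)
        return base


@dataclass
class OperatingPoint:
    """A state plus the feeding conditions it experiences."""

    state: OrganismState
    f: float
    s_X: float
    hyp: str


@dataclass
class LifecycleResult:
    """Trajectory, egg events and timeline of one simulated individual."""

    params: DEBParams
    hyp: str
    trajectory: Trajectory
    eggs: list[EggEvent]
    a_b: float
    t_puberty: float              # absolute age, d
    timeline: dict                # absolute ages of protocol landmarks, d
    schedule: UpRegulationSchedule | None
    start_point: OperatingPoint | None = None
    end_point: OperatingPoint | None = None

    @property
    def eggs_per_week(self) -> float:
        weeks = (self.timeline["lay_end"] - self.timeline["first_egg"]) / 7.0
        return len(self.eggs) / weeks

    def s_X_of(self, t: float) -> float:
        return s_X_at(t, self.schedule) if self.schedule is not None else 0.0

    def f_of(self, t: float) -> float:
        proto = self.timeline
        if t < self.a_b + proto["juvenile_f_end"]:
            return proto["f_juvenile"]
        if t < proto["experiment_start"]:
            return proto["f_mid"]
        return proto["f_adult"]


def weekly_egg_counts(eggs: list[EggEvent], window_start: float,
                      n_weeks: int) -> np.ndarray:
    """Egg counts in consecutive 7-day bins from the opening of laying."""
    counts = np.zeros(n_weeks, dtype=int)
    for e in eggs:
        w = int((e.time - window_start) // 7.0)
        if 0 <= w < n_weeks:
            counts[w] += 1
    return counts


def simulate_lifecycle(params: DEBParams, hyp: str,
                       protocol: ExperimentProtocol | None = None, *,
                       rng: np.random.Generator | None = None,
                       k_R: float | None = None,
                       egg_size_sampler=None,
                       laying: bool = True,
                       s_max: float | None = None,
                       rtol: float = 1e-6,
                       sample_step: float = 1.0) -> LifecycleResult:
    """Simulate one hen from fertilization to the end of the laying window.

    ``rng`` drives the inter-egg intervals (deterministic protocol otherwise);
    ``k_R`` overrides the calibrated laying rate; ``egg_size_sampler`` maps the
    maternal-effect egg energy to a realised one (defaults to the identity);
    ``laying=False`` runs the protocol without releasing eggs (buffer only).
    """
    proto = protocol or ExperimentProtocol()
    if rng is None:
        rng = np.random.default_rng(0)
    T = proto.T_b
    f_juv = proto.f_juvenile if proto.f_juvenile is not None else params.f_B
    f_adult = proto.f_adult if proto.f_adult is not None else params.f_mf
    smax = s_max if s_max is not None else params.s_max
    k_R_eff = k_R if k_R is not None else params.k_R_rate

    emap = embryo_map(params, T=T)
    # founder egg: mother at reference feeding
    E0_founder = emap.E0_for_density(params.f_ref * params.E_m)
    birth = emap.birth_state(E0_founder)
    a_b = birth.t

    parts: list[Trajectory] = []

    # --- juvenile: rich food, then reference food ---------------------------
    t_juv_end = a_b + proto.juvenile_f_end
    tr = integrate(birth, (a_b, t_juv_end), params, f=f_juv, hyp="none", T=T,
                   rtol=rtol, dense_step=sample_step)
    parts.append(tr)
    st = tr.final_state
    t_exp = a_b + proto.age_experiment_start
    tr = integrate(st, (t_juv_end, t_exp), params, f=proto.f_mid, hyp="none",
                   T=T, rtol=rtol, dense_step=sample_step)
    parts.append(tr)
    st = tr.final_state

    t_pub = None
    for p in parts:
        if "puberty" in p.events:
            t_pub = p.events["puberty"]
    start_point = OperatingPoint(state=st, f=f_adult, s_X=0.0, hyp=hyp)

    if t_pub is None:
        # continue at adult food until puberty, then restart the clock
        tr = integrate(st, (t_exp, t_exp + 400.0), params, f=f_adult,
                       hyp="none", T=T, rtol=rtol, dense_step=sample_step)
        if "puberty" not in tr.events:
            raise RuntimeError("puberty never reached under the protocol feeding")
        t_pub = tr.events["puberty"]
        i_cut = np.searchsorted(tr.t, t_pub, side="right")
        parts.append(Trajectory(t=tr.t[:i_cut], L=tr.L[:i_cut], E=tr.E[:i_cut],
                                E_H=tr.E_H[:i_cut], E_R=tr.E_R[:i_cut],
                                params=params, hyp=hyp, events=tr.events))
        st = OrganismState(t=t_pub, L=float(tr.L[i_cut - 1]),
                           E=float(tr.E[i_cut - 1]), E_H=params.E_Hp,
                           E_R=float(tr.E_R[i_cut - 1]))

    t_photo = t_pub + proto.pre_photostim
    t_first_egg = t_photo + proto.photostim
    t_end = t_first_egg + proto.laying_window_d
    if smax > 0:
        if proto.upreg_ramp_end == "first_egg":
            sched = UpRegulationSchedule(t0=t_first_egg - proto.upreg_lead,
                                         t1=t_first_egg, s_max=smax,
                                         plateau_until=t_end)
        else:
            sched = UpRegulationSchedule(t0=t_first_egg - proto.upreg_lead,
                                         t1=t_end, s_max=smax)
    else:
        sched = None
    s_fn = (lambda t: s_X_at(t, sched)) if sched is not None else 0.0

    timeline = {
        "experiment_start": t_exp, "photostim": t_photo,
        "first_egg": t_first_egg, "lay_end": t_end,
        "juvenile_f_end": proto.juvenile_f_end, "f_juvenile": f_juv,
        "f_mid": proto.f_mid, "f_adult": f_adult,
    }

    # --- adult, pre-laying --------------------------------------------------
    t_resume = max(st.t, t_exp)
    tr = integrate(st, (t_resume, t_first_egg), params, f=f_adult, s_X=s_fn,
                   hyp=hyp, T=T, rtol=rtol, dense_step=sample_step)
    parts.append(tr)
    st = tr.final_state

    # --- laying window ------------------------------------------------------
    eggs: list[EggEvent] = []
    if laying:
        t_attempt = t_first_egg
        while t_attempt < t_end:
            if t_attempt > st.t:
                tr = integrate(st, (st.t, t_attempt), params, f=f_adult,
                               s_X=s_fn, hyp=hyp, T=T, rtol=rtol,
                               dense_step=max(sample_step, 2.0))
                parts.append(tr)
                st = tr.final_state
            E0_m = emap.E0_for_density(st.reserve_density)
            E0 = egg_size_sampler(E0_m, rng) if egg_size_sampler else E0_m
            ev = attempt_lay(st, E0, params)
            if ev is not None:
                eggs.append(ev)
            t_attempt = st.t + draw_interval(k_R_eff, rng)
    if st.t < t_end:
        tr = integrate(st, (st.t, t_end), params, f=f_adult, s_X=s_fn,
                       hyp=hyp, T=T, rtol=rtol, dense_step=sample_step)
        parts.append(tr)
        st = tr.final_state

    end_point = OperatingPoint(
        state=st, f=f_adult,
        s_X=s_X_at(t_end, sched) if sched is not None else 0.0, hyp=hyp)

    traj = Trajectory.concatenate(parts)
    return LifecycleResult(params=params, hyp=hyp, trajectory=traj, eggs=eggs,
                           a_b=a_b, t_puberty=t_pub, timeline=timeline,
                           schedule=sched, start_point=start_point,
                           end_point=end_point)


# ---------------------------------------------------------------------------
# zero-variate predictions


def zero_variate_predictions(params: DEBParams, hyp: str = "none",
                             a_m_pred: float | None = None,
                             observed: dict | None = None) -> pd.DataFrame:
    """Predict the zero-variate calibration quantities from dedicated runs.

    Embryo run at reference food for ``a_b``/``W_wb``; juvenile run at f = 1
    for ``t_p``/``W_wx``/``W_wp``; a 14-day juvenile run at the control-study
    juvenile ``f`` for ``W_w14``; closed-form asymptotics for ``L_i``/``W_wi``.
    The life span ``a_m`` is a configuration passthrough (no aging submodel).
    """
    obs = dict(OBSERVED_ZERO_VARIATE)
    if observed:
        obs.update(observed)
    T = params.T_b
    f = params.f_ref

    E0 = initial_egg_energy(f * params.E_m, params, T=T)
    birth, a_b = simulate_embryo(E0, params, T=T)
    W_wb = wet_weight(birth, params)

    # juvenile run at reference food until puberty
    tr = integrate(birth, (a_b, a_b + 1500.0), params, f=f, hyp="none", T=T,
                   rtol=1e-7, dense_step=5.0)
    if "puberty" not in tr.events:
        raise RuntimeError("puberty not reached at reference food")
    t_p = tr.events["puberty"] - a_b

    def weight_at(t_target: float) -> float:
        i = int(np.argmin(np.abs(tr.t - t_target)))
        return float(tr.wet_weight()[i])

    W_wx = weight_at(tr.events["fledging"]) if "fledging" in tr.events else float("nan")
    W_wp = weight_at(tr.events["puberty"])

    tr14 = integrate(birth, (a_b, a_b + 14.0), params, f=params.f_B,
                     hyp="none", T=T, rtol=1e-7, dense_step=1.0)
    W_w14 = float(tr14.wet_weight()[-1])

    L_i = params.L_inf(f)
    W_wi = (params.d_Vw * L_i ** 3
            + f * params.E_m * L_i ** 3 * params.reserve_mass_coeff)

    preds = {
        "a_b": a_b, "t_p": t_p,
        "a_m": a_m_pred if a_m_pred is not None else obs["a_m"],
        "L_i": physical_length(L_i, params.del_M),
        "W_wb": W_wb, "W_w14": W_w14, "W_wx": W_wx, "W_wp": W_wp,
        "W_wi": W_wi,
    }
    rows = []
    for name, pred in preds.items():
        o = obs[name]
        rows.append({"name": name, "observed": o, "predicted": pred,
                     "relative_error": abs(pred - o) / abs(o)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# respiration proxy and ingestion


def o2_proxy(point: OperatingPoint, params: DEBParams,
             include_feeding: bool = False, T: float | None = None) -> float:
    """Weight-specific dissipation (J/d/g), a proxy for O2 consumption.

    Sums somatic and maturity maintenance with the overhead of growth
    (fraction ``1 - kap_G`` of structure synthesis) and, optionally, the heat
    increment of feeding, ``(1/kap_X - 1)`` of the assimilation that is
    metabolically processed into reserve.  Energy flowing into the
    reproduction buffer is storage, not dissipation (its ``kap_R`` overhead
    is paid at egg formation), so it does not appear here; under the
    direct-allocation hypothesis the extra assimilates likewise bypass the
    reserve machinery and carry no feeding increment.  Divided by wet weight.
    """
    fx = compute_fluxes(point.state, point.f, point.s_X, point.hyp, params, T=T)
    diss = fx.p_S + fx.p_J + (1.0 - params.kap_G) * max(fx.p_G, 0.0)
    if include_feeding:
        diss += (1.0 / params.kap_X - 1.0) * fx.p_A
    return diss / wet_weight(point.state, params)


def respiration_contrast(start: OperatingPoint, end: OperatingPoint,
                         include_feeding: bool, params: DEBParams,
                         T: float | None = None) -> float:
    """Percent change in weight-specific O2 proxy between two states."""
    r0 = o2_proxy(start, params, include_feeding=include_feeding, T=T)
    r1 = o2_proxy(end, params, include_feeding=include_feeding, T=T)
    return (r1 - r0) / r0 * 100.0


def ingestion_series(result: LifecycleResult,
                     energy_density: float | None = None,
                     t_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Back-calculated food intake p_X = p_A_total / kap_X along a run.

    Returns a frame with columns ``t_d`` and ``p_X_J_d`` plus ``food_g_d``
    when an energy density (J/g) is supplied.
    """
    p = result.params
    tr = result.trajectory
    rt = p.rates_at(result.timeline.get("T", p.T_b))
    ts = t_grid if t_grid is not None else tr.t
    Ls = np.interp(ts, tr.t, tr.L)
    EHs = np.interp(ts, tr.t, tr.E_H)
    p_X = np.zeros_like(ts, dtype=float)
    for i, (t, L, EH) in enumerate(zip(ts, Ls, EHs)):
        if EH < p.E_Hb:
            continue
        fv = result.f_of(t)
        sv = result.s_X_of(t)
        p_A_total = (1.0 + sv) * fv * rt.p_Am * L * L
        p_X[i] = p_A_total / p.kap_X
    out = pd.DataFrame({"t_d": ts, "p_X_J_d": p_X})
    if energy_density is not None:
        if energy_density <= 0:
            raise ValueError("food energy density must be > 0")
        out["food_g_d"] = out["p_X_J_d"] / energy_density
    return out


def male_daily_ingestion(params: DEBParams, T: float | None = None) -> float:
    """Food-energy intake (J/d) of a non-up-regulated adult male at f_mf.

    The male sits at his ultimate size for the adult feeding level; his
    reproduction buffer is debited ``E_sperm`` per mating opportunity, which
    does not alter ingestion.
    """
    rt = params.rates_at(T)
    f = params.f_mf
    L = params.L_inf(f)
    return f * rt.p_Am * L * L / params.kap_X
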