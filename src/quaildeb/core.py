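"""State dynamics of one individual: kappa-rule energy fluxes and integration.

The state is (L, E, E_H, E_R).  Mobilised reserve is split by the kappa-rule:
a fraction ``kap`` fuels somatic maintenance and growth, the rest fuels
maturity maintenance plus maturation (pre-puberty) or reproduction
(post-puberty).  When mobilisation cannot cover somatic maintenance the
growth rate turns negative and structure shrinks, with only a fraction
``kap_G`` of the energy previously invested in structure recovered.

Two egg-module variants rewire the fluxes of a feeding, up-regulated adult:

* ``H1``: the extra assimilation ``p_A_R = s_X f {p_Am} L^2`` is added to the
  maturation/reproduction flux ``p_R``;
* ``H2``: assimilation becomes ``(1+s_X) {p_Am} f L^2`` and somatic
  maintenance ``(1+s_X f) [p_M] L^3``.

With ``s_X = 0`` both variants reduce exactly to the standard model.
All rates are Arrhenius-corrected to the working temperature before use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import DEBParams, Rates

__all__ = [
    "OrganismState", "Fluxes", "Trajectory",
    "specific_growth_rate", "compute_fluxes", "arrhenius_correct",
    "wet_weight", "physical_length", "integrate",
]

HYPOTHESES = ("none", "H1", "H2")


@dataclass
class OrganismState:
    """Instantaneous state of one individual."""

    t: float      # age since fertilization, d
    L: float      # structural length, cm
    E: float      # reserve energy, J
    E_H: float    # maturity, J
    E_R: float = 0.0  # reproduction buffer, J

    def stage(self, params: DEBParams) -> str:
        if self.E_H < params.E_Hb:
            return "embryo"
        if self.E_H < params.E_Hp:
            return "juvenile"
        return "adult"

    @property
    def reserve_density(self) -> float:
        """[E] = E / L^3 (J/cm^3)."""
        return self.E / self.L ** 3

    def as_vector(self) -> np.ndarray:
        return np.array([self.L, self.E, self.E_H, self.E_R], float)


@dataclass
class Fluxes:
    """The seven powers (J/d) of the model at one instant."""

    p_A: float    # assimilation (includes up-regulated part under H2)
    p_C: float    # mobilization
    p_S: float    # somatic maintenance (inflated under H2)
    p_J: float    # maturity maintenance
    p_G: float    # growth (negative while shrinking)
    p_R: float    # maturation / reproduction (includes p_A_R under H1)
    p_A_R: float  # extra assimilation from feeding up-regulation


def _check_finite(**values) -> None:
    for name, val in values.items():
        if not math.isfinite(val):
            raise ValueError(f"{name} must be finite, got {val}")


def specific_growth_rate(E: float, L: float, params: DEBParams,
                         p_M_eff: float | None = None,
                         rates: Rates | None = None) -> float:
    """Specific growth rate r (1/d), with the starvation branch.

    ``r = (E v / L - p_M_eff L^3 / kap) / (E + E_G L^3 / kap)`` while
    ``kap E v >= p_M_eff L^4``; otherwise the cost of structure in the
    denominator is replaced by ``kap_G E_G`` (shrinking recovers only a
    fraction ``kap_G`` of the energy invested), and r may be negative.

    ``rates`` supplies temperature-corrected ``v``/``p_M``; when omitted the
    reference-temperature values are used.  ``p_M_eff`` overrides the
    volume-specific maintenance (H2 inflates it by ``1 + s_X f``).
    """
    _check_finite(E=E, L=L)
    if L <= 0:
        raise ValueError("L must be > 0")
    if E < 0:
        raise ValueError("E must be >= 0")
    v = rates.v if rates is not None else params.v
    p_M = p_M_eff if p_M_eff is not None else (
        rates.p_M if rates is not None else params.p_M)
    if p_M_eff is not None:
        _check_finite(p_M_eff=p_M_eff)
    kap = params.kap
    L3 = L ** 3
    numerator = E * v / L - p_M * L3 / kap
    if kap * E * v >= p_M * L3 * L:
        denom = E + params.E_G * L3 / kap
    else:
        denom = E + params.kap_G * params.E_G * L3 / kap
    return numerator / denom


def arrhenius_correct(rate: float, T: float, params: DEBParams,
                      T_from: float | None = None) -> float:
    """Correct a rate quoted at ``T_from`` (default T_ref) to temperature T."""
    _check_finite(rate=rate)
    return rate * params.temp_factor(T, T_from=T_from)


def compute_fluxes(state: OrganismState, f: float, s_X: float, hyp: str,
                   params: DEBParams, T: float | None = None,
                   rates: Rates | None = None) -> Fluxes:
    """All powers for one state under one egg-module hypothesis.

    ``f`` is the scaled functional response, ``s_X`` the instantaneous
    up-regulation level (0 outside the up-regulation window), ``hyp`` one of
    ``"none"``, ``"H1"``, ``"H2"``.  Rates are corrected to ``T``
    (default: body temperature).
    """
    if hyp not in HYPOTHESES:
        raise ValueError(f"unknown hypothesis {hyp!r}; expected one of {HYPOTHESES}")
    if f < 0:
        raise ValueError("f must be >= 0")
    if s_X < 0:
        raise ValueError("s_X must be >= 0")
    rt = rates if rates is not None else params.rates_at(T)
    L, E, E_H = state.L, state.E, state.E_H
    L2 = L * L
    L3 = L2 * L

    feeding = E_H >= params.E_Hb  # embryos neither feed nor assimilate
    p_A_base = rt.p_Am * f * L2 if feeding else 0.0
    p_A_R = s_X * f * rt.p_Am * L2 if feeding else 0.0

    p_M_eff = rt.p_M * (1.0 + s_X * f) if hyp == "H2" else rt.p_M
    r = specific_growth_rate(E, L, params, p_M_eff=p_M_eff, rates=rt)

    p_A = p_A_base + (p_A_R if hyp == "H2" else 0.0)
    p_C = E * (rt.v / L - r)
    p_S = p_M_eff * L3
    p_J = rt.k_J * min(E_H, params.E_Hp)
    p_G = r * params.E_G * L3
    p_R = (1.0 - params.kap) * p_C - p_J
    if hyp == "H1":
        p_R += p_A_R
    return Fluxes(p_A=p_A, p_C=p_C, p_S=p_S, p_J=p_J, p_G=p_G, p_R=p_R,
                  p_A_R=p_A_R)


def wet_weight(state: OrganismState, params: DEBParams) -> float:
    """Wet weight (g): structure + reserve (with water) + water-free buffer.

    ``W_w = d_Vw L^3 + E w_Ed d_Vw / (mu_E d_Vd) + E_R w_Ed d_Vw / mu_E``.
    """
    return (params.d_Vw * state.L ** 3
            + state.E * params.reserve_mass_coeff
            + state.E_R * params.buffer_mass_coeff)


def physical_length(L: float, delta: float) -> float:
    """Physical length L_w = L / delta for a given shape coefficient."""
    if delta <= 0:
        raise ValueError("shape coefficient must be > 0")
    return L / delta


# ---------------------------------------------------------------------------
# integration


@dataclass
class Trajectory:
    """Sampled solution of the state ODEs plus recorded stage transitions."""

    t: np.ndarray
    L: np.ndarray
    E: np.ndarray
    E_H: np.ndarray
    E_R: np.ndarray
    params: DEBParams
    hyp: str = "none"
    events: dict = field(default_factory=dict)  # threshold name -> time

    def state_at(self, i: int) -> OrganismState:
        return OrganismState(t=float(self.t[i]), L=float(self.L[i]),
                             E=float(self.E[i]), E_H=float(self.E_H[i]),
                             E_R=float(self.E_R[i]))

    @property
    def final_state(self) -> OrganismState:
        return self.state_at(-1)

    def wet_weight(self) -> np.ndarray:
        p = self.params
        return (p.d_Vw * self.L ** 3 + self.E * p.reserve_mass_coeff
                + self.E_R * p.buffer_mass_coeff)

    def to_frame(self) -> pd.DataFrame:
        p = self.params
        stage = np.where(self.E_H < p.E_Hb, "embryo",
                         np.where(self.E_H < p.E_Hp, "juvenile", "adult"))
        return pd.DataFrame({
            "t_d": self.t, "L_cm": self.L, "E_J": self.E,
            "E_H_J": self.E_H, "E_R_J": self.E_R, "stage": stage,
            "Ww_g": self.wet_weight(),
        })

    @staticmethod
    def concatenate(parts: Sequence["Trajectory"]) -> "Trajectory":
        parts = [p for p in parts if p.t.size]
        first = parts[0]
        events: dict = {}
        for p in parts:
            events.update(p.events)
        cat = lambda name: np.concatenate([getattr(p, name) for p in parts])
        return Trajectory(t=cat("t"), L=cat("L"), E=cat("E"), E_H=cat("E_H"),
                          E_R=cat("E_R"), params=first.params, hyp=first.hyp,
                          events=events)


def _as_fn(x) -> Callable[[float], float]:
    return x if callable(x) else (lambda t, _x=float(x): _x)


def integrate(state0: OrganismState, t_span: tuple[float, float],
              params: DEBParams, *, f=1.0, s_X=0.0, hyp: str = "none",
              T: float | None = None, t_eval: np.ndarray | None = None,
              rtol: float = 1e-7, dense_step: float | None = None,
              stop_at_event: str | None = None) -> Trajectory:
    """Integrate the state ODEs over ``t_span`` under constant temperature.

    ``f`` and ``s_X`` may be constants or callables of time.  Maturity
    threshold crossings (birth, fledging, puberty) are located by event
    detection; the integration restarts at each so the assimilation switch at
    birth is resolved sharply.  Sampled on ``t_eval`` if given, otherwise on a
    grid of step ``dense_step`` (default: ~daily) plus segment endpoints.

    Raises ``RuntimeError`` naming the time of failure if the solver fails,
    and if the reserve is exhausted before the end of the span while the
    individual is an embryo (egg too small to reach hatching).
    """
    if hyp not in HYPOTHESES:
        raise ValueError(f"unknown hypothesis {hyp!r}")
    f_fn, s_fn = _as_fn(f), _as_fn(s_X)
    rt = params.rates_at(T if T is not None else params.T_b)
    kap, E_G, E_Hb, E_Hp = params.kap, params.E_G, params.E_Hb, params.E_Hp
    kgEG = params.kap_G * E_G

    def rhs(t: float, y: np.ndarray) -> list[float]:
        L, E, E_H, E_R = y
        L = max(L, 1e-12)
        E = max(E, 0.0)
        fv = f_fn(t)
        sv = s_fn(t)
        L3 = L ** 3
        p_M_eff = rt.p_M * (1.0 + sv * fv) if hyp == "H2" else rt.p_M
        num = E * rt.v / L - p_M_eff * L3 / kap
        if kap * E * rt.v >= p_M_eff * L3 * L:
            r = num / (E + E_G * L3 / kap)
        else:
            r = num / (E + kgEG * L3 / kap)
        feeding = E_H >= E_Hb
        p_A_R = sv * fv * rt.p_Am * L * L if feeding else 0.0
        p_A = rt.p_Am * fv * L * L if feeding else 0.0
        if hyp == "H2":
            p_A += p_A_R
        p_C = E * (rt.v / L - r)
        p_J = rt.k_J * min(E_H, E_Hp)
        p_R = (1.0 - kap) * p_C - p_J
        if hyp == "H1":
            p_R += p_A_R
        dL = r * L / 3.0
        dE = p_A - p_C
        if E_H < E_Hp:
            dEH = max(p_R, 0.0)  # maturity never decreases
            dER = 0.0
        else:
            dEH = 0.0
            dER = p_R if (E_R > 0.0 or p_R > 0.0) else 0.0
        return [dL, dE, dEH, dER]

    thresholds = [("birth", params.E_Hb), ("fledging", params.E_Hx),
                  ("puberty", params.E_Hp)]
    t0, t1 = float(t_span[0]), float(t_span[1])
    y = state0.as_vector()
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite initial state")
    events_found: dict[str, float] = {}
    ts_parts, ys_parts = [], []
    if t_eval is None:
        step = dense_step if dense_step is not None else max((t1 - t0) / 200, 0.25)
        grid = np.arange(t0, t1, step)
        grid = np.append(grid[grid < t1 - 1e-9], t1)
    else:
        grid = np.asarray(t_eval, float)

    t_cur = t0
    atol = [1e-9, 1e-4, 1e-4, 1e-4]
    for _guard in range(12):
        pending = [(name, EH) for name, EH in thresholds if y[2] < EH]

        def make_event(EH_thr):
            ev = lambda t, yy: yy[2] - EH_thr
            ev.terminal = True
            ev.direction = 1.0
            return ev

        evs = [make_event(EH) for _, EH in pending]
        # reserve exhaustion guard (meaningful for embryos)
        low_E = lambda t, yy: yy[1] - max(1e-9 * state0.E, 1e-9)
        low_E.terminal = True
        low_E.direction = -1.0
        evs.append(low_E)

        seg_eval = grid[(grid >= t_cur) & (grid <= t1)]
        sol = solve_ivp(rhs, (t_cur, t1), y, method="RK45", rtol=rtol,
                        atol=atol, events=evs, t_eval=seg_eval, max_step=t1 - t0)
        if not sol.success:
            raise RuntimeError(f"ODE solver failed at t = {sol.t[-1] if sol.t.size else t_cur:.3f} d: {sol.message}")
        sol_t = np.asarray(sol.t, float)
        if sol_t.size:
            ts_parts.append(sol_t)
            ys_parts.append(np.asarray(sol.y, float).reshape(4, -1))
        if sol.status == 1:  # an event fired
            fired = [i for i, te in enumerate(sol.t_events) if te.size]
            i_ev = fired[0]
            t_ev = float(sol.t_events[i_ev][0])
            y = sol.y_events[i_ev][0].copy()
            if i_ev == len(evs) - 1:  # reserve exhausted
                if y[2] < params.E_Hb:
                    raise RuntimeError(
                        f"egg too small: reserve exhausted at t = {t_ev:.3f} d "
                        "before maturity reached the hatching threshold")
                # post-embryo reserve collapse: stop integration here
                ts_parts.append(np.array([t_ev]))
                ys_parts.append(y[:, None].copy())
                t_cur = t_ev
                break
            name, EH_thr = pending[i_ev]
            y[2] = EH_thr  # land exactly on the threshold
            events_found[name] = t_ev
            # the event state becomes a sample point
            ts_parts.append(np.array([t_ev]))
            ys_parts.append(y[:, None].copy())
            t_cur = t_ev
            if name == stop_at_event or t_cur >= t1:
                break
        else:
            t_cur = t1
            break
    else:
        raise RuntimeError("too many integration restarts")

    ts = np.concatenate(ts_parts) if ts_parts else np.array([t0])
    ys = np.concatenate(ys_parts, axis=1) if ys_parts else y[:, None]
    # ensure the final state is represented
    if ts.size == 0 or ts[-1] < t_cur - 1e-12:
        ts = np.append(ts, t_cur)
        ys = np.column_stack([ys, y])
    return Trajectory(t=ts, L=ys[0], E=ys[1], E_H=ys[2], E_R=ys[3],
                      params=params, hyp=hyp, events=events_found)
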