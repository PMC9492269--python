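"""Feeding up-regulation and the stochastic egg-release process.

Prior to and during egg-laying, hens up-regulate feeding.  The up-regulation
level ``s_X(t)`` ramps linearly from 0 at the start of the window ``t0`` to
``s_max`` at its end ``t1`` and is 0 outside the window.  Ovulation is a
Poisson point process at rate ``k_R``: intervals between laying attempts are
exponential with mean ``1/k_R`` (draws longer than 10 d are rejected and
redrawn, mirroring how such rare intervals were excluded from the weekly
reported data).  An attempt succeeds only if the reproduction buffer can pay
for the egg, ``kap_R * E_R >= E_0``; a failed attempt costs the hen a fresh
waiting interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import OrganismState
from .params import DEBParams

__all__ = [
    "UpRegulationSchedule", "LayingProcess", "EggEvent",
    "s_X_at", "extra_assimilation", "draw_interval", "attempt_lay",
    "INTERVAL_CUTOFF_D",
]

INTERVAL_CUTOFF_D = 10.0  # inter-egg intervals beyond this are redrawn


@dataclass(frozen=True)
class UpRegulationSchedule:
    """Linear feeding up-regulation ramp over the window [t0, t1].

    ``plateau_until`` optionally keeps the level at ``s_max`` beyond ``t1``
    (ramp during the preparation period, full up-regulation through laying);
    without it the level returns to 0 outside the window.
    """

    t0: float     # start of up-regulation, d
    t1: float     # end of the ramp, d
    s_max: float  # level reached at t1 (-)
    plateau_until: float | None = None

    def __post_init__(self):
        if not self.t0 < self.t1:
            raise ValueError("schedule requires t0 < t1")
        if self.s_max < 0:
            raise ValueError("s_max must be >= 0")


def s_X_at(t: float, sched: UpRegulationSchedule) -> float:
    """Up-regulation level at time t: 0 outside the window, linear ramp inside."""
    if t < sched.t0:
        return 0.0
    if t > sched.t1:
        if sched.plateau_until is not None and t <= sched.plateau_until:
            return sched.s_max
        return 0.0
    return sched.s_max * (t - sched.t0) / (sched.t1 - sched.t0)


def extra_assimilation(t: float, L: float, f: float,
                       sched: UpRegulationSchedule, params: DEBParams,
                       T: float | None = None) -> float:
    """Extra assimilation p_A_R = s_X(t) f {p_Am} L^2 (J/d), T-corrected."""
    rt = params.rates_at(T)
    return s_X_at(t, sched) * f * rt.p_Am * L * L


@dataclass
class LayingProcess:
    """Poisson egg-release clock (rate at body temperature)."""

    k_R_rate: float                 # 1/d
    next_attempt_time: float = 0.0  # d
    truncate: bool = True           # reject intervals > 10 d and redraw

    def __post_init__(self):
        if self.k_R_rate <= 0:
            raise ValueError("k_R_rate must be > 0")

    def step(self, rng: np.random.Generator) -> float:
        self.next_attempt_time += draw_interval(self.k_R_rate, rng,
                                                truncate=self.truncate)
        return self.next_attempt_time


@dataclass(frozen=True)
class EggEvent:
    """One laid egg."""

    time: float        # d
    E_0: float         # J
    egg_mass_g: float  # uncorrected wet mass, g


def draw_interval(k_R_rate: float, rng: np.random.Generator,
                  truncate: bool = True) -> float:
    """One inter-egg interval t_e ~ Exp(mean 1/k_R), optionally truncated.

    With ``truncate`` (the default), draws longer than 10 d are rejected and
    redrawn, i.e. the interval follows the exponential law conditioned on
    t_e <= 10 d.
    """
    if k_R_rate <= 0:
        raise ValueError("k_R_rate must be > 0")
    if not truncate:
        return float(rng.exponential(1.0 / k_R_rate))
    # inverse-CDF sample of the truncated exponential (exact, no reject loop)
    u = rng.random()
    return float(-math.log1p(-u * (1.0 - math.exp(-k_R_rate * INTERVAL_CUTOFF_D)))
                 / k_R_rate)


def attempt_lay(state: OrganismState, E_0: float,
                params: DEBParams) -> EggEvent | None:
    """Attempt ovulation: lay if ``kap_R * E_R >= E_0``, else return None.

    On success the buffer is debited ``E_0 / kap_R`` in place (the overhead
    ``(1/kap_R - 1) E_0`` is the cost of making the egg) and an
    :class:`EggEvent` is returned.  The caller schedules the next attempt a
    fresh exponential interval later in either case.
    """
    if E_0 <= 0:
        raise ValueError("E_0 must be > 0")
    if params.kap_R * state.E_R >= E_0:
        from .embryo import egg_wet_mass  # local import to avoid a cycle
        state.E_R -= E_0 / params.kap_R
        if state.E_R < -1e-6 * E_0:
            raise RuntimeError("laying gate violated: negative buffer after withdrawal")
        state.E_R = max(state.E_R, 0.0)
        return EggEvent(time=state.t, E_0=E_0,
                        egg_mass_g=egg_wet_mass(E_0, params))
    return None
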