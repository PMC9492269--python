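"""Embryo development, maternal-effect initial egg energy, and egg observables.

The initial energy in an egg, ``E_0``, is fixed by the maternal effect: the
reserve density of the hatchling at birth equals the reserve density of the
mother at laying, ``[E_b] = [E]``.  Because the mother's reserve density
tracks her feeding, ``E_0`` varies in time and better-fed hens lay larger
eggs.  Egg wet mass converts ``E_0`` with the reserve term of the wet-weight
formula; a multiplicative 1.08 correction adds the shell and extraembryonic
membranes, material that is never mobilised by the embryo and therefore never
enters the energy budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .core import OrganismState, Trajectory, integrate, wet_weight
from .params import DEBParams

__all__ = [
    "EggSpec", "SHELL_CORRECTION", "L_EMBRYO_INIT",
    "simulate_embryo", "initial_egg_energy", "egg_wet_mass",
    "egg_mass_to_E0", "default_egg_bounds", "EmbryoMap", "embryo_map",
]

SHELL_CORRECTION = 1.08   # shell + membranes, fraction of egg wet mass
L_EMBRYO_INIT = 1e-4      # cm; tiny initial structure avoids the L -> 0 singularity

# smallest and largest observed egg wet mass (g, shell included) used to bound
# sampled egg sizes
EGG_MASS_OBS_MIN = 8.8
EGG_MASS_OBS_MAX = 11.6


@dataclass(frozen=True)
class EggSpec:
    """One egg: initial energy, the mother's reserve density, shell fraction."""

    E_0: float                     # J
    mother_reserve_density: float  # J/cm^3
    shell_fraction: float = SHELL_CORRECTION - 1.0

    def __post_init__(self):
        if self.E_0 <= 0:
            raise ValueError("E_0 must be > 0")
        if not (0.0 <= self.shell_fraction < 1.0):
            raise ValueError("shell_fraction must be in [0, 1)")


def simulate_embryo(E_0: float, params: DEBParams, T: float | None = None,
                    rtol: float = 1e-8) -> tuple[OrganismState, float]:
    """Integrate an embryo from a near-zero structure until maturity E_Hb.

    Returns the birth state and the age at birth a_b (d).  Raises
    ``RuntimeError`` ("egg too small") if the reserve runs out first.
    """
    if E_0 <= 0:
        raise ValueError("E_0 must be > 0")
    y0 = OrganismState(t=0.0, L=L_EMBRYO_INIT, E=E_0, E_H=0.0)
    # generous horizon; birth event terminates the final segment
    traj = integrate(y0, (0.0, 2000.0), params, f=0.0, hyp="none", T=T,
                     rtol=rtol, dense_step=2000.0, stop_at_event="birth")
    if "birth" not in traj.events:
        raise RuntimeError("egg too small: maturity never reached the hatching threshold")
    a_b = traj.events["birth"]
    st = traj.final_state
    birth = OrganismState(t=a_b, L=st.L, E=st.E, E_H=params.E_Hb)
    return birth, a_b


def initial_egg_energy(mother_reserve_density: float, params: DEBParams,
                       T: float | None = None, xtol: float = 1e-3,
                       max_density_factor: float = 1.0) -> float:
    """E_0 such that the hatchling's reserve density equals the mother's.

    Solved by bracketing/bisection on ``E_0``; the hatchling density
    ``[E_b](E_0)`` is strictly increasing.  By default the mother's density
    must lie in ``(0, p_Am / v]``; a mother feeding above reference quality
    (f > 1, or an up-regulated hen) can exceed ``p_Am / v``, which callers
    admit by raising ``max_density_factor``.
    """
    cap = params.E_m * max_density_factor
    if not (0.0 < mother_reserve_density <= cap * (1 + 1e-9)):
        raise ValueError(
            f"mother reserve density must be in (0, {cap:.1f}], "
            f"got {mother_reserve_density}")

    def density_gap(E_0: float) -> float:
        birth, _ = simulate_embryo(E_0, params, T=T)
        return birth.reserve_density - mother_reserve_density

    lo, hi = 2.0 * params.E_Hb, 4.0 * params.E_Hb
    # expand until the egg is viable and brackets the target density
    for _ in range(40):
        try:
            if density_gap(lo) < 0:
                break
        except RuntimeError:
            break
        lo *= 0.7
    else:
        raise RuntimeError("failed to bracket E_0 from below")
    for _ in range(40):
        try:
            glo = density_gap(lo)
            if glo < 0:
                break
        except RuntimeError:
            pass
        lo *= 1.3
    for _ in range(60):
        if density_gap(hi) > 0:
            break
        hi *= 1.4
    else:
        raise RuntimeError("failed to bracket E_0 from above (E_Hb unreachable?)")
    return brentq(density_gap, lo, hi, xtol=xtol, rtol=1e-7)


def egg_wet_mass(E_0: float, params: DEBParams, corrected: bool = False) -> float:
    """Egg wet mass (g) from its initial energy.

    Uncorrected: the reserve-to-wet-mass conversion ``E_0 w_Ed d_Vw /
    (mu_E d_Vd)``.  Corrected: multiplied by 1.08 for shell plus membranes
    (observable only; the correction never enters the energy budget).
    """
    if E_0 < 0:
        raise ValueError("E_0 must be >= 0")
    m = E_0 * params.reserve_mass_coeff
    return m * SHELL_CORRECTION if corrected else m


def egg_mass_to_E0(mass_g: float, params: DEBParams, corrected: bool = False) -> float:
    """Invert :func:`egg_wet_mass`."""
    m = mass_g / SHELL_CORRECTION if corrected else mass_g
    return m / params.reserve_mass_coeff


def default_egg_bounds(params: DEBParams) -> tuple[float, float]:
    """(E_0_min, E_0_max) from the smallest/largest observed eggs.

    Observed egg masses include the shell, so the corrected mass is inverted.
    """
    return (egg_mass_to_E0(EGG_MASS_OBS_MIN, params, corrected=True),
            egg_mass_to_E0(EGG_MASS_OBS_MAX, params, corrected=True))


# ---------------------------------------------------------------------------
# cached embryo response maps
#
# Embryo dynamics involve no assimilation, so they are unaffected by p_Am and
# kap_X; a cohort whose hens differ only in those parameters shares one map.


class EmbryoMap:
    """Monotone interpolants of embryo outcomes as functions of E_0.

    Built from a geometric grid of egg energies; provides fast evaluation of
    hatchling reserve density, length, age and wet weight, and the inverse
    maternal-effect map density -> E_0.
    """

    def __init__(self, params: DEBParams, T: float | None = None,
                 n_grid: int = 25, span: tuple[float, float] = (2.2, 60.0)):
        self.params = params
        self.T = T
        E0s, dens, Lb, ab, Wwb = [], [], [], [], []
        for E_0 in np.geomspace(span[0] * params.E_Hb, span[1] * params.E_Hb, n_grid):
            try:
                birth, a_b = simulate_embryo(E_0, params, T=T, rtol=1e-7)
            except RuntimeError:
                continue
            d = birth.reserve_density
            # cover super-reference densities (f > 1 mothers, up-regulated hens)
            if d > params.E_m * 2.7:
                break
            E0s.append(E_0)
            dens.append(d)
            Lb.append(birth.L)
            ab.append(a_b)
            Wwb.append(wet_weight(birth, params))
        if len(E0s) < 4:
            raise RuntimeError("embryo map construction failed: too few viable eggs")
        E0s = np.array(E0s)
        dens = np.array(dens)
        keep = np.concatenate([[True], np.diff(dens) > 0])
        E0s, dens = E0s[keep], dens[keep]
        arr = lambda x: np.asarray(x)[keep]
        self._density = PchipInterpolator(E0s, dens)
        self._E0_of_density = PchipInterpolator(dens, E0s)
        self._Lb = PchipInterpolator(E0s, arr(Lb))
        self._ab = PchipInterpolator(E0s, arr(ab))
        self._Wwb = PchipInterpolator(E0s, arr(Wwb))
        self.E0_range = (float(E0s[0]), float(E0s[-1]))
        self.density_range = (float(dens[0]), float(dens[-1]))

    def birth_density(self, E_0: float) -> float:
        return float(self._density(E_0))

    def E0_for_density(self, density: float) -> float:
        lo, hi = self.density_range
        return float(self._E0_of_density(np.clip(density, lo, hi)))

    def birth_length(self, E_0: float) -> float:
        return float(self._Lb(E_0))

    def birth_age(self, E_0: float) -> float:
        return float(self._ab(E_0))

    def birth_weight(self, E_0: float) -> float:
        return float(self._Wwb(E_0))

    def birth_state(self, E_0: float) -> OrganismState:
        L = self.birth_length(E_0)
        return OrganismState(t=self.birth_age(E_0), L=L,
                             E=self.birth_density(E_0) * L ** 3,
                             E_H=self.params.E_Hb)


_MAP_CACHE: dict[tuple, EmbryoMap] = {}


def embryo_map(params: DEBParams, T: float | None = None) -> EmbryoMap:
    """Cached :class:`EmbryoMap`; keyed on the embryo-relevant parameters only,
    so hens differing in assimilation (zoom factor) share one map."""
    key = (params.v, params.p_M, params.E_G, params.kap, params.k_J,
           params.E_Hb, params.kap_G, params.T_A, params.T_ref, params.T_b,
           params.d_Vd, params.w_Ed, params.mu_E, T)
    if key not in _MAP_CACHE:
        if len(_MAP_CACHE) > 32:
            _MAP_CACHE.clear()
        _MAP_CACHE[key] = EmbryoMap(params, T=T)
    return _MAP_CACHE[key]
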