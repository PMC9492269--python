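"""Parameter sets for the bobwhite-quail DEB model.

The model follows the standard Dynamic Energy Budget (DEB) parameterisation:
an individual is described by structural length ``L`` (cm), reserve energy
``E`` (J), maturity ``E_H`` (J) and, after puberty, a reproduction buffer
``E_R`` (J).  Primary parameters (assimilation, conductance, maintenance,
growth cost, maturity thresholds) are quoted at the reference temperature
``T_ref`` = 20 degC and Arrhenius-corrected to the working temperature before
use; the quail body temperature is 38.9 degC.

Two calibrated parameter sets are shipped, one per energy-allocation
hypothesis for the extra assimilates ingested around egg-laying:

* ``H1`` -- extra assimilates are routed directly to the reproduction buffer;
* ``H2`` -- extra assimilates enter the reserve while somatic maintenance is
  inflated in proportion to the feeding up-regulation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

import yaml

__all__ = ["DEBParams", "Rates", "load_params", "preset"]


class Rates(NamedTuple):
    """Temperature-corrected rate parameters (all per day)."""

    p_Am: float  # J/d/cm^2
    v: float     # cm/d
    p_M: float   # J/d/cm^3
    k_J: float   # 1/d
    k_R: float   # 1/d


@dataclass(frozen=True)
class DEBParams:
    """Primary and auxiliary DEB parameters of one individual.

    Rate parameters ``p_Am``, ``v``, ``p_M`` and ``k_J`` are at ``T_ref``;
    ``k_R_rate`` is at body temperature ``T_b``.  Composition constants
    (``d_Vw``, ``d_Vd``, ``w_Ed``, ``mu_E``) convert energies to wet masses.
    """

    # --- primary / auxiliary parameters (calibrated) ---
    z: float            # zoom factor (-)
    p_Am: float         # max specific assimilation, J/d/cm^2 at T_ref
    kap_X: float        # digestion efficiency (-)
    v: float            # energy conductance, cm/d at T_ref
    kap: float          # allocation fraction to soma (-)
    p_M: float          # volume-specific somatic maintenance, J/d/cm^3 at T_ref
    E_G: float          # specific cost of structure, J/cm^3
    E_Hb: float         # maturity at birth (hatch), J
    E_Hx: float         # maturity at fledging, J
    E_Hp: float         # maturity at puberty, J
    del_M: float        # shape coefficient, total length (-)
    del_Me: float       # shape coefficient, embryo (-)
    del_Mt: float       # shape coefficient, tarsus (-)
    f_ref: float        # scaled functional response for zero-variate data (-)
    f_NB: float         # f for one juvenile growth dataset (-)
    f_B: float          # f for the control-study juvenile dataset (-)
    f_JH: float         # f for one juvenile growth dataset (-)
    f_L: float          # f for one juvenile growth dataset (-)
    f_mf: float         # f for adults during the experiment (-)
    E_sperm: float      # energy in sperm, males, J
    k_R_rate: float     # egg-laying rate, 1/d at T_b
    s_max: float        # max feeding up-regulation (-)
    # --- standard DEB constants the calibration leaves unprinted ---
    k_J: float = 0.002        # maturity maintenance rate, 1/d at T_ref
    kap_R: float = 0.95       # reproduction efficiency (-)
    kap_G: float = 0.80       # fraction of structure energy recovered on shrinking (-)
    T_A: float = 8000.0       # Arrhenius temperature, K
    T_ref: float = 293.15     # reference temperature, K (20 degC)
    T_b: float = 312.05       # body temperature, K (38.9 degC)
    d_Vw: float = 1.0         # specific density of wet structure, g/cm^3
    d_Vd: float = 0.3         # specific density of dry structure, g/cm^3
    w_Ed: float = 23.9        # molar weight of dry reserve, g/mol
    mu_E: float = 550000.0    # chemical potential of reserve, J/mol

    def __post_init__(self) -> None:
        if not (0.0 < self.kap < 1.0):
            raise ValueError(f"kap must be in (0,1), got {self.kap}")
        if not (0.0 < self.kap_X < 1.0):
            raise ValueError(f"kap_X must be in (0,1), got {self.kap_X}")
        if not (0.0 < self.kap_R <= 1.0):
            raise ValueError(f"kap_R must be in (0,1], got {self.kap_R}")
        if not (0.0 < self.kap_G < 1.0):
            raise ValueError(f"kap_G must be in (0,1), got {self.kap_G}")
        if not (self.E_Hb < self.E_Hx < self.E_Hp):
            raise ValueError("maturity thresholds must satisfy E_Hb < E_Hx < E_Hp")
        for name in ("p_Am", "v", "p_M", "E_G", "k_J", "k_R_rate",
                     "d_Vw", "d_Vd", "w_Ed", "mu_E", "T_A", "T_ref", "T_b",
                     "del_M", "del_Me", "del_Mt", "z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.s_max < 0:
            raise ValueError("s_max must be >= 0")

    # --- derived quantities -------------------------------------------------
    @property
    def E_m(self) -> float:
        """Maximum reserve density [E_m] = p_Am / v (J/cm^3); T-invariant."""
        return self.p_Am / self.v

    def L_inf(self, f: float = 1.0, p_M_eff: float | None = None) -> float:
        """Ultimate structural length f * kap * p_Am / p_M (cm); T-invariant."""
        p_M = self.p_M if p_M_eff is None else p_M_eff
        return f * self.kap * self.p_Am / p_M

    @property
    def reserve_mass_coeff(self) -> float:
        """Grams of wet mass per joule of reserve: w_Ed * d_Vw / (mu_E * d_Vd)."""
        return self.w_Ed * self.d_Vw / (self.mu_E * self.d_Vd)

    @property
    def buffer_mass_coeff(self) -> float:
        """Grams of wet mass per joule of reproduction buffer (water-free)."""
        return self.w_Ed * self.d_Vw / self.mu_E

    # --- temperature --------------------------------------------------------
    def temp_factor(self, T: float, T_from: float | None = None) -> float:
        """Arrhenius correction factor from ``T_from`` (default T_ref) to T."""
        T0 = self.T_ref if T_from is None else T_from
        if not (math.isfinite(T) and T > 0):
            raise ValueError(f"temperature must be finite and > 0, got {T}")
        return math.exp(self.T_A / T0 - self.T_A / T)

    def rates_at(self, T: float | None = None) -> Rates:
        """All rate parameters corrected to temperature ``T`` (default T_b).

        ``k_R_rate`` is quoted at body temperature and is corrected from T_b.
        """
        if T is None:
            T = self.T_b
        c = self.temp_factor(T)
        c_b = self.temp_factor(T, T_from=self.T_b)
        return Rates(p_Am=self.p_Am * c, v=self.v * c, p_M=self.p_M * c,
                     k_J=self.k_J * c, k_R=self.k_R_rate * c_b)

    # --- convenience --------------------------------------------------------
    def replace(self, **kwargs) -> "DEBParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DEBParams":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_params(path) -> DEBParams:
    """Load a flat key-value YAML parameter file."""
    with open(path) as fh:
        return DEBParams.from_dict(yaml.safe_load(fh))


def preset(name: str) -> DEBParams:
    """Return a shipped calibrated parameter set, ``"H1"`` or ``"H2"``."""
    name = name.upper()
    if name not in ("H1", "H2"):
        raise ValueError(f"unknown preset {name!r}; expected 'H1' or 'H2'")
    ref = resources.files("quaildeb.data").joinpath(f"params_{name}.yaml")
    with ref.open() as fh:
        return DEBParams.from_dict(yaml.safe_load(fh))
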