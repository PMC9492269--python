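import numpy as np
import pytest

from quaildeb import preset


@pytest.fixture(scope="session")
def h1():
    return preset("H1")


@pytest.fixture(scope="session")
def h2():
    return preset("H2")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def euler_integrate(state0, t_span, params, f, hyp, T, h=1e-3, s_X=0.0):
    """Independent fixed-step explicit-Euler oracle for the state ODEs."""
    rt = params.rates_at(T)
    L, E, E_H, E_R = state0.L, state0.E, state0.E_H, state0.E_R
    kap, E_G = params.kap, params.E_G
    t = t_span[0]
    n = int(round((t_span[1] - t_span[0]) / h))
    for _ in range(n):
        L3 = L ** 3
        p_M_eff = rt.p_M * (1.0 + s_X * f) if hyp == "H2" else rt.p_M
        num = E * rt.v / L - p_M_eff * L3 / kap
        if kap * E * rt.v >= p_M_eff * L3 * L:
            r = num / (E + E_G * L3 / kap)
        else:
            r = num / (E + params.kap_G * E_G * L3 / kap)
        feeding = E_H >= params.E_Hb
        p_A = rt.p_Am * f * L * L if feeding else 0.0
        if hyp == "H2" and feeding:
            p_A *= (1.0 + s_X)
        p_C = E * (rt.v / L - r)
        p_J = rt.k_J * min(E_H, params.E_Hp)
        p_R = (1.0 - kap) * p_C - p_J
        if hyp == "H1" and feeding:
            p_R += s_X * f * rt.p_Am * L * L
        L += h * r * L / 3.0
        E += h * (p_A - p_C)
        if E_H < params.E_Hp:
            E_H += h * max(p_R, 0.0)
        else:
            E_R += h * p_R
        t += h
    from quaildeb import OrganismState
    return OrganismState(t=t, L=L, E=E, E_H=E_H, E_R=E_R)
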