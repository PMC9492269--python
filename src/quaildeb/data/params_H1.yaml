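# Calibrated DEB parameters, bobwhite quail, energy-allocation hypothesis H1
# (extra assimilates routed directly to the reproduction buffer).
# Rates at T_ref = 20 degC unless noted; k_R_rate at body temperature 38.9 degC.
z: 2.62
p_Am: 1257.0
kap_X: 0.47
v: 0.0190
kap: 0.49
p_M: 233.2
E_G: 7320.0
E_Hb: 1.077e+4
E_Hx: 1.001e+6
E_Hp: 1.002e+6
del_M: 0.101
del_Me: 0.279
del_Mt: 0.5782
f_ref: 1.0
f_NB: 1.651
f_B: 2.125
f_JH: 1.888
f_L: 2.134
f_mf: 0.933
E_sperm: 1.134e+4
k_R_rate: 0.717
s_max: 1.434
# standard DEB constants not part of the calibration
k_J: 0.002
kap_R: 0.95
kap_G: 0.80
T_A: 8000.0
T_ref: 293.15
T_b: 312.05
d_Vw: 1.0
d_Vd: 0.3
w_Ed: 23.9
mu_E: 550000.0
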