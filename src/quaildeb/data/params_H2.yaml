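# Calibrated DEB parameters, bobwhite quail, energy-allocation hypothesis H2
# (extra assimilates enter the reserve; somatic maintenance inflated by up-regulation).
# Rates at T_ref = 20 degC unless noted; k_R_rate at body temperature 38.9 degC.
z: 2.60
p_Am: 1339.0
kap_X: 0.46
v: 0.0193
kap: 0.39
p_M: 203.7
E_G: 7332.0
E_Hb: 0.925e+4
E_Hx: 1.258e+6
E_Hp: 1.279e+6
del_M: 0.109
del_Me: 0.280
del_Mt: 0.544
f_ref: 1.0
f_NB: 1.651
f_B: 2.434
f_JH: 1.943
f_L: 2.134
f_mf: 0.931
E_sperm: 1.667e+4
k_R_rate: 0.728
s_max: 0.987
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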