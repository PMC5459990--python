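g_max_F = 0.35
h_F = 900.0
g_max_T = 0.45
h_T = 500.0
g_max_G = 0.5
h_G = 600.0
m0_F = 0.05
md_F = 0.4
P_crit_F = 900.0
m0_T = 0.15
md_T = 0.4
P_crit_T = 400.0
m_S = 0.05
k_m = 0.01
m_B0 = 0.3
P_crit_B = 700.0
k_B = 0.01
q0 = 0.1
d = 0.9
b = 0.9
I = 5.0
k_f = 20.0
C0 = 0.59
s_C = 0.0001
C_lo = 0.4
C_hi = 0.8
P_ref = 1700.0
M_ref = 0.5
D = 0.1
r0 = 0.3
lambda_r = 0.4
sigma = 0.04
dt = 1.0
dx = 1.0
fire_event_threshold = 0.5
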