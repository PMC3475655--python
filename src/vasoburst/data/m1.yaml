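# Parameter set m1: model fitted to in-vivo cell v1.
I_re: 600.0
I_ratio: 1.0
e_h: 2.0
i_h: -2.0
lambda_syn: 7.5
k_HAP: 60.0
lambda_HAP: 8.0
k_DAP: 0.0
lambda_DAP: 150.0
k_AHP: 0.00012
lambda_AHP: 10000.0
C_AHP: 200.0
C_rest: 113.0
k_C: 10.0
lambda_C: 2500.0
k_D: 1.68
lambda_D: 10000.0
k_L: 36.0
g_L: 8.5
V_rest: -56.0
V_thresh: -50.0
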