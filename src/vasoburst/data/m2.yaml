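# Parameter set m2: model fitted to in-vivo cell v2 (overrides on the v1 base).
I_re: 1050.0
lambda_HAP: 10.5
k_DAP: 1.15
k_AHP: 0.00017
k_C: 11.8
k_D: 2.79
lambda_D: 7500.0
g_L: 8.0
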