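# Parameter set m3: model fitted to in-vivo cell v3 (overrides on the v1 base).
I_re: 920.0
lambda_HAP: 9.5
k_DAP: 1.20
k_AHP: 0.00005
k_C: 12.0
k_D: 3.10
lambda_D: 7500.0
g_L: 8.0
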