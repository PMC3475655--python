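# Parameter set m5: model fitted to in-vivo cell v5 (overrides on the v1 base).
I_re: 530.0
lambda_HAP: 8.5
k_DAP: 0.90
k_AHP: 0.00004
k_C: 12.0
k_D: 2.15
lambda_D: 10000.0
g_L: 8.5
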