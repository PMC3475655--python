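# Parameter set m4: model fitted to in-vivo cell v4 (overrides on the v1 base).
I_re: 630.0
lambda_HAP: 10.5
k_DAP: 1.00
k_AHP: 0.00013
k_C: 12.0
k_D: 1.95
lambda_D: 10000.0
g_L: 10.5
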