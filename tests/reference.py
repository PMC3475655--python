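"""Independent, naive transcription of the one-step update rule.

Written directly from the model definition as plain Python, deliberately
separate from the production stepper, to serve as an oracle for
step-equivalence tests.
"""

import math


def reference_step(state, params, psp_input, forced_spike=False, store=None,
                   t=0.0):
    """One 1-ms update. ``state`` and the return value are dicts keyed by
    V_syn, HAP, DAP, AHP, C, D, T, D_store, t_last_spike."""
    s = dict(state)

    def decay(value, half_life):
        return value * math.exp(-math.log(2.0) / half_life)

    # 1. decay
    s["V_syn"] = decay(s["V_syn"], params.lambda_syn)
    s["HAP"] = decay(s["HAP"], params.lambda_HAP)
    s["DAP"] = decay(s["DAP"], params.lambda_DAP)
    s["AHP"] = decay(s["AHP"], params.lambda_AHP)
    s["C"] = params.C_rest + decay(s["C"] - params.C_rest, params.lambda_C)
    s["D"] = decay(s["D"], params.lambda_D)
    if store is not None:
        s["T"] = decay(s["T"], store.lambda_T)
        s["D_store"] = decay(s["D_store"], store.lambda_Dstore)
        if s["D_store"] < store.D_storecap:
            s["D_store"] = min(s["D_store"] + store.k_Dstore * s["T"],
                               store.D_storecap)
    # 2. input
    s["V_syn"] += psp_input
    # 3. membrane potential
    x = (s["C"] - params.C_rest - s["D"]) / params.k_L
    V_L = -params.g_L * (1.0 - math.tanh(x))
    V = params.V_rest + s["V_syn"] + s["HAP"] + s["DAP"] + s["AHP"] + V_L
    # 4. threshold / forced spike
    spiked = forced_spike or (
        V > params.V_thresh
        and (t - s["t_last_spike"]) >= params.refractory_ms)
    # 5. increments
    if spiked:
        s["C"] += params.k_C
        if s["C"] > params.C_AHP:
            s["AHP"] -= params.k_AHP * (s["C"] - params.C_AHP)
        s["HAP"] -= params.k_HAP
        s["DAP"] += params.k_DAP
        if store is None:
            s["D"] += params.k_D
        else:
            s["T"] += store.k_T
            if s["D_store"] > store.D_spike:
                s["D"] += params.k_D
                s["D_store"] -= store.D_spike
        s["t_last_spike"] = t
    return s, spiked
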