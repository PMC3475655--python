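# vasoburst

Integrate-and-fire simulation of **phasic bursting in magnocellular
vasopressin neurons**, with the spike-train statistics and population
protocols used to study how phasic cells encode osmotic input.

Vasopressin neurons respond to rising osmotic pressure by switching from
slow irregular firing to a *phasic* pattern — bursts and silences lasting
tens of seconds — generated intrinsically in each cell and asynchronous
across the population. `vasoburst` is for computational neuroendocrinologists
and systems physiologists who want a quantitatively realistic, cheap-to-run
single-cell model of this behaviour, and for anyone analysing spike trains
with the associated burst/ISI/hazard toolkit.

## The model

Each 1-ms step, PSP counts are drawn from twin Poisson processes
(EPSP rate *I*<sub>re</sub>, IPSP rate *I*<sub>ratio</sub>·*I*<sub>re</sub>,
fixed amplitudes *e*<sub>h</sub> = 2 mV, *i*<sub>h</sub> = −2 mV) and summed
into a decaying synaptic component *V*<sub>syn</sub>. The membrane potential
is a plain sum

&nbsp;&nbsp;&nbsp;&nbsp;*V* = *V*<sub>rest</sub> + *V*<sub>syn</sub> + HAP + DAP + AHP + *V*<sub>L</sub>

of exponentially decaying spike-triggered potentials: a fast hyperpolarising
afterpotential (HAP), an optional fast depolarising afterpotential (DAP),
and a slow calcium-gated afterhyperpolarisation (AHP, incremented by
*k*<sub>AHP</sub>·max(0, *C* − *C*<sub>AHP</sub>)). A spike fires when *V*
crosses *V*<sub>thresh</sub>, outside a 3-ms absolute refractory period.
Every half-life parameter λ maps to its time constant via τ = λ/ln 2, and
decay is applied as the exact per-step multiplier 2<sup>−dt/λ</sup>.

Bursting emerges from a K⁺ **leak current** whose sigmoidal activation
balances intracellular calcium *C* (raised *k*<sub>C</sub> per spike)
against dendritically released dynorphin *D* (raised *k*<sub>D</sub> per
spike, decaying ~10× slower):

&nbsp;&nbsp;&nbsp;&nbsp;*L* = 1 − tanh((*C* − *C*<sub>rest</sub> − *D*)/*k*<sub>L</sub>),&nbsp;&nbsp;*V*<sub>L</sub> = −*g*<sub>L</sub>·*L*

Calcium suppresses the hyperpolarising leak (a slow DAP, sustaining a burst
plateau through positive feedback); slowly accumulating dynorphin restores
it, collapsing the plateau and holding a hyperpolarised silence until *D*
decays — emergent bistability with no explicit switching variable.
Extensions: a readily-releasable dynorphin store replenished by a slow
activity signal (reproducing the delayed onset of phasic firing after
hypertonic injection), and a linear osmotic-pressure-to-input-rate map
*I*<sub>re</sub> = 20·(*O* − 280).

Five fitted parameter sets (`m1`–`m5`, each matched to an in-vivo recorded
cell) ship as YAML fixtures, together with the published cell-heterogeneity
table used for population experiments.

## Worked example

```bash
vasoburst simulate --params m1 --duration-s 3000 --seed 1 --out demo
cat demo/summary.csv
```

```
Intra(Hz),Burst Mean(s),Burst SD,Silence Mean(s),Silence SD,n_bursts
7.940944225575148,83.35079999999999,39.88328985928819,38.06670833333333,4.61647700704739,25
```

The cell fired 16537 spikes (5.51 spikes/s overall) in 25 bursts: an
intra-burst rate of 7.94 spikes/s, bursts averaging 83 s and silences 38 s —
the phasic regime of the supraoptic cell this parameter set was fitted to
(published fit: 7.90 Hz, 85 s, 38 s). The same library calls are available
in Python:

```python
import vasoburst as vb

params = vb.load_params("m1")
res = vb.simulate(params, 3_000_000, seed=1)          # 3000 s at 1-ms steps
bursts = vb.detect_bursts(res.train)                  # >25 spikes, no ISI >1.5 s
print(vb.burst_summary(bursts))

edges, counts = vb.isi_histogram(res.train, bin_ms=10, max_ms=500)
amp, decay, r2 = vb.fit_isi_tail(edges, counts, t_min_ms=150)
print(decay, r2)   # 0.0109 /ms, r² = 0.97: late spiking is Poisson-random
```

The exponential ISI tail (decay 0.0109/ms, r² 0.97) mirrors the in-vivo
observation that beyond ~150 ms after a spike, firing is driven by random
synaptic input. Other entry points: `simulate_population` /
`pulse_experiment` for asynchronous 100-cell populations and their
linearised rate coding, `antidromic_schedule` + `forced_ms` for burst
triggering/termination by evoked spikes, `norbni_experiment` for the
dynorphin-antagonist simulation, and `hypertonic_experiment` for the
osmotic-challenge protocol with the dynorphin-store extension.

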