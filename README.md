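# acmodes

Normal-mode analysis of an adapting auditory-cortex network: simulation of
MEG event-related fields (ERFs), short-term synaptic depression, and
adaptation-lifetime statistics.

## The problem

Repeating a sound attenuates the auditory evoked response — most visibly
the N1m deflection of the MEG — and the response recovers as the stimulus
onset interval (SOI) grows. `acmodes` implements a compact dynamical model
of this phenomenon for computational neuroscientists who want to study how
short-term synaptic depression (STSD), anatomical structure, and the
excitation–inhibition balance jointly shape ERF adaptation.

The model comprises five serially connected areas — inferior colliculus
(IC), thalamus, and the cortical core, belt and parabelt — each holding one
excitatory and one inhibitory mean-field population with state variables
u(t), v(t):

    τ_m u̇ = −u + W_ee Q g[u] − W_ei g[v] + i_aff(t)
    τ_m v̇ = −v + W_ie g[u] − W_ii g[v]
    q̇    = −q g[u]/τ_o + (1 − q)/τ_rec,     Q = diag(q)

with firing rate g[x] = tanh(αx) (or its linearisation αx) and synaptic
efficacy q depressed by transmitter release (τ_o) and replenished slowly
(τ_rec). Stimuli are afferent delta impulses at the IC.

With linear rates and piecewise-constant efficacy, the dynamics are linear,
d/dt (u;v) = M(Q)(u;v), and solve as a superposition of **normal modes**:
eigenvectors of M evolving as exp(λ_n t) with λ_n = γ_n + iω_n — damped
oscillators spread over the whole network. A slow–fast scheme (release is
much faster than replenishment) updates q stimulus-by-stimulus in closed
form, so an entire adaptation experiment reduces to one eigendecomposition
per stimulus. The simulated MEG signal weights every synaptic input by its
connection type (feedforward/feedback/lateral/inhibitory) through topology
matrices K1, K2 and sums over the cortex; it can be decomposed exactly into
per-mode or per-connection contributions. Peak amplitudes as a function of
SOI are summarised by the saturating exponential
P(SOI) = A(1 − exp(−(SOI − t0)/τ_soi)), whose time constant τ_soi is the
adaptation lifetime.

## Worked example

```python
import acmodes as m

params = m.ModelParameters()                      # published defaults
top = m.build_default_network(params)             # IC-thalamus-core-belt-parabelt

for soi in (0.5, 1.0, 2.5, 5.0, 10.0):
    train = m.StimulusTrain(soi=soi, n_stimuli=111)
    adapt = m.run_stimulus_train(top, params, train)
    wave = m.adapted_state_waveform(top, adapt)   # adapted-state ERF
    n1m = m.extract_peaks(wave).require("N1m")
    q = adapt.q[adapt.adapted]
    print(f"SOI {soi:4} s: N1m {n1m.magnitude:.3f} at {1e3*n1m.latency:5.1f} ms"
          f"   q = {q[2]:.3f}/{q[3]:.3f}/{q[4]:.3f} (core/belt/parabelt)")
```

prints

```
SOI  0.5 s: N1m 0.280 at  60.5 ms   q = 0.646/0.879/0.955 (core/belt/parabelt)
SOI  1.0 s: N1m 0.363 at  63.1 ms   q = 0.763/0.911/0.966 (core/belt/parabelt)
SOI  2.5 s: N1m 0.489 at  66.7 ms   q = 0.883/0.950/0.980 (core/belt/parabelt)
SOI  5.0 s: N1m 0.584 at  69.1 ms   q = 0.945/0.975/0.990 (core/belt/parabelt)
SOI 10.0 s: N1m 0.657 at  70.8 ms   q = 0.983/0.992/0.997 (core/belt/parabelt)
```

The N1m peak (model units; latencies in model time, ~30 ms ahead of sensor
time) grows and arrives later as the SOI increases, while the steady-state
synaptic efficacies q recover towards one — the classic recovery from
repetition suppression. Fitting the recovery model per signal:

```python
report = m.adaptation_lifetime_report(["DEF"], params)
print(report[["signal", "A", "t0_s", "tau_soi_s"]].round(3).to_string(index=False))
```

```
  signal     A   t0_s  tau_soi_s
     ERF 0.662 -1.016      2.655
    core 0.482 -1.183      2.558
    belt 0.205 -0.597      2.745
parabelt 0.036 -0.557      2.673
```

i.e. the ERF recovers with a lifetime of about 2.7 s, and the core's
contribution recovers some 200 ms faster than the belt's, although the STSD
time constants are identical everywhere — adaptation lifetime is a network
property, not a synaptic one.

A command-line interface exposes the same pipeline
(`acmodes simulate|spectrum|erf|fit|report|saturation|fixture|validate|trajectory`),
e.g.

```
acmodes report --variants DEF,TB,TBN --out results/
acmodes saturation --grid 0.2:20:99 --out results/
```

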