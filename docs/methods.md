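# Methods

## Model

The network is a five-area chain — IC, thalamus, core, belt, parabelt —
with one excitatory and one inhibitory mean-field population per area
(state variables u_i, v_i) and a synaptic-efficacy variable q_i per area
governing short-term synaptic depression (STSD) of the area's *outgoing*
excitatory synapses:

    τ_m u̇ = −u + W_ee Q g[u] − W_ei g[v] + i_aff(t)
    τ_m v̇ = −v + W_ie g[u] − W_ii g[v]
    q̇    = −q g[u]/τ_o + (1 − q)/τ_rec,        Q = diag(q)

Only excitatory-to-excitatory connections run between areas; W_ee is
tridiagonal in the serial (DEF) network (feedforward on the subdiagonal,
feedback on the superdiagonal, lateral on the diagonal) and the other three
weight matrices are scalar multiples of the identity. Matrix orientation is
row = receiver, column = sender, so Q scales columns (the efficacy of the
*pre*-synaptic population). IC and thalamus have much faster subcortical
recovery dynamics than cortex and are treated as non-adapting: their q is
pinned at 1.

Default parameters (dimensionless weights; time constants in seconds):

| parameter | value | meaning |
|---|---|---|
| w_ee_d / w_ee_ff / w_ee_fb | 2 / 0.5 / 0.4 | lateral / feedforward / feedback e→e weight |
| w_ie_d / w_ei_d / w_ii_d | 3.5 / 2.2 / 2.5 | local e→i / i→e / i→i weights |
| τ_m | 0.03 | membrane time constant |
| τ_o / τ_rec | 0.04 / 5 | transmitter release / replenishment |
| a | 0.02 | afferent impulse strength at the IC |
| α | 1 | firing-rate gain |
| k1_d / k1_ff / k1_fb | −1 / −1 / 15 | MEG multipliers of e→e inputs |
| k2_d | 2 | MEG multiplier of i→e inputs |

With these values every isolated column is a damped oscillator; the
network's coefficient matrix is stable.

Stimuli are periodic delta impulses at the IC's excitatory population
(onsets t_s = s·SOI). Integrating across the impulse gives an
instantaneous jump u_IC ← u_IC + a/τ_m; between onsets the input is zero.
Only equal-SOI trains are modelled; the sustained-response regime below
SOI ≈ 0.5 s is out of scope and merely triggers a warning, because the
slow-fast scheme assumes the state variables decay to zero between
stimuli.

## Normal modes

With linear firing rates (g[x] = αx) and a fixed efficacy vector q, the
homogeneous (u, v) dynamics are d/dt(u;v) = M(u;v) with

    M = (1/τ_m) [[αW_ee Q − I, −αW_ei], [αW_ie, −αW_ii − I]].

`spectral_decomposition` returns eigenvalues λ_n = γ_n + iω_n, unit-norm
right eigenvectors, and left eigenvectors taken as the rows of the inverse
of the right-eigenvector matrix, so the left/right system is biorthonormal
by construction (checked to 1e−10). Mode coefficients are bilinear
projections c = L·(u0;v0) (no conjugation), which makes the superposition
Σ c_n exp(λ_n t)(x_n;y_n) reproduce the initial state exactly and gives
conjugate coefficients on conjugate mode pairs for real states. Modes are
sorted by |ω| ascending (ties: γ descending) so conjugate partners are
adjacent; modes with |ω| < 1e−8 rad/s are classified overdamped and handled
with real arithmetic. A defective matrix (eigenvector condition number
above 1e10) raises rather than being silently regularised. Mode identity
across efficacy states is tracked greedily by maximal right-eigenvector
overlap.

The eigenvector normalisation is a convention: all physical observables
(eigenvalues, reconstructed trajectories, the per-mode product
|c_n|·|κ_n|) are invariant under per-mode rescaling, but |c_n| (input
efficiency) and κ_n (MEG efficiency) individually are not. Exported
per-mode efficiencies must therefore be compared only within one
convention; the invariance of the product is asserted in the tests.

## Slow-fast adaptation

Since τ_o ≪ τ_rec, transmitter release and replenishment separate: the
efficacy is held piecewise constant (Q = Q_s) within each inter-stimulus
interval, and at each onset it is updated in two sequenced steps — a fast
drop-off obtained by integrating the release term over the interval's
normal-mode trajectory, which has the closed form

    F_s(q_s) = q_s · exp( −(α/τ_o) Σ_n c_{n,s} x_{n,s} (e^{λ_{n,s}Δ} − 1)/λ_{n,s} ),

followed by exponential recovery towards one over the full interval,
q_{s+1} = 1 − (1 − F_s(q_s)) e^{−Δ/τ_rec}. Eigenvalues with |λ|Δ < 1e−12
use the limit (e^{λΔ}−1)/λ → Δ. Release and recovery each span the whole
interval; no overlap correction is applied. Each interval restarts from
the jump state (u, v assumed decayed), and the spectrum is recomputed from
M(Q_s) per stimulus, so an adaptation run is one 10×10 eigendecomposition
per stimulus. The default train is 111 stimuli (the repetition count of
the experimental paradigm the model addresses) with an early stop once
consecutive efficacies agree to 1e−6; the last recorded stimulus is the
adapted state. The closed-form drop-off is verified in the tests against
adaptive quadrature of the release integral on the numerically integrated
trajectory.

Known accuracy limits, quantified by `validate_against_full_model`
(SOI 0.5 s, Table defaults): against the full *linear* model, per-stimulus
peak discrepancies fall below 7% from the second stimulus on, but reach
16% (belt) and 22% (parabelt) on the first response, which the scheme by
construction computes at q = 1 while the true efficacy already falls
within the interval. Against the *tanh* model there is a persistent
9–13% offset, because the afferent jump a/τ_m ≈ 0.67 lies outside the
firing rate's linear range (tanh(0.67)/0.67 ≈ 0.87). These are properties
of the approximation, not of the implementation: with frozen efficacy the
integrator and the spectral solution agree to 1e−10, and the integrator
itself runs adaptive Runge–Kutta piecewise between onsets at rtol 1e−9,
restarting at each jump.

## MEG forward model

The simulated MEG signal sums each cortical area's synaptic input,
weighted by connection type:

    R(t) = Σ_j [ B (u;v) ]_j,    B = [[K1 ∘ W_ee Q, 0], [0, K2 ∘ W_ei]].

K1/K2 encode the physiology of primary currents: feedforward and lateral
excitatory inputs (and i→e inputs) drive currents away from the cortical
surface, feedback inputs toward it; subcortical areas contribute nothing,
but the thalamus→core synapse terminates in cortex and does contribute.
Because the MEG reflects the synaptic input actually delivered, the
depressed weights W_ee·Q enter B by default (`meg_weights="depressed"`);
the undepressed alternative (`"static"`) is retained as an option and
coincides with the default in the unadapted state. The depressed choice is
also what reproduces the anatomical-decomposition phenomenology (a stable
core impact alongside a three-fold belt/parabelt growth over the SOI
range).

Substituting the mode superposition gives R(t) = Σ_n c_n κ_n e^{λ_n t}
with MEG efficiency κ_n = Σ_j [B(x_n;y_n)]_j; a conjugate pair contributes
2Re(c_n κ_n e^{λ_n t}). Alternatively the summands of R are grouped by
receiving area (the source-modelling view), by sending area (each area's
impact), or by connection class; both decompositions sum to R(t) exactly
(asserted to 1e−9 relative). A 30-ms display shift standing in for
subcortical conduction delay is applied to exported timestamps only,
never to analysis.

## ERF landmarks

Landmarks are identified structurally, not by sign: the N1m is the largest
absolute deflection in its window; its polarity then defines the P1m and
P2m as the largest opposite-polarity deflections in theirs. Default
windows, in model time (which runs ~30 ms ahead of sensor time):
P1m (0, 40] ms, N1m (40, 200] ms, P2m (100, 350] ms after the N1m; all are
configurable. With the defaults the simulated P1m sits near 18 ms
(≈ 48 ms sensor time) and the N1m near 60–72 ms (≈ 90–100 ms sensor time).
A missing landmark is reported as an explicit None, never a silent zero.
Extrema are refined to sub-sample precision with a three-point parabolic
fit; without it, grid quantisation of the peaks leaks visible steps into
the finite-difference saturation statistics.

## Network variants

CP adds a direct core→parabelt connection and TB a direct thalamus→belt
connection, each a single feedforward entry at the generic serial weight
w_ee_ff = 0.5 (reciprocal feedback entries at w_ee_fb are available via a
switch, and both weights can be overridden). The added entry receives the
MEG multiplier of its connection type when it terminates in cortex. The
normalised variants CPN/TBN rescale W_ee uniformly so its element sum
matches the DEF network's (13.6), restoring the excitation–inhibition
balance. The single-feedforward default was chosen because it is the
minimal structural change and yields an added-excitation effect on the
adaptation lifetime of ~0.6 s, in the range the full analysis reports;
bidirectional additions roughly double the effect.

## Adaptation-lifetime statistics

Peak amplitude versus SOI is fitted with P(SOI) = A(1 − e^{−(SOI−t0)/τ_soi});
all three parameters are free. The fit is trust-region nonlinear least
squares (tolerances 1e−12) initialised by an integral-equation
linearisation: cumulative trapezoidal integrals of the data give the rate
c of y = a + b e^{cx} by linear regression, then a and b follow from a
second linear regression; the mapping A = a, τ = −1/c, t0 = τ·log(−b/a)
seeds the nonlinear step. Non-convergence returns a flagged result
carrying the initialiser's estimate. The default SOI design is
{0.5, 1, 2.5, 5, 10} s with 111 stimuli per condition, matching the
experimental blocks.

Per the lifetime report, the ERF signal is the N1m peak magnitude of the
adapted state. The per-area signal is, by default, the N1m-window peak of
the area's *incoming ERF contribution* — what source modelling would
attribute to that area. Fitting the raw per-area u(t) peaks instead
(`area_signal="state"`) yields a core intercept near −1.9 s and makes the
parabelt the slowest-recovering area; the contribution measure yields
intercepts in [−1.2, −0.6] s, a belt-minus-core lifetime differential of
~0.2 s, and near-equal belt/parabelt lifetimes in the serial network —
the pattern the per-area analysis is meant to capture. Both measures are
exposed.

The local saturation rate
f_j = (F_j − F_{j+1}) / ((F_j − F_∞)(SOI_{j+1} − SOI_j)) is an exact-
exponential diagnostic: on exponential data it is the constant
(1 − e^{−Δ/τ})/Δ (which approaches 1/τ only as the grid spacing Δ → 0).
F_∞ is the initial-state (unadapted) N1m peak, the ceiling of the
simulated amplitudes. Pairs with F_j = F_∞ are dropped with a warning. The
dense-grid experiment uses 99 evenly spaced SOIs from 0.2 to 20 s — a
two-decade span whose upper half sits well past the recovery knee — with
no early stop and 0.25-ms waveform sampling, because f_j at large SOI is a
ratio of near-vanishing differences and inherits any quantisation of the
adapted state. On this design f_j decreases monotonically and settles near
0.2 s⁻¹, about two thirds of the 1/τ_soi ≈ 0.32 s⁻¹ the single-exponential
fit would imply, and the fit's residuals are systematically positive at
small SOI — the single exponential is a serviceable summary but not the
true recovery law.

## Synthetic fixtures

`make_fixture` generates the two synthetic datasets the statistics layer
is tested against: exact (optionally multiplicatively noisy) samples of
the saturating-exponential recovery model, and sums of damped cosines with
known extrema for the peak extractor. They emulate the *shapes* the
pipeline consumes — they carry no network structure, no mode interference
and no adaptation dynamics — so tests passing on them validate the
fitting and extraction machinery, not the biophysics. Noise is Gaussian,
multiplicative, and seeded; the same seed reproduces the same file. At the
5-point SOI design with 2% noise, the recovery fit's τ estimate scatters
with ≈10% mean relative error — parameter recovery at this design is
validated in aggregate, not per replicate.

## Problem sizes and runtime

The network is 5 areas (10-dimensional linear system); every experiment
reduces to at most 111 eigendecompositions of a 10×10 matrix per SOI
condition. The full variant sweep (5 networks × 5 SOIs) runs in under a
second; the dense 99-SOI saturation experiment in ~10 s; the complete test
suite, including the full nonlinear reference integrations, in well under
a minute on one CPU.

## Known limitations

- The slow-fast scheme cannot represent within-interval depression of the
  very first response; accuracy at the top of the hierarchy is ~20% there.
- The linearised pipeline carries a systematic ~10% amplitude offset
  relative to the tanh model at the default input strength.
- Sub-0.5-s SOIs violate the between-stimulus decay assumption (warning
  only); oddball/non-periodic trains, tonotopy, conduction delays and
  realistic head models are out of scope.
- Cortical efficacies are not strictly monotone under a train: downstream
  areas rebound by ~2×10⁻⁴ as the core's depression reduces their drive.
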