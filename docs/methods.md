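# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `thalcort`, in the order the pipeline runs.

## Mean-field model

The model describes the mean firing rates and potentials of nine neural
masses of the basal ganglia–thalamo-cortical system: cortical excitatory
(e) and inhibitory (i) populations, striatal D1 and D2 populations, the
GPi/SNr treated as a single inhibitory output structure, the GPe, the STN,
thalamic relay nuclei (s), and the thalamic reticular nucleus (r).

**Firing.**  Q_a = Q_a^max / (1 + exp(−(V_a − θ_a)/σ′)), with V_a the sum of
the population's dendritic potentials.  Maximum rates, thresholds, and the
3.8 mV potential spread sit at values standard for this model family.

**Synapses.**  Each afferent projection contributes a dendritic potential
V_ab governed by the second-order operator
(1/αβ)·V̈ + (1/α + 1/β)·V̇ + V = G·ν_ab·φ_b(t − τ_ab),
with decay rate α, rise rate β, coupling ν_ab (V·s, signed by source
neurochemistry), delay τ_ab, and a gain G = H/η(α, β) chosen so that the
impulse response's *peak* equals H = 31.5 s⁻¹ for every (α, β).  η(α, β) is
the peak of the unit-DC-gain bi-exponential Green's function; the confluent
α = β limit uses the analytic α²t·e^(−αt) form.  Fixing the peak rather
than the area means that slowing the decay of GABAergic synapses (the
canonical effect of GABAergic anesthetics) prolongs the response and
increases the transferred charge without changing the maximal current —
receptor-side (α, β) defaults can be overridden per projection, and all
GABAergic projections carry explicit overrides so that state interpolation
acts on them.

**Fields.**  Outgoing mean fields obey the damped wave equation.  The model
carries no spatial structure, so the Laplacian term is dropped and the
field reduces to a second-order ODE per projection,
(1/γ²)·φ̈ + (2/γ)·φ̇ + φ = Q_b, with γ = v/r the damping rate (conduction
velocity over axonal range — distinct from the synaptic coupling despite
the shared symbol in some notations).  Only projections from cortical
excitatory neurons have long enough axons for finite γ (116 s⁻¹); all other
projections are treated as instantaneous (φ = Q_b), the standard reduction
for short-range connections.

**Connectivity.**  The projection set contains the canonical
basal-ganglia–thalamo-cortical circuit (cortex → striatum/STN/thalamus,
direct and indirect pathways through GPi/SNr and GPe, STN feedback,
pallido-thalamic output, thalamo-cortical and thalamo-striatal returns, TRN
inhibition of relay) plus pallidal afferents from GPe to cortical
interneurons, relay nuclei, TRN, and both striatal populations.

**Integration.**  Fixed-step explicit RK4 with ring-buffer delay lines;
delayed terms are linearly interpolated at half-step stage times; pre-t=0
history is the constant initial state.  dt defaults to 1e-4 s; outputs are
decimated to 1000 Hz.  Relay nuclei receive a constant external drive plus
seeded white noise (amplitude σ·ξ_n/√dt, so the spectral density is
dt-invariant).  Identical seeds and configs give bit-identical outputs —
the property the twin-run Lyapunov procedure relies on.  Halving dt changes
a noise-free waking run's mean cortical rate by <1% (tested).  A non-finite
state aborts with the first diverging population named.

**LFPs.**  The local field potential of a region is the sum of the absolute
values of its dendritic potentials (superposition of synaptic currents; no
cancellation between excitatory and inhibitory afferents).  The external
drive's dendritic potential is included, which adds a constant offset that
every downstream analysis removes.

**Dose.**  P = P₀·(P₁/P₀)^D interpolates every population, projection, and
external-input parameter geometrically between the waking set (D = 0) and
an altered-state set (D = 1); entries keep their sign and saturate as D
grows.  The rule requires sign-consistent endpoint vectors, which motivates
the threshold calibration below.

## Shipped brain-state configurations

The shipped configurations are the package's own physiologically bounded
parameter sets, constructed in two steps:

1. **Rate calibration.**  Given target mean rates per region (cortex 7.7,
   striatum 5.2, GPi/SNr 75.7, GPe 30.9, STN 13.6, relay 16.4, TRN
   15.4 s⁻¹ — each inside the empirical range for that region), the
   external drives follow in closed form from the sigmoid inverse at the
   deterministic fixed point.  The calibration is then re-expressed in a
   "threshold chart": a common positive external drive is fixed and the
   thresholds absorb the difference.  Because the sigmoid sees only V − θ,
   this leaves the dynamics exactly unchanged while making every entry of
   the parameter vector sign-consistent across states, as the geometric
   dose rule requires.
2. **Dynamical selection.**  The corticothalamic loop gain and TRN
   inhibition were selected against the tuning module's fitness criteria.
   The *waking* configuration sits just below the loop's oscillatory
   instability: it rings at ~8 Hz around the calibrated rates and its
   twin-run Lyapunov exponent is near zero (weakly chaotic/near-critical).
   The *anesthesia* endpoint raises loop gain and reticular inhibition with
   mildly prolonged GABAergic decay, producing high-amplitude, strongly
   chaotic (Λ ≈ +1 s⁻¹), delta-dominated, information-poor dynamics with
   intermittent bursts.  The *seizure* endpoint lowers the loop
   populations' saturation rates so the oscillatory instability saturates
   into a stable ~7 Hz spike-wave limit cycle; its larger common-noise
   drive entrains the twin runs, making the stochastic exponent clearly
   negative.  The anesthetic axis is phenomenological — it reproduces the
   dynamical signatures of the state (chaos, delta dominance, information
   poverty), not a biophysical dose-response of any specific agent, and its
   cortical rates exceed the waking rates rather than falling below them.

## Stochastic largest Lyapunov exponent

Two runs with identical noise; run 2 receives, at 9.999 s of a 20 s
simulation, an additive uniform perturbation of every dendritic potential,
scaled per afferent to 1e-6 of that potential's running standard deviation
(potentials with no spread are kicked relative to their magnitude instead,
so the kick never vanishes below floating-point resolution).  The
divergence ε(t) is the summed squared difference of the cortical and relay
LFPs, normalized by the squared maximal difference; Λ is the least-squares
slope of ln ε versus t from the perturbation to the first crossing of the
saturation threshold (0.1) for growing divergences, or to the numerical
floor (1e-16 of the running maximum) for converging ones.  Fit windows
shorter than 0.5 s are rejected.  On an uncoupled population relaxing at
rate α the procedure recovers Λ ≈ −2α (squared-distance convention), which
the tests verify against the closed form.

## Modified 0–1 chaos test

The input sequence is standardized (zero mean, unit variance) and drives
the planar walk p(n+1) = p(n) + φ(n)cos(cn), q(n+1) = q(n) + φ(n)sin(cn).
The time-averaged mean-square displacement M_c(n), computed for n up to
N/10 and regularized by the additive noise term σ·η_n (η uniform on
[−1/2, 1/2], σ = 0.5), grows linearly for chaotic drive and stays bounded
for periodic drive; K_c is the Pearson correlation of n with M_c(n) and K
the median over 100 uniform draws of c from (0, 2π).  Standardizing the
input makes the fixed noise level commensurate with the data and K
invariant under affine rescaling; c is drawn from the full interval for
fidelity to the published procedure (a flag restricts the range to avoid
resonances).  Before the test, series are band-passed to 1–13 Hz with a
zero-phase Kaiser-window FIR designed for 85 dB stop-band attenuation
(two-pass), then reduced to local extrema with prominence ≥10% of the
maximum amplitude; fewer than ten qualifying extrema is an error.  The test
classifies *deterministic* dynamics: noise-dominated signals read as
chaotic (K ≈ 1), a known limitation inherited from the method.

## Spectral transfer entropy

**Estimator.**  TE(X→Y) = I(Y_t ; X_{t−u}^{(l)} | Y_{t−1}^{(k)}) with the
Kraskov–Stögbauer–Grassberger algorithm-1 conditional-mutual-information
form: the Chebyshev radius of the 4th nearest neighbor in the joint space
counts neighbors in each marginal space, combined through digamma terms.
A seeded jitter of 1e-10 of each series' spread breaks ties
deterministically.  Values are in nats (the CLI converts to bits).  On
linear-Gaussian autoregressive benchmarks the estimate matches the
closed-form ½·ln(restricted/full residual variance) within sampling error
(tested against an internal regression oracle).

**Embedding.**  Histories k and l are chosen by the Ragwitz criterion —
the smallest history whose one-step nearest-neighbor prediction error is
within 2% of the best over candidates 1..5 (the parsimony margin stops
sampling noise from inflating the embedding).  The delay u is scanned over
1..20 samples with the minimal (1, 1) embedding, which localizes the TE
maximum more sharply than long histories; the selected (k, l, u) is then
held fixed across all surrogates of a pair so the surrogate contrast
isolates band content.

**Bands and surrogates.**  The maximal-overlap discrete wavelet transform
is implemented in the frequency domain from the orthonormal least-asymmetric
8-tap (sym8) filters: per-level transfer functions satisfy
Σ|A_j|² + |B|² = 1, so analysis/synthesis round-trips to machine precision
at any length ≥ 2^J, including the 4160-sample 10 s trials.  Band
randomization draws an IAAFT surrogate of the level's detail coefficients
and imposes its *phases* on the signal's own spectral amplitudes strictly
inside that level's dyadic band: out-of-band content and the total
amplitude spectrum are preserved exactly, while in-band temporal structure
is destroyed.  (Replacing the detail coefficients wholesale and inverting
also randomizes the band but loses the cross-band covariance, biasing the
surrogate's variance low; the phase-imposition form avoids that.)  The
plain IAAFT surrogate — exact amplitude multiset, spectrum matched to
within tolerance — is also exposed directly.

**SOSO.**  The swap-out-swap-out test scrambles the sender's send-levels
and the receiver's receive-levels jointly (the staged sender-then-receiver
variant is not implemented), re-estimates TE per surrogate, and reports
strength = TE_original − mean(TE_surrogates) and the add-one p-value
(1 + #{TE_i ≥ TE_orig})/(1 + n), whose floor with 100 surrogates is
1/101 = 0.0099 — the original estimate counts as one member of its own
null ranking, so a perfect separation is never reported as p = 0.
Strength may be negative at the noise floor.  The exploratory J×J sweep uses few surrogates and z-scores the
strength matrix.

**Working rate.**  All transfer analyses run at 416 Hz, chosen so the
dyadic bands align with canonical neural rhythms: level 2 is exactly
52–104 Hz (high gamma) and levels 5–8 jointly cover 0.8125–13 Hz
(delta/theta/alpha).

## Preprocessing

Recordings are split into non-overlapping 10 s trials (remainder dropped),
detrended, notch-filtered at the line frequency and all harmonics below
Nyquist by zeroing the DFT bins within ±2 Hz (a zero-phase spectral
projection — chosen over recursive notch cascades because the projection is
idempotent, which the tests verify to numerical tolerance), demeaned, and
resampled by polyphase anti-aliased decimation to 416 Hz (transfer
analyses) or 500 Hz (chaos test).  Welch spectra default to 2 s segments,
50% overlap, Hann taper.  Artifact rejection is a flag honored downstream;
an optional amplitude-threshold flagger stands in for manual visual
inspection and is off by default.

## Group statistics and controls

One-tailed Wilcoxon signed-rank tests on paired per-subject medians are
exact (full enumeration) for n ≤ 25 without ties, so all-subjects-one-way
results are the dyadic rationals 1/2ⁿ; ties fall back to the normal
approximation with a warning.  Per-subject significance across trials is
combined with the harmonic-mean p-value; pervasiveness across subjects uses
a one-sided binomial test at a 0.05 null rate.  Controls: non-spectral TE,
the Tort modulation index (18 phase bins, 1–13 Hz phase × 52–104 Hz
amplitude), and a permutation ANCOVA for state effects adjusted for band
power (Freedman–Lane residual permutation — the standard residual-permutation
scheme, adopted because the procedure's original description leaves the
permutation scheme open).  Lempel–Ziv complexity binarizes at the median
and normalizes the LZ76 phrase count by n/log₂n.  The bi-symmetric log
transform (C = 1) is provided for display of signed quantities spanning
decades.  No multiple-comparison correction is applied anywhere, by design.

## Synthetic benchmarks

Every estimator has a seeded generator with a ground-truth sidecar: a
cross-frequency coupled pair in which the sender's phase-jittered ~6 Hz
drive multiplies the receiver's 78 Hz carrier envelope at a 10-sample
delay (amplitude modulation is the package's choice of coupling mechanism
for the test harness — the physiological code of cross-frequency
communication is an open question, and the generator makes no claim about
it); logistic maps at r = 3.2/3.99/4.0, a noisy sine, and white noise for
the 0–1 test; and a bivariate linear-Gaussian AR pair whose transfer
entropy has a closed form.

## The in-silico dose experiment

`run_insilico` sweeps the anesthetic and seizure arms.  Per dose and seed:
a 20 s twin-run pair yields the Lyapunov exponent; the unperturbed twin's
post-burn-in LFPs (first 5 s discarded) feed the 0–1 statistic (full 15 s,
because slow anesthetized dynamics need the longer stretch to yield enough
extrema) and, over the final 10 s, the bidirectional low→high band-pair
transfer strengths.  Before the transfer-entropy step, seeded white
measurement noise at 5% of each LFP's standard deviation is added —
emulating the sensor noise every real electrode carries, and giving the
nearest-neighbor estimator the stochastic floor it needs on otherwise
noise-poor simulated series (without it the estimator rewards determinism,
scoring chaotic states highest).  Default scales: the full experiment is
specified at 50 doses × 10 runs per arm; the shipped tests run a coarse
3-dose grid with 4 runs and 7 surrogates, which suffices to resolve the
inverted-U of transfer strength around the near-critical doses and the
positive association between the 0–1 statistic and the Lyapunov exponent.
The dose axis interpolates the relay noise amplitude along with everything
else, so mid-dose seizure configs carry more input noise than waking; this
contributes to the seizure arm's shallower strength decay.

## Known limitations

- The model is spatially uniform; no cortical sheet, no conductance-based
  or spiking dynamics.
- The parameter search is a plain genetic algorithm over the fitness
  criteria; no surrogate-model (Bayesian) stage.
- The 0–1 test reads stochastic signals as chaotic; the waking model's
  noise-driven ringing therefore scores low K only because its 1–13 Hz
  component is dominated by the regular oscillation.
- The synthetic cohort and benchmark generators emulate band-limited
  coupling, trial structure, and line noise, but not volume conduction,
  electrode drift, movement artifacts, or non-stationarity across trials —
  passing tests bound estimator behavior on clean, stationary signals only.
- Empirical EDF reading requires MNE; delimited text is the primary format.
- The mouse hardware band-pass of real recordings (0.1–100 Hz) truncates
  the upper half of the 52–104 Hz analysis band; the package applies no
  compensation.
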