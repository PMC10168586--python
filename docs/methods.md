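# Methods

## The model

`bgbeta` simulates a reduced rodent basal-ganglia network to study how
dopamine depletion turns two latent β-band resonators into one strong,
pathological β oscillator. The network (the *Complete Model*) contains
six populations — striatal D1 and D2 medium spiny neurons (6000 each),
fast-spiking interneurons (FSN, 420), the two external-pallidum
subpopulations GPe-TA (264) and GPe-TI (780), and the subthalamic
nucleus (STN, 408) — wired by 19 random projections with fixed
per-pathway probability, delay, sign and weight. GPi and SNr are
deliberately absent: they receive BG output but feed nothing back, so
they cannot shape the oscillations under study.

Neurons are adaptive conductance-based point models integrated with
classical RK4 at a fixed step h = 0.1 ms:

* **aeif** (STN, GPe-TA, GPe-TI):
  `C_m dV/dt = -g_L(V-E_L) + g_L·ΔT·exp((V-V_th)/ΔT) - g_ex(V-E_ex) - g_in(V-E_in) - w + I_e`
* **aqif** (D1, D2): the exponential spike term is replaced by
  `k(V-E_L)(V-V_th)`
* **aqif2** (FSN): as aqif, but the adaptation current relaxes to
  `a(V-V_b)³` below the pivot `V_b` and to 0 above it.

Synaptic conductances decay exponentially and jump by the synaptic
weight on each presynaptic spike after the pathway's axonal delay; the
adaptation current obeys `τ_w dw/dt = -w + a(V-E_L)` and jumps by `b`
at each spike. A spike is detected when V crosses `V_peak`; V is reset
to `V_reset`. All parameter values live in
`src/bgbeta/data/complete_model.yaml`; the per-population external
drives are independent Poisson trains (rate `ν_ext`, per-neuron weight
jittered uniformly within ±0.05 nS of the table value).

Every simulation runs 500 ms of warm-up (discarded) plus, by default,
10 000 ms of analysis time.

## Dopamine depletion and the two-loop picture

Dopamine depletion is modelled purely as a gain `D_d` on the external
drive of D2 (and of its auxiliary surrogate D2\*, when present):
`ν_ext(D_d) = D_d·ν_ext,1`. Raising `D_d` raises D2 activity and, via
D2→D1 inhibition, lowers D1 — the canonical firing-rate signature of
the dopamine-depleted striatum. Effects of dopamine on connectivity are
deliberately out of scope.

An ablation screen (below) identifies five connections whose removal
collapses β power; they form two loops sharing GPe-TI:

* the **STN loop**: STN ⇄ GPe-TI (excitation / inhibition), natural
  mode ≈ 19 Hz;
* the **STR loop**: the inhibitory ring D2 → GPe-TI → FSN → D2,
  natural mode ≈ 13 Hz.

The *Simplified Model* isolates this pair: GPe-TI is split into equal
halves GPTI-A (STN loop) and GPTI-B (STR loop); D1 and GPe-TA are
dropped. Inter-loop pathways (D2→GPTI-A, STN→GPTI-B, GPTI-A→FSN,
GPTI-B→STN, and the GPTI cross-half inhibition) carry probability
`ε·p₁`; rate-matched auxiliary populations D2\*, STN\*, GPTI\*
(half-size, externally driven only) carry the complement `(1-ε)·p₁`
(probability doubled for the halved-size D2\* and STN\*), so the mean
input to every nucleus is the same for every ε. At ε = 0 the loops are
fully independent; at ε = 1 the auxiliaries are disconnected and the
connectivity statistics match the Complete Model restricted to these
nuclei.

## Simplified-Model calibration

The reference tuning of the two-loop network is not available as data,
so the package ships an explicit calibration
(`bgbeta.builders.calibrate_simplified`, frozen result in
`src/bgbeta/data/simplified_model.yaml`, regenerable with
`scripts/calibrate_simplified.py`):

1. **Auxiliary drives.** D2\*, STN\* and GPTI\* have no recurrent
   input, so their neurons are independent and a small externally
   driven population suffices for calibration. STN\* and GPTI\* are
   matched to their counterparts' Complete-Model reference rates
   (≈16.7 and ≈55 Hz) by bisection on `I_e`; D2\* is matched (≈2.3 Hz)
   by scaling its *drive rate* instead, so that the dopamine gain
   `D_d`, which multiplies the drive, keeps its full leverage on the
   surrogate exactly as on D2 itself.
2. **Real-population inputs.** Populations in the Simplified Model
   lose the inhibition of the dropped nuclei (D1, GPe-TA, half the
   GPTI self-inhibition). Compensation is found by a damped
   diagonal-secant iteration on full network simulations at ε = 0,
   targeting the same reference rates — through `ν_ext` for D2 (for
   the same dopamine-leverage reason) and through `I_e` offsets for
   FSN, GPTI-A, GPTI-B and STN.
3. **Loop gains.** With the table weights the isolated loops barely
   oscillate — partly because splitting GPe-TI halves the in-loop
   pallidal in-degrees — so band-corrected β power sits near the
   shot-noise floor and band-mean frequencies drift toward the
   flat-spectrum value of 16 Hz. The five loop weights are therefore
   scaled by two gains (striatal ring ×1.75, subthalamo-pallidal pair
   ×1.75, approximately undoing the halving), chosen from a grid scan
   as the working point at which (i) population rates stay near their
   physiological windows, (ii) each isolated loop shows a clear
   resonance at its natural mode (≈13 Hz and ≈19 Hz), and (iii) the
   two oscillators are balanced, i.e. at full coupling the network
   synchronizes near the midpoint of the two natural modes rather than
   being dragged to either one. Larger striatal gains destabilize the
   rate calibration (runaway GPTI-B activity).

Residual imperfections of this stand-in tuning: D2 runs somewhat hot
(≈3 Hz) and GPTI-B somewhat cold (≈34 Hz) in the isolated-loop regime;
and the recalibrated striatal ring sits *above* its oscillation
bifurcation, so its ε = 0 β survives the large-n limit instead of
decaying (the subthalamic loop's fluctuation-driven β decays as
expected). The loop frequencies — the quantities this model variant
exists for — are unaffected.

## Spectral analysis

Population activity is the spike count of a fixed observer subsample in
1 ms bins. PSDs are Welch averages (2000-sample segments, 1000
overlap, Tukey α = 0.25 taper, constant detrend, one-sided density at
fs = 1 kHz); a 10 s series yields 9 averaged segments. Two β-band
scalars are computed on [m, M] = [8, 24] Hz by trapezoid quadrature on
the Welch grid (edge bins included):

* `Mean f` — power-weighted mean frequency (flat spectrum → 16 Hz);
* `Mean PSD` — band-average power.

`Mean PSD` is biased by finite-size shot noise, so the reported
intensity is `PSD† = Mean PSD − Q(ν₀, N)`, where Q is the band power
of a surrogate with i.i.d. Binomial(N, ν₀) bin counts run through the
identical pipeline (Monte-Carlo, 8–20 repeats; for white noise Q equals
2Nν₀(1−ν₀)/fs under this normalization). Because data and null share
the normalization, PSD† does not depend on the density-vs-spectrum
convention; absolute PSD units are implementation-defined and only
corrected or relative quantities are compared across studies.

Time-resolved quantities use a sliding single-segment tapered window
(2000 ms window; 500 ms step for traces, 250 ms for burst statistics so
that a 10 s run yields ≥30 window samples). Burst asymmetry is the
adjusted Fisher–Pearson sample skewness of the windowed β-power
distribution, computed per run and averaged across replicate runs —
pooling windows across replicates would inflate the estimate through
between-run differences in mean power.

## Experiments

* **Ablation screen.** For every non-self internal connection S→T, the
  S→T synapses are replaced by synapses (same probability and weight)
  from an auxiliary copy S\* of S that receives only external input
  with `I_e` calibrated to S's baseline rate — a rate-matched but
  oscillation-free surrogate. The score
  `R(S→T) = Σ_p MeanPSD_p(surrogate) / Σ_p MeanPSD_p(intact)` over the
  six real populations flags β generators at `R < 1/3`; self-inhibition
  rows are excluded, and connections within one SD of the threshold are
  reported as borderline. The screen is run in the pathological state
  (`D_d = 1.03`): the screened quantity is residual β power, which
  requires an active β state to be meaningful.
* **Knob sweeps** (`D_d`, ε, n, κ) aggregate rate, Mean f and PSD† of
  STN and D2 over independent replicates (4 by default; each replicate
  re-draws wiring and noise), reporting across-replicate SDs.
* **Size scaling.** `N_p(n) = n·N_p` with probabilities divided by n
  (expected in-degree invariant); observers stay at the n = 1 sizes so
  spectra are comparable. Synchronized β survives n → large;
  unsynchronized β decays toward the shot-noise level.
* **Optogenetic-style battery** (baseline `D_d = 1.03`): cortical
  inhibition (STN drive ×0.75; a fixed random 20% of each striatal
  population ×0.25), STN drive modulation (×κ, κ ∈ [0.65, 1.7]), and
  pallidal inhibition (I_e − 480 pA in GPe-TA, − 120 pA in GPe-TI).
  Reported: STN rate changes and β PSD† against the low-D_d reference
  band.
* **Burst analysis** (`D_d ≈ 0.90`): spectrogram, instantaneous
  Δf(t) = f_STN(t) − f_D2(t) and β power with medians, skewness per
  depletion level, and the fraction of windows where below-median Δf
  coincides with above-median β power.

## Numerical choices

* **Fixed-step spike handling.** A step whose endpoint reaches
  `V_peak` is accepted; the spike is timestamped at the step end and
  reset is applied before the next step (no sub-step interpolation).
  δ-increments are applied at step boundaries — exact for exponential
  synapses. All table delays are integer multiples of h.
* **Stage-voltage clamp.** Within the RK4 right-hand side the voltage
  is clamped at `V_peak` (and the aeif exponential argument capped).
  The quadratic/exponential spike mechanisms diverge in finite time by
  construction; without the clamp the stage values of a crossing step
  contaminate the adaptation current through `a(V−E_L)`. A hard floor
  at −150 mV guards the downward branch of the quadratic models.
* **Conductance propagation.** The linear conductance decay is advanced
  with the same RK4 stage factors as the rest of the state (the
  4th-order Taylor polynomial of `exp(−h/τ)`), keeping the scheme's
  order uniform.
* **Randomness.** A master seed feeds `numpy` `SeedSequence` streams:
  per-connection streams for wiring, one stream for drive-weight
  jitter and observer draws (build time), and per-run streams for
  initial conditions and the kernel's Poisson arrivals (drawn as
  exponential gaps, one variate per event). Identical seeds give
  bit-identical rasters. The kernel uses a single RNG stream per run;
  per-neuron substreams are not maintained.
* **Initial conditions.** V starts at `E_L` ± 5 mV uniform, w = g = 0;
  the 500 ms warm-up removes the transient.
* **Delay buffers.** Per-neuron ring buffers of length
  (max delay)/h + 2 accumulate scheduled conductance jumps; a spike at
  step end s+1 with delay d is consumed at the start of step s+1+d,
  never earlier.
* **Connectivity realization.** One Bernoulli(p) trial per ordered
  pair, realized as a Binomial(N, p) out-degree with distinct uniform
  targets; no autapses, no multi-edges (the tables' "connection
  probability per pair" reading). With `t_ref = 0` for every
  population, refractory logic is a structural no-op (still
  implemented and tested).

## Known quantitative deviations

The mechanism — two delay-determined β resonators sharing GPe-TI,
synchronized by dopamine-driven strengthening of the striatal loop —
reproduces in full, but this implementation's operating point differs
from the reference in ways worth knowing:

* **Shifted dopamine axis.** The D1/D2 rate crossing sits near
  `D_d ≈ 0.93` (reference ≈ 1.0) and the synchronization knee of the
  Complete Model near `D_d ≈ 0.94`. The burst regime (right-skewed
  windowed β power, mean skewness ≈ +0.4-0.6) occupies the narrow band
  `D_d ≈ 0.875-0.925` just below the knee, with strongly
  seed-dependent per-run estimates; above the knee transient *dips*
  of the sustained oscillation give near-zero or negative skewness.
  The positive skewness in the burst band stays below the reference
  range (0.85-1.5): bursting is present but weaker-tailed here.
* **D1 marginally hypoactive.** At reference parameters D1 fires at
  ≈0.45 Hz, a hair below its 0.5-2.5 Hz window (all other populations
  are in-window); the D1/D2 balance is tilted toward D2 relative to
  the reference implementation.
* **Striatal dominance.** D2 runs at the upper edge of its window, so
  the striato-pallidal loop carries a larger β share than the
  subthalamo-pallidal one. The ablation screen consequently flags
  four of the five loop connections decisively, but scores the
  STN→GPe-TI excitation at R ≈ 0.5 (above the 1/3 threshold):
  removing it halves rather than collapses total β.
* **Perturbation magnitudes.** Cortical opto-style inhibition lowers
  the STN rate by ≈25% (reference −15%); pallidal opto-style
  inhibition raises it by ≈+14% (reference +85%) — with ≈18 nS of
  inhibitory conductance on GPe-TI, the −120 pA current is largely
  absorbed by the shrinking inhibitory driving force as the nucleus
  hyperpolarizes toward E_in, so STN is only mildly disinhibited. The
  directional signatures (β not suppressed under cortical inhibition;
  STN rate up and β collapsed to the low-D_d band under pallidal
  inhibition; GPe-TA silenced) all reproduce.

## What the simulations do and do not show

All data are generated by the model itself; there is no external
recording in the loop. Passing checks therefore demonstrate internal
consistency of the mechanism — two delay-determined resonators,
coupling-controlled synchronization, dopamine-gain control of the
striatal resonator — at the adopted network scale (≈14 k neurons,
~10³-fold smaller than the biological counts; the n-scaling analysis
is the control for this reduction). They do not validate the neuron
parameters against in-vivo data beyond the published rate windows, and
the external drive is stationary Poisson: cortical β bursts or input
correlations, plasticity, and dopamine effects on connectivity are all
outside the model.

## Problem sizes used in the shipped checks

The test suite runs desk-scale versions of every experiment (5 s
simulations, 1–2 replicates, n ∈ {1, 4}; 10 s where distributional
statistics need the samples), with tolerances widened accordingly; the
`scripts/acceptance.py` entry point re-runs the headline quantities at
10 s with 2–3 replicates. The full-scale protocol (4 replicates,
n up to 8) is available through the CLI and the `experiments` module.
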