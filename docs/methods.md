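# Methods

`granulayer` models how long-term plasticity at the mossy-fiber (mf) to
cerebellar granule cell (GrC) synapse retunes the gain and frequency
bandwidth of burst transmission through the granular layer, and implements
the analysis pipelines used to quantify that retuning from patch-clamp-like
traces. This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Presynaptic dynamics

Short-term dynamics follow the Tsodyks–Markram three-state scheme. The
transmitter resource is split into available (X), released (Y) and
recovered (Z) fractions with X + Y + Z = 1:

    dX/dt = Z/τ_rec,   dY/dt = −Y/τ_inact,   dZ/dt = Y/τ_inact − Z/τ_rec.

The dynamic release probability P relaxes to its initial value p with the
facilitation time constant τ_facil. At a presynaptic spike, release uses the
pre-jump P (a fraction P·X moves from X to Y), and P then jumps by p·(1 − P)
for subsequent events. We use the canonical form in which P relaxes *toward*
p; a literal transcription of dP/dt = −P/τ_F would decay P to zero and
contradict the facilitation it is meant to produce, so the canonical form is
the only self-consistent reading.

Between events the linear system is advanced in closed form (including the
degenerate τ_inact = τ_rec case via the t·e^(−t/τ) solution), so
conservation holds to machine precision for arbitrarily long intervals. A
brute-force RK4 oracle verifies the closed form to 1e−6 over random
parameter draws.

Parameters per synapse class (ms, dimensionless):

| class    | p    | τ_rec | τ_facil | τ_inact | sites |
|----------|------|-------|---------|---------|-------|
| mf→GrC   | 0.42 | 8     | 5       | 1       | 6     |
| mf→GoC   | 0.42 | 8     | 5       | 1       | 1     |
| PF/AA→GoC| 0.10 | 8     | 5       | 1       | 1     |
| GoC→GrC  | 0.35 | 36    | 58.5    | 0.1     | 1     |

Long-term plasticity is expressed purely presynaptically as a ±50 % change
of p (mf→GrC: LTP 0.63, LTD 0.21; GoC→GrC: LTP 0.525, LTD 0.175).

Stochastic release is site-level all-or-none: each of the n_rel = 6 sites
independently releases its full available resource with Bernoulli
probability P, and the postsynaptic conductance is split equally across
sites (gmax/n_rel per site). Whether the underlying stochastic model is
all-or-none or graded per site is not settled; all-or-none was chosen and a
law-of-large-numbers test confirms the stochastic mean converges to the
deterministic release.

## Transmitter and receptors

A release of fraction Y produces a cleft glutamate transient
T = Y·(Ts + Td): a 1 ms rectangular synaptic pulse (Ts_max = 1 mM) plus an
exponentially decaying diffusion/spillover wave (Td_max = 0.3 mM,
τ = 1.2 ms). Both components are scaled by Y for physical consistency.
Extra-synaptic NMDA receptors see only Td. The waveform constants are
surrogates at the scale commonly used for this synapse; none are printed in
the source literature, and all are configurable.

Receptors are continuous-time Markov schemes. AMPA is a three-state C–O–D
chain (k_o+ = 5.4, k_o− = 0.82, k_d+ = 1.12, k_d− = 0.013 ms⁻¹) whose
opening is driven by the saturating two-site function
S = T²/(T + K_B)², K_B = 0.44 mM. NMDA uses two identical sequential
glutamate-binding steps (k_1± = k_2± = 5 mM⁻¹ms⁻¹ / 0.1 ms⁻¹) into a
doubly-bound closed state from which both the open state
(k_o+ = 0.03, k_o− = 0.966 ms⁻¹) and the desensitized state
(k_d+ = 0.00012, k_d− = 0.009 ms⁻¹) are entered; this five-state wiring is
the only one that uses every published constant. NMDA carries the standard
magnesium block B(V) = 1/(1 + exp(−0.062·V)·[Mg]/3.57) with [Mg] = 1.2 mM.
Kainate reuses the AMPA scheme with 20× slower recovery from
desensitization (slow temporal summation); GABA-A is represented by fast
(transient) and slow (sustained, spillover-driven) surrogate schemes with a
−65 mV reversal. Kainate and GABA-A rate constants are calibrated
surrogates, not published values.

Occupancies are propagated with sub-stepped RK4 on the master equation;
Runge–Kutta preserves the linear invariant Σoccupancy exactly, and the
propagator matches `expm` to 1e−6 at constant transmitter.

Currents are ohmic: I = gmax·O·B(V)·(V − V_rev), with gmax in pS
(mf→GrC AMPA 1200, NMDA 18800, divided by n_rel per site). The bare printed
conductance numbers are read as pS; this reproduces EPSCs of the correct
tens-of-pA scale (the simulated mf→GrC EPSC at −70 mV comes out near
−30 pA against a recorded mean of 29.7 pA without any tuning).

## Compartmental neurons

Each compartment integrates the canonical membrane equation

    C_m dV/dt = −Σ g_i (V − V_i) − Σ g_syn (V − V_syn) − Σ g_br (V − V_br) + I_inj

(the published equation is typographically garbled; this is the only
dimensionally consistent reading). Gating particles follow first-order
kinetics with x_∞ = α/(α+β), τ_x = 1/(α+β), integrated by exponential
Euler; voltages use backward Euler on the full compartment tree (dense
solve; the cells have ≤ 52 compartments). Default dt = 0.025 ms; halving dt
changes subthreshold responses by < 0.5 % RMS. Dendritic-tip calcium uses a
200 nm submembrane shell, d[Ca]/dt = −I_Ca/(2FAd) − β([Ca] − [Ca]₀) with
β = 0.6 ms⁻¹ (units assumed; the source prints the value bare) and
[Ca]₀ = 100 nM, integrated by exponential update; the calcium reversal is a
Nernst potential against 2 mM external.

Temperature scaling uses Q10 power laws, q10^((T_sim − T_orig)/10), with
class values 3 (channel gating), 2.4 (receptor gating), 1.5 (permeation)
and 1.3 (transmitter diffusion). The printed "Q10 = (T_sim − T_orig)/10" is
read as defining the exponent, since the listed class values only make
sense as bases. Kinetics are referenced at 30 °C and simulations default to
30 °C (the recording-chamber temperature), so the scaling is exercised by
tests at 37 °C rather than active by default.

**Granule cell.** Soma (5.8 µm sphere), four dendrites (30 µm × 0.75 µm, 4
segments each; the printed "15 µm diameter" is anatomically implausible and
is read as a half-length — 30 µm is also the unique length at which the
printed 0.042 nS per-branch tonic-GABA leak equals the printed doubled
density of 60 µS/cm²), a 5-segment hillock and a 30-segment axon. Published
absolute conductances are used verbatim with their placements (Na/K_DR
hillock; K_A/K_IR/K_slow soma; Ca/K_Ca dendritic tips with calcium shells;
Lkg1 everywhere, area-weighted; Lkg2 per dendrite). The published table
prints nine values against eight non-Na labels; the dendritic localization
column resolves the extra value as the per-branch Lkg2 (4 × 0.042 ≈ 0.17).
The gating rate functions themselves are not printed anywhere in the source;
the shipped defaults are plausible kinetics in the style of the published
GrC model family, and every ChannelDef is replaceable, so the quantitative
claims about this module are property-level (resting stability, placement,
convergence), not waveform-exact. The leak reversal is the one free
parameter: it is solved at build time (secant on the DC fixed point) so the
soma rests at exactly −70 mV, mirroring the source model's own calibration
step; the solved value lands near −29 mV, in the family of published GrC
leak reversals. A 1 s simulation from a perturbed start returns to
−70 ± 1 mV.

**Golgi cell.** Five compartments: 27 µm spherical soma, three
113 µm × 3 µm dendrites, one 1200 µm × 2.4 µm axon; 1 µF/cm² (the printed
"1 mF/cm²" is treated as the standard 1 µF/cm²), R_m = 47.6 kΩ·cm²,
R_a = 100 Ω·cm. This yields 23/32/90 pF (soma/dendrites/axon), total
145 pF. All active conductances are somatic. The published magnitudes are
not printed; the shipped set (Na 900 nS, K_DR 350, K_A 60, Ca 20, K_Ca 100,
K_slow 10, persistent Na 6 nS, passive reversal −55 mV) was chosen once to
make the cell an autonomous pacemaker (~20 Hz), the qualitative behaviour
of the source model. The source model's Markov afterhyperpolarization
current is replaced by the HH-style K_Ca surrogate. Note the long axon is
only approximately electrotonically compact: the passive somatic input
resistance is ~14 % above the total-area lumped estimate, and the exact
star-network value is what the tests pin down.

## Microcircuit and protocols

The circuit wires 1–4 mfs onto the GrC (one synapse per dendritic tip,
round-robin) and onto 0–4 GoCs; the GrC excites each GoC through parallel-
fiber (AMPA+NMDA+kainate, p = 0.1) and ascending-axon (AMPA+NMDA, ~2×
conductance) synapses; each GoC inhibits one GrC dendrite (GABA-A
fast+slow, round-robin when n_GoC < 4). All synaptic delays are 1 ms;
GoC→GrC and GrC→GoC transmission is triggered by −20 mV upward somatic
threshold crossings. Four named presets cover the quantitatively analysed
excitation/inhibition combinations: (1mf,3GoC), (2mf,2GoC), (3mf,2GoC),
(4mf,3GoC).

The mf→GoC synapse inherits the mf→GrC parameters and is calibrated at
wiring time: one deterministic stimulus is delivered to the voltage-clamped
(−70 mV) GoC and both gmax values are scaled linearly so the
baseline-subtracted peak equals −66 pA (the clamp current is linear in gmax
under ideal clamp, so the calibration is exact; a second pass removes any
residual).

Protocols: five-pulse bursts at 10–500 Hz repeated over trials (trials are
simulated independently from reset state — the 10 s inter-trial interval is
far beyond every time constant in the model); theta-burst stimulation
(8 × 10 pulses at 100 Hz every 250 ms, 80 stimuli) — TBS is the induction
protocol and does not itself change weights here, induction modelling being
out of scope, so the runner verifies schedule and records responses; and
somatic voltage clamp, ideal by default with an optional series-resistance
mode. In current clamp the holding potential (−65 mV) is set by a somatic
bias current solved against the isolated GrC's DC fixed point; with
spontaneously firing GoCs present, occasional background IPSPs ride on that
baseline, as they do in slices. Trial randomness comes from a
counter-based seed stream ([seed, trial]), so runs are bit-reproducible and
trials independent.

## Analysis pipelines

**Passive parameters.** Clamp-step transients are fitted with
I(t) = I_ss + (I_peak − I_ss)·e^(−t/τ); Rs = dV/I_peak,
Rm = dV/I_ss − Rs, Cm = τ(Rs+Rm)/(Rs·Rm). With the study's parameters the
transient τ is ~42 µs against a 50 µs sample interval, so the fit leans on
the extrapolated peak; recovery is within 5 % at 2 % amplitude noise.

**EPSCs and plasticity.** Amplitudes are baseline-subtracted (5 ms
pre-stimulus mean) extrema in a 10 ms post-stimulus window, measured on a
lightly smoothed trace (0.3 ms boxcar) because a raw max over noise is
biased upward. PPR is second/first peak, so depression gives < 1 and LTP
(higher p) decreases it. Percent change is 100·(mean_post −
mean_pre)/mean_pre with a delta-method SEM; classification uses a ±5 % dead
band (real cells all classify; the band guards synthetic edge cases). All
trials enter the average, including stochastic failures.

**Gain curves.** Per frequency, four burst metrics over trials: mean spike
count (sc), probability of ≥ 1 spike per burst (sp), first-spike-latency SD
(fssd, n−1 denominator, undefined below two spiking trials and then treated
as worst-case — this keeps the index defined where spiking is rare, which
is also where gain is low), and average maximum depolarization above
baseline (amd, baseline-subtracted by choice). The analysis window runs
from the first stimulus to 50 ms after the last (the source never defines
one). Each metric is min-max normalized per cell across frequencies (fssd
inverted; an all-constant metric contributes 0), and the four sum to the
compound gain index cGI ∈ [0, 4]. Per-cell amd-based gain lies in [0, 1] by
construction; published *averaged* amd fits exceed 1, indicating the
population curves were not unit-normalized — this package keeps the
per-cell definition rather than reverse-engineering a figure.

Gain curves are fitted with g(f) = (A1 − A2)/(1 + (f/f_c)^p) + A2 by
bounded least squares, multi-started over f_c ∈ {10, 30, 50, 100, 200} Hz
with p ∈ [0.5, 20] (initial 4). g(f_c) = (A1+A2)/2 identically. Summary
statistics: Δf_c, Δmax gain (max(A1,A2)) and Δrelative gain
((Gmax−Gmin)/Gmin, undefined if Gmin ≤ 0). Cutoff histograms use left-closed
bins with default edges 0/20/50/100/200/500 Hz.

## Synthetic data

The generators emulate: the two-resistor (Rs–Rm) pipette circuit transient
(20 kHz sampling, proportional "amplitude" noise); double-exponential EPSC
trains (rise 0.3 ms, decay 3 ms — typical mf→GrC AMPA scale; additive
2 pA Gaussian noise) with per-stimulus scaling for PPR; five-pulse burst
voltage responses in which an EPSP staircase follows a sigmoidal
depolarization profile, a trial spikes with a sigmoidal burst-level
probability (first spike on the first pulse with sigmoidally
frequency-dependent latency jitter, later pulses at a fixed conditional
probability 0.5 so the expected count stays proportional to the
probability profile), 0.5 mV voltage noise and a 1 ms triangular spike
surrogate peaking at +30 mV (only threshold crossings matter downstream);
and noisy sigmoidal gain curves. Default effect sizes are the recorded
means: EPSC +28.5 %/−36.8 %, EPSP +31.2 %/−27.8 %, PPR −27.4 %/+23.8 %,
cutoff −67 %/+89 % and maximum gain +24 %/−13 % for LTP/LTD.

What passing closure tests show: every analysis operation recovers the
statistical structure its generator injects, at realistic noise levels.
What they do not show: performance on real recordings with electrode
artifacts, line noise, drifting series resistance, cell-to-cell kinetic
variability or non-Gaussian noise — none of which the generators emulate.

## Problem sizes and reproducibility

The shipped acceptance run uses 50-trace EPSC epochs, 20 gain-curve
replicates at 10 log-spaced frequencies, a 1 s resting-stability
simulation, and single-stimulus clamp calibration. The circuit-level
directional checks (LTP up / LTD down; same-sign GABAergic plasticity
shrinking the displacement from control) are probed at a single frequency
(100 Hz) with deterministic release on the 2mf presets — the package's
chosen desk-scale summary of the full four-preset frequency sweeps, whose
directions they reproduce. All randomness flows from explicit seeds;
identical configs and seeds give bit-identical outputs.

## Known limitations

- Channel gating kinetics and GoC conductance magnitudes are configurable
  surrogates, not transcriptions; waveform-exact reproduction of the
  published cutoff frequencies (95/156 Hz control, 105→76 Hz under LTP) is
  out of scope, and those quantities are treated as directional.
- Plasticity induction (the calcium/BCM side) is not modelled; plasticity
  is an expression-level release-probability change.
- The clamp is ideal by default; the series-resistance mode is a first-order
  emulation (no capacitance compensation artifacts).
- Population statistics of the recorded cell sample (incidence percentages,
  population cutoff histograms) are properties of that sample and are not
  reproduced.
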