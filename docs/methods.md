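# Methods

## The model

`stimplast.netsim` simulates a layered thalamocortical microcircuit of
event-driven leaky integrate-and-fire neurons. Each neuron carries a single
state variable, the membrane voltage V relative to rest, expressed as a sum of
per-channel synaptic contributions minus a post-spike hyperpolarization term:

    V_i(t) = sum_c U_c(t) - H_i(t)

A synaptic event on channel c (AMPA, NMDA or GABA_A) at time t0 deflects
U_c instantaneously by `w_s * E_c`, where `w_s` is the synaptic weight (mV)
and `E_c` a signed polarity scale (+1 depolarizing for AMPA/NMDA, -1 for
GABA_A); the contribution then decays as `exp(-(t - t0)/tau_c)` with the
receptor time constant. NMDA is treated as a slow depolarizing channel
(tau = 40 ms) without voltage dependence, consistent with the single-state
neuron. Nothing is clocked: state is advanced in closed form between events.

**Firing.** A neuron fires when an arriving event leaves it with
`V >= V_threshold + R(t)` while `V < V_block` (depolarization blockade) and
the absolute refractory period `tau_abs` has elapsed since its last spike.
`R(t)` is a post-spike threshold increment decaying with `tau_R`; firing also
adds a hyperpolarization `H` decaying with `tau_H`, and clears the synaptic
contributions (spike reset). Because all state components decay between
events, firing is defined to occur only at event times; a crossing produced
purely by the threshold offset decaying faster than the voltage between two
events is not detected. The fixed-step test oracle implements the same
semantics, so the oracle-equivalence tests check the integration, not a
different model.

**Spikes propagate** to each efferent synapse after a delay
`delta_cond + d/v`: a base synaptic conduction delay plus axon length over
conduction velocity (default v = 1000 um/ms, so cross-sheet delays stay well
below the plasticity window).

**Plasticity.** Excitatory (AMPA/NMDA) synapses onto cortical targets are
plastic under a rectangular STDP rule: any pre-input/post-spike pairing with
|dt| <= T = 10 ms changes the weight by one increment epsilon — potentiation
when the input precedes the spike, depression otherwise — and weights are
clamped to [0, 5 x baseline]. Pairings are nearest-event: a spike pairs with
the most recent input on each afferent synapse, an input with the most recent
spike of its target. The default increment is 0.002 x baseline weight. This
is deliberately small: with a symmetric additive rule, causal pre-post
correlations in a recurrent excitatory network potentiate on average, and
larger increments drive weights toward the 5x ceiling even without
stimulation within a session. At 0.002 the rest-state mean weight drift over
a 90 s session stays below ~5% while conditioning still produces clear
potentiation.

**Structure.** 14 populations — thalamic reticular (inhibitory) and relay
(excitatory) cells, plus pyramidal, fast-spiking and low-threshold-spiking
cells in layers 2/3, 4, 5 and 6 — with per-495 counts, so the network size is
always a multiple of 495 (default scale 4 = 1980 neurons). Cells are placed
uniformly on a 1 x 1 mm sheet per layer, and connected with probability
`p_max * exp(-d/falloff)` in planar distance d. The published source for this
model family cites its parameter tables rather than printing them; the tables
shipped in `netsim/params.py` are this package's own calibration, chosen so
that (a) cortical cells fire at ~3 Hz spontaneously during tactile phases and
(b) touch evokes cortical responses inside the 0-70 ms analysis window. All
values are overridable through the configuration mapping (YAML/JSON).

**Stimulation.** Touch is a forced suprathreshold AMPA deflection (30 mV)
delivered to the 25% of relay cells nearest the sheet center; touch times have
uniform 400-800 ms inter-event intervals (mean 600 ms) in model sessions, or
Poisson 0.5 Hz in experiment-like sessions. Microstimulation pulses force the
same deflection onto a random 10% of layer-5 pyramidal cells (axonal
recruitment is non-contiguous); refractoriness and blockade still apply, and
the electrical pulse shape is not modelled. In spike-triggered mode a pulse
follows each spike of a reference unit by 5 ms (optional lockout, default
none); the reference unit is a random pyramidal cell within 250 um of the
center — the touch-responsive region — excluding microstimulation targets. In
random mode the conditioning phase receives a gamma-distributed pulse train
whose inter-pulse mean and variance are moment-matched to the reference
unit's pre-phase activity. Background drive is an independent per-neuron
Poisson stream of subthreshold AMPA kicks (25 Hz, 6.5 mV), calibrated
together with the weights to the ~3 Hz operating point.

**Determinism.** All randomness flows through seeded generators; simultaneous
events resolve in a fixed order (phase boundaries, stimulus events, synaptic
deliveries, background, then insertion order), so identical (config, seed)
pairs give identical spike tables.

## Analysis pipeline

All windows follow the standard touch-response conventions: peristimulus
range -250 to +300 ms, baseline statistics over [-250, 0) ms, response window
[0, 70] ms.

* **PSTH** — trial-aligned histogram smoothed with a Gaussian kernel. The
  source description ("a Gaussian density kernel with a 20 ms window") is
  read as sigma = 20 ms, truncated at +-3 sigma; both are configurable. The
  histogram is accumulated over a padded range so kernel mass is conserved
  away from the requested edges.
* **Response metrics** — peak rate and its latency in the response window;
  AUC as area above the baseline mean within the window (signed); a unit is
  touch-responsive when the peak exceeds baseline mean + 3 SD (SD across
  baseline time bins; a degenerate zero-SD baseline falls back to a strict
  mean comparison and is flagged). Sharpness is peak rate divided by the
  response-curve width at the 3-SD level, measured at the crossings nearest
  the peak. Off-responses to stimulus retraction are not analysed.
* **Fano factor** — across-trial variance/mean of spike counts in 20 ms
  windows stepped by 3 ms; windows with zero mean count are undefined (NaN)
  and excluded from ensemble averages. The stimulus-locked decrease is
  quantified as the drop from the baseline-window mean FF to the post-onset
  trough (minimum of the unit-averaged FF curve within 0-70 ms): the dip is a
  short transient, and the trough is the standard readout of stimulus-driven
  variability quenching. At desk scale (~50 trials per phase) the trough
  carries a downward noise bias, so measured decreases run larger than
  full-scale values.
* **Mutual information** — spike trains binned at 10 ms (mostly 0/1 counts at
  ~10 Hz), binarized, and MI estimated with the plug-in estimator. Bias is
  removed by subtracting the mean MI of 20 surrogates in which the bins of
  one member of the pair are randomly permuted — a scheme that destroys
  timing while preserving marginals (the original toolkit's exact shuffle
  construction is not described). Corrected values are not floored at zero.
* **Multi-information** — total correlation (sum of marginal entropies minus
  joint entropy) of binarized counts, shuffle-corrected by permuting every
  sub-ensemble member but the first. The joint over ~42 units is not
  estimable, so the statistic is averaged over 50 random sub-ensembles of 5
  units (a documented divergence from the original analysis, whose
  tractability strategy is unstated). At sub-ensemble size 2 the statistic
  routes through the pairwise estimator and reduces to it exactly.
* **Session statistics** — percentage change PC = 100 x (after - before) /
  before; Wilcoxon signed-rank across sessions on paired values; two-sample
  Kolmogorov-Smirnov on pooled distributions; bootstrap CI (100 resamples) of
  mean pair-level differences. Sessions are pooled as independent
  observations; no multiple-testing correction by default (Benjamini-Hochberg
  available but off, matching the source analysis).
* **Recorded ensemble** — simulation analyses sample up to 42 cortical units
  within 250 um of the sheet center (an electrode-array-like patch over the
  touch-activated region), always including the reference unit; this mirrors
  the experimental 42 +- 8 units per session. Whole-sheet sampling would
  dilute touch responsiveness far below the experimental regime.

## Synthetic sessions

`stimplast.synthetic` generates experiment-like sessions with known ground
truth so every estimator can be validated by recovery. Each unit's background
is a sum of a shared Poisson source (thinned per unit to reach a target
pairwise count correlation — with thinning probabilities
`q_i = sqrt(c b_i / b_max)` every pair's correlation is c) and an independent
Poisson remainder whose rate is modulated by a piecewise-constant gamma gain
process (0.5 s blocks), giving a controllable super-Poisson baseline Fano
factor `FF = 1 + g^2 mu_I^2 / mu`. Touch responses are Gaussian rate bumps
(sigma = 10 ms) at per-unit latencies drawn inside the 0-70 ms window;
off-responses are not generated. The `BeforeAfterEffect` fields are applied
exactly in expectation: the peak change is defined on the kernel-smoothed
peak via the closed-form attenuation of a 10 ms bump by the 20 ms analysis
kernel; the Fano and correlation changes are pre-compensated for gain
dilution at the relevant window/bin sizes, so the measured quantities — not
just latent parameters — move by the injected percentage.

What the generator does not emulate: stimulation artifacts, electrode drift,
spike-sorting noise, slow nonstationarity beyond the gain blocks, or any
causal link between conditioning and the injected effects. Recovery tests
therefore validate the estimators and the comparison logic, not the model of
plasticity; the simulator provides the mechanistic side.

Known interaction: the correlation target refers to the stationary background
component. Touch-locked covariation among responsive units adds a roughly
phase-constant extra correlation, so correlation-change recovery is exact for
non-responsive ensembles and approximate (slightly diluted) when strong
responses are present.

## Problem sizes and numerical choices

Reproduction runs use scale 1 (495 neurons), three 30 s phases and 10 seeds —
the package's desk-scale operating point; at this size one session simulates
in ~15 s and the full batch, analysis included, in a few minutes. Scaling
down from the published 1980-neuron, 100 s-phase setting preserves signs and
approximate magnitudes of the conditioning effects but inflates
trial-count-limited quantities (the Fano trough) and the variance of
ratio-based summaries (multi-information PC). Percentage changes of noisy
ratios carry a positive Jensen bias of order Var(denominator)/denominator^2;
ensemble-level summaries keep this small, and ground-truth recovery tests use
mean-then-ratio aggregation for the same reason.

Ties and degenerate inputs: simultaneous events follow the fixed priority
order above; zero-variance units yield NaN correlations (flagged, excluded
from means); empty phases or unit sets raise errors rather than returning
silent defaults; corrected MI may be slightly negative and is reported as-is.

## Known limitations

* The default parameter tables are calibrated, not inherited: quantitative
  agreement with the published model is expected only at the level the
  reproduction checks enforce (signs, and magnitudes within seed-to-seed
  spread at desk scale). Response sharpening (width narrowing) under
  conditioning is not reproduced — in this parameterization potentiated
  recurrence slightly broadens responses, so the sharpness gain is smaller
  than published.
* Thalamocortical synapses are non-plastic by default (cortical-target
  plasticity only); a single flat sheet per layer, no oscillatory embedding,
  no habituation — so, as in the original model, random-vs-spike-triggered
  differences and persistent-touch habituation are outside its scope.
* The event-driven engine is pure Python; it is comfortable at desk scale
  but a 1980-neuron, 300 s session takes tens of minutes.
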