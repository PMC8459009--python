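# Methods

This note documents the model, the defaults, the numerical choices and the
open design decisions behind `neocolumn`, and what the bundled
configuration can and cannot be taken to show.

## Neuron model

Each neuron is an adaptive exponential integrate-and-fire (aEIF) unit with
membrane potential V (mV) and adaptation current w (pA):

    C dV/dt = -g_L (V - E_L) + g_L exp((V - V_th)/ΔT) + I - w
    τ_w dw/dt = a (V - E_L) - w

A spike is a threshold crossing: when a forward-Euler step carries V above
V_th, the spike is stamped at the end of that step, V is reset to V_r and w
incremented by b. Units are fixed package-wide to pA, pF, nS, mV and ms
(self-consistent: pA/pF = mV/ms).

Two deliberate departures from the textbook aEIF:

* **Exponential prefactor.** The spike-initiation term is `g_L·exp(...)`,
  *without* the usual ΔT factor, so the term contributes exactly g_L (as a
  number, in pA) at V = V_th. The canonical `g_L·ΔT·exp(...)` form is
  available via `simulation.canonical_exp_term` for sensitivity checks; all
  defaults and tests use the bare form.
* **No V_peak, no refractory period.** Spikes are threshold crossings, not
  full action-potential upswings; since the reset fires in the same step as
  the crossing, the exponential term only matters in a narrow band below
  threshold. Because an unstable fixed point of the subthreshold dynamics
  always lies *above* V_th while V_r must lie below it, single neurons in
  this model are never intrinsically bistable — persistent activity has to
  be a network or drive phenomenon (see "Stimulation", below).

The exponent (V − V_th)/ΔT is clamped at +10 before exponentiation
(configurable), preventing overflow in the one step where a strong stimulus
throws V far past threshold before the reset.

**Integration.** Forward Euler at dt = 0.05 ms (configurable). Against an
adaptive high-order reference integration with event detection, spike times
on randomized suprathreshold protocols stay within 0.2 ms over 100 ms
(tested); timing error grows roughly linearly with elapsed time, so very
long single-trajectory comparisons will drift beyond that. Halving dt
changes the default column's total spike count by about 1–2%.

## Synapses

Receptors AMPA, NMDA, GABA_A. A presynaptic spike at t_sp with short-term
plasticity efficiency a contributes, after the transmission delay τ_D,

    g(t) = g_max · a · (exp(-(t-t_sp-τ_D)/τ_off) - exp(-(t-t_sp-τ_D)/τ_on))

and the current g(t)·s(V)·(V − E_rev) is subtracted from the drive. s(V) is
the NMDA magnesium-block gate 1.08/(1 + 0.19·exp(−0.064·V)) — its three
constants are frozen, not configuration — and 1 for the other receptors.

Kernel constants (defaults): AMPA 0.2/2 ms on/off, E_rev = 0, τ_D = 1 ms;
NMDA 2/100 ms, E_rev = 0, τ_D = 1 ms; GABA_A 0.5/8 ms, E_rev = −70 mV,
τ_D = 0.8 ms. Delays shorter than one step round up to one step.

**Short-term plasticity** follows the Tsodyks–Markram per-spike recursion.
With Δt the interval since the previous presynaptic spike:

    u_{n+1} = u_n e^(-Δt/τ_facil) + U (1 - u_n e^(-Δt/τ_facil))
    R_{n+1} = R_n (1 - u_{n+1}) e^(-Δt/τ_rec) + 1 - e^(-Δt/τ_rec)
    a_{n+1} = u_{n+1} · R_{n+1}

first spike: u₁ = U, R₁ = 1 − U, hence a₁ = U(1−U). Note the ordering
convention: u updates first and the just-updated u enters R's depression
factor, and the transmitted efficiency uses the post-update pair. Defaults
U = 0.25, τ_facil = 500 ms, τ_rec = 300 ms, applied identically to every
connection (AMPA + NMDA of an excitatory projection scale together; GABA_A
of inhibitory projections the same way). Efficiency is evaluated at spike
*emission* time, not delivery time; the two differ when τ_D > 0.

**Bookkeeping.** The engine never sums over past events. Each neuron keeps
one onset and one offset accumulator per receptor; deliveries increment
both, each decays by exp(−dt/τ) per step, and their difference equals the
direct kernel sum at grid times to better than 1e−9 (tested). Because the
plasticity constants are global, all outgoing synapses of a neuron share
one (u, R) state, kept once per presynaptic neuron — an exact, not
approximate, consolidation.

## The column

2,000 neurons; layers L2/3 (1,000), L5 (600), L6 (400). The only counts
pinned by design are the total and the 900 L2/3 pyramidal cells, which
occupy ids 1–900 in row-major image order; everything else is a provisional
split (L2/3: 40 LL-IN, 20 BPC, 20 LBC, 20 MC; L5: 450 PC, 60 LL-IN, 30
each BPC/LBC/MC; L6 mirrors L5 at 2/3 scale) and config-overridable.

Connectivity is block-random: every ordered (pre, post) pair is connected
independently with the probability assigned to its (layer, class) block
pair by an ordered rule list (wildcards allowed, later rules win).
Autapses are off by default (a flag restores them). Excitatory sources
project AMPA+NMDA, inhibitory sources GABA_A. A parallel rule list assigns
per-projection conductance scales. Construction is deterministic per seed,
and the wiring depends only on the seed — the two species' columns built
from one seed are wired identically, so any behavioural difference is
attributable to the membrane tables.

**Membrane tables.** One row per (layer, class); LBC rows may be omitted
and then inherit the layer's PC entry (basket cells are
electrophysiologically PC-like); BPC/MC fall back to the LL-IN entry. The
bundled rodent and human tables are *constructed*, not measured: they
encode the qualitative species contrasts — human L5/L6 PC capacitance about
half the rodent value (150/130 vs 290/260 pF), human LL-IN capacitance
about double (120 vs 60 pF), human V_r and V_th depolarized by 3–6 mV
across classes — on top of generic cortical aEIF values. Swap in real
tables via the `aeif_tables` section or the CSV importer
(`layer, cell_class, C, g_L, E_L, V_r, V_th, Delta_T, tau_w, a, b`).

Background currents: 250 pA to excitatory cells, 200 pA to interneurons.
With the bundled tables these put every PC slightly *below* rheobase (so
the readout sheet is silent at rest) and the interneurons above it, which
is what makes the baseline state species-dependent: the rodent's
lower-threshold interneurons fire substantially faster at rest.

## Stimulation and readout

A 30×30 binary image maps pixel (r, c) to L2/3 PC id 30(r−1)+c. The four
bundled patterns (star, circle, square, triangle — 202/316/400/242 ON
pixels) are generated deterministically and also frozen as plain-text PBM
fixtures; any 30×30 PBM can be substituted.

Default stimulation is rate-coded: every ON-pixel neuron receives an
independent 50 Hz Poisson train of 1 ms, 1,150 pA current pulses throughout
the 201–300 ms retention window, while the output is read from spikes in
the closed 202–300 ms window (pixel ON iff ≥1 spike). The amplitude is
deliberately *marginal*: about 7.7 mV of depolarization against a ~8 mV
gap to threshold, so whether a pulse converts to a spike depends on the
concurrent synaptic state — that is what makes the assay sensitive to the
inhibitory tone and hence to the species tables. A deterministic
single-rectangle mode (`pulse`) is also provided; note that with a 1 ms
pulse ending before the decode window opens, a randomly-wired column
retains no pattern-specific signal (stimulated and unstimulated cells see
identically distributed recurrent input afterwards, and the per-neuron
aftereffects of one spike are all refractory-like), so that mode's decoded
output is pattern-free. The rate-coded default is the configuration under
which "persistent activity" is operationally measured here: maintained,
selective firing under ongoing low-rate drive, shaped by the recurrent
network.

Salt-and-pepper noise flips exactly round(900·p) distinct uniformly chosen
pixels of the *input* image (the classic set-to-random-extreme variant is
behind a flag); accuracy is always scored against the clean pattern.

## Metrics and statistics

* Spike density: network spikes per ms in a window (baseline 100–200 ms,
  persistent activity 200–300 ms).
* Excited-neuron ratio: % of stimulated neurons with post ≥ 1.5 × pre
  counts *and* post > pre over the equal-length pre/post windows. The
  zero-baseline edge case is resolved as: silent→silent is not excited,
  silent→any firing is (any increase from zero exceeds 50%). The
  denominator is the stimulated (ON-pixel) set, not all 900 cells.
* Transfer accuracy: % pixelwise agreement (both ON→spiking and
  OFF→silent count), i.e. 100·(1 − normalized Hamming distance).
* Summaries: mean ± SEM (sd/√n, ddof = 1) per group over nine independent
  repeats by default; one-way ANOVA across groups; stars at 0.05 / 0.01 /
  0.0001. Repeats redraw both the wiring and the stimulus randomness (each
  can be frozen separately); all streams derive from one master seed.

## Experiments

`run_species_comparison` swaps tables on identical wiring;
`morph_single_param` moves one membrane parameter (optionally scoped to
chosen layer/class entries) between species, with a multiplicative probe
for threshold excursions expressed as scaling the E_L→V_th distance;
`sweep_background` shifts the (PC, IN) background pairs, default (250,200),
(300,250), (200,150) pA; `sweep_std_recovery` substitutes τ_rec globally,
default grid 144–536 ms bracketing the fast/slow depression-recovery
regimes (accuracy is reported without any monotonicity assumption — the
dependence is genuinely non-monotone); `noise_robustness` sweeps the flip
proportion.

The response surface regresses mean assay accuracy on five normalized
parameters — C_L5PC, C_L6PC and the three layers' LL-IN thresholds — each
mapped linearly so the rodent value is 0 and the human value 1. Samples
come from a seeded Latin hypercube (default 30 points) rather than a full
factorial; the model has no cross terms, so the fit is ordinary least
squares in the monomial basis. An iterative least-squares mode initialized
at 1 is kept for parity and agrees with OLS to solver precision. A
vertex-form rewriter exposes each parameter's parabola axis
γ(x − x_v)².

## What the defaults do and do not show

Everything quantitative here depends on the provisional tables,
probabilities and stimulus waveform. The bundled configuration was
calibrated — by scanning the synaptic conductances (final values AMPA 0.8,
NMDA 0.6, GABA_A 12 nS), the pulse amplitude, and the cross-layer
probabilities (descending L2/3→L5/L6 PC 0.20/0.12 at 2× weight, ascending
feedback 0.02/0.01) — until the column sits in the regime where the four
qualitative species contrasts hold with margin across seeds and patterns:
human baseline density lower, human persistent-activity density and
excited ratio higher, and accuracy degrading with input noise. The
mechanism is consistent throughout: the rodent column's low-threshold
interneurons impose a strong inhibitory tone that suppresses marginal
pulse responses, while the human column's quieter interneurons and
low-capacitance deep pyramidal cells let the stimulus recruit the deep
layers. Absolute magnitudes (densities of a few tens of spikes/ms,
accuracies in the 90s) should not be read as predictions; directional
contrasts, and the machinery for recomputing them under better-measured
tables, are the deliverable. The synthetic patterns are noise-free
geometric bitmaps; real stimuli, neuromodulation, structured (distance-
dependent) connectivity, layer 4, and synaptic parameter differences
between species are all outside the model.

## Problem sizes

Defaults throughout were chosen for a desk-scale machine: 300 ms of
simulated time per run, 2,000 neurons, ~260k synapses, nine repeats per
condition (a full two-species, four-pattern comparison is 72 runs and
takes on the order of a minute on one CPU core with the numba engine). The
response surface defaults to 30 Latin-hypercube samples × 3 repeats.
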