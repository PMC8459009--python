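# Default two-species column configuration.
#
# The architecture fixes the published constraints exactly: 2,000 neurons
# total and 900 L2/3 pyramidal cells (ids 1-900).  The per-layer totals
# (L2/3 = 1000, L5 = 600, L6 = 400) and the within-layer interneuron splits
# are PROVISIONAL estimates from the rodent-PFC literature ratios; every
# count can be overridden.  L6 mirrors the L5 structure.
#
# Membrane tables are likewise provisional: they are constructed to satisfy
# the qualitative species contrasts (human L5/L6 PC capacitance about half
# the rodent value, human LL-IN capacitance about twice, human V_r and V_th
# higher throughout) rather than copied from any single dataset.  Swap in
# measured tables via CSV import for quantitative work.

architecture:
  layers:
    "L2/3": {PC: 900, LL-IN: 40, BPC: 20, LBC: 20, MC: 20}
    "L5":   {PC: 450, LL-IN: 60, BPC: 30, LBC: 30, MC: 30}
    "L6":   {PC: 300, LL-IN: 40, BPC: 20, LBC: 20, MC: 20}

aeif_tables:
  rodent:
    "L2/3":
      PC:    {C: 150, g_L: 11, E_L: -70, V_r: -60, V_th: -44, Delta_T: 1.5, tau_w: 150, a: 2, b: 40}
      LL-IN: {C: 60,  g_L: 6,  E_L: -66, V_r: -60, V_th: -45, Delta_T: 1.0, tau_w: 20,  a: 0, b: 5}
      BPC:   {C: 50,  g_L: 5,  E_L: -66, V_r: -60, V_th: -45, Delta_T: 1.0, tau_w: 50,  a: 1, b: 10}
      MC:    {C: 70,  g_L: 5,  E_L: -66, V_r: -60, V_th: -45, Delta_T: 1.0, tau_w: 80,  a: 2, b: 15}
    "L5":
      PC:    {C: 290, g_L: 11, E_L: -70, V_r: -60, V_th: -44, Delta_T: 1.5, tau_w: 150, a: 2, b: 40}
      LL-IN: {C: 60,  g_L: 6,  E_L: -66, V_r: -60, V_th: -45, Delta_T: 1.0, tau_w: 20,  a: 0, b: 5}
      BPC:   {C: 50,  g_L: 5,  E_L: -66, V_r: -60, V_th: -45, Delta_T: 1.0, tau_w: 50,  a: 1, b: 10}
      MC:    {C: 70,  g_L: 5,  E_L: -66, V_r: -60, V_th: -45, Delta_T: 1.0, tau_w: 80,  a: 2, b: 15}
    "L6":
      PC:    {C: 260, g_L: 11, E_L: -70, V_r: -60, V_th: -44, Delta_T: 1.5, tau_w: 150, a: 2, b: 40}
      LL-IN: {C: 60,  g_L: 6,  E_L: -66, V_r: -60, V_th: -45, Delta_T: 1.0, tau_w: 20,  a: 0, b: 5}
      BPC:   {C: 50,  g_L: 5,  E_L: -66, V_r: -60, V_th: -45, Delta_T: 1.0, tau_w: 50,  a: 1, b: 10}
      MC:    {C: 70,  g_L: 5,  E_L: -66, V_r: -60, V_th: -45, Delta_T: 1.0, tau_w: 80,  a: 2, b: 15}
  human:
    "L2/3":
      PC:    {C: 140, g_L: 11, E_L: -70, V_r: -57, V_th: -42, Delta_T: 1.5, tau_w: 150, a: 2, b: 40}
      LL-IN: {C: 120, g_L: 6,  E_L: -66, V_r: -56, V_th: -39, Delta_T: 1.0, tau_w: 20,  a: 0, b: 5}
      BPC:   {C: 60,  g_L: 5,  E_L: -66, V_r: -57, V_th: -42, Delta_T: 1.0, tau_w: 50,  a: 1, b: 10}
      MC:    {C: 80,  g_L: 5,  E_L: -66, V_r: -57, V_th: -42, Delta_T: 1.0, tau_w: 80,  a: 2, b: 15}
    "L5":
      PC:    {C: 150, g_L: 11, E_L: -70, V_r: -57, V_th: -42, Delta_T: 1.5, tau_w: 150, a: 2, b: 40}
      LL-IN: {C: 120, g_L: 6,  E_L: -66, V_r: -56, V_th: -39, Delta_T: 1.0, tau_w: 20,  a: 0, b: 5}
      BPC:   {C: 60,  g_L: 5,  E_L: -66, V_r: -57, V_th: -42, Delta_T: 1.0, tau_w: 50,  a: 1, b: 10}
      MC:    {C: 80,  g_L: 5,  E_L: -66, V_r: -57, V_th: -42, Delta_T: 1.0, tau_w: 80,  a: 2, b: 15}
    "L6":
      PC:    {C: 130, g_L: 11, E_L: -70, V_r: -57, V_th: -42, Delta_T: 1.5, tau_w: 150, a: 2, b: 40}
      LL-IN: {C: 120, g_L: 6,  E_L: -66, V_r: -56, V_th: -39, Delta_T: 1.0, tau_w: 20,  a: 0, b: 5}
      BPC:   {C: 60,  g_L: 5,  E_L: -66, V_r: -57, V_th: -42, Delta_T: 1.0, tau_w: 50,  a: 1, b: 10}
      MC:    {C: 80,  g_L: 5,  E_L: -66, V_r: -57, V_th: -42, Delta_T: 1.0, tau_w: 80,  a: 2, b: 15}

# Large basket cells (LBC) carry the PC parameters of their layer and are
# therefore omitted from the tables above.

synapses:
  AMPA:  {g_max: 0.8,  E_rev: 0.0,   tau_on: 0.2, tau_off: 2.0,   tau_D: 1.0}
  NMDA:  {g_max: 0.6,  E_rev: 0.0,   tau_on: 2.0, tau_off: 100.0, tau_D: 1.0}
  GABAA: {g_max: 12.0, E_rev: -70.0, tau_on: 0.5, tau_off: 8.0,   tau_D: 0.8}

stp: {U: 0.25, tau_facil: 500.0, tau_rec: 300.0}

connectivity:
  default: 0.0
  rules:
    # same-layer excitation: PCs onto every class of their own layer
    - {src_layer: "L2/3", src_class: PC, tgt_layer: "L2/3", p: 0.10}
    - {src_layer: "L5",   src_class: PC, tgt_layer: "L5",   p: 0.10}
    - {src_layer: "L6",   src_class: PC, tgt_layer: "L6",   p: 0.10}
    # cross-layer excitation (descending drive strong, ascending feedback weak)
    - {src_layer: "L2/3", src_class: PC, tgt_layer: "L5",   tgt_class: PC, p: 0.20}
    - {src_layer: "L2/3", src_class: PC, tgt_layer: "L6",   tgt_class: PC, p: 0.12}
    - {src_layer: "L5",   src_class: PC, tgt_layer: "L2/3", tgt_class: PC, p: 0.02}
    - {src_layer: "L5",   src_class: PC, tgt_layer: "L6",   tgt_class: PC, p: 0.06}
    - {src_layer: "L6",   src_class: PC, tgt_layer: "L5",   tgt_class: PC, p: 0.06}
    - {src_layer: "L6",   src_class: PC, tgt_layer: "L2/3", tgt_class: PC, p: 0.01}
    # local inhibition: LL-INs onto every class of their own layer
    - {src_layer: "L2/3", src_class: LL-IN, tgt_layer: "L2/3", p: 0.25}
    - {src_layer: "L5",   src_class: LL-IN, tgt_layer: "L5",   p: 0.25}
    - {src_layer: "L6",   src_class: LL-IN, tgt_layer: "L6",   p: 0.25}
    # cross-layer interneurons: bipolar cells target interneurons of other
    # layers (disinhibitory motif)
    - {src_class: BPC, tgt_class: LL-IN, p: 0.10}
    - {src_class: BPC, tgt_class: MC,    p: 0.10}
    # long-range interneurons: basket and Martinotti cells inhibit PCs of
    # every layer
    - {src_class: LBC, tgt_class: PC, p: 0.12}
    - {src_class: MC,  tgt_class: PC, p: 0.08}
  weight_rules:
    # the descending L2/3 -> deep-layer pathway carries stronger synapses
    - {src_layer: "L2/3", src_class: PC, tgt_layer: "L5", tgt_class: PC, scale: 2.0}
    - {src_layer: "L2/3", src_class: PC, tgt_layer: "L6", tgt_class: PC, scale: 2.0}
  allow_autapses: false

background_currents: {excitatory: 250.0, inhibitory: 200.0}

# Rate-coded stimulation: ON-pixel L2/3 PCs receive independent 50 Hz
# Poisson trains of 1 ms, 2000 pA current pulses throughout the 201-300 ms
# retention window, during which the output is read out.
stimulus: {onset: 201.0, duration: 99.0, amplitude: 1150.0, mode: poisson50, poisson_rate: 50.0, pulse_width: 1.0}

assay:
  t_end: 300.0
  baseline_window: [100.0, 200.0]
  pa_window: [200.0, 300.0]
  decode_window: [202.0, 300.0]
  n_repeats: 9

simulation: {dt: 0.05, exp_clamp: 10.0, canonical_exp_term: false}
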