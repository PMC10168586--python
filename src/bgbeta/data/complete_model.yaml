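# Canonical parameterization of the basal-ganglia network ("Complete Model").
#
# populations: reference size and point-neuron model of each nucleus.
# neuron_params: per-population membrane, synaptic, adaptation and drive
#   parameters.  Units: C_m pF; E_* mV; tau_* ms; V_* mV; I_e pA; a nS
#   (FSN: nS/mV^2); b pA; Delta_T mV; g_L nS; k nS/mV; nu_ext kHz;
#   dev_ext_weight nS.
# connections: random-connectivity table.  Each internal row is an
#   independent Bernoulli(p) trial per ordered (source, target) neuron pair;
#   "ext" rows (p = 1, delay 0) are the per-neuron Poisson drives.

populations:
  D1:   {size: 6000, model: aqif}
  D2:   {size: 6000, model: aqif}
  FSN:  {size: 420,  model: aqif2}
  GPTA: {size: 264,  model: aeif}
  GPTI: {size: 780,  model: aeif}
  STN:  {size: 408,  model: aeif}

neuron_params:
  D1:
    C_m: 15.2
    E_L: -78.2
    E_ex: 0.0
    E_in: -74.0
    tau_ex: 12.0
    tau_in: 10.0
    V_th: -29.7
    I_e: 0.0
    t_ref: 0.0
    V_reset: -60.0
    a: -20.0
    b: 67.0
    tau_w: 100.0
    V_peak: 40.0
    k: 1.0
    nu_ext: 1.12
    dev_ext_weight: 0.05
  D2:
    C_m: 15.2
    E_L: -80.0
    E_ex: 0.0
    E_in: -74.0
    tau_ex: 12.0
    tau_in: 10.0
    V_th: -29.7
    I_e: 0.0
    t_ref: 0.0
    V_reset: -60.0
    a: -20.0
    b: 91.0
    tau_w: 100.0
    V_peak: 40.0
    k: 1.0
    nu_ext: 1.083
    dev_ext_weight: 0.05
  FSN:
    C_m: 80.0
    E_L: -80.0
    E_ex: 0.0
    E_in: -74.0
    tau_ex: 12.0
    tau_in: 10.0
    V_th: -50.0
    I_e: 0.0
    t_ref: 0.0
    V_reset: -60.0
    a: 0.025
    b: 0.0
    tau_w: 5.0
    V_peak: 25.0
    k: 1.0
    V_b: -55.0
    nu_ext: 0.944
    dev_ext_weight: 0.05
  GPTI:
    C_m: 40.0
    E_L: -55.1
    E_ex: 0.0
    E_in: -65.0
    tau_ex: 10.0
    tau_in: 5.5
    V_th: -54.7
    I_e: 12.0
    t_ref: 0.0
    V_reset: -60.0
    a: 2.5
    b: 70.0
    tau_w: 20.0
    V_peak: 15.0
    Delta_T: 1.7
    g_L: 1.0
    nu_ext: 1.53
    dev_ext_weight: 0.05
  GPTA:
    C_m: 60.0
    E_L: -55.1
    E_ex: 0.0
    E_in: -65.0
    tau_ex: 10.0
    tau_in: 5.5
    V_th: -54.7
    I_e: 1.0
    t_ref: 0.0
    V_reset: -60.0
    a: 2.5
    b: 105.0
    tau_w: 20.0
    V_peak: 15.0
    Delta_T: 2.55
    g_L: 1.0
    nu_ext: 0.17
    dev_ext_weight: 0.05
  STN:
    C_m: 60.0
    E_L: -80.2
    E_ex: 0.0
    E_in: -84.0
    tau_ex: 4.0
    tau_in: 8.0
    V_th: -64.0
    I_e: 5.0
    t_ref: 0.0
    V_reset: -70.0
    a: 0.0
    b: 0.05
    tau_w: 333.0
    V_peak: 15.0
    Delta_T: 16.2
    g_L: 10.0
    nu_ext: 0.5
    dev_ext_weight: 0.05

connections:
  - {source: D1,   target: D1,   p: 0.0607, delay: 1.7, sign: I, weight: 0.12}
  - {source: D1,   target: D2,   p: 0.0140, delay: 1.7, sign: I, weight: 0.30}
  - {source: D2,   target: D1,   p: 0.0653, delay: 1.7, sign: I, weight: 0.36}
  - {source: D2,   target: D2,   p: 0.0840, delay: 1.7, sign: I, weight: 0.20}
  - {source: D2,   target: GPTI, p: 0.0833, delay: 7.0, sign: I, weight: 1.28}
  - {source: FSN,  target: D1,   p: 0.0381, delay: 1.7, sign: I, weight: 6.60}
  - {source: FSN,  target: FSN,  p: 0.0238, delay: 1.0, sign: I, weight: 0.50}
  - {source: FSN,  target: D2,   p: 0.0262, delay: 1.7, sign: I, weight: 4.80}
  - {source: GPTI, target: GPTI, p: 0.0321, delay: 1.0, sign: I, weight: 1.20}
  - {source: GPTI, target: GPTA, p: 0.0321, delay: 1.0, sign: I, weight: 0.35}
  - {source: GPTI, target: FSN,  p: 0.0128, delay: 7.0, sign: I, weight: 1.60}
  - {source: GPTI, target: STN,  p: 0.0385, delay: 1.0, sign: I, weight: 0.08}
  - {source: GPTA, target: D1,   p: 0.0379, delay: 7.0, sign: I, weight: 0.35}
  - {source: GPTA, target: D2,   p: 0.0379, delay: 7.0, sign: I, weight: 0.61}
  - {source: GPTA, target: FSN,  p: 0.0379, delay: 7.0, sign: I, weight: 1.85}
  - {source: GPTA, target: GPTA, p: 0.0189, delay: 1.0, sign: I, weight: 0.35}
  - {source: GPTA, target: GPTI, p: 0.0189, delay: 1.0, sign: I, weight: 1.20}
  - {source: STN,  target: GPTA, p: 0.0735, delay: 2.0, sign: E, weight: 0.13}
  - {source: STN,  target: GPTI, p: 0.0735, delay: 2.0, sign: E, weight: 0.42}
  - {source: ext,  target: D1,   p: 1.0,    delay: 0.0, sign: E, weight: 0.45}
  - {source: ext,  target: D2,   p: 1.0,    delay: 0.0, sign: E, weight: 0.45}
  - {source: ext,  target: FSN,  p: 1.0,    delay: 0.0, sign: E, weight: 0.50}
  - {source: ext,  target: GPTI, p: 1.0,    delay: 0.0, sign: E, weight: 0.25}
  - {source: ext,  target: GPTA, p: 1.0,    delay: 0.0, sign: E, weight: 0.15}
  - {source: ext,  target: STN,  p: 1.0,    delay: 0.0, sign: E, weight: 0.25}

# Target per-population mean-rate windows (Hz) used for calibration checks.
rate_windows:
  D1:   [0.5, 2.5]
  D2:   [0.5, 2.5]
  FSN:  [10.0, 20.0]
  GPTA: [5.0, 15.0]
  GPTI: [40.0, 60.0]
  STN:  [12.0, 20.0]
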