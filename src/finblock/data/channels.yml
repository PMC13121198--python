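# Channel kinetics and region mechanism bindings (rates in 1/ms, V in mV).
#
# Rate-law forms (singularity-removed where applicable):
#   linoid : a*(v-vh) / (1 - exp(-(v-vh)/k)); limit a*k at v == vh
#   exp    : a * exp((v-vh)/k)
#   sigmoid: a / (1 + exp(-(v-vh)/k))
#
# Front-end channels are Fohlmeister-Miller-style retinal ganglion cell
# kinetics (fast Na, delayed-rectifier K, inactivating A-type K); nodal
# channels are MRG-style mammalian axon kinetics at body temperature
# (fast Na m3h, persistent Na p3, slow K s).  Maximal conductances were
# calibrated so the ON 1.4-um fibre fires a stable ~120 Hz train under the
# standard 0.13 nA soma step (see docs/methods.md).
version: finblock-channels-1

channels:
  na_rgc:
    erev: 35.0
    gates:
      m:
        power: 3
        alpha: {form: linoid, a: 0.6, vh: -30.0, k: 10.0}
        beta: {form: exp, a: 20.0, vh: -55.0, k: -18.0}
      h:
        power: 1
        alpha: {form: exp, a: 0.4, vh: -50.0, k: -20.0}
        beta: {form: sigmoid, a: 6.0, vh: -20.0, k: 10.0}
  kdr_rgc:
    erev: -75.0
    gates:
      n:
        power: 4
        alpha: {form: linoid, a: 0.02, vh: -40.0, k: 10.0}
        beta: {form: exp, a: 0.4, vh: -50.0, k: -80.0}
  ka_rgc:
    erev: -75.0
    gates:
      a:
        power: 3
        alpha: {form: linoid, a: 0.006, vh: -90.0, k: 10.0}
        beta: {form: exp, a: 0.1, vh: -30.0, k: -10.0}
      ha:
        power: 1
        alpha: {form: exp, a: 0.04, vh: -70.0, k: -20.0}
        beta: {form: sigmoid, a: 0.6, vh: -40.0, k: 10.0}
  naf_node:
    erev: 50.0
    gates:
      m:
        power: 3
        alpha: {form: linoid, a: 6.57, vh: -20.4, k: 10.3}
        beta: {form: linoid, a: -0.304, vh: -25.7, k: -9.16}
      h:
        power: 1
        alpha: {form: linoid, a: -0.34, vh: -114.0, k: -11.0}
        beta: {form: sigmoid, a: 12.6, vh: -31.8, k: 13.4}
  nap_node:
    erev: 50.0
    gates:
      p:
        power: 3
        alpha: {form: linoid, a: 0.0353, vh: -27.0, k: 10.2}
        beta: {form: linoid, a: -0.000883, vh: -34.0, k: -10.0}
  ks_node:
    erev: -90.0
    gates:
      s:
        power: 1
        alpha: {form: sigmoid, a: 0.3, vh: -53.0, k: 5.0}
        beta: {form: sigmoid, a: 0.03, vh: -90.0, k: 1.0}

# Per-region mechanism sets: membrane capacitance (uF/cm2), leak
# (S/cm2, mV) and maximal channel conductances (S/cm2).
mechanisms:
  dendrite:
    cm: 1.0
    g_leak: 5.0e-5
    e_leak: -58.0
    channels: {na_rgc: 0.030, kdr_rgc: 0.012, ka_rgc: 0.011}
  soma:
    cm: 1.0
    g_leak: 5.0e-5
    e_leak: -58.0
    channels: {na_rgc: 0.105, kdr_rgc: 0.018, ka_rgc: 0.016}
  AH:
    cm: 1.0
    g_leak: 5.0e-5
    e_leak: -58.0
    channels: {na_rgc: 0.225, kdr_rgc: 0.030, ka_rgc: 0.016}
  AIS:
    cm: 1.0
    g_leak: 5.0e-5
    e_leak: -58.0
    channels: {na_rgc: 1.050, kdr_rgc: 0.100}
  DA:
    cm: 1.0
    g_leak: 5.0e-5
    e_leak: -58.0
    channels: {na_rgc: 0.150, kdr_rgc: 0.050}
  node:
    cm: 2.0
    g_leak: 0.007
    e_leak: -90.0
    channels: {naf_node: 3.0, nap_node: 0.01, ks_node: 0.08}
  # Myelinated regions: passive axolemma only (nodal regions carry the
  # active channels in mammalian optic nerve fibre models).
  PN:
    cm: 2.0
    g_leak: 1.0e-3
    e_leak: -80.0
    channels: {}
  JN:
    cm: 2.0
    g_leak: 1.0e-4
    e_leak: -80.0
    channels: {}
  IN:
    cm: 2.0
    g_leak: 1.0e-4
    e_leak: -80.0
    channels: {}

# MRG-style double-cable passive elements for the myelinated regions:
# per-lamella-membrane myelin capacitance/conductance (uF/cm2, S/cm2),
# periaxonal-space width (um) and axial resistivity (ohm cm; also used
# for the axoplasm).
double_cable:
  mycm_per_lamella: 0.1
  mygm_per_lamella: 0.001
  rho_axial_ohm_cm: 70.0
  periaxonal_width_um: {node: 0.002, PN: 0.002, JN: 0.004, IN: 0.004}
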