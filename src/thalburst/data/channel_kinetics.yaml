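# Frozen channel-kinetics parameter sets, version 1.
#
# One block per membrane mechanism.  The low-threshold (T-type) calcium
# current and submembranal calcium decay follow the classic thalamocortical
# relay-cell formulation (GHK flux, m^2 h open probability, +2 mV screening
# shift); the resting-potential channel set (Ih, IA, IKir, INaP) follows the
# canonical TC-neuron resting-conductance models; the fast spiking currents
# are Traub-style sodium/potassium rate equations with a shifted threshold.
# The reticular-cell T current (ITs) uses the slower reticular kinetics.
# All voltages in mV, time constants in ms, temperatures in deg C.
version: 1
IT:
  shift: 2.0            # screening-charge shift added to V
  m_vhalf: -57.0
  m_slope: 6.2
  h_vhalf: -81.0
  h_slope: 4.0
  q10_m: 3.6
  q10_h: 2.8
  t_ref: 24.0
IT_RT:                  # reticular-cell variant (single-compartment RT model)
  shift: 0.0
  m_vhalf: -52.0
  m_slope: 7.4
  h_vhalf: -80.0
  h_slope: 5.0
  q10_m: 5.0
  q10_h: 3.0
  t_ref: 24.0
Ih:
  vhalf: -82.0
  slope: 5.49
  e_rev: -43.0
Ia:
  q10: 2.8
  t_ref: 23.5
IKir:
  vhalf: -97.9
  slope: 9.7
INaP:
  vhalf: -57.9
  slope: 6.4
NaK_spk:
  vtraub_tc: -65.0      # shifted spike threshold for TC somata
  vtraub_rt: -55.0
  q10: 3.0
  t_ref: 36.0
Cadecay:
  depth_um: 0.1         # submembranal shell depth
  tau_ms: 5.0           # extrusion time constant
  ca_rest_mM: 2.4e-4    # 240 nM resting internal calcium
ions:
  e_k: -100.0
  e_na: 88.0
  cao_mM: 2.0
  cai0_mM: 2.4e-4
  temperature: 33.0
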