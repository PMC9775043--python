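# Golgi-cell model: five compartments (spherical soma, three dendrites, one
# axon), all active conductances somatic, passive membrane elsewhere.  The
# printed geometry with 1 uF/cm^2 specific capacitance (the printed "1
# mF/cm^2" is read as the standard 1 uF/cm^2) yields ~23 / ~32 / ~90 pF for
# soma / dendrites / axon, summing to ~145 pF.
#
# The active conductance magnitudes are not printed; the somatic set below
# (with a persistent-Na current and a Ca-gated K surrogate for the AHP
# current) is tuned once to sustain spontaneous pacemaker firing at a few
# tens of Hz, the qualitative behaviour of the source model.
name: goc
temperature: 30.0
t_orig: 30.0
v_init: -60.0
cm_specific_uF_cm2: 1.0
axial_resistivity_ohm_cm: 100.0
rm_kohm_cm2: 47.6
e_leak_mV: -55.0       # depolarised passive reversal drives pacemaking
soma:
  diameter_um: 27.0
dendrites:
  count: 3
  length_um: 113.0
  diameter_um: 3.0
axon:
  length_um: 1200.0
  diameter_um: 2.4
calcium:
  beta_per_ms: 0.6
channels:              # absolute somatic conductances (nS)
  Na:     {gbar_nS: 900.0}
  Na_p:   {gbar_nS: 6.0}
  K_DR:   {gbar_nS: 350.0}
  K_A:    {gbar_nS: 60.0}
  Ca:     {gbar_nS: 20.0}
  K_Ca:   {gbar_nS: 100.0}
  K_slow: {gbar_nS: 10.0}
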