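# Tissue-factor (extrinsic) pathway reaction table and plasma baselines.
#
# The network tracks the nine proteins of the extrinsic coagulation cascade
# (TF, FII, FV, FVII, FVIII, FIX, FX, fibrinogen, TFPI) and their active
# forms and complexes.  Rate constants follow the Hockin-Mann lineage of
# TF-pathway models and standard enzyme-kinetics literature; second-order
# constants are given in 1/(nM s), catalytic constants in 1/s, Michaelis
# constants in nM.  The contact (FXII) pathway is absent: the experiments
# this model mirrors inhibit it with corn trypsin inhibitor.
#
# version: 1

plasma_baselines_nM:
  VII: 10.0
  VIIa: 0.1        # ~1% of FVII circulates activated
  IX: 90.0
  IXa: 0.0
  X: 170.0
  Xa: 0.0
  II: 1400.0
  IIa: 0.0
  V: 20.0
  Va: 0.0
  VIII: 0.7
  VIIIa: 0.0
  tenase: 0.0      # IXa:VIIIa
  prothrombinase: 0.0  # Xa:Va
  fibrinogen: 9000.0
  fibrin: 0.0
  TFPI: 2.5
  Xa_TFPI: 0.0

rate_constants:
  # thrombin feedback activation (mass action, 1/(nM s))
  k_v_by_iia: 2.0e-2
  k_viii_by_iia: 2.0e-2
  k_vii_by_iia: 2.3e-5
  k_vii_by_xa: 1.3e-2
  # fluid-phase prothrombin activation by Xa (slow)
  k_ii_by_xa: 7.5e-6
  # intrinsic tenase IXa:VIIIa
  kon_tenase: 1.0e-2       # 1/(nM s)
  koff_tenase: 5.0e-3      # 1/s
  kcat_tenase_x: 8.2       # 1/s
  km_tenase_x: 63.0        # nM
  # prothrombinase Xa:Va
  kon_prothrombinase: 0.4  # 1/(nM s)
  koff_prothrombinase: 0.2 # 1/s
  kcat_prothrombinase: 30.0
  km_prothrombinase: 300.0
  # fibrinogen -> fibrin by thrombin
  kcat_fibrin: 59.0
  km_fibrin: 7200.0
  # TFPI inhibition of Xa
  kon_tfpi_xa: 9.0e-4
  koff_tfpi_xa: 3.6e-4

# Phospholipid availability: tenase / prothrombinase assembly requires the
# procoagulant membrane of deposited platelets.  Assembly rates scale with
# min(1, phi_bound / phi_ref).
platelet_surface:
  phi_ref: 0.01
  # fibrin polymer must anchor to the platelet aggregate: deposition ramps
  # linearly from zero at phi_fibrin_on (sparse fringe, fibrin washes out)
  # to full rate at phi_fibrin_full
  phi_fibrin_on: 0.03
  phi_fibrin_full: 0.12

surface_reactions:
  # Thrombogenic-patch chemistry, surface species in mol/m^2.
  # Second-order constants in 1/(M s) (act on near-wall concentrations).
  kon_tf_vii: 3.2e6
  koff_tf_vii: 3.1e-3
  kon_tf_viia: 2.3e7
  koff_tf_viia: 3.1e-3
  k_tfvii_act_by_xa: 2.3e7     # TF:VII + Xa -> TF:VIIa
  k_tfviia_inhib: 3.2e8        # TF:VIIa + Xa:TFPI -> dead complex
  kcat_x: 6.0                  # TF:VIIa activating X, 1/s
  km_x: 238.0                  # nM
  kcat_ix: 2.4
  km_ix: 243.0

# Brownian diffusivities (m^2/s) by transport class; the shear-dependent
# red-cell augmentation is added on top (Zydney-Colton form).
diffusivity:
  protein: 5.0e-11
  fibrinogen: 3.1e-11
  platelet: 1.6e-13
shear_enhancement:
  k_sh: 0.15
  rbc_radius_um: 2.75
  hematocrit: 0.4
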