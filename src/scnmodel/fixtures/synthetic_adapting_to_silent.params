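# scnmodel-params v1
# synthetic stand-in: adapting-to-silent cell -- an even weaker potassium
# current fails to repolarize the membrane under a +30 pA pulse, so sodium
# stays inactivated and firing ceases after the initial spikes; calibrated
# within this package, not transcribed
C_pF = 5.7
gNa_nS = 30.0
gK_nS = 28.0
gCa_nS = 0.5
gLNa_nS = 0.15140845070422534
gLK_nS = 0.3485915492957746
gH_nS = 0.0
gA_nS = 0.0
gsynE_nS = 0.0
gsynI_nS = 0.0
ENa_mV = 45.0
EK_mV = -97.0
ECa_mV = 54.0
EH_mV = -35.0
EsynE_mV = 0.0
EsynI_mV = -85.0
sf_gA = 1.0
sf_tau_hA = 1.0
sf_leak = 1.0
mNa_vhalf_mV = -34.0
mNa_dv_mV = 8.0
mNa_instantaneous = true
hNa_vhalf_mV = -42.0
hNa_dv_mV = -7.0
hNa_tau0_ms = 0.3
hNa_tau1_ms = 140.0
n_vhalf_mV = -13.0
n_dv_mV = 62.0
n_tau0_ms = 1.2
n_tau1_ms = 1.5
mCa_vhalf_mV = -42.0
mCa_dv_mV = 7.0
mCa_tau0_ms = 1.0
mCa_tau1_ms = 1.0
hCa_vhalf_mV = -50.0
hCa_dv_mV = -7.0
hCa_tau0_ms = 300.0
hCa_tau1_ms = 200.0
mH_vhalf_mV = -75.0
mH_dv_mV = -9.0
mH_tau0_ms = 200.0
mH_tau1_ms = 300.0
mA_vhalf_mV = -45.0
mA_dv_mV = 12.0
mA_instantaneous = true
hA_vhalf_mV = -55.0
hA_dv_mV = -10.0
hA_tau0_ms = 140.0
hA_tau1_ms = 50.0
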