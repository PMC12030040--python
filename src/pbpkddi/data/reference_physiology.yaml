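# Reference healthy-adult physiology, version 1.
# Standard literature values for a 70-kg healthy volunteer; these stand in
# for the (proprietary) population database of commercial PBPK platforms and
# are the anchor for all packaged fixture calibrations.
version: 1
body_weight: 70.0          # kg
hepatic_blood_flow: 90.0   # L/h  (~1.5 L/min total hepatic blood flow)
gfr: 7.2                   # L/h  (120 mL/min)
liver_weight: 1650.0       # g
mppgl: 40.0                # mg microsomal protein per g liver
hematocrit: 0.45
plasma_volume_fraction: 0.0436   # L plasma per kg body weight
enzyme_activity:
  UGT1A1: 1.0
  UGT1A9: 1.0
  hepatic_unassigned: 1.0
transporter_activity:
  OAT1: 1.0
  OAT3: 1.0
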