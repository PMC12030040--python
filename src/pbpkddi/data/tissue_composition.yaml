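# Tissue composition table for mechanistic Kp / Vss prediction, version 1.
# Fractional tissue volumes of extracellular water (f_ew), intracellular
# water (f_iw), neutral lipid (f_nl) and neutral phospholipid (f_np),
# tissue:plasma albumin ratios (ra) and tissue volumes as fraction of body
# weight (v, L/kg), from the published tissue-composition literature.
#
# albumin_accessibility is a single documented calibration constant applied
# to all tissue albumin ratios: interstitial albumin is only partially
# available for binding relative to plasma. Calibrated once against the
# reference acidic compound (predicted Vss 0.12 L/kg at Kp scalar 1.5) and
# frozen with this table version.
version: 1
ph_plasma: 7.4
ph_intracellular: 7.0
plasma_f_nl: 0.0023
plasma_f_np: 0.0013
albumin_accessibility: 0.708
tissues:
  adipose: {f_ew: 0.135, f_iw: 0.017, f_nl: 0.853,  f_np: 0.0016, ra: 0.049, v: 0.2137}
  bone:    {f_ew: 0.100, f_iw: 0.346, f_nl: 0.017,  f_np: 0.0017, ra: 0.100, v: 0.0856}
  brain:   {f_ew: 0.162, f_iw: 0.620, f_nl: 0.039,  f_np: 0.0015, ra: 0.048, v: 0.0200}
  gut:     {f_ew: 0.282, f_iw: 0.475, f_nl: 0.038,  f_np: 0.0125, ra: 0.158, v: 0.0171}
  heart:   {f_ew: 0.320, f_iw: 0.456, f_nl: 0.014,  f_np: 0.0111, ra: 0.157, v: 0.0047}
  kidney:  {f_ew: 0.273, f_iw: 0.483, f_nl: 0.012,  f_np: 0.0242, ra: 0.130, v: 0.0044}
  liver:   {f_ew: 0.161, f_iw: 0.573, f_nl: 0.014,  f_np: 0.0240, ra: 0.086, v: 0.0257}
  lung:    {f_ew: 0.336, f_iw: 0.446, f_nl: 0.022,  f_np: 0.0128, ra: 0.212, v: 0.0076}
  muscle:  {f_ew: 0.118, f_iw: 0.630, f_nl: 0.010,  f_np: 0.0072, ra: 0.064, v: 0.4000}
  skin:    {f_ew: 0.382, f_iw: 0.291, f_nl: 0.060,  f_np: 0.0044, ra: 0.277, v: 0.0371}
  spleen:  {f_ew: 0.207, f_iw: 0.579, f_nl: 0.0077, f_np: 0.0113, ra: 0.097, v: 0.0026}
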