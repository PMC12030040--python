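# Cabotegravir oral compound file, version 1.
#
# Physicochemistry, in vitro CLint and Ki values are the measured inputs of
# the published oral cabotegravir model. Four constants are package
# calibrations, fixed once against the printed clinical anchors and never
# re-fit at run time:
#   - per-enzyme ISEFs (0.3863 / 0.4687) and the unassigned hepatic CLint
#     (0.3113 uL/min/mg) set so that CL/F = 0.140 L/h with
#     fm(UGT1A1)=0.59, fm(UGT1A9)=0.35 on the reference subject;
#   - direct renal clearance 0.001 L/h, consistent with <1% of dose
#     excreted unchanged;
#   - Weibull dissolution (scale 0.4 h, shape 1.0) with ka derived from
#     Papp (0.1 x 25.6 = 2.56 1/h), set so single-dose Tmax falls in the
#     observed 2-3 h window (the measured dissolution curve is unpublished).
schema_version: 1
name: cabotegravir
molecular_weight: 405.4
logp: 1.58
compound_type: monoprotic-acid
pka1: 7.71
blood_plasma_ratio: 0.54
fu_plasma: 0.006
papp: 25.6
absorption:
  model: dissolution-limited
  weibull_scale_h: 0.4
  weibull_shape: 1.0
  ka_per_papp: 0.1
  fa: 1.0
  fg: 1.0
distribution:
  vss_mode: predicted
  kp_scalar: 1.5
  sac_kin: 0.03
  sac_kout: 0.07
elimination:
  enzyme_clints:
    UGT1A1: {clint: 4.5, fu_mic: 0.5, isef: 0.3863}
    UGT1A9: {clint: 2.2, fu_mic: 0.5, isef: 0.4687}
    hepatic_unassigned: {clint: 0.3113, fu_mic: 1.0, isef: 1.0}
  renal:
    mode: direct_clr
    clr_direct: 0.001
interaction:
  inhibition:
    OAT1: 0.405
    OAT3: 0.205
    UGT1A9: 23.0
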