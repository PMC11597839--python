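# RP-TLC calibration standards (acetone:Tris pH 7.4 mobile phases, RP-18
# plates): literature octanol-water logP, extrapolated R_M0, fitted slope
# magnitude (-b, per percent organic modifier) and per-compound fit r, plus
# the logP_TLC reported for each standard when treated as an unknown.
# The benzamide row is internally inconsistent with the published calibration
# (1.0587*0.9499 - 0.0267 = 0.98, not 0.66) and is flagged for exclusion.
compound_id,name,logp_lit,r_m0,minus_b,fit_r,logp_tlc_reported,flagged
A,benzamide,0.64,0.9499,0.0167,0.9902,0.66,1
B,acetanilide,1.21,1.2020,0.0228,0.9988,1.25,0
C,prednisone,1.62,1.6729,0.0302,0.9933,1.74,0
D,4-bromoacetophenone,2.43,2.4678,0.0340,0.9947,2.58,0
E,benzophenone,3.18,2.7252,0.0365,0.9979,2.86,0
F,anthracene,4.45,3.9213,0.0488,0.9947,4.12,0
G,dibenzyl,4.79,4.8432,0.0608,0.9910,5.10,0
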