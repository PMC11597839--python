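# Experimentally determined chromatographic lipophilicity (logP_TLC) of the
# fifteen triazole-aniline derivatives, from the calibrated RP-TLC experiment.
compound_id,logp_tlc
2a,1.24
2b,1.35
2c,1.15
3a,2.35
3b,2.30
3c,1.29
4a,2.66
4b,2.74
4c,1.67
5a,2.69
5b,2.62
5c,1.67
6a,3.23
6b,3.28
6c,2.26
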