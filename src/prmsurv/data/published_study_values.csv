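subject_id,compartment,conc_ng_ul,dilution_factor,normalized_conc_ng_ul,error_ng_ul,cv_pct
infant1,feed,38.10,1,38.10,1.11,5.84
infant1,gastric,32.26,1.004,32.41,0.31,1.91
infant1,intestinal,10.04,1.14,11.45,0.20,3.57
infant1,stool,N/D,0.45,,,
infant2,feed,18.66,1,18.66,0.29,3.12
infant2,gastric,11.70,1.25,14.67,0.30,4.08
infant2,intestinal,1.63,1.51,2.47,0.01,1.01
infant2,stool,1.97,1.14,2.25,0.005,0.44
infant3,feed,18.51,1,18.51,0.27,2.87
infant3,gastric,16.14,1.14,18.44,0.20,2.21
infant3,intestinal,5.48,1.30,7.14,0.08,2.34
infant3,stool,1.24,0.76,0.95,0.002,0.45
infant4,feed,16.17,1,16.17,0.47,5.81
infant4,gastric,14.42,1.01,14.57,0.36,4.90
infant4,intestinal,5.39,1.14,6.16,0.09,2.82
infant4,stool,0.65,1.23,0.80,0.02,3.30
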