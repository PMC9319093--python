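model_id,total_stars,lock_distance,auc
CIT_1,22.0,2.09,0.811
TTA_5,16.0,2.97,0.808
IT_1,11.5,2.41,0.797
PY3_10,4.0,1.94,0.791
TR_1,32.0,2.95,0.763
CF-DM,11.5,3.40,0.834
PF-DM,8.5,3.27,0.783
AF-DM,19.0,4.28,0.752
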