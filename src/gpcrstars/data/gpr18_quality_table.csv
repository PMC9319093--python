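model_id,errat,verify3d,prove,rama_core,rama_disallowed,labelled_residues,rwplus,molprobity,rosetta,dfire,goap,opus_psp,predicted_global_quality
AF-DM,99.3,53.06,2.9,95.2,0.0,0,-7935,0.650,-,-656.4,-,-,-
CF-DM,88.38,52.04,4.6,94.1,0.0,10,-7691,1.550,-,-634.9,-,-,-
PF-DM,95.71,44.56,5.4,93.0,0.4,11,-7673,1.460,-,-633.5,-,-,-
TR_1,100.0,70.75,2.9,95.6,0.0,1,-7987,0.880,-768.2,-654.3,-3713,-5913,0.255
TTA_5,98.25,60.88,2.8,93.7,1.1,10,-7769,1.223,-829.4,-639.2,-3606,-5426,0.270
CIT_1,100.0,70.41,3.1,92.6,0.4,2,-7829,1.297,-670.2,-642.0,-3487,-5876,0.237
IT_1,100.0,60.20,3.1,93.3,1.1,5,-7770,1.449,-589.7,-637.5,-3434,-5678,0.214
PY3_10,98.60,66.33,3.6,90.7,1.5,11,-7614,1.494,-595.3,-624.5,-3467,-5459,0.222
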