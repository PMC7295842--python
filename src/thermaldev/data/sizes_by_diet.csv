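diet,measure,mean,se,n
Calliphora_larvae,L3_length_mm,20.08,0.2,24
Calliphora_larvae,L3_weight_mg,65.75,2.38,24
Calliphora_larvae,pupal_weight_mg,174.72,4.28,23
Calliphora_larvae,adult_length_mm,20.38,0.28,21
Calliphora_larvae,adult_weight_mg,149.52,3.61,21
Calliphora_puparia,L3_length_mm,20.68,0.26,17
Calliphora_puparia,L3_weight_mg,71.17,3.9,17
Calliphora_puparia,pupal_weight_mg,184.86,9.12,16
Calliphora_puparia,adult_length_mm,20.66,0.37,16
Calliphora_puparia,adult_weight_mg,160.1,8.84,16
Lucilia_larvae,L3_length_mm,20.6,0.21,20
Lucilia_larvae,L3_weight_mg,69.63,1.96,20
Lucilia_larvae,pupal_weight_mg,176.24,4.08,20
Lucilia_larvae,adult_length_mm,20.35,0.28,17
Lucilia_larvae,adult_weight_mg,149.01,3.84,17
Lucilia_puparia,L3_length_mm,19.29,0.23,14
Lucilia_puparia,L3_weight_mg,59.71,1.76,14
Lucilia_puparia,pupal_weight_mg,169.67,4.25,14
Lucilia_puparia,adult_length_mm,20.65,0.25,13
Lucilia_puparia,adult_weight_mg,145.11,4.42,13
Necrodes_larvae,L3_length_mm,16.07,0.18,15
Necrodes_larvae,L3_weight_mg,28.19,0.97,15
Necrodes_larvae,pupal_weight_mg,58.6,15.75,2
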