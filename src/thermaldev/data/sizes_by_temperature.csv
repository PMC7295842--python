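temperature_C,measure,mean,se,n
10,L3_length_mm,16.85,0.21,10
10,L3_weight_mg,45.91,1.97,10
12.5,L3_length_mm,18.29,0.32,12
12.5,L3_weight_mg,56.67,2.79,12
15,L3_length_mm,20.53,0.36,20
15,L3_weight_mg,74.83,2.82,20
15,pupal_weight_mg,177.9,3.69,12
15,adult_length_mm,19.67,0.58,9
15,adult_weight_mg,147.69,4.29,9
17.5,L3_length_mm,20.28,0.29,16
17.5,L3_weight_mg,69.72,2.68,16
17.5,pupal_weight_mg,185.01,6.63,11
17.5,adult_length_mm,21.1,0.39,10
17.5,adult_weight_mg,158.83,6.01,10
20,L3_length_mm,19.88,0.26,20
20,L3_weight_mg,65.14,1.48,20
20,pupal_weight_mg,160.86,4.47,16
20,adult_length_mm,20.9,0.34,15
20,adult_weight_mg,140.73,4.14,15
22.5,L3_length_mm,19.78,0.29,20
22.5,L3_weight_mg,62.88,2.65,20
22.5,pupal_weight_mg,148.16,4.83,19
22.5,adult_length_mm,19.65,0.35,17
22.5,adult_weight_mg,127.72,3.95,17
25,L3_length_mm,19.39,0.12,19
25,L3_weight_mg,60.06,1.19,19
25,pupal_weight_mg,146.7,3.06,19
25,adult_length_mm,18.11,0.26,18
25,adult_weight_mg,124.65,2.6,18
27.5,L3_length_mm,18.6,0.29,20
27.5,L3_weight_mg,51.07,1.83,20
27.5,pupal_weight_mg,130.45,5.25,15
27.5,adult_length_mm,17.61,0.45,14
27.5,adult_weight_mg,114.57,8.04,14
30,L3_length_mm,19.13,0.44,19
30,L3_weight_mg,48.87,1.88,19
30,pupal_weight_mg,110.16,5.23,10
30,adult_length_mm,17.5,0.59,5
30,adult_weight_mg,94.56,2.48,5
32.5,L3_length_mm,17.5,0.25,18
32.5,L3_weight_mg,38.18,2.05,18
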