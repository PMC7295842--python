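temperature_C,stage,mean_d,se_d,n
10,egg,22.9,0.24,19
10,L1,12.9,0.54,9
10,L2,14.06,0.27,8
12.5,egg,16.58,0.18,25
12.5,L1,8.92,0.14,13
12.5,L2,9.89,0.22,14
15,egg,8.41,0.04,40
15,L1,4.99,0.1,20
15,L2,5.09,0.12,20
15,L3,67.74,10.81,5
15,pupa,24.97,1.83,5
15,total,122.21,6.63,4
17.5,egg,5.9,0.08,29
17.5,L1,4.05,0.14,14
17.5,L2,4.34,0.12,14
17.5,L3,42.74,4.51,11
17.5,pupa,19.11,0.43,10
17.5,total,76.88,4.99,10
20,egg,4.29,0.02,40
20,L1,2.65,0.04,20
20,L2,3.12,0.07,19
20,L3,18.4,0.5,19
20,pupa,15.51,0.21,17
20,total,43.91,0.57,17
22.5,egg,3.33,0.03,40
22.5,L1,2.28,0.07,18
22.5,L2,2.46,0.08,18
22.5,L3,17.74,0.62,16
22.5,pupa,12.25,0.19,13
22.5,total,37.63,0.58,13
25,egg,2.82,0.02,37
25,L1,1.86,0.04,20
25,L2,2.32,0.04,20
25,L3,13.8,0.38,20
25,pupa,9.57,0.17,18
25,total,29.91,0.74,18
27.5,egg,2.58,0.02,40
27.5,L1,1.62,0.04,19
27.5,L2,2.08,0.05,19
27.5,L3,13.66,0.49,17
27.5,pupa,8.07,0.25,13
27.5,total,27.64,0.48,13
30,egg,2.18,0.02,36
30,L1,1.38,0.02,17
30,L2,1.66,0.08,17
30,L3,10.56,0.47,16
30,pupa,7.48,0.16,8
30,total,22.18,0.42,7
32.5,egg,2.1,0.02,35
32.5,L1,1.33,0.03,17
32.5,L2,1.78,0.04,17
32.5,L3,9.02,0.58,6
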