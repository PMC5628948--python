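ga_weeks,p05,p10,p25,p50,p75,p90,p95
14,0.224,0.256,0.295,0.348,0.416,0.494,0.592
15,0.331,0.376,0.431,0.505,0.598,0.703,0.834
16,0.562,0.633,0.719,0.835,0.979,1.14,1.33
17,0.958,1.07,1.21,1.39,1.61,1.86,2.15
18,1.45,1.60,1.80,2.06,2.36,2.69,3.09
19,2.09,2.31,2.58,2.91,3.32,3.76,4.27
20,2.95,3.25,3.60,4.04,4.57,5.13,5.78
21,3.98,4.36,4.80,5.37,6.03,6.73,7.53
22,5.06,5.53,6.06,6.74,7.53,8.35,9.29
23,6.26,6.81,7.44,8.24,9.16,10.1,11.2
24,7.70,8.35,9.09,10.0,11.1,12.2,13.5
25,9.41,10.2,11.0,12.1,13.4,14.7,16.1
26,11.4,12.3,13.4,14.6,16.1,17.6,19.3
27,13.8,14.9,16.1,17.6,19.3,21.0,22.9
28,16.5,17.8,19.2,20.9,22.9,25.0,27.2
29,19.5,21.0,22.7,24.7,27.1,29.5,32.1
30,22.8,24.5,26.5,28.9,31.7,34.5,37.6
31,26.3,28.3,30.5,33.4,36.5,39.8,43.4
32,29.9,32.2,34.8,38.0,41.6,45.3,49.5
33,33.7,36.3,39.2,42.8,46.9,51.0,55.7
34,37.6,40.5,43.7,47.7,52.2,56.8,61.9
35,41.6,44.7,48.2,52.6,57.6,62.6,68.2
36,45.6,49.0,52.8,57.5,62.9,68.3,74.3
37,49.6,53.2,57.3,62.4,68.1,74.0,80.4
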