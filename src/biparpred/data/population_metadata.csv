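pop_no,pedigree,tester,n_families,n_snps,gy_ww_mean,gy_ww_sd,gy_ws_mean,gy_ws_sd,ad_ww_mean,ad_ww_sd,ad_ws_mean,ad_ws_sd,ph_ww_mean,ph_ww_sd,ph_ws_mean,ph_ws_sd
1,P1 x P2,T1,165,201,6.98,1.91,2.34,1.48,61.72,8.28,86.78,10.64,215.02,37.06,151.68,49.85
2,P2 x P3,T1,162,188,7.03,2.12,2.69,1.61,62.39,8.57,84.48,11.67,218.53,37.91,152.50,36.14
3,P2 x P4,T1,126,183,7.57,2.64,2.34,1.51,62.66,8.55,86.30,11.88,214.90,39.08,160.57,31.51
4,P2 x P5,T1,163,209,7.62,2.32,2.76,1.48,62.46,8.87,82.17,10.57,215.27,37.90,156.78,34.66
5,P4 x P1,T1,183,208,6.27,2.37,2.81,1.67,64.97,8.25,83.88,9.77,199.38,46.76,155.99,36.42
6,P6 x P7,T1,173,195,6.32,2.15,2.70,1.88,60.32,7.43,74.18,10.83,180.97,34.53,160.08,27.26
7,P8 x P9,T1,181,212,6.67,1.98,2.55,1.69,61.37,6.75,75.22,10.08,192.42,38.06,169.55,22.55
8,P8 x P7,T1,184,212,6.67,1.92,2.59,1.28,60.43,5.15,81.88,11.25,174.38,40.46,139.08,35.87
9,P10 x P11,T1,184,211,7.06,1.91,1.75,1.50,64.26,8.33,89.67,12.57,216.63,44.08,154.39,24.57
10,P12 x P13,T1,174,194,7.31,2.23,2.44,1.62,65.20,8.17,88.47,11.04,220.70,45.49,166.41,29.92
11,P17 x P18,T2,184,185,5.45,1.91,1.99,1.33,63.55,8.10,86.28,17.74,243.99,35.67,177.80,23.01
12,P18 x P19,T2,160,162,6.66,2.84,2.38,1.23,66.04,9.09,84.84,12.85,243.56,38.78,180.78,22.17
13,P19 x P15,T2,178,176,6.38,2.73,1.90,1.05,65.76,8.86,84.83,94.46,242.57,46.75,172.52,24.19
14,P20 x P17,T2,173,166,6.95,2.86,2.03,1.16,64.14,8.77,87.85,12.61,232.14,42.01,166.06,36.08
15,P21 x P22,T2,176,172,6.82,2.87,2.04,1.06,63.08,8.20,85.00,11.33,219.31,33.64,156.47,23.74
16,P22 x P23,T2,155,184,6.63,2.61,1.75,0.99,64.01,8.43,85.22,11.32,233.82,41.48,158.36,28.42
17,P19 x P15,T3,164,255,9.11,0.91,5.55,0.80,100.81,1.56,98.97,1.25,223.02,7.81,192.59,6.87
18,P19 x P26,T3,278,283,9.91,1.31,3.66,0.66,65.64,0.95,79.93,1.57,247.07,10.13,192.29,8.19
19,P19 x P27,T3,216,217,8.37,1.26,4.64,0.94,62.03,1.59,85.59,1.43,251.26,10.49,223.70,8.93
20,P24 x P25,T4,247,199,10.00,1.31,4.88,0.55,62.32,1.04,85.12,1.23,233.92,10.11,211.86,7.68
21,P28 x P29,T5,249,238,2.54,0.48,1.54,0.28,54.38,0.76,64.79,1.38,155.07,9.90,126.86,6.66
22,P30 x P31,T6,245,271,5.38,0.72,1.56,0.33,55.46,0.91,70.82,0.98,232.45,10.94,169.63,7.40
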